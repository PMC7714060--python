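"""Pairwise molecular-evolution machinery.

Implements the quantitative core of the domain/micro-exon comparison:

* global protein alignment (Needleman-Wunsch, affine gaps, BLOSUM62) via
  Biopython's ``PairwiseAligner``, with codon back-threading;
* Nei-Gojobori (1986) counting of synonymous/nonsynonymous sites and
  differences with equal pathway weighting, Jukes-Cantor correction, and
  window-restricted Ka/Ks;
* a one-sided Wilcoxon signed-rank test, exact by enumeration (dynamic
  programming over doubled midranks) for small n, normal approximation with
  continuity correction otherwise;
* Poisson-corrected protein distances, Saitou-Nei neighbor joining with
  deterministic tie-breaking, and nonparametric bootstrap supports.

Distance matrices use :class:`skbio.DistanceMatrix`; trees are
:class:`skbio.TreeNode` (bootstrap supports stored on ``node.support``).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from scipy.stats import norm
from skbio import DistanceMatrix, TreeNode

# --------------------------------------------------------------------------
# genetic code tables
# --------------------------------------------------------------------------
_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
_BASES = "ACGT"

SATURATION_CAP = 10.0


def _check_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon not allowed: {codon}")
    return codon


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------
@dataclass
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float


@dataclass
class CodonAlignment:
    """Codon-level view of a protein alignment; gap columns hold '---'."""

    codons_a: list[str]
    codons_b: list[str]
    col_to_res_a: list[int | None]
    col_to_res_b: list[int | None]

    def __len__(self) -> int:
        return len(self.codons_a)

    def columns_for_residues(self, which: str, residues: tuple[int, int]) -> tuple[int, int]:
        """Alignment-column interval covering a residue interval of one sequence."""
        res_map = self.col_to_res_a if which == "a" else self.col_to_res_b
        cols = [c for c, r in enumerate(res_map) if r is not None and residues[0] <= r < residues[1]]
        if not cols:
            raise ValueError(f"residues {residues} not present in alignment")
        return (cols[0], cols[-1] + 1)


def align_proteins(
    a: str,
    b: str,
    substitution_table: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    id_a: str = "a",
    id_b: str = "b",
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences (affine gap costs).

    Among co-optimal alignments the aligner's deterministic enumeration
    order fixes the result, so repeated runs agree exactly.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    matrix = substitution_matrices.load(substitution_table)
    alphabet = set(str(matrix.alphabet))
    for name, seq in ((id_a, a), (id_b, b)):
        bad = set(seq) - alphabet
        if bad:
            raise ValueError(f"invalid residue(s) {sorted(bad)} in sequence {name}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(a, b)[0]
    return PairwiseAlignment(
        id_a=id_a, id_b=id_b, aligned_a=str(aln[0]), aligned_b=str(aln[1]),
        score=float(aln.score),
    )


def thread_codons(aln: PairwiseAlignment, cds_a: str, cds_b: str) -> CodonAlignment:
    """Replace residue columns of a protein alignment with their codons."""
    from .genes import translate  # local import to avoid a cycle

    for name, aligned, cds in (("a", aln.aligned_a, cds_a), ("b", aln.aligned_b, cds_b)):
        prot = aligned.replace("-", "")
        cds_nostop = cds[:-3] if len(cds) == 3 * (len(prot) + 1) and cds[-3:] in STOP_CODONS else cds
        if len(cds_nostop) != 3 * len(prot):
            raise ValueError(
                f"cds_{name} length {len(cds)} does not match protein length {len(prot)}"
            )
        trans = translate(cds_nostop)
        for i, (x, y) in enumerate(zip(trans, prot)):
            if x != y:
                raise ValueError(
                    f"translation mismatch in sequence {name} at residue {i}: "
                    f"{x} != {y}"
                )

    codons_a: list[str] = []
    codons_b: list[str] = []
    map_a: list[int | None] = []
    map_b: list[int | None] = []
    ia = ib = 0
    for ra, rb in zip(aln.aligned_a, aln.aligned_b):
        if ra == "-":
            codons_a.append("---")
            map_a.append(None)
        else:
            codons_a.append(cds_a[3 * ia:3 * ia + 3])
            map_a.append(ia)
            ia += 1
        if rb == "-":
            codons_b.append("---")
            map_b.append(None)
        else:
            codons_b.append(cds_b[3 * ib:3 * ib + 3])
            map_b.append(ib)
            ib += 1
    return CodonAlignment(codons_a, codons_b, map_a, map_b)


# --------------------------------------------------------------------------
# NG86 counting
# --------------------------------------------------------------------------
@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts of one sense codon.

    Per codon position, the synonymous fraction is computed over the single
    nucleotide changes that do not create a stop codon (stop mutations are
    excluded from numerator and denominator); n = 3 - s.
    """
    codon = _check_codon(codon)
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1:]
            if mut in STOP_CODONS:
                continue
            valid += 1
            if CODON_TO_AA[mut] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return (s, 3.0 - s)


@lru_cache(maxsize=None)
def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts between two codons.

    All minimal mutational pathways (orderings of the differing positions)
    are enumerated with equal weight; pathways passing through a stop codon
    are excluded. Identical codons return (0, 0).
    """
    codon_a, codon_b = _check_codon(codon_a), _check_codon(codon_b)
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return (0.0, 0.0)
    totals: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = codon_a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        # no stop-free pathway (does not occur for standard-code sense pairs,
        # kept as a defensive fallback): weight all pathways equally,
        # classifying stop-passing steps by amino-acid change
        for order in itertools.permutations(diff):
            cur = codon_a
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
                if nxt in STOP_CODONS or CODON_TO_AA.get(nxt) != CODON_TO_AA.get(cur):
                    nd += 1
                else:
                    sd += 1
                cur = nxt
            totals.append((sd, nd))
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return (sd, nd)


@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    n_codons: int


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * np.log1p(-(4.0 / 3.0) * p)


def _comparable(ca: str, cb: str) -> bool:
    return (
        "-" not in ca and "-" not in cb
        and "N" not in ca and "N" not in cb
        and ca not in STOP_CODONS and cb not in STOP_CODONS
    )


def kaks(caln: CodonAlignment, region: tuple[int, int] | None = None) -> KaKsResult:
    """NG86 Ka/Ks over comparable codon columns, optionally window-restricted.

    Site counts are averaged between the two sequences; differences are
    summed; proportions receive the Jukes-Cantor multiple-hit correction.
    The ratio is reported missing (None) when Ks is 0 or the correction is
    undefined (ps or pn >= 3/4).
    """
    lo, hi = region if region is not None else (0, len(caln))
    S = N = Sd = Nd = 0.0
    ncod = 0
    for c in range(lo, hi):
        ca, cb = caln.codons_a[c], caln.codons_b[c]
        if not _comparable(ca, cb):
            continue
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        d_s, d_n = ng86_differences(ca, cb)
        Sd += d_s
        Nd += d_n
        ncod += 1
    if ncod == 0:
        raise ValueError("no comparable codon columns in region")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(ps)
    Ka = _jukes_cantor(pn)
    ratio = None
    if Ks is not None and Ka is not None and Ks > 0:
        ratio = Ka / Ks
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn, Ks=Ks, Ka=Ka,
                      ratio=ratio, n_codons=ncod)


# --------------------------------------------------------------------------
# Wilcoxon signed-rank
# --------------------------------------------------------------------------
@dataclass
class TestResult:
    statistic: float
    n_used: int
    n_zero_dropped: int
    pvalue: float
    alternative: str
    method: str


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _exact_sf_and_cdf(ranks2: np.ndarray) -> np.ndarray:
    """Counts of W2 = sum of a subset of doubled ranks, for all 2^n subsets."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        new = counts.copy()
        new[r:] += counts[:total + 1 - r]
        counts = new
    return counts


def compare_kaks_paired(
    ratios_region: list[float | None],
    ratios_domain: list[float | None],
    alternative: str = "greater",
    exact_threshold: int = 25,
) -> TestResult:
    """One-sided Wilcoxon signed-rank test on paired Ka/Ks ratios.

    Pairs with a missing ratio are dropped, then zero differences are
    dropped (their count is reported). The null distribution is exact (full
    enumeration via dynamic programming over doubled midranks) when the
    retained n is <= ``exact_threshold``, otherwise a normal approximation
    with continuity correction and midrank tie variance is used.
    """
    if len(ratios_region) != len(ratios_domain):
        raise ValueError("paired lists must have equal length")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative: {alternative}")
    diffs = []
    for x, y in zip(ratios_region, ratios_domain):
        if x is None or y is None:
            continue
        x, y = float(x), float(y)
        if np.isnan(x) or np.isnan(y):
            continue
        diffs.append(x - y)
    diffs = np.asarray(diffs, dtype=float)
    n_zero = int(np.sum(diffs == 0))
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        raise ValueError("no usable pairs after dropping missing and zero differences")

    ranks = _midranks(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    w_minus = float(ranks[diffs < 0].sum())

    if n <= exact_threshold:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _exact_sf_and_cdf(ranks2)
        denom = counts.sum()
        w2p = int(round(2 * w_plus))
        w2m = int(round(2 * w_minus))
        p_ge = counts[w2p:].sum() / denom  # P(W+ >= obs)
        p_le_via_minus = counts[w2m:].sum() / denom  # P(W+ <= obs) by symmetry
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le_via_minus
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le_via_minus))
        method = "exact"
    else:
        mean = ranks.sum() / 2.0
        sd = np.sqrt((ranks ** 2).sum() / 4.0)
        if alternative == "greater":
            z = (w_plus - mean - 0.5) / sd
            p = float(norm.sf(z))
        elif alternative == "less":
            z = (w_plus - mean + 0.5) / sd
            p = float(norm.cdf(z))
        else:
            z = (abs(w_plus - mean) - 0.5) / sd
            p = float(2 * norm.sf(z))
        p = min(1.0, max(0.0, p))
        method = "normal-approx"
    return TestResult(statistic=w_plus, n_used=n, n_zero_dropped=n_zero,
                      pvalue=float(p), alternative=alternative, method=method)


# --------------------------------------------------------------------------
# distances, neighbor joining, bootstrap
# --------------------------------------------------------------------------
def poisson_distance(a: str, b: str, cap: float = SATURATION_CAP) -> float:
    """Poisson-corrected distance -ln(1-p) over both-ungapped columns.

    Saturated pairs (p = 1) are set to ``cap``.
    """
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    n = mism = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        n += 1
        if x != y:
            mism += 1
    if n == 0:
        raise ValueError("no comparable columns")
    p = mism / n
    if p >= 1.0:
        return cap
    return float(-np.log(1.0 - p))


def distance_matrix_from_alignment(
    rows: dict[str, str] | list[tuple[str, str]], cap: float = SATURATION_CAP
) -> DistanceMatrix:
    """Pairwise Poisson distances over a set of equal-length aligned rows."""
    items = list(rows.items()) if isinstance(rows, dict) else list(rows)
    names = [n for n, _ in items]
    seqs = [s for _, s in items]
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = poisson_distance(seqs[i], seqs[j], cap=cap)
    return DistanceMatrix(d, ids=names)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the smallest (i, j) index pair in the
    current working order; negative branch lengths are clamped to 0. The
    final three nodes are joined at an (unrooted) trifurcating root via the
    three-point formula.
    """
    ids = list(dm.ids)
    n0 = len(ids)
    if n0 < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    size = 2 * n0
    d = np.zeros((size, size))
    d[:n0, :n0] = dm.data
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    active = list(range(n0))
    nxt = n0

    while len(active) > 3:
        idx = np.array(active)
        sub = d[np.ix_(idx, idx)]
        m = len(idx)
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major argmin = smallest (i, j) tie-break
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(0.0, li), max(0.0, lj)
        ni, nj = nodes[idx[i]], nodes[idx[j]]
        ni.length, nj.length = float(li), float(lj)
        parent = TreeNode(children=[ni, nj])
        nodes.append(parent)
        for k_pos, k in enumerate(idx):
            if k_pos in (i, j):
                continue
            dk = 0.5 * (sub[i, k_pos] + sub[j, k_pos] - dij)
            d[nxt, k] = d[k, nxt] = max(0.0, dk)
        active = [k for k in active if k not in (idx[i], idx[j])] + [nxt]
        nxt += 1

    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    la = max(0.0, (dab + dac - dbc) / 2.0)
    lb = max(0.0, (dab + dbc - dac) / 2.0)
    lc = max(0.0, (dac + dbc - dab) / 2.0)
    for node, ln in zip((nodes[a], nodes[b], nodes[c]), (la, lb, lc)):
        node.length = float(ln)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def _bipartitions(tree: TreeNode, all_taxa: frozenset[str]) -> set[tuple[str, ...]]:
    """Canonical nontrivial bipartitions of an unrooted tree."""
    out: set[tuple[str, ...]] = set()
    n = len(all_taxa)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > n - 2:
            continue
        other = all_taxa - side
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out.add(tuple(sorted(canon)))
    return out


def bootstrap_support(
    rows: dict[str, str] | list[tuple[str, str]],
    n_reps: int = 2000,
    seed: int | None = None,
    cap: float = SATURATION_CAP,
) -> TreeNode:
    """NJ tree from aligned rows with column-bootstrap bipartition supports.

    Columns are resampled with replacement ``n_reps`` times; for each
    replicate the distance matrix and NJ tree are rebuilt and bipartition
    occurrence frequencies (0-100) are recorded on the full-data tree.
    ``n_reps = 0`` returns the tree without supports.
    """
    items = list(rows.items()) if isinstance(rows, dict) else list(rows)
    if len(items) < 4:
        raise ValueError("bootstrap supports need at least 4 taxa")
    names = [n for n, _ in items]
    mat = np.array([list(s) for _, s in items])
    ncols = mat.shape[1]
    if ncols < 1:
        raise ValueError("alignment must have at least one column")

    base_tree = neighbor_joining(
        distance_matrix_from_alignment(items, cap=cap)
    )
    if n_reps == 0:
        return base_tree

    all_taxa = frozenset(names)
    counts: dict[tuple[str, ...], int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        sampled = ["".join(row) for row in mat[:, cols]]
        try:
            tree = neighbor_joining(
                distance_matrix_from_alignment(list(zip(names, sampled)), cap=cap)
            )
        except ValueError:
            continue  # replicate with no comparable columns for some pair
        for bip in _bipartitions(tree, all_taxa):
            counts[bip] = counts.get(bip, 0) + 1

    for node in base_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(all_taxa) - 2:
            continue
        other = all_taxa - side
        canon = tuple(sorted(min(side, other, key=lambda s: (len(s), tuple(sorted(s))))))
        node.support = 100.0 * counts.get(canon, 0) / n_reps
    return base_tree
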
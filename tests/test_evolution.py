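import itertools

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import wilcoxon
from skbio import DistanceMatrix

import mexscan as mx
from mexscan.evolution import (
    SENSE_CODONS,
    STOP_CODONS,
    _bipartitions,
    distance_matrix_from_alignment,
)


# ----------------------------------------------------------------------
# independent brute-force oracles (genetic code consulted via Biopython)
# ----------------------------------------------------------------------
def oracle_sites(codon):
    aa = str(Seq(codon).translate())
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if str(Seq(mut).translate()) == "*":
                continue
            tot += 1
            syn += str(Seq(mut).translate()) == aa
        if tot:
            s += syn / tot
    return s, 3.0 - s


def oracle_differences(a, b):
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if str(Seq(nxt).translate()) == "*":
                ok = False
                break
            sd += str(Seq(nxt).translate()) == str(Seq(cur).translate())
            nd += str(Seq(nxt).translate()) != str(Seq(cur).translate())
            cur = nxt
        if ok:
            paths.append((sd, nd))
    assert paths, f"no stop-free pathway for {a}->{b}"
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def oracle_signed_rank_p(diffs, alternative="greater"):
    """Exact one-sided p by direct enumeration of all sign assignments."""
    diffs = np.asarray([d for d in diffs if d != 0], float)
    n = len(diffs)
    absd = np.abs(diffs)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    i = 0
    sa = absd[order]
    while i < n:
        j = i
        while j + 1 < n and sa[j + 1] == sa[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    w_obs = ranks[diffs > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        if alternative == "greater":
            count += w >= w_obs - 1e-12
        else:
            count += w <= w_obs + 1e-12
    return count / 2 ** n


# ---------------------------------------------------------------- NG86
def test_ng86_sites_worked_values():
    assert mx.ng86_sites("TTT") == pytest.approx((1 / 3, 8 / 3))
    assert mx.ng86_sites("ATG") == (0.0, 3.0)


def test_ng86_sites_conservation_and_errors():
    for codon in SENSE_CODONS:
        s, n = mx.ng86_sites(codon)
        assert s + n == pytest.approx(3.0)
    with pytest.raises(ValueError, match="stop"):
        mx.ng86_sites("TAA")
    with pytest.raises(ValueError, match="invalid"):
        mx.ng86_sites("AXG")


def test_ng86_differences_worked_values():
    assert mx.ng86_differences("TTT", "TTT") == (0.0, 0.0)
    assert mx.ng86_differences("TTT", "TTC") == (1.0, 0.0)  # Phe->Phe
    assert mx.ng86_differences("TTT", "GTC") == (1.0, 1.0)  # both 2-step paths
    with pytest.raises(ValueError):
        mx.ng86_differences("TAA", "TTT")


def test_ng86_matches_oracle_on_sample():
    rng = np.random.default_rng(7)
    codons = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=40)]
    for a, b in zip(codons[:20], codons[20:]):
        assert mx.ng86_sites(a) == pytest.approx(oracle_sites(a))
        assert mx.ng86_differences(a, b) == pytest.approx(oracle_differences(a, b))


# ---------------------------------------------------------------- alignment
def test_align_identical_sequences_gapless():
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    seq = "MKVLW"
    aln = mx.align_proteins(seq, seq)
    assert aln.aligned_a == aln.aligned_b == seq
    assert aln.score == sum(m[c, c] for c in seq)


def test_align_single_gap_placement_is_optimal():
    aln = mx.align_proteins("MKV", "MV")
    assert aln.aligned_a.replace("-", "") == "MKV"
    assert aln.aligned_b.replace("-", "") == "MV"
    # brute force: enumerate every gapped placement of MV against MKV
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")

    def score(a, b, open_=10, ext=1):
        s, gap = 0.0, False
        for x, y in zip(a, b):
            if x == "-" or y == "-":
                s -= ext if gap else open_
                gap = True
            else:
                s += m[x, y]
                gap = False
        return s

    candidates = [("MKV", "-MV"), ("MKV", "M-V"), ("MKV", "MV-")]
    best = max(score(a, b) for a, b in candidates)
    assert aln.score == best
    assert score(aln.aligned_a, aln.aligned_b) == best


def test_align_rejects_empty_or_invalid():
    with pytest.raises(ValueError, match="empty"):
        mx.align_proteins("", "MK")
    with pytest.raises(ValueError, match="invalid residue"):
        mx.align_proteins("M1K", "MK")


def test_thread_codons_gapless_gaps_and_errors():
    aln = mx.align_proteins("MK", "MK")
    caln = mx.thread_codons(aln, "ATGAAA", "ATGAAG")
    assert caln.codons_a == ["ATG", "AAA"] and caln.codons_b == ["ATG", "AAG"]

    aln2 = mx.align_proteins("MKV", "MV")
    caln2 = mx.thread_codons(aln2, "ATGAAAGTT", "ATGGTC")
    assert "---" in caln2.codons_b
    assert [c for c in caln2.codons_b if c != "---"] == ["ATG", "GTC"]

    with pytest.raises(ValueError, match="length"):
        mx.thread_codons(aln, "ATGAAATT", "ATGAAG")
    with pytest.raises(ValueError, match="mismatch"):
        mx.thread_codons(aln, "ATGCCC", "ATGAAG")  # CCC is Pro, not Lys


# ---------------------------------------------------------------- Ka/Ks
def _identical_caln(n=100, seed=0):
    rng = np.random.default_rng(seed)
    cds = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, size=n))
    prot = mx.translate(cds + "TAA")
    aln = mx.align_proteins(prot, prot)
    return mx.thread_codons(aln, cds, cds)


def test_kaks_identical_sequences():
    res = mx.kaks(_identical_caln())
    assert res.Ka == res.Ks == 0.0
    assert res.ratio is None
    assert res.S + res.N == pytest.approx(3 * res.n_codons)


def test_kaks_region_none_equals_full_and_symmetry():
    rng = np.random.default_rng(3)
    anc = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, size=120))
    a, b = mx.evolve_pair(anc + "TAA", 0.5, 0.2, seed=5)
    caln = mx.thread_codons(mx.align_proteins(mx.translate(a), mx.translate(b)), a, b)
    full = mx.kaks(caln)
    region = mx.kaks(caln, region=(0, len(caln)))
    assert (full.Sd, full.Nd, full.Ka, full.Ks) == (region.Sd, region.Nd, region.Ka, region.Ks)
    # symmetry in the two sequences
    caln_sw = mx.thread_codons(mx.align_proteins(mx.translate(b), mx.translate(a)), b, a)
    sw = mx.kaks(caln_sw)
    assert sw.Sd == pytest.approx(full.Sd) and sw.Nd == pytest.approx(full.Nd)
    assert sw.ratio == pytest.approx(full.ratio)


def test_kaks_disjoint_windows_sum_exactly():
    caln = _identical_caln(n=60, seed=9)
    a, b = mx.evolve_pair("".join(caln.codons_a), 0.4, 0.25, seed=1)
    caln = mx.thread_codons(mx.align_proteins(mx.translate(a), mx.translate(b)), a, b)
    w1, w2 = mx.kaks(caln, (0, 20)), mx.kaks(caln, (20, 60))
    full = mx.kaks(caln, (0, 60))
    assert w1.Sd + w2.Sd == pytest.approx(full.Sd)
    assert w1.Nd + w2.Nd == pytest.approx(full.Nd)
    assert w1.S + w2.S == pytest.approx(full.S)
    assert w1.N + w2.N == pytest.approx(full.N)


def test_kaks_empty_region_errors():
    caln = _identical_caln(n=10)
    with pytest.raises(ValueError, match="no comparable"):
        mx.kaks(caln, region=(0, 0))


# ---------------------------------------------------------------- Wilcoxon
def test_wilcoxon_n3_all_positive_exact():
    res = mx.compare_kaks_paired([1.0, 2.0, 3.0], [0.1, 0.2, 0.3])
    assert res.pvalue == pytest.approx(0.125)
    assert res.method == "exact" and res.n_used == 3


def test_wilcoxon_drops_missing_and_zero_pairs():
    res = mx.compare_kaks_paired([1.0, None, 2.0, 3.0], [1.0, 0.5, 1.0, 1.0])
    assert res.n_used == 2 and res.n_zero_dropped == 1
    with pytest.raises(ValueError, match="no usable pairs"):
        mx.compare_kaks_paired([1.0, 2.0], [1.0, 2.0])


@settings(max_examples=40)
@given(st.lists(st.integers(min_value=-50, max_value=50), min_size=1, max_size=10))
def test_wilcoxon_exact_matches_enumeration(diffs):
    if all(d == 0 for d in diffs):
        return
    x = [float(d) for d in diffs]
    y = [0.0] * len(x)
    for alternative in ("greater", "less"):
        mine = mx.compare_kaks_paired(x, y, alternative=alternative)
        assert mine.pvalue == pytest.approx(
            oracle_signed_rank_p(x, alternative), abs=1e-12
        )


def test_wilcoxon_exact_matches_scipy_without_ties():
    rng = np.random.default_rng(11)
    x = rng.normal(0.2, 1.0, size=20)
    res = mx.compare_kaks_paired(list(x), [0.0] * 20, alternative="greater")
    ref = wilcoxon(x, alternative="greater", method="exact")
    assert res.pvalue == pytest.approx(ref.pvalue)
    assert res.statistic == ref.statistic


def test_wilcoxon_normal_approximation_close_to_exact_at_n25():
    rng = np.random.default_rng(4)
    x = list(rng.normal(0.3, 1.0, size=25))
    y = [0.0] * 25
    exact = mx.compare_kaks_paired(x, y, exact_threshold=25)
    approx = mx.compare_kaks_paired(x, y, exact_threshold=0)
    assert approx.method == "normal-approx"
    assert abs(exact.pvalue - approx.pvalue) < 0.01


# ---------------------------------------------------------------- distances / NJ
def test_poisson_distance_values():
    assert mx.poisson_distance("MKV", "MKV") == 0.0
    a = "A" * 10
    b = "A" * 9 + "C"
    assert mx.poisson_distance(a, b) == pytest.approx(-np.log(0.9))
    assert mx.poisson_distance("AAA", "CCC") == 10.0  # saturated -> cap
    with pytest.raises(ValueError, match="no comparable"):
        mx.poisson_distance("--", "A-")


def test_nj_three_taxon_closed_form():
    dm = DistanceMatrix(np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float),
                        ids=["A", "B", "C"])
    tree = mx.neighbor_joining(dm)
    lengths = {t.name: t.length for t in tree.children}
    assert lengths == {"A": 1.0, "B": 1.0, "C": 2.0}
    with pytest.raises(ValueError, match="at least 3"):
        mx.neighbor_joining(DistanceMatrix(np.zeros((2, 2)), ids=["A", "B"]))


def test_nj_recovers_planted_additive_trees():
    # build additive matrices from random planted trees via skbio TreeNode
    from skbio import TreeNode

    rng = np.random.default_rng(21)
    for n_taxa in (4, 6, 8):
        taxa = [f"t{i}" for i in range(n_taxa)]
        subtrees = [TreeNode(name=t) for t in taxa]
        while len(subtrees) > 1:
            i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
            b = subtrees.pop(j)
            a = subtrees.pop(i)
            a.length = float(rng.uniform(0.1, 1.0))
            b.length = float(rng.uniform(0.1, 1.0))
            subtrees.append(TreeNode(children=[a, b]))
        planted = subtrees[0]
        dm = planted.tip_tip_distances()
        est = mx.neighbor_joining(DistanceMatrix(dm.data, ids=list(dm.ids)))
        est_d = est.tip_tip_distances()
        for x, y in itertools.combinations(taxa, 2):
            assert est_d[x, y] == pytest.approx(dm[x, y], abs=1e-9)
        # topology: unrooted bipartitions match
        all_taxa = frozenset(taxa)
        assert _bipartitions(est, all_taxa) == _bipartitions(planted, all_taxa)


def test_nj_matches_skbio_on_random_matrix():
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(5)
    n = 6
    pts = rng.uniform(0, 1, size=(n, 4))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])
    mine = mx.neighbor_joining(dm)
    ref = skbio_nj(dm)
    all_taxa = frozenset(dm.ids)
    assert _bipartitions(mine, all_taxa) == _bipartitions(ref, all_taxa)


def test_nj_taxon_order_invariance():
    rng = np.random.default_rng(13)
    d = rng.uniform(0.5, 2.0, size=(5, 5))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    ids = [f"x{i}" for i in range(5)]
    t1 = mx.neighbor_joining(DistanceMatrix(d, ids=ids))
    perm = [3, 1, 4, 0, 2]
    t2 = mx.neighbor_joining(
        DistanceMatrix(d[np.ix_(perm, perm)], ids=[ids[i] for i in perm])
    )
    all_taxa = frozenset(ids)
    assert _bipartitions(t1, all_taxa) == _bipartitions(t2, all_taxa)


# ---------------------------------------------------------------- bootstrap
ROWS = {
    "A": "A" * 30,
    "B": "A" * 28 + "CC",
    "C": "T" * 30,
    "D": "T" * 28 + "GG",
}


def test_bootstrap_high_support_for_clear_split():
    tree = mx.bootstrap_support(ROWS, n_reps=200, seed=1)
    sups = [n.support for n in tree.non_tips(include_self=False)
            if getattr(n, "support", None) is not None]
    assert sups and max(sups) >= 95


def test_bootstrap_seeded_reproducible_and_zero_reps():
    t1 = mx.bootstrap_support(ROWS, n_reps=50, seed=42)
    t2 = mx.bootstrap_support(ROWS, n_reps=50, seed=42)
    s1 = sorted(n.support for n in t1.non_tips(include_self=False)
                if getattr(n, "support", None) is not None)
    s2 = sorted(n.support for n in t2.non_tips(include_self=False)
                if getattr(n, "support", None) is not None)
    assert s1 == s2
    t0 = mx.bootstrap_support(ROWS, n_reps=0, seed=0)
    assert all(getattr(n, "support", None) is None
               for n in t0.non_tips(include_self=False))


def test_distance_matrix_from_alignment_symmetry():
    dm = distance_matrix_from_alignment(ROWS)
    assert np.allclose(dm.data, dm.data.T)
    assert np.all(np.diag(dm.data) == 0)
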
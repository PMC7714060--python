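"""Synthetic genomes with planted micro-exon/domain ground truth.

The generator emits a genome FASTA, a GFF3 annotation, an InterProScan-style
domain table and a JSON ground-truth file that are mutually consistent by
construction. Gene blueprints mirror the architectures seen in rice
(MH63-like defaults): ERF/DREB genes with a single AP2 domain, AP2-subfamily
genes with two AP2 repeats carrying 9-nt (R1M1) or 26+31-nt tandem (R1M2,
R1M3) micro-exons in R1 and a 45-nt micro-exon (R2M1) in R2, RAV (AP2+B3)
and "other" architectures, and MIKC genes (SRF-TF + K-box) whose K-box
C-terminal region is encoded by a tandem micro-exon pair (M1, M2).

Planted counts are deterministic (never sampled), so enrichment fractions
round-trip exactly through the pipeline. Intron/UTR lengths are uniform
draws from configured ranges and chromosome background sequence is i.i.d.
uniform over ACGT; splice-site motifs and indel evolution are deliberately
not modeled.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coords import GenomicInterval
from .evolution import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, ng86_sites
from .genes import reverse_complement
from .io import AnnotationSet, RawGene, RawTranscript, write_gff3

_BASES = np.array(list("ACGT"))


# --------------------------------------------------------------------------
# blueprints: (protein_len, domains, cds cut points, planted micro-exons)
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class PlantedMicro:
    segment_index: int      # == exon index in transcript orientation
    coding_length: int
    type_label: str         # expected pipeline type label
    in_domain: bool
    domain: str             # expected domain context ("AP2/R1", "K-box", "none")


@dataclass(frozen=True)
class Blueprint:
    family: str
    subfamily: str | None
    protein_len: int
    domains: tuple[tuple[str, int, int], ...]  # (accession, res_start, res_end)
    cuts: tuple[int, ...]                      # CDS cut points (nt, sorted)
    micros: tuple[PlantedMicro, ...]


BLUEPRINTS: dict[str, Blueprint] = {
    "erf": Blueprint("AP2/ERF", "ERF/DREB", 220, (("PF00847", 50, 110),), (300,), ()),
    "erf_micro_in": Blueprint(
        "AP2/ERF", "ERF/DREB", 220, (("PF00847", 50, 110),), (180, 192),
        (PlantedMicro(1, 12, "unclassified", True, "AP2/R1"),)),
    "erf_micro_out": Blueprint(
        "AP2/ERF", "ERF/DREB", 220, (("PF00847", 50, 110),), (420, 429),
        (PlantedMicro(1, 9, "unclassified", False, "none"),)),
    "ap2_r1m1": Blueprint(
        "AP2/ERF", "AP2", 350, (("PF00847", 100, 160), ("PF00847", 180, 240)),
        (360, 369),
        (PlantedMicro(1, 9, "R1M1", True, "AP2/R1"),)),
    "ap2_triple": Blueprint(
        "AP2/ERF", "AP2", 350, (("PF00847", 100, 160), ("PF00847", 180, 240)),
        (330, 356, 387, 600, 645),
        (PlantedMicro(1, 26, "R1M2", True, "AP2/R1"),
         PlantedMicro(2, 31, "R1M3", True, "AP2/R1"),
         PlantedMicro(4, 45, "R2M1", True, "AP2/R2"))),
    "rav": Blueprint(
        "AP2/ERF", "RAV", 300, (("PF00847", 20, 80), ("PF02362", 150, 250)), (), ()),
    "other": Blueprint(
        "AP2/ERF", "other", 260, (("PF00847", 30, 90), ("PF13966", 150, 200)),
        (390,), ()),
    "mikc": Blueprint(
        "MIKC", None, 240, (("PF00319", 1, 59), ("PF01486", 80, 160)),
        (387, 429, 474),
        (PlantedMicro(1, 42, "M1", True, "K-box"),
         PlantedMicro(2, 45, "M2", True, "K-box"))),
    "mikc_nterm": Blueprint(
        "MIKC", None, 240, (("PF00319", 1, 59), ("PF01486", 80, 160)),
        (189, 198, 387, 429, 474),
        (PlantedMicro(1, 9, "unclassified", False, "none"),
         PlantedMicro(3, 42, "M1", True, "K-box"),
         PlantedMicro(4, 45, "M2", True, "K-box"))),
}


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic genome.

    Defaults mirror the MH63-like family census: 141 AP2/ERF genes
    (113 ERF/DREB of which two carry an in-domain micro-exon, 22 AP2
    subfamily, 4 RAV, 2 other) and 31 MIKC genes, most with the C-terminal
    K-box tandem micro-exon pair.
    """

    seed: int
    n_erf: int = 113
    n_erf_micro_in: int = 2
    n_erf_micro_out: int = 0
    n_ap2_r1m1: int = 12
    n_ap2_triple: int = 10
    n_rav: int = 4
    n_other: int = 2
    n_mikc: int = 27
    n_mikc_nterm: int = 4
    minus_strand_probability: float = 0.5
    force_strand: str | None = None
    intron_length_range: tuple[int, int] = (80, 300)
    utr5_range: tuple[int, int] = (30, 150)
    utr3_range: tuple[int, int] = (50, 200)
    spacer_range: tuple[int, int] = (200, 500)
    n_chromosomes: int = 2
    alt_isoform_every: int = 5  # every k-th gene gets a shorter second isoform

    def gene_plan(self) -> list[str]:
        plan = []
        plan += ["erf"] * (self.n_erf - self.n_erf_micro_in - self.n_erf_micro_out)
        plan += ["erf_micro_in"] * self.n_erf_micro_in
        plan += ["erf_micro_out"] * self.n_erf_micro_out
        plan += ["ap2_r1m1"] * self.n_ap2_r1m1
        plan += ["ap2_triple"] * self.n_ap2_triple
        plan += ["rav"] * self.n_rav
        plan += ["other"] * self.n_other
        plan += ["mikc"] * self.n_mikc
        plan += ["mikc_nterm"] * self.n_mikc_nterm
        return plan

    @classmethod
    def for_enrichment(
        cls,
        seed: int,
        ap2_fraction: float = 0.768,
        n_ap2_family_microexons: int = 250,
        kbox_fraction: float = 0.923,
        n_mikc_genes: int = 60,
        **kwargs,
    ) -> "SyntheticConfig":
        """Config whose planted in-domain proportions hit the targets exactly.

        AP2/ERF: ``round(f * N)`` micro-exons are planted inside AP2 domains
        (via R1M1 and R1M2/R1M3/R2M1 architectures) and the remainder outside
        domains in ERF/DREB genes. MIKC: every gene carries the in-K-box
        tandem pair; the number of genes with an extra out-of-domain
        micro-exon is chosen so the planted fraction matches the target at
        the printed precision.
        """
        n_in = round(ap2_fraction * n_ap2_family_microexons)
        n_out = n_ap2_family_microexons - n_in
        n_triple = n_in // 6
        n_r1m1 = n_in - 3 * n_triple
        n_nterm = round(2 * n_mikc_genes * (1 - kbox_fraction) / kbox_fraction)
        return cls(
            seed=seed,
            n_erf=n_out + 5, n_erf_micro_in=0, n_erf_micro_out=n_out,
            n_ap2_r1m1=n_r1m1, n_ap2_triple=n_triple,
            n_rav=2, n_other=1,
            n_mikc=n_mikc_genes - n_nterm, n_mikc_nterm=n_nterm,
            **kwargs,
        )


@dataclass
class GroundTruth:
    families: dict[str, tuple[str, str | None]] = field(default_factory=dict)
    microexons: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "families": {g: list(v) for g, v in self.families.items()},
            "microexons": self.microexons,
        }, indent=2, sort_keys=True)


@dataclass
class SyntheticBundle:
    fasta: Path
    gff3: Path
    domains: Path
    truth_json: Path
    truth: GroundTruth
    config: SyntheticConfig


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx) + "TAA"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _phases(seg_lens: list[int]) -> list[int]:
    phases = []
    cum = 0
    for ln in seg_lens:
        phases.append((3 - cum % 3) % 3)
        cum += ln
    return phases


def _build_gene(
    gene_id: str, chrom: str, strand: str, bp: Blueprint,
    rng: np.random.Generator, cfg: SyntheticConfig, with_alt_isoform: bool,
):
    """Return (local_seq, RawGene in gene-local coordinates, domain rows)."""
    cds_total = 3 * bp.protein_len + 3
    cuts = [0, *bp.cuts, cds_total]
    seg_lens = [cuts[i + 1] - cuts[i] for i in range(len(cuts) - 1)]
    cds_nt = _random_cds(rng, bp.protein_len)
    u5 = int(rng.integers(*cfg.utr5_range))
    u3 = int(rng.integers(*cfg.utr3_range))
    introns = [int(rng.integers(*cfg.intron_length_range))
               for _ in range(len(seg_lens) - 1)]

    cursor = 0
    local_exons: list[tuple[int, int]] = []
    local_cds: list[tuple[int, int]] = []
    for i, seg in enumerate(seg_lens):
        ex_start = cursor
        if i == 0:
            cursor += u5
        cs = cursor
        cursor += seg
        ce = cursor
        if i == len(seg_lens) - 1:
            cursor += u3
        local_exons.append((ex_start, cursor))
        local_cds.append((cs, ce))
        if i < len(introns):
            cursor += introns[i]
    L = cursor

    seq = list(_random_seq(rng, L))
    pos = 0
    for cs, ce in local_cds:
        seq[cs:ce] = cds_nt[pos:pos + (ce - cs)]
        pos += ce - cs
    seq = "".join(seq)

    if strand == "-":
        seq = reverse_complement(seq)
        flip = lambda iv: (L - iv[1], L - iv[0])  # noqa: E731
        local_exons = [flip(iv) for iv in local_exons]
        local_cds = [flip(iv) for iv in local_cds]

    phases = _phases(seg_lens)

    def iv(p):
        return GenomicInterval(chrom, p[0], p[1], strand)

    tid = f"{gene_id}.1"
    tr = RawTranscript(
        id=tid,
        interval=iv((min(e[0] for e in local_exons), max(e[1] for e in local_exons))),
        exons=[iv(e) for e in local_exons],
        cds=[(iv(c), ph) for c, ph in zip(local_cds, phases)],
    )
    transcripts = [tr]

    if with_alt_isoform and len(seg_lens) > 1:
        # shorter isoform: CDS truncated at a codon boundary inside segment 2
        keep = (seg_lens[0] + min(seg_lens[1], 30)) // 3 * 3
        ordered = sorted(local_cds, key=lambda c: c[0], reverse=(strand == "-"))
        alt_cds: list[tuple[int, int]] = []  # transcript order
        remaining = keep
        for cs, ce in ordered:
            take = min(ce - cs, remaining)
            if take <= 0:
                break
            alt_cds.append((cs, cs + take) if strand == "+" else (ce - take, ce))
            remaining -= take
        ph = _phases([c[1] - c[0] for c in alt_cds])
        alt = RawTranscript(
            id=f"{gene_id}.2", interval=tr.interval,
            exons=list(tr.exons),
            cds=[(iv(c), p) for c, p in zip(alt_cds, ph)],
        )
        transcripts.append(alt)

    gene = RawGene(
        id=gene_id,
        interval=iv((min(e[0] for e in local_exons), max(e[1] for e in local_exons))),
        transcripts=transcripts,
    )
    domain_rows = [
        (tid, acc, bp.protein_len, rs, re_) for acc, rs, re_ in bp.domains
    ]
    return seq, gene, domain_rows


def _shift_gene(gene: RawGene, offset: int) -> RawGene:
    def sh(ivl: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(ivl.chrom, ivl.start + offset, ivl.end + offset, ivl.strand)

    return RawGene(
        id=gene.id, interval=sh(gene.interval),
        transcripts=[
            RawTranscript(
                id=t.id, interval=sh(t.interval),
                exons=[sh(e) for e in t.exons],
                cds=[(sh(c), p) for c, p in t.cds],
            ) for t in gene.transcripts
        ],
    )


def generate_genome(config: SyntheticConfig, outdir: str | Path) -> SyntheticBundle:
    """Emit FASTA + GFF3 + domain TSV + ground-truth JSON for ``config``.

    The same seed yields byte-identical files. Raises when a blueprint
    plants a micro-exon longer than its domain window (infeasible
    architecture).
    """
    for bp in BLUEPRINTS.values():
        for m in bp.micros:
            if m.in_domain:
                dom = next(
                    (d for d in bp.domains if _expected_domain_matches(m.domain, d)),
                    None,
                )
                if dom is not None and m.coding_length > 3 * (dom[2] - dom[1]):
                    raise ValueError(
                        f"infeasible architecture: {m.coding_length}-nt micro-exon "
                        f"exceeds domain window {dom}"
                    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    plan = config.gene_plan()

    chrom_parts: dict[str, list[str]] = {
        f"chr{i + 1}": [] for i in range(config.n_chromosomes)
    }
    chrom_cursor = {c: 0 for c in chrom_parts}
    genes: list[RawGene] = []
    domain_rows: list[tuple] = []
    truth = GroundTruth()

    for gi, kind in enumerate(plan):
        bp = BLUEPRINTS[kind]
        gene_id = f"SYN{gi + 1:04d}"
        chrom = f"chr{(gi % config.n_chromosomes) + 1}"
        if config.force_strand is not None:
            strand = config.force_strand
        else:
            strand = "-" if rng.random() < config.minus_strand_probability else "+"
        with_alt = config.alt_isoform_every > 0 and (gi % config.alt_isoform_every == 2)
        seq, gene, drows = _build_gene(gene_id, chrom, strand, bp, rng, config, with_alt)
        spacer = int(rng.integers(*config.spacer_range))
        chrom_parts[chrom].append(_random_seq(rng, spacer))
        chrom_cursor[chrom] += spacer
        genes.append(_shift_gene(gene, chrom_cursor[chrom]))
        chrom_parts[chrom].append(seq)
        chrom_cursor[chrom] += len(seq)
        domain_rows.extend(drows)
        truth.families[gene_id] = (bp.family, bp.subfamily)
        for m in bp.micros:
            truth.microexons.append({
                "gene": gene_id,
                "exon_index": m.segment_index,
                "coding_length": m.coding_length,
                "type": m.type_label,
                "in_domain": m.in_domain,
                "domain": m.domain,
            })

    fasta_path = outdir / "genome.fasta"
    with fasta_path.open("w") as fh:
        for chrom in sorted(chrom_parts):
            fh.write(f">{chrom}\n")
            seq = "".join(chrom_parts[chrom])
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")

    gff_path = outdir / "annotation.gff3"
    write_gff3(AnnotationSet(genes=genes), gff_path)

    dom_path = outdir / "domains.tsv"
    with dom_path.open("w") as fh:
        for pid, acc, plen, rs, re_ in domain_rows:
            # InterProScan column layout; residue coords 1-based inclusive
            fh.write(
                f"{pid}\t-\t{plen}\tPfam\t{acc}\tsynthetic domain\t{rs + 1}\t{re_}\n"
            )

    truth_path = outdir / "truth.json"
    truth_path.write_text(truth.to_json() + "\n")
    return SyntheticBundle(
        fasta=fasta_path, gff3=gff_path, domains=dom_path,
        truth_json=truth_path, truth=truth, config=config,
    )


def _expected_domain_matches(label: str, dom: tuple[str, int, int]) -> bool:
    acc = dom[0]
    if label.startswith("AP2"):
        return acc in ("PF00847", "PF00876")
    if label == "K-box":
        return acc == "PF01486"
    return False


# --------------------------------------------------------------------------
# ortholog-pair evolution
# --------------------------------------------------------------------------
def _syn_fraction_sites(cds: str) -> float:
    """Total synonymous sites of a CDS (independent per-codon counting)."""
    total = 0.0
    for i in range(0, len(cds), 3):
        total += ng86_sites(cds[i:i + 3])[0]
    return total


def evolve_pair(
    ancestor_cds: str,
    omega: float,
    target_ks: float,
    seed: int,
    proposal_cap: int | None = None,
) -> tuple[str, str]:
    """Diverge two lineages from an ancestor under an acceptance-probability model.

    Random single-nucleotide substitutions are proposed alternately on the
    two lineages; synonymous proposals are always accepted, nonsynonymous
    ones with probability ``omega`` and stop-creating ones never. The walk
    stops once the realized synonymous divergence — accepted synonymous
    events per ancestral synonymous site, counted by the per-codon site
    oracle, independent of any downstream estimator — reaches ``target_ks``.
    """
    if len(ancestor_cds) % 3 != 0:
        raise ValueError("ancestor CDS length must be divisible by 3")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    for i in range(0, len(ancestor_cds), 3):
        if ancestor_cds[i:i + 3] in STOP_CODONS and i < len(ancestor_cds) - 3:
            raise ValueError(f"internal stop codon at nt {i}")
    anc = ancestor_cds[:-3] if ancestor_cds[-3:] in STOP_CODONS else ancestor_cds
    L = len(anc)
    s_sites = _syn_fraction_sites(anc)
    if s_sites <= 0:
        raise ValueError("ancestor has no synonymous sites")
    rng = np.random.default_rng(seed)
    seqs = [list(anc), list(anc)]
    syn_events = 0
    if proposal_cap is None:
        proposal_cap = max(10_000, int(200 * s_sites * max(target_ks, 0.01)))
    proposals = 0
    while syn_events / s_sites < target_ks:
        if proposals >= proposal_cap:
            raise RuntimeError(
                f"target synonymous divergence {target_ks} unreachable within "
                f"{proposal_cap} proposals (omega={omega})"
            )
        proposals += 1
        lineage = int(rng.integers(0, 2))
        pos = int(rng.integers(0, L))
        cur = seqs[lineage]
        base = cur[pos]
        alt = "ACGT".replace(base, "")[int(rng.integers(0, 3))]
        c0 = pos - pos % 3
        codon = "".join(cur[c0:c0 + 3])
        mut = codon[:pos - c0] + alt + codon[pos - c0 + 1:]
        if mut in STOP_CODONS:
            continue
        if CODON_TO_AA[mut] == CODON_TO_AA[codon]:
            cur[pos] = alt
            syn_events += 1
        elif rng.random() < omega:
            cur[pos] = alt
    return "".join(seqs[0]), "".join(seqs[1])


# --------------------------------------------------------------------------
# expression tables
# --------------------------------------------------------------------------
def generate_tpm(
    gene_ids: list[str],
    conditions: list[str],
    seed: int,
    tissue_specific: dict[str, str] | None = None,
    specificity_fold: float = 20.0,
):
    """Lognormal TPM table (genes x conditions) with optional planted
    tissue-specific genes (``gene -> condition`` with elevated expression)."""
    import pandas as pd

    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    rng = np.random.default_rng(seed)
    mat = rng.lognormal(mean=1.5, sigma=1.0, size=(len(gene_ids), len(conditions)))
    df = pd.DataFrame(mat, index=gene_ids, columns=conditions)
    for gene, cond in (tissue_specific or {}).items():
        df.loc[gene, cond] *= specificity_fold
    return df
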
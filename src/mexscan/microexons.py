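"""Micro-exon calling, domain overlap, positional typing and tandem detection.

A micro-exon is an exon whose *coding* portion is at most ``threshold_nt``
nucleotides (default 51). Coding length is measured on the CDS-overlapping
part of the exon only — UTR bases cannot overlap a protein domain, so they
do not count toward the threshold. First and last coding exons are eligible:
the C-terminal K-box tandem pair sits at the end of the coding region in
many MIKC genes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .coords import GenomicInterval, interval_overlap
from .genes import GeneModel, build_coordinate_map
from .io import DomainHit

DEFAULT_THRESHOLD_NT = 51


@dataclass
class MicroExon:
    gene_id: str
    transcript_id: str
    exon_index: int
    genomic: GenomicInterval
    coding_length: int
    cds_start: int
    cds_end: int
    res_start: int
    res_end: int
    start_partial: bool = False
    end_partial: bool = False
    is_first_coding: bool = False
    is_last_coding: bool = False
    domain_label: str = "none"
    type_label: str | None = None
    tandem_group: int | None = None

    @property
    def residues(self) -> tuple[int, int]:
        return (self.res_start, self.res_end)


@dataclass(frozen=True)
class TypeRule:
    """One positional micro-exon class: name, domain context, exact coding length."""

    name: str
    context: str  # R1, R2, K-box, ...
    length_nt: int
    position: str = "any"  # any | internal | N-terminal | C-terminal


@dataclass
class MicroExonTypeConfig:
    rules: list[TypeRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.rules]
        if len(names) != len(set(names)):
            raise ValueError("duplicate type names in MicroExonTypeConfig")
        for r in self.rules:
            if not (0 < r.length_nt):
                raise ValueError(f"non-positive length for type {r.name}")


#: The four positional classes recurrently observed in AP2-subfamily genes:
#: 9/26/31-nt micro-exons in the N-terminal AP2 repeat (R1) and a 45-nt
#: micro-exon in the C-terminal repeat (R2).
DEFAULT_TYPE_CONFIG = MicroExonTypeConfig(rules=[
    TypeRule("R1M1", "R1", 9),
    TypeRule("R1M2", "R1", 26),
    TypeRule("R1M3", "R1", 31),
    TypeRule("R2M1", "R2", 45),
])


def call_microexons(
    gene: GeneModel, threshold_nt: int = DEFAULT_THRESHOLD_NT
) -> list[MicroExon]:
    """Call micro-exons on the representative transcript of ``gene``.

    One MicroExon per exon whose CDS-overlapping portion has length in
    [1, threshold_nt]. Exons without CDS overlap (pure UTR) are skipped.
    """
    if gene.representative is None:
        return []
    t = gene.representative_transcript
    if not t.valid or not t.is_coding:
        return []
    cmap = build_coordinate_map(t)
    L = cmap.cds_length
    out: list[MicroExon] = []
    for idx, exon in enumerate(t.exons):
        lo_cds = None
        hi_cds = None
        g_lo = None
        g_hi = None
        coding = 0
        for b in cmap.blocks:
            s, e = max(exon.start, b.g_start), min(exon.end, b.g_end)
            if s >= e:
                continue
            coding += e - s
            if t.strand == "+":
                cs = b.cds_start + (s - b.g_start)
                ce = b.cds_start + (e - b.g_start)
            else:
                cs = b.cds_start + (b.g_end - e)
                ce = b.cds_start + (b.g_end - s)
            lo_cds = cs if lo_cds is None else min(lo_cds, cs)
            hi_cds = ce if hi_cds is None else max(hi_cds, ce)
            g_lo = s if g_lo is None else min(g_lo, s)
            g_hi = e if g_hi is None else max(g_hi, e)
        if coding == 0 or not (1 <= coding <= threshold_nt):
            continue
        out.append(MicroExon(
            gene_id=gene.id,
            transcript_id=t.id,
            exon_index=idx,
            genomic=GenomicInterval(t.chrom, g_lo, g_hi, t.strand),
            coding_length=coding,
            cds_start=lo_cds,
            cds_end=hi_cds,
            res_start=lo_cds // 3,
            res_end=math.ceil(hi_cds / 3),
            start_partial=lo_cds % 3 != 0,
            end_partial=hi_cds % 3 != 0,
            is_first_coding=lo_cds == 0,
            is_last_coding=hi_cds == L,
        ))
    return out


def assign_domain(
    micro: MicroExon, hits: list[DomainHit], min_overlap_aa: int = 1
) -> MicroExon:
    """Label ``micro`` with the domain hit its residues overlap most.

    Overlap is computed on the closed (partial-codon-inclusive) residue
    projection; ties go to the N-terminal-most hit. AP2 hits carry their
    repeat label (``AP2/R1``); SRF-TF is reported as ``MADS-box``.
    """
    best = None
    best_key = None
    for h in hits:
        ov = interval_overlap((micro.res_start, micro.res_end), (h.start, h.end))
        if ov >= min_overlap_aa:
            key = (-ov, h.start)
            if best_key is None or key < best_key:
                best, best_key = h, key
    if best is None:
        micro.domain_label = "none"
    elif best.label == "AP2":
        micro.domain_label = f"AP2/{best.repeat_label or 'R1'}"
    elif best.label == "SRF-TF":
        micro.domain_label = "MADS-box"
    else:
        micro.domain_label = best.label
    return micro


def _position_class(micro: MicroExon) -> str:
    if micro.is_first_coding:
        return "N-terminal"
    if micro.is_last_coding:
        return "C-terminal"
    return "internal"


def _context(micro: MicroExon) -> str:
    if micro.domain_label.startswith("AP2/"):
        return micro.domain_label.split("/", 1)[1]
    return micro.domain_label


def classify_type(
    micro: MicroExon, config: MicroExonTypeConfig = DEFAULT_TYPE_CONFIG
) -> str:
    """Match a micro-exon against the positional type configuration.

    The unique rule matching (domain context, exact coding length, position
    class) wins; no match yields "unclassified"; two matches indicate a
    malformed configuration and raise ``ValueError``.
    """
    ctx = _context(micro)
    pos = _position_class(micro)
    matches = [
        r for r in config.rules
        if r.context == ctx
        and r.length_nt == micro.coding_length
        and r.position in ("any", pos)
    ]
    if len(matches) > 1:
        raise ValueError(
            f"ambiguous type configuration: {[r.name for r in matches]} all match"
        )
    micro.type_label = matches[0].name if matches else "unclassified"
    return micro.type_label


def detect_tandem(micros: list[MicroExon]) -> list[list[MicroExon]]:
    """Group maximal runs of consecutive-exon micro-exons on one transcript.

    Groups of length >= 2 are tandem; within K-box context members are
    labeled M1, M2, ... in 5'->3' order (the common two-exon arrangement at
    the K-box C terminus).
    """
    micros = sorted(micros, key=lambda m: m.exon_index)
    groups: list[list[MicroExon]] = []
    run: list[MicroExon] = []
    for m in micros:
        if run and m.exon_index == run[-1].exon_index + 1:
            run.append(m)
        else:
            if len(run) >= 2:
                groups.append(run)
            run = [m]
    if len(run) >= 2:
        groups.append(run)
    for gid, group in enumerate(groups, start=1):
        for m in group:
            m.tandem_group = gid
        if all(m.domain_label == "K-box" for m in group):
            for k, m in enumerate(group, start=1):
                m.type_label = f"M{k}"
    return groups


def summarize_overlap(
    micros: list[MicroExon],
    families: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-family micro-exon counts and in-domain fractions.

    ``families`` maps gene id -> family name (AP2/ERF, MIKC, none). The
    denominator for each family row is the number of micro-exons in genes of
    that family; "in domain" means the family's hallmark domain (AP2 repeats
    for AP2/ERF, K-box for MIKC). A genome-wide row counts overlap with any
    domain. Empty groups report a missing (NaN) fraction.
    """
    families = families or {}

    def fam_of(m: MicroExon) -> str:
        return families.get(m.gene_id, "none")

    rows = []
    specs = [
        ("AP2/ERF", lambda m: fam_of(m) == "AP2/ERF",
         lambda m: m.domain_label.startswith("AP2")),
        ("MIKC", lambda m: fam_of(m) == "MIKC",
         lambda m: m.domain_label == "K-box"),
        ("all", lambda m: True, lambda m: m.domain_label not in ("none", "")),
    ]
    for name, in_group, in_domain in specs:
        grp = [m for m in micros if in_group(m)]
        n = len(grp)
        k = sum(1 for m in grp if in_domain(m))
        rows.append({
            "group": name,
            "n_microexons": n,
            "n_in_domain": k,
            "fraction": (k / n) if n else float("nan"),
        })
    return pd.DataFrame(rows)


def microexon_table(micros: list[MicroExon]) -> pd.DataFrame:
    """Flatten micro-exons into the report-table layout."""
    cols = ["gene", "transcript", "exon_index", "chrom", "start", "end", "strand",
            "coding_length", "residues", "domain_label", "type_label", "tandem_group"]
    rows = [{
        "gene": m.gene_id, "transcript": m.transcript_id, "exon_index": m.exon_index,
        "chrom": m.genomic.chrom, "start": m.genomic.start, "end": m.genomic.end,
        "strand": m.genomic.strand, "coding_length": m.coding_length,
        "residues": f"{m.res_start}-{m.res_end}", "domain_label": m.domain_label,
        "type_label": m.type_label, "tandem_group": m.tandem_group,
    } for m in micros]
    return pd.DataFrame(rows, columns=cols)
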
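"""Readers and writers for the formats the pipeline consumes and emits.

FASTA parsing is delegated to Biopython, GFF3 parsing to gffutils and newick
serialization to scikit-bio; this module only converts between on-disk
conventions (1-based inclusive GFF3/InterProScan coordinates) and the
package-internal 0-based half-open convention (:mod:`mexscan.coords`).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

from .coords import GenomicInterval, to_one_based, to_zero_based

#: Accession -> domain label used throughout the pipeline. PF00847 is the
#: canonical Pfam AP2 family; PF00876 is accepted as an AP2 synonym as well so
#: that scans reporting either accession are not silently dropped.
DEFAULT_ACCESSION_MAP: dict[str, str] = {
    "PF00847": "AP2",
    "PF00876": "AP2",
    "PF02362": "B3",
    "PF00319": "SRF-TF",
    "PF01486": "K-box",
}


@dataclass(frozen=True)
class FastaRecord:
    """A named sequence (nucleotide or amino acid)."""

    id: str
    sequence: str


@dataclass
class RawTranscript:
    id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    # (interval, phase); phase is None when the GFF3 column held "."
    cds: list[tuple[GenomicInterval, int | None]] = field(default_factory=list)


@dataclass
class RawGene:
    id: str
    interval: GenomicInterval
    transcripts: list[RawTranscript] = field(default_factory=list)


@dataclass
class AnnotationSet:
    """Gene -> mRNA -> exon/CDS feature graph parsed from a GFF3 file."""

    genes: list[RawGene] = field(default_factory=list)


@dataclass
class DomainHit:
    """A domain interval in protein coordinates (0-based half-open)."""

    protein_id: str
    accession: str
    label: str
    start: int
    end: int
    repeat_label: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Sequences are uppercased; record order is preserved. Duplicate ids and
    empty files raise ``ValueError``.
    """
    records: list[FastaRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id: {rec.id}")
            seen.add(rec.id)
            records.append(FastaRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def fasta_as_dict(records: list[FastaRecord]) -> dict[str, str]:
    return {r.id: r.sequence for r in records}


def read_gff3(path: str | Path) -> AnnotationSet:
    """Parse a GFF3 file with gene/mRNA/exon/CDS rows into an AnnotationSet.

    1-based inclusive coordinates are converted to 0-based half-open.
    CDS phase is retained. A CDS or mRNA row whose Parent cannot be resolved
    raises ``ValueError``.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[RawGene] = []
    seen_mrnas: set[str] = set()
    seen_cds = 0
    for g in db.features_of_type("gene", order_by="start"):
        gs, ge = to_zero_based(g.start, g.end)
        gene = RawGene(id=g.id, interval=GenomicInterval(g.seqid, gs, ge, g.strand))
        for m in db.children(g.id, featuretype="mRNA", order_by="start"):
            ms, me = to_zero_based(m.start, m.end)
            tr = RawTranscript(
                id=m.id, interval=GenomicInterval(m.seqid, ms, me, m.strand)
            )
            for ex in db.children(m.id, featuretype="exon", order_by="start"):
                es, ee = to_zero_based(ex.start, ex.end)
                tr.exons.append(GenomicInterval(ex.seqid, es, ee, ex.strand))
            for c in db.children(m.id, featuretype="CDS", order_by="start"):
                cs, ce = to_zero_based(c.start, c.end)
                phase = None if c.frame in (None, ".", "") else int(c.frame)
                tr.cds.append(
                    (GenomicInterval(c.seqid, cs, ce, c.strand), phase)
                )
                seen_cds += 1
            seen_mrnas.add(m.id)
            gene.transcripts.append(tr)
        genes.append(gene)

    n_mrna = sum(1 for _ in db.features_of_type("mRNA"))
    n_cds = sum(1 for _ in db.features_of_type("CDS"))
    if n_mrna != len(seen_mrnas):
        raise ValueError("mRNA feature(s) without a resolvable parent gene")
    if n_cds != seen_cds:
        raise ValueError("CDS feature(s) without a resolvable parent mRNA")
    return AnnotationSet(genes=genes)


def write_gff3(annotation: AnnotationSet, path: str | Path) -> None:
    """Serialize an AnnotationSet back to GFF3 (inverse of :func:`read_gff3`)."""
    lines = ["##gff-version 3"]

    def row(chrom, ftype, start0, end0, strand, attrs, phase="."):
        s1, e1 = to_one_based(start0, end0)
        return f"{chrom}\t.\t{ftype}\t{s1}\t{e1}\t.\t{strand}\t{phase}\t{attrs}"

    for gene in annotation.genes:
        gi = gene.interval
        lines.append(row(gi.chrom, "gene", gi.start, gi.end, gi.strand, f"ID={gene.id}"))
        for tr in gene.transcripts:
            ti = tr.interval
            lines.append(
                row(ti.chrom, "mRNA", ti.start, ti.end, ti.strand,
                    f"ID={tr.id};Parent={gene.id}")
            )
            for k, ex in enumerate(sorted(tr.exons, key=lambda e: e.start)):
                lines.append(
                    row(ex.chrom, "exon", ex.start, ex.end, ex.strand,
                        f"ID={tr.id}.exon{k};Parent={tr.id}")
                )
            for k, (cd, phase) in enumerate(sorted(tr.cds, key=lambda c: c[0].start)):
                lines.append(
                    row(cd.chrom, "CDS", cd.start, cd.end, cd.strand,
                        f"ID={tr.id}.cds{k};Parent={tr.id}",
                        phase="." if phase is None else str(phase))
                )
    Path(path).write_text("\n".join(lines) + "\n")


def _merge_same_label(hits: list[DomainHit]) -> list[DomainHit]:
    """Merge overlapping same-label hits on one protein into their union."""
    hits = sorted(hits, key=lambda h: (h.start, h.end))
    merged: list[DomainHit] = []
    for h in hits:
        if merged and h.start < merged[-1].end:
            prev = merged[-1]
            warnings.warn(
                f"merging overlapping {h.label} hits on {h.protein_id}: "
                f"[{prev.start},{prev.end}) + [{h.start},{h.end})"
            )
            merged[-1] = DomainHit(
                protein_id=prev.protein_id, accession=prev.accession,
                label=prev.label, start=prev.start, end=max(prev.end, h.end),
            )
        else:
            merged.append(h)
    return merged


def read_domain_table(
    path: str | Path, accession_map: dict[str, str] | None = None
) -> list[DomainHit]:
    """Read a domain-hit table in InterProScan TSV column layout.

    Accepts either the full InterProScan layout (protein id, MD5, length,
    analysis, accession, description, start, end, ...) or a minimal 4-column
    layout (protein id, accession, start, end). Coordinates in the file are
    1-based inclusive protein coordinates and are converted to 0-based
    half-open. Overlapping same-label hits on one protein are merged into
    their union (with a warning); hits of the same label are then numbered
    R1, R2, ... from the N terminus.
    """
    accession_map = DEFAULT_ACCESSION_MAP if accession_map is None else accession_map
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] >= 8:
        cols = (0, 4, 6, 7)
    elif df.shape[1] >= 4:
        cols = (0, 1, 2, 3)
    else:
        raise ValueError(f"domain table needs >= 4 tab-separated columns, got {df.shape[1]}")

    raw: list[DomainHit] = []
    for _, r in df.iterrows():
        pid, acc = str(r[cols[0]]), str(r[cols[1]])
        try:
            s1, e1 = int(r[cols[2]]), int(r[cols[3]])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"non-numeric domain coordinates for {pid}/{acc}: "
                f"{r[cols[2]]!r}, {r[cols[3]]!r}"
            ) from exc
        s0, e0 = to_zero_based(s1, e1)
        raw.append(
            DomainHit(protein_id=pid, accession=acc,
                      label=accession_map.get(acc, "other"), start=s0, end=e0)
        )

    # merge overlaps and assign repeat labels per (protein, label)
    out: list[DomainHit] = []
    groups: dict[tuple[str, str], list[DomainHit]] = {}
    for h in raw:
        groups.setdefault((h.protein_id, h.label), []).append(h)
    for (_, _), hits in groups.items():
        merged = _merge_same_label(hits)
        for k, h in enumerate(merged):
            h.repeat_label = f"R{k + 1}"
            out.append(h)
    out.sort(key=lambda h: (h.protein_id, h.start, h.label))
    return out


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write a tree as newick; internal-node supports become node labels."""
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf names in tree")
    out = tree.copy()
    for node in out.non_tips(include_self=False):
        sup = getattr(node, "support", None)
        if sup is not None:
            node.name = f"{sup:g}"
            # scikit-bio would otherwise emit its own "support:name" label
            node.support = None
    buf = StringIO()
    out.write(buf, format="newick")
    Path(path).write_text(buf.getvalue())


def read_newick(path: str | Path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.non_tips(include_self=False):
        if node.name is not None:
            try:
                node.support = float(node.name)
            except ValueError:
                pass
    return tree


def write_report_tables(result, outdir: str | Path) -> dict[str, Path]:
    """Materialize a scan result as TSV tables plus a JSON run manifest.

    Writes per-group summary counts, per-gene family assignments, the
    per-micro-exon table and (when computed) the Ka/Ks pair and test tables.
    Missing values are written as ".".
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write to output directory {outdir}: {exc}") from exc

    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame | None):
        if df is None:
            return
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, na_rep=".")
        written[name] = p

    emit("summary", result.summary)
    emit("families", result.families)
    emit("microexons", result.microexons)
    emit("kaks_pairs", getattr(result, "kaks_pairs", None))
    emit("kaks_tests", getattr(result, "kaks_tests", None))
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")
    written["manifest"] = manifest_path
    return written
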
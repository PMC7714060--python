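"""Transcript models, CDS splicing/translation and coordinate projection.

The projection machinery maps intervals among three spaces: genomic
(0-based half-open on a chromosome), CDS (offsets 0..L along the spliced,
phase-trimmed coding sequence) and protein (residue indices 0..L/3). On the
"-" strand CDS offset 0 corresponds to the highest genomic coordinate.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .coords import GenomicInterval
from .io import AnnotationSet

log = logging.getLogger(__name__)


@dataclass
class CdsSegment:
    interval: GenomicInterval
    phase: int | None


@dataclass
class TranscriptModel:
    """One isoform: exons and CDS segments ordered 5'->3' in transcript orientation."""

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[CdsSegment] = field(default_factory=list)
    valid: bool = True
    invalid_reason: str | None = None
    cds_seq: str | None = None
    protein: str | None = None

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)


@dataclass
class GeneModel:
    id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    representative: str | None = None

    @property
    def representative_transcript(self) -> TranscriptModel:
        if self.representative is None:
            raise ValueError(f"no representative selected for gene {self.id}")
        for t in self.transcripts:
            if t.id == self.representative:
                return t
        raise ValueError(f"representative {self.representative} not in gene {self.id}")


@dataclass(frozen=True)
class CdsBlock:
    cds_start: int
    cds_end: int
    g_start: int
    g_end: int


@dataclass
class CdsCoordinateMap:
    """Ordered pairing of genomic blocks with contiguous CDS offsets."""

    transcript_id: str
    chrom: str
    strand: str
    blocks: list[CdsBlock]

    @property
    def cds_length(self) -> int:
        return self.blocks[-1].cds_end if self.blocks else 0

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3


@dataclass(frozen=True)
class ProteinProjection:
    """Residue interval covering a genomic interval, with partial-codon flags."""

    res_start: int
    res_end: int
    start_partial: bool
    end_partial: bool


def assemble_transcripts(annotation: AnnotationSet) -> list[GeneModel]:
    """Build GeneModels with exons/CDS ordered 5'->3' in transcript orientation.

    Transcripts whose CDS segments are not contained in any exon are flagged
    invalid and their CDS is dropped (logged as a warning).
    """
    genes: list[GeneModel] = []
    for raw in annotation.genes:
        gene = GeneModel(id=raw.id, chrom=raw.interval.chrom, strand=raw.interval.strand)
        for rt in raw.transcripts:
            rev = rt.interval.strand == "-"
            exons = sorted(rt.exons, key=lambda e: e.start, reverse=rev)
            cds = sorted(rt.cds, key=lambda c: c[0].start, reverse=rev)
            t = TranscriptModel(
                id=rt.id, gene_id=raw.id, chrom=rt.interval.chrom,
                strand=rt.interval.strand, exons=exons,
                cds=[CdsSegment(interval=c, phase=p) for c, p in cds],
            )
            for seg in t.cds:
                if not any(ex.contains(seg.interval) for ex in t.exons):
                    t.valid = False
                    t.invalid_reason = (
                        f"CDS segment [{seg.interval.start},{seg.interval.end}) "
                        f"not contained in any exon"
                    )
                    log.warning("transcript %s flagged invalid: %s", t.id, t.invalid_reason)
                    break
            gene.transcripts.append(t)
        genes.append(gene)
    return genes


def select_representative(gene: GeneModel) -> str:
    """Return the id of the transcript with the longest protein.

    Ties break by lexicographically smallest transcript id. Raises when the
    gene has no valid coding transcript with a computed protein.
    """
    candidates = [
        t for t in gene.transcripts if t.valid and t.is_coding and t.protein
    ]
    if not candidates:
        raise ValueError(f"gene {gene.id} has no valid coding transcript")
    best = min(candidates, key=lambda t: (-len(t.protein), t.id))
    return best.id


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def splice_cds(transcript: TranscriptModel, genome: dict[str, str]) -> str:
    """Concatenate CDS segments 5'->3', reverse-complementing on "-" strand.

    Leading bases are trimmed according to the first segment's phase
    ("." counts as 0). A final length not divisible by 3 flags the
    transcript invalid (the sequence is still returned).
    """
    if transcript.chrom not in genome:
        raise KeyError(f"chromosome {transcript.chrom} not in genome")
    chrom_seq = genome[transcript.chrom]
    parts: list[str] = []
    for seg in transcript.cds:
        iv = seg.interval
        if iv.end > len(chrom_seq):
            raise ValueError(
                f"CDS segment [{iv.start},{iv.end}) exceeds {transcript.chrom} "
                f"length {len(chrom_seq)}"
            )
        s = chrom_seq[iv.start:iv.end]
        parts.append(reverse_complement(s) if transcript.strand == "-" else s)
    seq = "".join(parts)
    phase = transcript.cds[0].phase or 0 if transcript.cds else 0
    seq = seq[phase:]
    if len(seq) % 3 != 0:
        transcript.valid = False
        transcript.invalid_reason = f"CDS length {len(seq)} not divisible by 3"
    return seq


def translate(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    A single trailing stop codon is trimmed. Codons containing ambiguous
    bases translate to "X". Raises on length not divisible by 3; an internal
    stop raises ``ValueError`` (callers flag the transcript invalid).
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValueError(f"internal stop codon at residue {prot.index('*')}")
    return prot


def finalize_gene(gene: GeneModel, genome: dict[str, str]) -> GeneModel:
    """Splice/translate every transcript and pick the representative isoform.

    Transcripts that fail splicing or translation are flagged invalid; a gene
    with no surviving coding transcript keeps ``representative = None`` (it is
    excluded from the family scan downstream).
    """
    for t in gene.transcripts:
        if not t.valid or not t.is_coding:
            continue
        try:
            t.cds_seq = splice_cds(t, genome)
            if t.valid:
                t.protein = translate(t.cds_seq)
        except (ValueError, KeyError) as exc:
            t.valid = False
            t.invalid_reason = str(exc)
            log.warning("transcript %s flagged invalid: %s", t.id, exc)
    try:
        gene.representative = select_representative(gene)
    except ValueError:
        gene.representative = None
        log.warning("gene %s excluded: no valid coding transcript", gene.id)
    return gene


def build_coordinate_map(transcript: TranscriptModel) -> CdsCoordinateMap:
    """Pair genomic blocks with CDS offsets for a valid coding transcript."""
    if not transcript.is_coding:
        raise ValueError(f"transcript {transcript.id} has no CDS")
    blocks: list[CdsBlock] = []
    off = 0
    for i, seg in enumerate(transcript.cds):
        gs, ge = seg.interval.start, seg.interval.end
        if i == 0:
            phase = seg.phase or 0
            if transcript.strand == "+":
                gs += phase
            else:
                ge -= phase
        if ge <= gs:
            continue
        blocks.append(CdsBlock(off, off + (ge - gs), gs, ge))
        off += ge - gs
    return CdsCoordinateMap(
        transcript_id=transcript.id, chrom=transcript.chrom,
        strand=transcript.strand, blocks=blocks,
    )


def protein_interval_to_genomic(
    cmap: CdsCoordinateMap, residues: tuple[int, int]
) -> list[GenomicInterval]:
    """Genomic blocks covering CDS nucleotides [3*start, 3*end).

    Blocks are returned in transcript (5'->3') order and may be split across
    CDS segments.
    """
    rs, re_ = residues
    if rs < 0 or re_ > cmap.protein_length or re_ <= rs:
        raise ValueError(
            f"residue interval [{rs},{re_}) outside protein of length "
            f"{cmap.protein_length}"
        )
    lo, hi = 3 * rs, 3 * re_
    out: list[GenomicInterval] = []
    for b in cmap.blocks:
        s, e = max(lo, b.cds_start), min(hi, b.cds_end)
        if s >= e:
            continue
        if cmap.strand == "+":
            gs = b.g_start + (s - b.cds_start)
            ge = b.g_start + (e - b.cds_start)
        else:
            gs = b.g_end - (e - b.cds_start)
            ge = b.g_end - (s - b.cds_start)
        out.append(GenomicInterval(cmap.chrom, gs, ge, cmap.strand))
    return out


def genomic_interval_to_protein(
    cmap: CdsCoordinateMap, g: GenomicInterval
) -> ProteinProjection | None:
    """Smallest residue interval whose codons intersect ``g``.

    Returns ``None`` when ``g`` does not intersect the CDS. Partial-codon
    flags mark boundaries where ``g`` cuts a codon, so the residue interval
    is a closed cover (superset) of the touched residues.
    """
    if g.chrom != cmap.chrom:
        return None
    lo = None
    hi = None
    for b in cmap.blocks:
        is_, ie = max(g.start, b.g_start), min(g.end, b.g_end)
        if is_ >= ie:
            continue
        if cmap.strand == "+":
            cs = b.cds_start + (is_ - b.g_start)
            ce = b.cds_start + (ie - b.g_start)
        else:
            cs = b.cds_start + (b.g_end - ie)
            ce = b.cds_start + (b.g_end - is_)
        lo = cs if lo is None else min(lo, cs)
        hi = ce if hi is None else max(hi, ce)
    if lo is None:
        return None
    return ProteinProjection(
        res_start=lo // 3,
        res_end=math.ceil(hi / 3),
        start_partial=lo % 3 != 0,
        end_partial=hi % 3 != 0,
    )
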
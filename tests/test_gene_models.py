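import numpy as np
import pytest

import mexscan as mx
from mexscan.coords import GenomicInterval
from mexscan.genes import (
    CdsSegment,
    GeneModel,
    TranscriptModel,
    build_coordinate_map,
    genomic_interval_to_protein,
    protein_interval_to_genomic,
)
from mexscan.io import AnnotationSet, RawGene, RawTranscript

from conftest import build_gene, random_transcript


def _raw_gene(strand, exon_coords, cds_coords, phases=None):
    phases = phases or [0] * len(cds_coords)
    iv = lambda s, e: GenomicInterval("c", s, e, strand)  # noqa: E731
    lo = min(s for s, _ in exon_coords)
    hi = max(e for _, e in exon_coords)
    tr = RawTranscript(
        id="g.1", interval=iv(lo, hi),
        exons=[iv(s, e) for s, e in exon_coords],
        cds=[(iv(s, e), p) for (s, e), p in zip(cds_coords, phases)],
    )
    return AnnotationSet(genes=[RawGene(id="g", interval=iv(lo, hi), transcripts=[tr])])


def test_assemble_orders_exons_by_strand():
    plus = mx.assemble_transcripts(
        _raw_gene("+", [(0, 10), (20, 30), (40, 50)], [(0, 10)])
    )[0].transcripts[0]
    assert [e.start for e in plus.exons] == [0, 20, 40]

    minus = mx.assemble_transcripts(
        _raw_gene("-", [(100, 150), (200, 250)], [(200, 250), (100, 150)])
    )[0].transcripts[0]
    assert [s.interval.start for s in minus.cds] == [200, 100]  # 5'->3' on "-"


def test_assemble_flags_cds_outside_exon():
    genes = mx.assemble_transcripts(
        _raw_gene("+", [(0, 10)], [(15, 21)])
    )
    t = genes[0].transcripts[0]
    assert not t.valid
    assert "not contained" in t.invalid_reason


def test_noncoding_transcript_retained_without_protein():
    ann = _raw_gene("+", [(0, 30)], [])
    ann.genes[0].transcripts[0].cds = []
    gene = mx.assemble_transcripts(ann)[0]
    mx.finalize_gene(gene, {"c": "A" * 30})
    assert gene.representative is None  # excluded from family scan
    assert gene.transcripts[0].protein is None


@pytest.mark.parametrize(
    "lengths,ids,expected",
    [
        ((120, 250), ("t1", "t2"), "t2"),  # longest protein wins
        ((100, 100), ("t2", "t10"), "t10"),  # tie -> lexicographically smallest
        ((77,), ("only",), "only"),
    ],
)
def test_select_representative(lengths, ids, expected):
    gene = GeneModel(id="g", chrom="c", strand="+")
    for L, tid in zip(lengths, ids):
        t = TranscriptModel(id=tid, gene_id="g", chrom="c", strand="+",
                            cds=[CdsSegment(GenomicInterval("c", 0, 3), 0)])
        t.protein = "M" * L
        gene.transcripts.append(t)
    assert mx.select_representative(gene) == expected


def test_select_representative_requires_coding():
    gene = GeneModel(id="g", chrom="c", strand="+",
                     transcripts=[TranscriptModel(id="t", gene_id="g",
                                                  chrom="c", strand="+")])
    with pytest.raises(ValueError, match="no valid coding"):
        mx.select_representative(gene)


def test_splice_cds_plus_strand_concatenation():
    genome = {"c": "ATGCCCCCCCAAAGGG"}
    t = TranscriptModel(
        id="t", gene_id="g", chrom="c", strand="+",
        cds=[CdsSegment(GenomicInterval("c", 0, 3), 0),
             CdsSegment(GenomicInterval("c", 10, 13), None)],
    )
    assert mx.splice_cds(t, genome) == "ATGAAA"


def test_splice_cds_minus_strand_reverse_complement():
    t = TranscriptModel(
        id="t", gene_id="g", chrom="c", strand="-",
        cds=[CdsSegment(GenomicInterval("c", 0, 3), 0)],
    )
    assert mx.splice_cds(t, {"c": "CAT"}) == "ATG"


def test_splice_cds_phase_trim_and_errors():
    t = TranscriptModel(
        id="t", gene_id="g", chrom="c", strand="+",
        cds=[CdsSegment(GenomicInterval("c", 0, 7), 1)],
    )
    assert mx.splice_cds(t, {"c": "GATGAAATTT"}) == "ATGAAA"  # first base dropped
    assert t.valid

    t2 = TranscriptModel(
        id="t2", gene_id="g", chrom="c", strand="+",
        cds=[CdsSegment(GenomicInterval("c", 0, 4), 0)],
    )
    mx.splice_cds(t2, {"c": "ATGAAA"})
    assert not t2.valid  # length not divisible by 3

    t3 = TranscriptModel(
        id="t3", gene_id="g", chrom="c", strand="+",
        cds=[CdsSegment(GenomicInterval("c", 2, 99), 0)],
    )
    with pytest.raises(ValueError, match="exceeds"):
        mx.splice_cds(t3, {"c": "ATGAAA"})


def test_translate_examples():
    assert mx.translate("ATGAAATAA") == "MK"  # trailing stop trimmed
    with pytest.raises(ValueError, match="internal stop"):
        mx.translate("ATGTAAAAA")
    assert mx.translate("ATGNNAAAA") == "MXK"  # ambiguous codon -> X
    with pytest.raises(ValueError, match="divisible"):
        mx.translate("ATGA")


def test_coordinate_map_blocks_and_conservation():
    t = TranscriptModel(
        id="t", gene_id="g", chrom="c", strand="+",
        cds=[CdsSegment(GenomicInterval("c", 100, 104), 0),
             CdsSegment(GenomicInterval("c", 200, 205), None)],
    )
    cmap = build_coordinate_map(t)
    assert [(b.cds_start, b.cds_end, b.g_start, b.g_end) for b in cmap.blocks] == [
        (0, 4, 100, 104), (4, 9, 200, 205)
    ]
    assert sum(b.cds_end - b.cds_start for b in cmap.blocks) == cmap.cds_length == 9


def test_coordinate_map_minus_strand_offset_zero_is_highest_coordinate():
    t = TranscriptModel(
        id="t", gene_id="g", chrom="c", strand="-",
        cds=[CdsSegment(GenomicInterval("c", 200, 206), 0),
             CdsSegment(GenomicInterval("c", 100, 103), None)],
    )
    cmap = build_coordinate_map(t)
    g = protein_interval_to_genomic(cmap, (0, 1))
    assert (g[0].start, g[0].end) == (203, 206)  # CDS 0 maps to highest coords


def test_protein_interval_to_genomic_split_across_segments():
    t = TranscriptModel(
        id="t", gene_id="g", chrom="c", strand="+",
        cds=[CdsSegment(GenomicInterval("c", 100, 104), 0),
             CdsSegment(GenomicInterval("c", 200, 205), None)],
    )
    cmap = build_coordinate_map(t)
    blocks = protein_interval_to_genomic(cmap, (1, 2))
    assert [(b.start, b.end) for b in blocks] == [(103, 104), (200, 202)]
    with pytest.raises(ValueError, match="outside protein"):
        protein_interval_to_genomic(cmap, (0, 4))


def test_genomic_interval_to_protein_partial_codon_flags():
    t = TranscriptModel(
        id="t", gene_id="g", chrom="c", strand="+",
        cds=[CdsSegment(GenomicInterval("c", 0, 30), 0)],
    )
    cmap = build_coordinate_map(t)
    # one full codon
    p = genomic_interval_to_protein(cmap, GenomicInterval("c", 3, 6))
    assert (p.res_start, p.res_end, p.start_partial, p.end_partial) == (1, 2, False, False)
    # last nt of codon 3 plus all of codon 4 -> residues [2,4), start-partial
    p = genomic_interval_to_protein(cmap, GenomicInterval("c", 8, 12))
    assert (p.res_start, p.res_end) == (2, 4)
    assert p.start_partial and not p.end_partial
    # no CDS intersection
    assert genomic_interval_to_protein(cmap, GenomicInterval("c", 40, 45)) is None


def test_projection_round_trip_property_random_transcripts():
    rng = np.random.default_rng(2024)
    for _ in range(200):
        t, cmap = random_transcript(rng)
        n_res = cmap.protein_length
        if n_res < 2:
            continue
        rs = int(rng.integers(0, n_res - 1))
        re_ = int(rng.integers(rs + 1, n_res + 1))
        blocks = protein_interval_to_genomic(cmap, (rs, re_))
        # conservation: 3 nt per residue on both strands
        assert sum(b.length for b in blocks) == 3 * (re_ - rs)
        # round trip on whole-codon intervals is the identity
        for b in blocks:
            proj = genomic_interval_to_protein(cmap, b)
            assert rs <= proj.res_start and proj.res_end <= re_
        lo = min(b.start for b in blocks)
        hi = max(b.end for b in blocks)
        proj = genomic_interval_to_protein(cmap, GenomicInterval("c", lo, hi, t.strand))
        assert (proj.res_start, proj.res_end) == (rs, re_)
        assert not proj.start_partial and not proj.end_partial


def test_translate_splice_matches_planted_protein():
    gene, genome = build_gene([60, 9, 33], strand="-", seed=5)
    t = gene.representative_transcript
    assert t.protein is not None and len(t.protein) == (60 + 9 + 33) // 3 - 1
    assert mx.translate(mx.splice_cds(t, genome)) == t.protein
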
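import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mexscan.coords import GenomicInterval
from mexscan.genes import (
    CdsSegment,
    GeneModel,
    TranscriptModel,
    build_coordinate_map,
    finalize_gene,
)
from mexscan.simulate import _random_cds

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_gene(
    seg_lens,
    strand="+",
    utr5=6,
    utr3=6,
    intron=20,
    chrom="c1",
    gene_id="g1",
    seed=0,
    cds_nt=None,
):
    """Construct a single-transcript gene plus its genome from CDS segment
    lengths (5'->3' in transcript orientation). Returns (GeneModel, genome).
    """
    rng = np.random.default_rng(seed)
    total = sum(seg_lens)
    if cds_nt is None:
        assert total % 3 == 0
        cds_nt = _random_cds(rng, total // 3 - 1)  # includes trailing TAA
    assert len(cds_nt) == total

    cursor = 0
    exons, cds = [], []
    for i, seg in enumerate(seg_lens):
        ex_start = cursor
        if i == 0:
            cursor += utr5
        cs = cursor
        cursor += seg
        ce = cursor
        if i == len(seg_lens) - 1:
            cursor += utr3
        exons.append((ex_start, cursor))
        cds.append((cs, ce))
        if i < len(seg_lens) - 1:
            cursor += intron
    L = cursor
    seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, size=L)))
    pos = 0
    for cs, ce in cds:
        seq[cs:ce] = cds_nt[pos:pos + (ce - cs)]
        pos += ce - cs
    seq = "".join(seq)

    if strand == "-":
        seq = "".join({"A": "T", "C": "G", "G": "C", "T": "A"}[b] for b in reversed(seq))
        exons = [(L - e, L - s) for s, e in exons]
        cds = [(L - e, L - s) for s, e in cds]

    phases = []
    cum = 0
    for seg in seg_lens:
        phases.append((3 - cum % 3) % 3)
        cum += seg
    t = TranscriptModel(
        id=f"{gene_id}.1", gene_id=gene_id, chrom=chrom, strand=strand,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        cds=[CdsSegment(GenomicInterval(chrom, s, e, strand), p)
             for (s, e), p in zip(cds, phases)],
    )
    gene = GeneModel(id=gene_id, chrom=chrom, strand=strand, transcripts=[t])
    genome = {chrom: seq}
    finalize_gene(gene, genome)
    return gene, genome


def random_transcript(rng):
    """A random multi-segment coding transcript on a random strand."""
    n_seg = int(rng.integers(1, 6))
    seg_lens = [int(rng.integers(1, 40)) for _ in range(n_seg)]
    # pad so total is a positive multiple of 3 and >= 6
    total = sum(seg_lens)
    seg_lens[-1] += (3 - total % 3) % 3
    if sum(seg_lens) < 6:
        seg_lens[-1] += 6
    strand = "+" if rng.random() < 0.5 else "-"
    cursor = int(rng.integers(0, 50))
    cds = []
    for seg in seg_lens:
        cds.append((cursor, cursor + seg))
        cursor += seg + int(rng.integers(10, 60))
    L = cursor + 10
    if strand == "-":
        cds = [(L - e, L - s) for s, e in reversed(cds)]
        cds = list(reversed(cds))  # keep transcript order (descending start)
    t = TranscriptModel(
        id="t", gene_id="g", chrom="c", strand=strand,
        exons=[GenomicInterval("c", s, e, strand) for s, e in cds],
        cds=[CdsSegment(GenomicInterval("c", s, e, strand), 0 if i == 0 else None)
             for i, (s, e) in enumerate(cds)],
    )
    # recompute phases properly (transcript order)
    cum = 0
    for seg in t.cds:
        seg.phase = (3 - cum % 3) % 3
        cum += seg.interval.length
    return t, build_coordinate_map(t)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small synthetic genome exercising every gene blueprint."""
    import mexscan as mx

    cfg = mx.SyntheticConfig(
        seed=11, n_erf=6, n_erf_micro_in=1, n_erf_micro_out=1,
        n_ap2_r1m1=3, n_ap2_triple=3, n_rav=2, n_other=1,
        n_mikc=4, n_mikc_nterm=2,
    )
    return mx.generate_genome(cfg, tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def small_scan(small_bundle):
    import warnings

    import mexscan as mx

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mx.run_scan(mx.RunConfig(
            genome_path=small_bundle.fasta,
            gff3_path=small_bundle.gff3,
            domains_path=small_bundle.domains,
        ))
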
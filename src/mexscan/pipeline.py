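"""End-to-end orchestration: read -> assemble -> classify -> call -> type ->
summarize, with optional Ka/Ks comparison and NJ trees of domain sequences."""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evolution import (
    KaKsResult,
    TestResult,
    align_proteins,
    bootstrap_support,
    compare_kaks_paired,
    kaks,
    thread_codons,
)
from .families import FAMILY_AP2_ERF, FAMILY_MIKC, FamilyAssignment, classify_protein
from .genes import GeneModel, assemble_transcripts, finalize_gene
from .io import (
    DEFAULT_ACCESSION_MAP,
    DomainHit,
    fasta_as_dict,
    read_domain_table,
    read_fasta,
    read_gff3,
    write_newick,
    write_report_tables,
)
from .microexons import (
    DEFAULT_THRESHOLD_NT,
    DEFAULT_TYPE_CONFIG,
    MicroExon,
    MicroExonTypeConfig,
    assign_domain,
    call_microexons,
    classify_type,
    detect_tandem,
    microexon_table,
    summarize_overlap,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome_path: str | Path
    gff3_path: str | Path
    domains_path: str | Path
    tpm_path: str | Path | None = None
    pairs_path: str | Path | None = None
    threshold_nt: int = DEFAULT_THRESHOLD_NT
    accession_map: dict[str, str] | None = None
    type_config: MicroExonTypeConfig | None = None
    min_overlap_aa: int = 1
    outdir: str | Path | None = None
    seed: int = 0
    bootstrap_reps: int = 2000
    alternative: str = "greater"
    build_tree: bool = False

    def __post_init__(self) -> None:
        if self.threshold_nt < 1:
            raise ValueError("threshold_nt must be >= 1")
        for p in (self.genome_path, self.gff3_path, self.domains_path,
                  self.tpm_path, self.pairs_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")


@dataclass
class ScanResult:
    genes: list[GeneModel]
    assignments: dict[str, FamilyAssignment]
    micros: list[MicroExon]
    families: pd.DataFrame
    microexons: pd.DataFrame
    summary: pd.DataFrame
    kaks_pairs: pd.DataFrame | None = None
    kaks_tests: pd.DataFrame | None = None
    trees: dict[str, object] = field(default_factory=dict)
    zscores: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def zscore_expression(tpm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z score of log2(TPM + 1) across conditions.

    Zero-variance rows (including all-zero genes) standardize to all zeros.
    Negative TPM values raise ``ValueError``.
    """
    if (tpm.values < 0).any():
        raise ValueError("TPM values must be non-negative")
    logged = np.log2(tpm + 1.0)
    mean = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=1)
    z = logged.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def _hits_by_gene(
    hits: list[DomainHit], genes: list[GeneModel]
) -> dict[str, list[DomainHit]]:
    """Match domain hits (keyed by protein id) to genes via the
    representative transcript id or the gene id itself."""
    lookup: dict[str, str] = {}
    for g in genes:
        lookup[g.id] = g.id
        if g.representative is not None:
            lookup[g.representative] = g.id
    out: dict[str, list[DomainHit]] = {}
    for h in hits:
        gid = lookup.get(h.protein_id)
        if gid is not None:
            out.setdefault(gid, []).append(h)
    return out


def _family_table(assignments: dict[str, FamilyAssignment]) -> pd.DataFrame:
    rows = []
    for gid in sorted(assignments):
        a = assignments[gid]
        rows.append({
            "gene": gid, "family": a.family,
            "subfamily": a.subfamily if a.subfamily else None,
            "n_AP2": a.count("AP2"), "n_B3": a.count("B3"),
            "n_SRF-TF": a.count("SRF-TF"), "n_K-box": a.count("K-box"),
        })
    cols = ["gene", "family", "subfamily", "n_AP2", "n_B3", "n_SRF-TF", "n_K-box"]
    return pd.DataFrame(rows, columns=cols)


_DOMAIN_FOR_TYPE = {
    "R1": "domain:AP2/R1",
    "R2": "domain:AP2/R2",
    "M": "domain:K-box",
}


def _domain_region_for_type(type_label: str) -> str | None:
    for prefix, dom in _DOMAIN_FOR_TYPE.items():
        if type_label.startswith(prefix):
            return dom
    return None


def _kaks_result_row(gene_a, gene_b, region, res: KaKsResult) -> dict:
    return {
        "gene_a": gene_a, "gene_b": gene_b, "region": region,
        "S": res.S, "N": res.N, "Sd": res.Sd, "Nd": res.Nd,
        "Ka": res.Ka, "Ks": res.Ks, "ratio": res.ratio, "n_codons": res.n_codons,
    }


def compute_pair_kaks(
    gene_a: GeneModel,
    gene_b: GeneModel,
    hits_a: list[DomainHit],
    micros_a: list[MicroExon],
) -> list[dict]:
    """Ka/Ks of whole-domain regions and typed micro-exon windows for a pair.

    Full proteins are aligned globally; regions are gene_a's domain hits and
    typed micro-exons, mapped through the codon alignment.
    """
    ta, tb = gene_a.representative_transcript, gene_b.representative_transcript
    aln = align_proteins(ta.protein, tb.protein, id_a=gene_a.id, id_b=gene_b.id)
    caln = thread_codons(aln, ta.cds_seq, tb.cds_seq)
    rows: list[dict] = []
    for h in hits_a:
        if h.label == "AP2":
            label = f"domain:AP2/{h.repeat_label or 'R1'}"
        elif h.label in ("K-box", "SRF-TF"):
            label = f"domain:{'K-box' if h.label == 'K-box' else 'MADS-box'}"
        else:
            continue
        try:
            region = caln.columns_for_residues("a", (h.start, h.end))
            rows.append(_kaks_result_row(gene_a.id, gene_b.id, label, kaks(caln, region)))
        except ValueError as exc:
            log.warning("skipping %s %s/%s: %s", label, gene_a.id, gene_b.id, exc)
    for m in micros_a:
        if m.type_label in (None, "unclassified"):
            continue
        try:
            region = caln.columns_for_residues("a", (m.res_start, m.res_end))
            rows.append(
                _kaks_result_row(gene_a.id, gene_b.id, m.type_label, kaks(caln, region))
            )
        except ValueError as exc:
            log.warning("skipping %s %s/%s: %s", m.type_label, gene_a.id, gene_b.id, exc)
    return rows


def _kaks_tests(pair_df: pd.DataFrame, alternative: str) -> pd.DataFrame:
    """Paired Wilcoxon tests: each micro-exon type vs its containing domain."""
    rows = []
    types = sorted(
        t for t in pair_df["region"].unique() if not t.startswith("domain:")
    )
    for t in types:
        dom = _domain_region_for_type(t)
        if dom is None:
            continue
        micro = pair_df[pair_df["region"] == t].set_index(["gene_a", "gene_b"])["ratio"]
        domr = pair_df[pair_df["region"] == dom].set_index(["gene_a", "gene_b"])["ratio"]
        joined = pd.concat([micro, domr], axis=1, keys=["micro", "domain"]).dropna()
        if joined.empty:
            continue
        try:
            res: TestResult = compare_kaks_paired(
                joined["micro"].tolist(), joined["domain"].tolist(),
                alternative=alternative,
            )
        except ValueError as exc:
            log.warning("no usable pairs for %s vs %s: %s", t, dom, exc)
            continue
        rows.append({
            "region": t, "vs": dom, "W": res.statistic, "n_used": res.n_used,
            "n_zero_dropped": res.n_zero_dropped, "pvalue": res.pvalue,
            "alternative": res.alternative, "method": res.method,
        })
    return pd.DataFrame(
        rows, columns=["region", "vs", "W", "n_used", "n_zero_dropped",
                       "pvalue", "alternative", "method"],
    )


def _star_profile_rows(seqs: dict[str, str]) -> dict[str, str]:
    """Map every sequence onto the columns of the longest member.

    Each sequence is aligned pairwise to the reference; residues aligned to
    reference columns are kept, insertions relative to the reference are
    dropped. The result is a rectangular profile suitable for distance
    computation (recorded in the manifest as the alignment strategy).
    """
    ref_name = max(seqs, key=lambda k: (len(seqs[k]), k))
    ref = seqs[ref_name]
    rows = {ref_name: ref}
    for name, seq in seqs.items():
        if name == ref_name:
            continue
        aln = align_proteins(ref, seq, id_a=ref_name, id_b=name)
        row = [
            b for a, b in zip(aln.aligned_a, aln.aligned_b) if a != "-"
        ]
        rows[name] = "".join(row)
    return rows


def run_scan(config: RunConfig) -> ScanResult:
    """Execute the full scan and (when ``config.outdir`` is set) write the
    report bundle: TSV tables, newick trees and a JSON run manifest.

    Outputs are held in memory until the run completes, so a failing stage
    leaves no partial files behind.
    """
    genome = _stage("read_genome")(lambda: fasta_as_dict(read_fasta(config.genome_path)))()
    annotation = _stage("read_gff3")(lambda: read_gff3(config.gff3_path))()
    hits = _stage("read_domains")(
        lambda: read_domain_table(config.domains_path, config.accession_map)
    )()

    @_stage("assemble")
    def assemble():
        genes = assemble_transcripts(annotation)
        for g in genes:
            finalize_gene(g, genome)
        return genes

    genes = assemble()
    coding_genes = [g for g in genes if g.representative is not None]
    hits_by_gene = _hits_by_gene(hits, coding_genes)

    @_stage("classify_families")
    def classify():
        return {
            g.id: classify_protein(hits_by_gene.get(g.id, []), gene_id=g.id)
            for g in coding_genes
        }

    assignments = classify()
    families = {g: a.family for g, a in assignments.items()}

    type_config = config.type_config or DEFAULT_TYPE_CONFIG

    @_stage("microexons")
    def scan_micros():
        micros: list[MicroExon] = []
        for g in coding_genes:
            gm = call_microexons(g, threshold_nt=config.threshold_nt)
            for m in gm:
                assign_domain(m, hits_by_gene.get(g.id, []),
                              min_overlap_aa=config.min_overlap_aa)
                classify_type(m, type_config)
            detect_tandem(gm)
            micros.extend(gm)
        return micros

    micros = scan_micros()
    summary = summarize_overlap(micros, families)
    family_df = _family_table(assignments)
    micro_df = microexon_table(micros)

    kaks_pairs_df = None
    kaks_tests_df = None
    if config.pairs_path is not None:
        @_stage("kaks")
        def run_kaks():
            pairs = pd.read_csv(config.pairs_path, sep="\t", header=None,
                                comment="#", names=["gene_a", "gene_b"], dtype=str)
            by_id = {g.id: g for g in coding_genes}
            micros_by_gene: dict[str, list[MicroExon]] = {}
            for m in micros:
                micros_by_gene.setdefault(m.gene_id, []).append(m)
            rows: list[dict] = []
            for _, pr in pairs.iterrows():
                ga, gb = by_id.get(pr.gene_a), by_id.get(pr.gene_b)
                if ga is None or gb is None:
                    log.warning("pair (%s, %s) skipped: unknown gene", pr.gene_a, pr.gene_b)
                    continue
                rows.extend(compute_pair_kaks(
                    ga, gb, hits_by_gene.get(ga.id, []), micros_by_gene.get(ga.id, [])
                ))
            df = pd.DataFrame(rows, columns=[
                "gene_a", "gene_b", "region", "S", "N", "Sd", "Nd",
                "Ka", "Ks", "ratio", "n_codons"])
            return df, _kaks_tests(df, config.alternative)

        kaks_pairs_df, kaks_tests_df = run_kaks()

    trees: dict[str, object] = {}
    if config.build_tree:
        @_stage("tree")
        def build_trees():
            out = {}
            specs = {
                "AP2_domains": ("AP2", FAMILY_AP2_ERF),
                "Kbox_domains": ("K-box", FAMILY_MIKC),
            }
            for name, (label, family) in specs.items():
                seqs: dict[str, str] = {}
                for g in coding_genes:
                    if assignments[g.id].family != family:
                        continue
                    prot = g.representative_transcript.protein
                    for h in hits_by_gene.get(g.id, []):
                        if h.label != label:
                            continue
                        key = f"{g.id}|{h.repeat_label}" if label == "AP2" else g.id
                        seqs[key] = prot[h.start:h.end]
                if len(seqs) < 4:
                    continue
                rows = _star_profile_rows(seqs)
                out[name] = bootstrap_support(
                    rows, n_reps=config.bootstrap_reps, seed=config.seed
                )
            return out

        trees = build_trees()

    zscores = None
    if config.tpm_path is not None:
        @_stage("zscore")
        def z():
            tpm = pd.read_csv(config.tpm_path, sep="\t", index_col=0)
            return zscore_expression(tpm)

        zscores = z()

    manifest = {
        "mexscan_version": __version__,
        "seed": config.seed,
        "threshold_nt": config.threshold_nt,
        "min_overlap_aa": config.min_overlap_aa,
        "accession_map": config.accession_map or DEFAULT_ACCESSION_MAP,
        "alternative": config.alternative,
        "bootstrap_reps": config.bootstrap_reps,
        "alignment_strategy": "pairwise-to-longest-reference star profile",
        "counts": {
            "genes": len(genes),
            "coding_genes": len(coding_genes),
            "families": {
                f: int(sum(1 for a in assignments.values() if a.family == f))
                for f in sorted({a.family for a in assignments.values()})
            },
            "microexons": len(micros),
        },
        "inputs": {
            "genome": str(config.genome_path),
            "gff3": str(config.gff3_path),
            "domains": str(config.domains_path),
            "tpm": str(config.tpm_path) if config.tpm_path else None,
            "pairs": str(config.pairs_path) if config.pairs_path else None,
        },
    }

    result = ScanResult(
        genes=genes, assignments=assignments, micros=micros,
        families=family_df, microexons=micro_df, summary=summary,
        kaks_pairs=kaks_pairs_df, kaks_tests=kaks_tests_df,
        trees=trees, zscores=zscores, manifest=manifest,
    )

    if config.outdir is not None:
        outdir = Path(config.outdir)
        write_report_tables(result, outdir)
        for name, tree in trees.items():
            write_newick(tree, outdir / f"{name}.nwk")
        if zscores is not None:
            zscores.to_csv(outdir / "expression_zscores.tsv", sep="\t", na_rep=".")
    return result
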
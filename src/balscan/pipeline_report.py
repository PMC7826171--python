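"""End-to-end scan orchestration, ranked candidate tables, and the
ecological-load worked-example calculators.

The scan chains: cosmopolitan SNP calling -> TSP calling against the
outgroup -> genomic class / NS-S annotation -> per-class enrichment ->
H_E filtering -> exon contrasts -> gene-set SFS contrast -> allele trees
with CPD_w-b -> ancient/recent classification -> candidate table ranked by
CPD_w-b. Every stage's randomness derives from one master seed via
stage-name hashing, so outputs are byte-identical across reruns and adding
a stage never perturbs earlier stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .allele_trees import (
    LocusSkipped,
    analyze_locus,
    bonferroni,
    classify_locus,
    default_window,
    extract_window,
)
from .exon_contrast import exon_table, gene_set_sfs_contrast, length_binned_contrast
from .formats_io import (
    longest_transcripts,
    read_fasta,
    read_gff,
    read_phased_vcf,
    read_sync,
    write_newick,
)
from .poolseq_stats import StatFilters
from .simulate import derive_seed
from .tsp_scan import (
    GenomeAnnotation,
    annotate_records,
    enrichment_test,
    filter_by_he,
    scan_sites,
    thin_by_distance,
)

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Paths, thresholds and the master seed for one scan run."""

    fasta: str
    gff: str
    sync: str
    vcf: str
    manifest: str  # JSON: populations, oceans, samples, pool size
    out_dir: str
    maf_threshold: float = 0.05
    thin_distance: int = 500
    he_min: float = 0.30
    promoter_bp: int = 1000
    window_flank_bp: int = 500
    min_coverage: int = 10
    max_coverage: int = 100
    min_count: int = 2
    n_perm: int = 999
    n_boot: int = 200
    alpha: float = 0.05
    seed: int = 1
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must be in (0, 0.5)")
        if not 0 <= self.he_min < 0.5:
            raise ValueError("he_min must be in [0, 0.5)")
        if self.thin_distance < 0 or self.promoter_bp < 0:
            raise ValueError("distances must be non-negative")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")

    def filters(self) -> StatFilters:
        return StatFilters(
            min_coverage=self.min_coverage, max_coverage=self.max_coverage,
            min_count=self.min_count, maf=self.maf_threshold,
        )

    def repro_record(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(
            {"balscan": __version__, "config": payload}, sort_keys=True
        )


@dataclass
class ScanResult:
    config: ScanConfig
    n_snps: int
    n_cosmopolitan: int
    n_tsps: int
    n_tsps_he: int
    n_thinned: int
    candidate_genes: list[str]
    candidate_table: list[dict]
    enrichment: list
    counts_by_stage: dict[str, int] = field(default_factory=dict)


def ecological_load(w_max: float, w_mean: float) -> float:
    """Ecological load Le = (Wmax - Wmean) / Wmax.

    The fitness cost borne by offspring settling in habitats suboptimal for
    their genotype: 0 when mean fitness equals the optimum.
    """
    if w_max <= 0:
        raise ValueError("w_max must be positive")
    if not 0 < w_mean <= w_max:
        raise ValueError("w_mean must satisfy 0 < w_mean <= w_max")
    return (w_max - w_mean) / w_max


def survival_fraction(density_settlement: float, density_maturity: float) -> float:
    """Percent survival from settlement to maturity, to one decimal."""
    if density_settlement <= 0 or density_maturity <= 0:
        raise ValueError("densities must be positive")
    if density_maturity > density_settlement:
        raise ValueError("maturity density cannot exceed settlement density")
    return round(100.0 * density_maturity / density_settlement, 1)


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

def run_scan(config: ScanConfig) -> ScanResult:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = "# " + config.repro_record() + "\n"
    filters = config.filters()

    with open(config.manifest) as fh:
        manifest = json.load(fh)
    populations = manifest["populations"]
    oceans = manifest["oceans"]
    n_chrom = manifest.get("n_chrom_per_pool", 2 * manifest.get("pool_size", 24))
    sample_map = {
        s: (meta["population"], meta["species"])
        for s, meta in manifest["samples"].items()
    }

    refs = read_fasta(config.fasta)
    models = read_gff(config.gff)
    genes = longest_transcripts(models)
    sync_records = list(read_sync(config.sync, populations))
    phased = read_phased_vcf(config.vcf, sample_map)

    contigs_seen = {
        "fasta": set(refs),
        "gff": {m.contig_id for m in models},
        "sync": {r.contig_id for r in sync_records},
        "vcf": set(np.unique(phased.contigs)) if phased.n_sites else set(),
    }
    for src, seen in contigs_seen.items():
        missing = seen - set(refs)
        if missing:
            raise ValueError(f"{src} references contig(s) absent from FASTA: {sorted(missing)}")

    counts: dict[str, int] = {"sync_sites": len(sync_records)}

    outgroup_samples = [s for s, (pop, sp) in sample_map.items() if sp == "outgroup"]
    if not outgroup_samples:
        raise ValueError("manifest declares no outgroup sample")
    og_sample = outgroup_samples[0]

    def outgroup_lookup(contig, pos, ref, alt):
        return phased.genotype_at(contig, pos, og_sample)

    all_snps, tsps = scan_sites(
        sync_records, outgroup_lookup, config.maf_threshold, filters
    )
    counts["snps"] = len(all_snps)
    counts["cosmopolitan"] = sum(r.is_cosmopolitan for r in all_snps)
    counts["tsps"] = len(tsps)

    annotation = GenomeAnnotation(genes, config.promoter_bp)
    annotate_records(all_snps, annotation, refs)

    thinned = thin_by_distance(sorted(all_snps, key=lambda r: (r.contig_id, r.pos)),
                               config.thin_distance)
    counts["thinned_panel"] = len(thinned)

    enrich = enrichment_test(tsps, all_snps)
    tsps_he = filter_by_he(tsps, config.he_min)
    counts["tsps_he"] = len(tsps_he)

    exon_stats = exon_table(genes, sync_records, all_snps, n_chrom, filters)
    counts["exons"] = len(exon_stats)

    # candidate genes: >= 1 nonsynonymous TSP among the H_E-filtered set
    candidates = sorted({
        r.gene_id for r in tsps_he if r.effect == "NS" and r.gene_id is not None
    })
    counts["candidate_genes"] = len(candidates)

    sfs_cand = sfs_other = None
    if candidates:
        gene_of = lambda r: r.gene_id  # noqa: E731
        sfs_cand, sfs_other = gene_set_sfs_contrast(
            candidates, list(genes), all_snps, gene_of,
            n_boot=config.n_boot, seed=derive_seed(config.seed, "sfs"),
        )

    # allele trees per candidate gene, window anchored on its top NS TSP
    basin_map_pop = oceans
    cpd_results, trees = [], {}
    for gene_id in candidates:
        gene_tsps = [r for r in tsps_he if r.gene_id == gene_id and r.effect == "NS"]
        top = max(gene_tsps, key=lambda r: (min(np.mean(list(r.he.values())), 0.5), -r.pos))
        window = default_window(top, genes, config.window_flank_bp)
        try:
            hs = extract_window(top, phased, window)
            res, tree, rooted = analyze_locus(
                gene_id, hs, config.n_perm, derive_seed(config.seed, "perm", gene_id)
            )
        except LocusSkipped as exc:
            logger.info("candidate %s skipped: %s", gene_id, exc)
            cpd_results.append(None)
            trees[gene_id] = (None, False)
            continue
        cpd_results.append(res)
        trees[gene_id] = (tree, rooted)
    kept = [r for r in cpd_results if r is not None]
    bonferroni(kept)
    for r in kept:
        tree, rooted = trees[r.gene_id]
        basin_of_tip = {}
        if tree is not None:
            for t in tree.tips():
                sample = t.name.rsplit(".", 1)[0]
                pop, sp = sample_map.get(sample, (None, None))
                if sp == "focal" and pop in basin_map_pop:
                    basin_of_tip[t.name] = basin_map_pop[pop]
        r.classification = classify_locus(r, tree, basin_of_tip, config.alpha, rooted)
    counts["classified"] = len(kept)

    # ------------------------------------------------------------------ outputs
    _write_tsp_table(out / "tsps.tsv", header, all_snps, populations)
    _write_enrichment(out / "enrichment.tsv", header, enrich)
    _write_exon_stats(out / "exon_stats.tsv", header, exon_stats)
    if sfs_cand is not None:
        _write_sfs(out / "sfs.tsv", header, sfs_cand, sfs_other)
    _write_cpd(out / "cpd_results.tsv", header, kept)
    table = _candidate_table(kept, tsps_he, exon_stats)
    _write_candidates(out / "candidates.tsv", header, table)
    for gene_id, (tree, rooted) in trees.items():
        if tree is not None:
            (out / f"{gene_id}.nwk").write_text(write_newick(tree) + "\n")
    summary = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "counts": counts,
        "candidates": [row["gene_id"] for row in table],
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")

    for stage, n in counts.items():
        logger.info("stage %s: %d records", stage, n)
    return ScanResult(
        config=config, n_snps=counts["snps"], n_cosmopolitan=counts["cosmopolitan"],
        n_tsps=counts["tsps"], n_tsps_he=counts["tsps_he"],
        n_thinned=counts["thinned_panel"], candidate_genes=candidates,
        candidate_table=table, enrichment=enrich, counts_by_stage=counts,
    )


def _candidate_table(cpd_results, tsps_he, exon_stats) -> list[dict]:
    by_gene_tsps: dict[str, list] = {}
    for r in tsps_he:
        if r.gene_id:
            by_gene_tsps.setdefault(r.gene_id, []).append(r)
    exon_by_gene: dict[str, list] = {}
    for e in exon_stats:
        exon_by_gene.setdefault(e.gene_id, []).append(e)
    rows = []
    for res in cpd_results:
        gene_tsps = by_gene_tsps.get(res.gene_id, [])
        exons = exon_by_gene.get(res.gene_id, [])
        pis = [e.mean_pi() for e in exons if e.mean_pi() is not None]
        ds = [e.mean_d() for e in exons if e.mean_d() is not None]
        rows.append({
            "gene_id": res.gene_id,
            "n_tsps": len(gene_tsps),
            "n_ns_tsps": sum(r.effect == "NS" for r in gene_tsps),
            "cpd_wb": res.cpd_wb,
            "p_value": res.p_value,
            "adjusted_p": res.adjusted_p,
            "class": res.classification,
            "mean_exon_pi": float(np.mean(pis)) if pis else None,
            "mean_exon_d": float(np.mean(ds)) if ds else None,
        })
    rows.sort(key=lambda r: (-(r["cpd_wb"] if r["cpd_wb"] is not None else -np.inf),
                             r["gene_id"]))
    return rows


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _write_rows(path: Path, header_comment: str, columns: list[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment)
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _write_tsp_table(path, header, records, populations) -> None:
    cols = ["contig", "pos", "ref", "alt", "cosmopolitan", "tsp", "outgroup_state",
            "genomic_class", "effect", "gene_id",
            *[f"alt_freq_{p}" for p in populations]]
    rows = [
        [r.contig_id, r.pos, r.ref_allele, r.alt_allele, int(r.is_cosmopolitan),
         int(r.is_tsp), r.outgroup_state, r.genomic_class, r.effect, r.gene_id,
         *[r.alt_freq.get(p) for p in populations]]
        for r in records
    ]
    _write_rows(path, header, cols, rows)


def _write_enrichment(path, header, enrich) -> None:
    cols = ["genomic_class", "tsp_in", "tsp_out", "other_in", "other_out",
            "odds_ratio", "p_value", "adjusted_p"]
    rows = [[e.genomic_class, e.a, e.b, e.c, e.d, e.odds_ratio, e.p_value, e.adjusted_p]
            for e in enrich]
    _write_rows(path, header, cols, rows)


def _write_exon_stats(path, header, exon_stats) -> None:
    cols = ["gene_id", "exon_index", "contig", "start", "end", "length", "has_tsp",
            "mean_pi", "mean_d", "mean_fst", "he_ns_sum", "he_s_sum", "he_ratio"]
    rows = [
        [e.gene_id, e.exon_index, e.contig_id, e.interval[0] + 1, e.interval[1],
         e.length, int(e.has_tsp), e.mean_pi(), e.mean_d(), e.mean_fst,
         e.he_ns_sum, e.he_s_sum, e.he_ratio]
        for e in exon_stats
    ]
    _write_rows(path, header, cols, rows)


def _write_sfs(path, header, cand, other) -> None:
    cols = ["group", "bin_low", "bin_high", "proportion", "ci_low", "ci_high"]
    rows = []
    for name, s in (("candidate", cand), ("other", other)):
        for i in range(len(s.proportions)):
            rows.append([
                name, s.bin_edges[i], s.bin_edges[i + 1], s.proportions[i],
                None if s.ci_low is None else s.ci_low[i],
                None if s.ci_high is None else s.ci_high[i],
            ])
    _write_rows(path, header, cols, rows)


def _write_cpd(path, header, results) -> None:
    cols = ["gene_id", "cpd_wb", "within_iqr_low", "within_iqr_high",
            "between_iqr_low", "between_iqr_high", "p_value", "adjusted_p",
            "class", "n_haplotypes", "flags"]
    rows = []
    for r in sorted(results, key=lambda x: (-(x.cpd_wb if x.cpd_wb is not None else -np.inf), x.gene_id)):
        wiqr = r.within_iqr or (None, None)
        biqr = r.between_iqr or (None, None)
        rows.append([r.gene_id, r.cpd_wb, wiqr[0], wiqr[1], biqr[0], biqr[1],
                     r.p_value, r.adjusted_p, r.classification, r.n_haplotypes,
                     ",".join(r.flags) or None])
    _write_rows(path, header, cols, rows)


def _write_candidates(path, header, table) -> None:
    cols = ["gene_id", "n_tsps", "n_ns_tsps", "cpd_wb", "p_value", "adjusted_p",
            "class", "mean_exon_pi", "mean_exon_d"]
    rows = [[row[c] for c in cols] for row in table]
    _write_rows(path, header, cols, rows)
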
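"""Contrasts between TSP-bearing exons and all other exons.

Balancing selection leaves localized footprints: TSP-bearing exons are
expected to show elevated pi and Tajima's D, reduced between-population
F_ST, an excess of nonsynonymous over synonymous heterozygosity (sheltered
load), and gene-level folded SFS mass at intermediate frequencies. Because
recombination erodes these signatures over distance, the contrasts are
binned by exon length; both groups run through identical code paths, so
swapping group labels swaps outputs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import GeneModel, SiteCounts
from .poolseq_stats import (
    SfsSpectrum,
    StatFilters,
    folded_sfs,
    window_fst,
    window_stats,
)
from .tsp_scan import TspRecord


@dataclass
class ExonStat:
    gene_id: str
    exon_index: int
    contig_id: str
    interval: tuple[int, int]  # 0-based half-open
    length: int
    has_tsp: bool
    pi: dict[str, float | None]
    tajimas_d: dict[str, float | None]
    mean_fst: float | None
    he_ns_sum: float
    he_s_sum: float

    @property
    def he_ratio(self) -> float | None:
        """Sheltered-load ratio: sum of NS-site H_E over sum of S-site H_E.

        Sums (not ratios of means) keep the statistic defined whenever any
        synonymous heterozygosity exists; None when he_s_sum = 0.
        """
        if self.he_s_sum == 0:
            return None
        return self.he_ns_sum / self.he_s_sum

    def mean_pi(self) -> float | None:
        vals = [v for v in self.pi.values() if v is not None]
        return float(np.mean(vals)) if vals else None

    def mean_d(self) -> float | None:
        vals = [v for v in self.tajimas_d.values() if v is not None]
        return float(np.mean(vals)) if vals else None


@dataclass
class LengthBinnedContrast:
    statistic: str
    bin_edges: np.ndarray
    groups: dict[str, dict]  # group -> {mean, ci_low, ci_high, n} arrays


def per_exon_stats(gene_id: str, exon_index: int, contig: str,
                   interval: tuple[int, int], site_counts: list[SiteCounts],
                   snp_records: list[TspRecord], n_chrom: int,
                   filters: StatFilters | None = None) -> ExonStat:
    """Window statistics restricted to one exon.

    ``snp_records`` must already carry effect annotations; has_tsp is true
    when any TSP falls inside the exon, and the NS/S H_E sums run over
    classified coding SNPs inside the exon (mean H_E across populations
    per site).
    """
    start0, end0 = interval
    stats = window_stats(site_counts, interval, n_chrom, filters)
    fsts = [f.fst for f in window_fst(site_counts, interval, filters) if f.fst is not None]
    in_exon = [
        r for r in snp_records
        if r.contig_id == contig and start0 <= r.pos - 1 < end0
    ]
    he_ns = he_s = 0.0
    has_tsp = False
    for r in in_exon:
        if r.is_tsp:
            has_tsp = True
        if r.he:
            mean_he = float(np.mean(list(r.he.values())))
            if r.effect == "NS":
                he_ns += mean_he
            elif r.effect == "S":
                he_s += mean_he
    return ExonStat(
        gene_id=gene_id, exon_index=exon_index, contig_id=contig,
        interval=interval, length=end0 - start0, has_tsp=has_tsp,
        pi={s.population_id: s.pi for s in stats},
        tajimas_d={s.population_id: s.tajimas_d for s in stats},
        mean_fst=float(np.mean(fsts)) if fsts else None,
        he_ns_sum=he_ns, he_s_sum=he_s,
    )


def exon_table(gene_models: dict[str, GeneModel], site_counts: list[SiteCounts],
               snp_records: list[TspRecord], n_chrom: int,
               filters: StatFilters | None = None) -> list[ExonStat]:
    by_contig: dict[str, list[SiteCounts]] = {}
    for rec in site_counts:
        by_contig.setdefault(rec.contig_id, []).append(rec)
    out = []
    for m in gene_models.values():
        for i, ival in enumerate(m.exons):
            out.append(per_exon_stats(
                m.gene_id, i, m.contig_id, ival,
                by_contig.get(m.contig_id, []), snp_records, n_chrom, filters,
            ))
    return out


_STATS = {
    "pi": lambda e: e.mean_pi(),
    "tajimas_d": lambda e: e.mean_d(),
    "fst": lambda e: e.mean_fst,
    "he_ratio": lambda e: e.he_ratio,
}


def length_binned_contrast(exon_stats: list[ExonStat], statistic: str,
                           bin_width: int = 250, max_length: int = 3000,
                           n_boot: int = 200, seed: int | None = None
                           ) -> LengthBinnedContrast:
    """Group means (TSP-bearing vs other exons) per exon-length bin, with
    percentile-bootstrap 95% CIs over exons. ``n_boot=0`` returns point
    estimates only, deterministically. The last bin is open-ended.
    """
    if statistic not in _STATS:
        raise ValueError(f"unknown statistic {statistic!r}")
    get = _STATS[statistic]
    edges = np.arange(0, max_length + bin_width, bin_width, dtype=float)
    edges = np.append(edges, np.inf)
    n_bins = len(edges) - 1
    rng = np.random.default_rng(seed)
    groups = {}
    for name, flag in (("tsp", True), ("other", False)):
        mean = np.full(n_bins, np.nan)
        lo = np.full(n_bins, np.nan)
        hi = np.full(n_bins, np.nan)
        n = np.zeros(n_bins, dtype=int)
        members = [e for e in exon_stats if e.has_tsp == flag]
        for b in range(n_bins):
            vals = np.array([
                v for e in members
                if edges[b] <= e.length < edges[b + 1]
                and (v := get(e)) is not None
            ])
            n[b] = vals.size
            if vals.size == 0:
                continue
            mean[b] = vals.mean()
            if n_boot > 0 and vals.size > 0:
                boots = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
                lo[b] = np.percentile(boots, 2.5)
                hi[b] = np.percentile(boots, 97.5)
        groups[name] = {"mean": mean, "ci_low": lo, "ci_high": hi, "n": n}
    return LengthBinnedContrast(statistic, edges, groups)


def gene_set_sfs_contrast(candidate_gene_ids, all_gene_ids, snp_records: list[TspRecord],
                          gene_of_snp, n_bins: int = 10, n_boot: int = 200,
                          seed: int | None = None
                          ) -> tuple[SfsSpectrum, SfsSpectrum]:
    """Folded SFS of candidate-gene SNPs vs the remaining genes' SNPs.

    ``gene_of_snp(record)`` maps a SNP record to a gene id (None = not in a
    gene; such SNPs are ignored). Frequencies are the per-SNP mean alternate
    frequency across populations; CIs come from gene-level bootstrap. When
    the candidate set covers every gene the two spectra coincide.
    """
    candidates = set(candidate_gene_ids)
    if not candidates:
        raise ValueError("empty candidate gene set")
    background = set(all_gene_ids) - candidates or candidates
    freqs = {"cand": [], "other": []}
    units = {"cand": [], "other": []}
    for r in snp_records:
        g = gene_of_snp(r)
        if g is None or not r.alt_freq:
            continue
        f = float(np.mean(list(r.alt_freq.values())))
        if not 0.0 < f < 1.0:
            continue
        if g in candidates:
            freqs["cand"].append(f)
            units["cand"].append(g)
        if g in background:
            freqs["other"].append(f)
            units["other"].append(g)
    rng = np.random.default_rng(seed)
    out = []
    for key in ("cand", "other"):
        out.append(folded_sfs(
            freqs[key], n_bins=n_bins, bootstrap_units=units[key],
            n_boot=n_boot, rng=rng,
        ))
    return out[0], out[1]
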
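"""Diversity and differentiation statistics from pool-seq read counts.

Pool-seq treats a pool of diploids as one library: per-site read counts are a
noisy multinomial sample of the pool's allele frequencies. The estimators here
follow the classical single-locus theory:

* per-site nucleotide diversity from reads,
  ``pi = C/(C-1) * (1 - sum_a (c_a/C)^2)`` — the unbiased mean pairwise
  difference among the C reads at the site;
* Watterson's theta, ``theta_w = S / (a_n * L)`` with
  ``a_n = sum_{i<n} 1/i`` at ``n`` = pool chromosomes (2 x diploids pooled);
* Tajima's D with the standard Tajima (1989) variance constants at
  ``n`` = pool chromosomes;
* per-site F_ST from pooled allele frequencies,
  ``F_ST = (pi_T - pi_S) / pi_T`` (frequency form, clamped at 0);
* expected heterozygosity ``H_E = 2 p (1 - p)``;
* the folded site frequency spectrum with gene-level bootstrap CIs.

Using the raw pool chromosome count in theta/D (rather than a
coverage-adjusted effective sample size) is a deliberate simplification: the
scan's inferences are contrasts between exon groups that share the coverage
regime, and the plain estimator is exactly testable against neutral coalescent
expectations. An exact-haplotype path (``haplotype_pi`` etc.) provides the
oracle for those tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .formats_io import SiteCounts

ACGT = slice(0, 4)  # usable columns of a sync 6-vector; N and del are excluded


@dataclass
class StatFilters:
    """Site-level filters shared by the scan.

    min_coverage / max_coverage bound usable (A+T+C+G) reads per pool;
    a site is called polymorphic when the minor allele has >= min_count
    reads and frequency >= maf across the pooled counts.
    """

    min_coverage: int = 10
    max_coverage: int = 100
    min_count: int = 2
    maf: float = 0.05


@dataclass
class WindowStats:
    contig_id: str
    interval: tuple[int, int]
    population_id: str
    pi: float | None  # per-site
    theta_w: float | None  # per-site
    tajimas_d: float | None
    n_snps: int
    mean_coverage: float


@dataclass
class PairwiseFst:
    pop_a: str
    pop_b: str
    interval: tuple[int, int]
    fst: float | None


@dataclass
class SfsSpectrum:
    bin_edges: np.ndarray  # length n_bins + 1 over [0, 0.5]
    proportions: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    n_snps: int = 0

    def __post_init__(self) -> None:
        if self.n_snps and abs(float(self.proportions.sum()) - 1.0) > 1e-9:
            raise ValueError("SFS proportions must sum to 1")


# ---------------------------------------------------------------------------
# per-site estimators
# ---------------------------------------------------------------------------

def usable_coverage(counts6: np.ndarray) -> int:
    return int(np.asarray(counts6)[..., ACGT].sum())


def pi_site(counts6, min_coverage: int = 2) -> float | None:
    """Unbiased mean pairwise difference among reads at one site.

    Equals (number of differing read pairs) / C(C, 2). Returns None when
    usable coverage is below ``max(2, min_coverage)``.
    """
    c = np.asarray(counts6, dtype=float)[..., ACGT]
    cov = c.sum()
    if cov < max(2, min_coverage):
        return None
    return float(cov / (cov - 1.0) * (1.0 - ((c / cov) ** 2).sum()))


def harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def theta_watterson(n_snps: int, n_chrom: int, window_length: int) -> float:
    """Watterson's per-site theta for a window: S / (a_n * L)."""
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    if n_chrom < 2:
        raise ValueError("need at least 2 chromosomes")
    return n_snps / (harmonic(n_chrom) * window_length)


def tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) of Tajima (1989) for sample size n chromosomes."""
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    return c1 / a1, c2 / (a1 * a1 + a2)


def tajimas_d(pi_sum: float, n_snps: int, n_chrom: int,
              min_snps: int = 3) -> float | None:
    """Tajima's D from a window's summed pi and segregating-site count.

    Returns None below ``min_snps`` segregating sites or when the variance
    term is non-positive.
    """
    if n_snps < min_snps:
        return None
    e1, e2 = tajima_constants(n_chrom)
    var = e1 * n_snps + e2 * n_snps * (n_snps - 1)
    if var <= 0:
        return None
    a1 = harmonic(n_chrom)
    return float((pi_sum - n_snps / a1) / math.sqrt(var))


def major_minor(counts_total: np.ndarray, min_count: int = 2,
                maf: float = 0.05) -> tuple[int, int] | None:
    """Indices (major, minor) of a biallelic site's alleles, or None.

    An allele is "observed" when it has >= min_count reads and pooled
    frequency >= maf. Monomorphic and >2-allele sites return None.
    A 50/50 tie reports the higher base index (non-reference-first ordering
    is resolved downstream) as minor — deterministic tie-break.
    """
    c = np.asarray(counts_total, dtype=np.int64)[ACGT]
    cov = c.sum()
    if cov == 0:
        return None
    observed = np.flatnonzero((c >= min_count) & (c / cov >= maf))
    if observed.size != 2:
        return None
    a, b = observed
    if c[a] > c[b]:
        return int(a), int(b)
    if c[b] > c[a]:
        return int(b), int(a)
    return int(a), int(b)  # tie: later-indexed allele is minor


def pool_frequency(counts6: np.ndarray, allele_idx: int) -> float | None:
    c = np.asarray(counts6, dtype=float)[ACGT]
    cov = c.sum()
    if cov == 0:
        return None
    return float(c[allele_idx] / cov)


def fst_site(counts_a, counts_b, min_coverage: int = 10) -> float | None:
    """Per-site F_ST between two pools: (pi_T - pi_S) / pi_T, clamped at 0.

    pi_S is the mean of the two within-pool heterozygosities (frequency
    form, 2p(1-p) summed over alleles); pi_T uses the mean allele
    frequencies. None when either pool fails coverage or pi_T = 0
    (monomorphic for the same allele in both pools).
    """
    a = np.asarray(counts_a, dtype=float)[..., ACGT]
    b = np.asarray(counts_b, dtype=float)[..., ACGT]
    cov_a, cov_b = a.sum(), b.sum()
    if cov_a < min_coverage or cov_b < min_coverage:
        return None
    pa, pb = a / cov_a, b / cov_b
    pi_a = 1.0 - (pa**2).sum()
    pi_b = 1.0 - (pb**2).sum()
    pbar = (pa + pb) / 2.0
    pi_t = 1.0 - (pbar**2).sum()
    if pi_t <= 0:
        return None
    fst = (pi_t - (pi_a + pi_b) / 2.0) / pi_t
    return float(max(fst, 0.0))


def heterozygosity(p: float) -> float:
    """Expected heterozygosity 2p(1-p) of a biallelic site."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    return 2.0 * p * (1.0 - p)


# ---------------------------------------------------------------------------
# window aggregation over sync records
# ---------------------------------------------------------------------------

def n_observed_alleles(counts_total: np.ndarray, filters: StatFilters) -> int:
    """Alleles with >= min_count reads and frequency >= maf."""
    c = np.asarray(counts_total, dtype=np.int64)[ACGT]
    cov = c.sum()
    if cov == 0:
        return 0
    return int(((c >= filters.min_count) & (c / cov >= filters.maf)).sum())


def is_polymorphic(counts_total: np.ndarray, filters: StatFilters) -> bool:
    return major_minor(counts_total, filters.min_count, filters.maf) is not None


def window_stats(records: list[SiteCounts], interval: tuple[int, int],
                 n_chrom: int, filters: StatFilters | None = None,
                 min_snps_for_d: int = 3) -> list[WindowStats]:
    """Per-population window statistics from sync records inside ``interval``.

    ``interval`` is 0-based half-open; the window length (denominator for
    per-site pi and theta) is its width — sites absent from the sync are
    treated as monomorphic.
    """
    filters = filters or StatFilters()
    start0, end0 = interval
    length = end0 - start0
    if length <= 0:
        raise ValueError("empty window")
    in_win = [r for r in records if start0 <= r.pos - 1 < end0]
    out = []
    if not in_win:
        pops = ()
    else:
        pops = in_win[0].population_ids
    for k, pop in enumerate(pops):
        pi_sum, n_snps, covs = 0.0, 0, []
        for rec in in_win:
            c = rec.counts[k]
            cov = usable_coverage(c)
            covs.append(cov)
            if cov < filters.min_coverage or cov > filters.max_coverage:
                continue
            # pi counts every filtered polymorphic site, including >2-allele
            # sites; the SNP count for theta/D is biallelic sites only.
            if n_observed_alleles(c, filters) >= 2:
                p = pi_site(c, filters.min_coverage)
                if p is not None:
                    pi_sum += p
            if is_polymorphic(c, filters):
                n_snps += 1
        pi = pi_sum / length
        theta = theta_watterson(n_snps, n_chrom, length)
        d = tajimas_d(pi_sum, n_snps, n_chrom, min_snps_for_d)
        out.append(WindowStats(
            contig_id=in_win[0].contig_id, interval=interval, population_id=pop,
            pi=pi, theta_w=theta, tajimas_d=d, n_snps=n_snps,
            mean_coverage=float(np.mean(covs)) if covs else 0.0,
        ))
    return out


def window_fst(records: list[SiteCounts], interval: tuple[int, int],
               filters: StatFilters | None = None) -> list[PairwiseFst]:
    """Mean per-site F_ST over polymorphic sites, for every population pair."""
    filters = filters or StatFilters()
    start0, end0 = interval
    in_win = [r for r in records if start0 <= r.pos - 1 < end0]
    if not in_win:
        return []
    pops = in_win[0].population_ids
    out = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            vals = []
            for rec in in_win:
                total = rec.counts[i] + rec.counts[j]
                if not is_polymorphic(total, filters):
                    continue
                f = fst_site(rec.counts[i], rec.counts[j], filters.min_coverage)
                if f is not None:
                    vals.append(f)
            fst = float(np.mean(vals)) if vals else None
            out.append(PairwiseFst(pops[i], pops[j], interval, fst))
    return out


# ---------------------------------------------------------------------------
# folded SFS
# ---------------------------------------------------------------------------

def folded_sfs(frequencies, n_bins: int = 10, bootstrap_units=None,
               n_boot: int = 0, seed: int | None = None,
               rng: np.random.Generator | None = None) -> SfsSpectrum:
    """Folded SFS over (0, 0.5] with optional gene-level percentile bootstrap.

    ``bootstrap_units`` assigns each frequency to a resampling unit (gene id);
    CIs are 95% percentile intervals over ``n_boot`` resamples of units.
    Bins are right-inclusive: bin i covers (edges[i], edges[i+1]].
    """
    freqs = np.asarray(list(frequencies), dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency list")
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("frequencies must lie strictly in (0, 1)")
    folded = np.minimum(freqs, 1.0 - freqs)
    edges = np.linspace(0.0, 0.5, n_bins + 1)

    def _props(x: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(edges, x, side="left") - 1, 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins).astype(float)
        return counts / counts.sum()

    props = _props(folded)
    ci_low = ci_high = None
    if n_boot > 0:
        if bootstrap_units is None:
            raise ValueError("bootstrap requires per-frequency unit labels")
        units = np.asarray(list(bootstrap_units))
        if units.shape != freqs.shape:
            raise ValueError("bootstrap_units must match frequencies")
        uniq = np.unique(units)
        groups = {u: folded[units == u] for u in uniq}
        if rng is None:
            rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, n_bins))
        for b in range(n_boot):
            pick = rng.choice(uniq, size=uniq.size, replace=True)
            sample = np.concatenate([groups[u] for u in pick])
            boots[b] = _props(sample)
        ci_low = np.percentile(boots, 2.5, axis=0)
        ci_high = np.percentile(boots, 97.5, axis=0)
    return SfsSpectrum(edges, props, ci_low, ci_high, n_snps=int(freqs.size))


# ---------------------------------------------------------------------------
# exact-haplotype oracle path
# ---------------------------------------------------------------------------

def haplotype_allele_counts(haps: np.ndarray) -> list[dict[str, int]]:
    haps = np.asarray(haps, dtype="U1")
    out = []
    for j in range(haps.shape[1]):
        vals, counts = np.unique(haps[:, j], return_counts=True)
        out.append(dict(zip(vals.tolist(), counts.tolist())))
    return out


def haplotype_pi(haps: np.ndarray) -> float:
    """Sum over sites of mean pairwise difference among haplotypes."""
    haps = np.asarray(haps, dtype="U1")
    n = haps.shape[0]
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    total = 0.0
    for site in haplotype_allele_counts(haps):
        c = np.array(list(site.values()), dtype=float)
        total += (n * n - (c**2).sum()) / (n * (n - 1))
    return float(total)


def haplotype_segsites(haps: np.ndarray) -> int:
    haps = np.asarray(haps, dtype="U1")
    return int(sum(len(s) > 1 for s in haplotype_allele_counts(haps)))


def haplotype_tajimas_d(haps: np.ndarray, min_snps: int = 3) -> float | None:
    n = np.asarray(haps).shape[0]
    return tajimas_d(haplotype_pi(haps), haplotype_segsites(haps), n, min_snps)
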
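"""Allele trees and the CPD_w-b statistic for dating balanced polymorphisms.

For each candidate region, phased haplotypes of the single sequenced
individuals (plus the outgroup diploid) are turned into a neighbor-joining
tree on p-distances. The cophenetic distance (CPD) between two tips is their
path length on the tree; the statistic

    CPD_w-b = mean(within-population tip pairs) - mean(between-population pairs)

(outgroup excluded from both sets) is positive when a population's own
haplotypes are more diverged from each other than haplotypes from different
populations — the signature of two ancient allelic classes cutting across
geography. Under the neutral phylogeographic expectation (haplotypes cluster
by population and basin) CPD_w-b is strongly negative.

Significance is assessed by permuting population labels over the
non-outgroup tips (one-sided, CPD_w-b > 0), Bonferroni-corrected across
candidate loci. A locus is classified *ancient* when CPD_w-b > 0, the
adjusted p-value clears alpha, and the ocean-basin tip sets are not
reciprocally monophyletic on the rooted tree; otherwise *recent*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .formats_io import HaplotypeSet, PhasedGenotypes
from .tsp_scan import TspRecord

logger = logging.getLogger(__name__)


@dataclass
class CpdResult:
    gene_id: str
    cpd_wb: float | None
    within_iqr: tuple[float, float] | None
    between_iqr: tuple[float, float] | None
    p_value: float | None = None
    adjusted_p: float | None = None
    classification: str | None = None  # "ancient" | "recent"
    n_haplotypes: int = 0
    flags: tuple[str, ...] = ()


class LocusSkipped(RuntimeError):
    """A candidate region that cannot support an allele tree."""


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

def extract_window(tsp: TspRecord, phased: PhasedGenotypes,
                   window: tuple[int, int], max_masked_frac: float = 0.5,
                   min_haplotypes: int = 4) -> HaplotypeSet:
    """Phased haplotypes over all SNPs in a 0-based half-open window.

    Haplotypes with more than ``max_masked_frac`` masked sites are dropped
    (both haplotypes of an unphased individual drop together since unphased
    het sites mask both). Raises :class:`LocusSkipped` when fewer than
    ``min_haplotypes`` usable haplotypes or zero SNPs remain.
    """
    hs = phased.haplotypes_in_window(tsp.contig_id, window)
    if hs.n_sites == 0:
        raise LocusSkipped(f"{tsp.contig_id}:{tsp.pos}: no SNPs in window")
    frac_masked = hs.mask.mean(axis=1)
    keep = frac_masked <= max_masked_frac
    if keep.sum() < min_haplotypes:
        raise LocusSkipped(
            f"{tsp.contig_id}:{tsp.pos}: only {int(keep.sum())} usable haplotypes"
        )
    return hs.subset(keep)


def default_window(tsp: TspRecord, gene_models=None, flank_bp: int = 500
                   ) -> tuple[int, int]:
    """TSP-bearing exon if the TSP is exonic, else +-flank_bp around it."""
    p0 = tsp.pos - 1
    if gene_models and tsp.gene_id in gene_models:
        for s, e in gene_models[tsp.gene_id].exons:
            if s <= p0 < e:
                return (s, e)
    return (max(0, p0 - flank_bp), p0 + flank_bp + 1)


# ---------------------------------------------------------------------------
# distances and trees
# ---------------------------------------------------------------------------

def pairwise_distance(hs: HaplotypeSet) -> DistanceMatrix:
    """p-distance matrix: mismatches / jointly unmasked sites.

    Raises :class:`LocusSkipped` when some pair shares no unmasked site.
    """
    n = hs.n_haplotypes
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    ids = [lab.tip_id for lab in hs.labels]
    d = np.zeros((n, n))
    valid = ~hs.mask
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise LocusSkipped(f"haplotypes {ids[i]} and {ids[j]} share no sites")
            mism = int((hs.haplotypes[i, both] != hs.haplotypes[j, both]).sum())
            d[i, j] = d[j, i] = mism / m
    return DistanceMatrix(d, ids)


def build_tree(dm: DistanceMatrix, outgroup_tips: list[str]) -> tuple[TreeNode, bool]:
    """Neighbor-joining tree, negative branch lengths clamped to zero,
    rooted on the outgroup tips. Returns (tree, rooted_flag); when the
    outgroup tips are absent the unrooted NJ tree is returned flagged."""
    if len(dm.ids) == 2:
        a, b = dm.ids
        tree = TreeNode.read([f"({a}:{dm[a, b] / 2},{b}:{dm[a, b] / 2});"])
    else:
        tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    present = {t.name for t in tree.tips()}
    og = [t for t in outgroup_tips if t in present]
    if not og:
        return tree, False
    try:
        rooted = tree.root_by_outgroup(og)
    except Exception:  # non-monophyletic outgroup in the unrooted tree
        rooted = tree.root_by_outgroup([og[0]])
    return rooted, True


def cophenetic(tree: TreeNode) -> DistanceMatrix:
    return tree.tip_tip_distances()


# ---------------------------------------------------------------------------
# CPD_w-b
# ---------------------------------------------------------------------------

def _pair_sets(labels: dict[str, str], ids: list[str]):
    """Index pairs (within, between) over non-outgroup tips.

    ``labels`` maps tip id -> population id, with outgroup tips absent."""
    idx = [i for i, t in enumerate(ids) if t in labels]
    within, between = [], []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            (within if labels[ids[i]] == labels[ids[j]] else between).append((i, j))
    return within, between


def cpd_wb(dm: DistanceMatrix, population_labels: dict[str, str]
           ) -> tuple[float | None, tuple, tuple]:
    """CPD_w-b from a cophenetic matrix and tip -> population labels.

    Returns (statistic, within-pair IQR, between-pair IQR); the statistic is
    None when no within-population pair exists.
    """
    ids = list(dm.ids)
    within, between = _pair_sets(population_labels, ids)
    if not within or not between:
        return None, (), ()
    data = dm.data
    w = np.array([data[i, j] for i, j in within])
    b = np.array([data[i, j] for i, j in between])
    iqr = lambda x: (float(np.percentile(x, 25)), float(np.percentile(x, 75)))  # noqa: E731
    return float(w.mean() - b.mean()), iqr(w), iqr(b)


def permutation_test(dm: DistanceMatrix, population_labels: dict[str, str],
                     n_perm: int = 999, seed: int | None = None,
                     rng: np.random.Generator | None = None) -> float:
    """One-sided permutation p-value for CPD_w-b > 0.

    Population labels are permuted over the non-outgroup tips;
    p = (1 + #{permuted CPD_w-b >= observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    pops = list(population_labels.values())
    if len(set(pops)) < 2:
        raise ValueError("permutation test needs at least two populations")
    observed, _, _ = cpd_wb(dm, population_labels)
    if observed is None:
        raise ValueError("CPD_w-b undefined: no within-population pairs")
    ids = list(dm.ids)
    tips = [t for t in ids if t in population_labels]
    tip_idx = np.array([ids.index(t) for t in tips])
    label_arr = np.array([population_labels[t] for t in tips])
    data = dm.data
    if rng is None:
        rng = np.random.default_rng(seed)
    # pair index cache over the non-outgroup submatrix
    sub = data[np.ix_(tip_idx, tip_idx)]
    iu = np.triu_indices(len(tips), k=1)
    pair_d = sub[iu]
    n_exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(label_arr)
        same = perm[iu[0]] == perm[iu[1]]
        stat = pair_d[same].mean() - pair_d[~same].mean()
        if stat >= observed:
            n_exceed += 1
    return (1 + n_exceed) / (n_perm + 1)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def basins_reciprocally_monophyletic(tree: TreeNode, basin_map: dict[str, str]
                                     ) -> bool:
    """True when each ocean basin's (non-outgroup) tips form a clade.

    ``basin_map`` maps tip id -> basin; outgroup tips are omitted from it.
    A basin with a single tip is trivially monophyletic.
    """
    tips_by_basin: dict[str, list[str]] = {}
    for t in tree.tips():
        if t.name in basin_map:
            tips_by_basin.setdefault(basin_map[t.name], []).append(t.name)
    focal = {name for names in tips_by_basin.values() for name in names}
    for basin, names in tips_by_basin.items():
        if len(names) == 1:
            continue
        lca = tree.lca(names)
        clade_focal = {t.name for t in lca.tips() if t.name in focal}
        if clade_focal != set(names):
            return False
    return True


def classify_locus(result: CpdResult, tree: TreeNode | None,
                   basin_map: dict[str, str], alpha: float = 0.05,
                   rooted: bool = True) -> str:
    """"ancient" iff CPD_w-b > 0, adjusted p < alpha, and the basin tip sets
    violate reciprocal monophyly on the rooted tree; else "recent". With an
    unrooted tree the monophyly check is skipped (flagged upstream)."""
    if result.cpd_wb is None or result.adjusted_p is None:
        return "recent"
    if not (result.cpd_wb > 0 and result.adjusted_p < alpha):
        return "recent"
    if rooted and tree is not None:
        if basins_reciprocally_monophyletic(tree, basin_map):
            return "recent"
    return "ancient"


# ---------------------------------------------------------------------------
# per-locus driver
# ---------------------------------------------------------------------------

def analyze_locus(gene_id: str, hs: HaplotypeSet, n_perm: int, seed: int
                  ) -> tuple[CpdResult, TreeNode | None, bool]:
    """Distance matrix -> NJ tree -> CPD_w-b -> permutation p for one locus."""
    dm = pairwise_distance(hs)
    outgroup_tips = [lab.tip_id for lab in hs.labels if lab.species == "outgroup"]
    tree, rooted = build_tree(dm, outgroup_tips)
    coph = cophenetic(tree)
    labels = {
        lab.tip_id: lab.population_id for lab in hs.labels if lab.species != "outgroup"
    }
    stat, wiqr, biqr = cpd_wb(coph, labels)
    flags = () if rooted else ("unrooted",)
    if stat is None:
        return (
            CpdResult(gene_id, None, None, None, n_haplotypes=hs.n_haplotypes,
                      flags=flags + ("no_within_pairs",)),
            tree, rooted,
        )
    p = permutation_test(coph, labels, n_perm=n_perm, seed=seed)
    return (
        CpdResult(gene_id, stat, wiqr, biqr, p_value=p,
                  n_haplotypes=hs.n_haplotypes, flags=flags),
        tree, rooted,
    )


def bonferroni(results: list[CpdResult]) -> None:
    """Adjust p-values across candidate loci in place."""
    tested = [r for r in results if r.p_value is not None]
    k = len(tested)
    for r in tested:
        r.adjusted_p = min(1.0, r.p_value * k)
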
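"""Synthetic pool-seq datasets with and without ancient balanced haplotypes.

The generator emulates the study system the scan is built for: a focal
species sampled in two ocean basins (one Pacific and several Atlantic
populations), plus a single diploid outgroup individual of a sister species.
Neutral loci evolve under a three-level split model (outgroup split, ocean
split, panmixia within each ocean), simulated with msprime under an
infinite-sites mutation model. Balanced loci carry two ancient allelic
classes, X and Y, separated by ``Poisson(2 * mu * t_balanced * L)`` fixed
differences; both classes segregate in every focal population (class
frequency drawn per population from ``class_freq_range``) and in the
outgroup, which is what makes their diverged sites trans-species
polymorphisms by construction. Within each class, haplotypes carry their own
coalescent-distributed variation under the same demography.

Pool-seq observation: per site, read depth is Poisson(coverage_mean), each
read copies a uniformly chosen chromosome of the pool, and with probability
``error_rate`` the read base is replaced by a uniform different base.

One master seed determines every output byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import msprime
import numpy as np

from .formats_io import (
    GeneModel,
    HaplotypeLabel,
    HaplotypeSet,
    NUCLEOTIDES,
    PhasedSample,
    ReferenceSeq,
    SiteCounts,
    write_fasta,
    write_gff,
    write_phased_vcf,
    write_sync,
)

logger = logging.getLogger(__name__)

PACIFIC = "pacific"
ATLANTIC = "atlantic"
OUTGROUP_POP = "OUT"


def derive_seed(master: int, *tags) -> int:
    """Stable per-stage seed in [1, 2^31): hashing stage tags means adding a
    stage never perturbs the randomness of existing stages."""
    key = f"{master}:" + ":".join(str(t) for t in tags)
    h = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 2) + 1


@dataclass
class SimConfig:
    """Study-condition parameters of the generator.

    Defaults mirror the sampling design the scan assumes: six focal
    populations (one Pacific, five Atlantic) each pooled at 24 diploids
    (the study pooled 20-38 per population), one phased diploid individual
    per population plus one outgroup diploid, an ocean split ~2 My of
    generations ago, a species split ~8 My ago, and balanced alleles older
    than the species split (10 My). ``mu`` and ``ne`` are chosen so that
    within-population diversity (4*Ne*mu = 0.4%) sits in the study's
    observed 0.5-1% range while the species split is >> 2*Ne generations,
    making neutral trans-species polymorphism vanishingly rare.
    """

    seed: int = 1
    populations: tuple[str, ...] = ("WCAN", "ME", "RI", "ICE", "NOR", "UK")
    pacific_populations: tuple[str, ...] = ("WCAN",)
    pool_size: int = 24  # diploid individuals per pool
    coverage_mean: float = 50.0
    error_rate: float = 0.001
    mu: float = 2e-9  # per site per generation
    ne: float = 5e5
    locus_length: int = 600
    n_neutral_loci: int = 20
    n_balanced_loci: int = 10
    t_split_oceans: float = 2e6  # generations
    t_split_species: float = 8e6
    t_balanced: float = 1e7
    class_freq_range: tuple[float, float] = (0.2, 0.8)
    het_excess: float = 0.5  # balanced-locus heterozygote excess over HWE
    recombination_rate: float = 0.0
    intergenic_bp: int = 2000

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.01:
            raise ValueError("error_rate must be in [0, 0.01)")
        if not 10 <= self.pool_size <= 100:
            raise ValueError("pool_size must be within [10, 100]")
        lo, hi = self.class_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("class_freq_range must be within (0, 1)")
        if min(lo, 1 - hi) * 2 * self.pool_size < 1:
            raise ValueError(
                "class_freq_range incompatible with pool size: expected "
                "minor-class copies per pool < 1"
            )
        if set(self.pacific_populations) - set(self.populations):
            raise ValueError("pacific_populations must be a subset of populations")
        if self.t_split_oceans > self.t_split_species:
            raise ValueError("ocean split cannot predate the species split")

    @property
    def oceans(self) -> dict[str, str]:
        return {
            p: (PACIFIC if p in self.pacific_populations else ATLANTIC)
            for p in self.populations
        }

    @property
    def n_chrom_per_pool(self) -> int:
        return 2 * self.pool_size

    def demography(self) -> msprime.Demography:
        d = msprime.Demography()
        for name in (PACIFIC, ATLANTIC, "focal_anc", "outgroup_sp", "root"):
            d.add_population(name=name, initial_size=self.ne)
        d.add_population_split(
            time=self.t_split_oceans, derived=[PACIFIC, ATLANTIC], ancestral="focal_anc"
        )
        d.add_population_split(
            time=self.t_split_species, derived=["focal_anc", "outgroup_sp"], ancestral="root"
        )
        return d


@dataclass
class SimTruth:
    """Generator-side ground truth for one locus."""

    locus_id: str
    label: str  # "neutral" or "balanced"
    class_per_hap: list[str] | None = None  # "X"/"Y", aligned with HaplotypeSet rows
    class_freq: dict[str, float] | None = None  # true per-population Y frequency
    diverged_positions: list[int] = field(default_factory=list)  # 1-based, locus-local


# ---------------------------------------------------------------------------
# locus-level simulation
# ---------------------------------------------------------------------------

def _random_reference(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


def _integer_positions(float_positions, length: int, taken: set[int]) -> list[int]:
    """Map strictly increasing float positions to distinct integer 1-based
    positions, preserving order and avoiding ``taken``.

    Positions are assigned by rank onto the free integer slots, so the
    infinite-sites property of the continuous simulation is preserved
    exactly as long as the locus is not saturated."""
    m = len(float_positions)
    if m == 0:
        return []
    avail = [p for p in range(1, length + 1) if p not in taken]
    if m > len(avail):
        raise ValueError("locus saturated: more mutations than available sites")
    out: list[int] = []
    prev_k = -1
    n_av = len(avail)
    for i, p in enumerate(float_positions):
        k = int(p / length * n_av)
        k = min(max(prev_k + 1, k), n_av - (m - i))
        out.append(avail[k])
        taken.add(avail[k])
        prev_k = k
    return out


def _focal_sample_sets(config: SimConfig, per_pop_haps: dict[str, int],
                       n_outgroup_haps: int) -> list[msprime.SampleSet]:
    sets = [
        msprime.SampleSet(per_pop_haps[p], population=config.oceans[p], ploidy=1)
        for p in config.populations
    ]
    if n_outgroup_haps:
        sets.append(msprime.SampleSet(n_outgroup_haps, population="outgroup_sp", ploidy=1))
    return sets


def _simulate_genealogy_variants(config: SimConfig, per_pop_haps: dict[str, int],
                                 n_outgroup_haps: int, seed: int):
    """Run msprime under the split demography; return (positions, genotypes)
    with float positions and 0/1 derived-state genotype matrix."""
    ts = msprime.sim_ancestry(
        samples=_focal_sample_sets(config, per_pop_haps, n_outgroup_haps),
        demography=config.demography(),
        sequence_length=config.locus_length,
        recombination_rate=config.recombination_rate,
        ploidy=2,
        random_seed=seed,
    )
    mts = msprime.sim_mutations(
        ts, rate=config.mu, model=msprime.BinaryMutationModel(),
        discrete_genome=False, random_seed=derive_seed(seed, "mut"),
    )
    positions = [s.position for s in mts.sites()]
    geno = mts.genotype_matrix().T if mts.num_sites else np.zeros(
        (mts.num_samples, 0), dtype=np.int8
    )
    return positions, geno


def _labels(config: SimConfig, per_pop_individuals: dict[str, int],
            outgroup_individuals: int = 1) -> list[HaplotypeLabel]:
    labels = []
    for p in config.populations:
        for i in range(per_pop_individuals[p]):
            for k in (0, 1):
                labels.append(HaplotypeLabel(f"{p}_i{i}", p, "focal", k))
    for i in range(outgroup_individuals):
        for k in (0, 1):
            labels.append(HaplotypeLabel(f"{OUTGROUP_POP}_i{i}", OUTGROUP_POP, "outgroup", k))
    return labels


def simulate_neutral_locus(config: SimConfig, locus_index: int) -> HaplotypeSet:
    """One neutral locus: coalescent haplotypes for every focal pool plus the
    outgroup diploid under the three-level split model."""
    seed = derive_seed(config.seed, "neutral", locus_index)
    rng = np.random.default_rng(derive_seed(seed, "bases"))
    ref = _random_reference(config.locus_length, rng)
    per_pop = {p: config.n_chrom_per_pool for p in config.populations}
    float_pos, geno = _simulate_genealogy_variants(config, per_pop, 2, seed)
    positions = np.array(
        _integer_positions(float_pos, config.locus_length, set()), dtype=np.int64
    )
    n_haps = geno.shape[0]
    ref_alleles = np.array([ref[p - 1] for p in positions], dtype="U1")
    alts = np.array(
        [_other_base(b, rng) for b in ref_alleles], dtype="U1"
    ) if positions.size else np.empty(0, dtype="U1")
    haps = np.tile(ref_alleles, (n_haps, 1)) if positions.size else np.empty(
        (n_haps, 0), dtype="U1"
    )
    if positions.size:
        haps[geno.astype(bool)] = np.broadcast_to(alts, haps.shape)[geno.astype(bool)]
    labels = _labels(config, {p: config.pool_size for p in config.populations})
    hs = HaplotypeSet(
        contig_id=f"locus{locus_index}", window=(0, config.locus_length),
        positions=positions, ref_alleles=ref_alleles, haplotypes=haps,
        mask=np.zeros_like(haps, dtype=bool), labels=labels,
    )
    hs.reference = ref  # full locus reference, used by emit_dataset
    return hs


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in NUCLEOTIDES if b != base]
    return choices[int(rng.integers(3))]


def _pair_with_het_excess(n_x: int, n_y: int, n_ind: int, het_excess: float,
                          rng: np.random.Generator) -> list[tuple[str, str]]:
    """Assign 2*n_ind haplotype classes to diploids with heterozygote excess.

    Under Hardy-Weinberg the expected X/Y heterozygote count is
    n_x*n_y/(2*n_ind); marginal overdominance with strong genotype-dependent
    juvenile mortality enriches surviving adults for heterozygotes, modeled
    as a (1 + het_excess) multiplier capped by the allele counts.
    """
    assert n_x + n_y == 2 * n_ind
    target = (1.0 + het_excess) * n_x * n_y / (2.0 * n_ind)
    n_het = min(min(n_x, n_y), int(round(target)))
    if (n_x - n_het) % 2:  # parity: remaining X haplotypes must pair up
        n_het = n_het + 1 if n_het + 1 <= min(n_x, n_y) else n_het - 1
    genotypes = (
        [("X", "Y")] * n_het
        + [("X", "X")] * ((n_x - n_het) // 2)
        + [("Y", "Y")] * ((n_y - n_het) // 2)
    )
    rng.shuffle(genotypes)
    return genotypes


def implant_balanced_locus(config: SimConfig, locus_index: int,
                           trans_species: bool = True
                           ) -> tuple[HaplotypeSet, SimTruth]:
    """One balanced locus: two ancient allelic classes segregating everywhere.

    The classes differ at Poisson(2*mu*t_balanced*L) sites; each class's
    haplotypes additionally carry their own coalescent variation under the
    split demography. The single outgroup diploid is an X/Y heterozygote, so
    every diverged site is a trans-species polymorphism by construction.
    """
    if trans_species and config.t_balanced < config.t_split_species:
        raise ValueError(
            "trans-species balanced locus requires t_balanced >= t_split_species"
        )
    seed = derive_seed(config.seed, "balanced", locus_index)
    rng = np.random.default_rng(derive_seed(seed, "locus-rng"))
    L = config.locus_length
    ref = _random_reference(L, rng)

    # per-population class composition (Y = derived class), both classes
    # guaranteed present in every pool
    n2 = config.n_chrom_per_pool
    q = {p: float(rng.uniform(*config.class_freq_range)) for p in config.populations}
    n_y = {p: int(np.clip(round(n2 * q[p]), 1, n2 - 1)) for p in config.populations}
    n_x = {p: n2 - n_y[p] for p in config.populations}

    # within-class coalescent variation (one outgroup haplotype per class)
    pos_x, geno_x = _simulate_genealogy_variants(config, n_x, 1, derive_seed(seed, "X"))
    pos_y, geno_y = _simulate_genealogy_variants(config, n_y, 1, derive_seed(seed, "Y"))
    taken: set[int] = set()
    int_x = _integer_positions(pos_x, L, taken)
    int_y = _integer_positions(pos_y, L, taken)

    # fixed class differences
    n_div = int(rng.poisson(2.0 * config.mu * config.t_balanced * L))
    free = np.setdiff1d(np.arange(1, L + 1), np.fromiter(taken, dtype=np.int64, count=len(taken)))
    if n_div > free.size:
        raise ValueError("locus saturated: class divergence exceeds free sites")
    div_pos = sorted(int(p) for p in rng.choice(free, size=n_div, replace=False))

    positions = np.array(sorted([*int_x, *int_y, *div_pos]), dtype=np.int64)
    col = {int(p): j for j, p in enumerate(positions)}
    ref_alleles = np.array([ref[p - 1] for p in positions], dtype="U1")

    # assemble per-class haplotype rows in generator order, then reorder into
    # diploid individuals with heterozygote excess
    rows_x = _class_rows(geno_x, int_x, positions, ref_alleles, col, rng)
    rows_y = _class_rows(geno_y, int_y, positions, ref_alleles, col, rng)
    for p in div_pos:  # class Y carries the diverged allele
        j = col[p]
        alt = _other_base(ref_alleles[j], rng)
        rows_y[:, j] = alt

    haps, class_per_hap = [], []
    off_x = off_y = 0
    for p in config.populations:
        genotypes = _pair_with_het_excess(
            n_x[p], n_y[p], config.pool_size, config.het_excess,
            np.random.default_rng(derive_seed(seed, "pair", p)),
        )
        for g in genotypes:
            for cls in g:
                if cls == "X":
                    haps.append(rows_x[off_x]); off_x += 1
                else:
                    haps.append(rows_y[off_y]); off_y += 1
                class_per_hap.append(cls)
    # outgroup diploid: one haplotype per class
    haps.append(rows_x[off_x]); class_per_hap.append("X")
    haps.append(rows_y[off_y]); class_per_hap.append("Y")

    haps = np.array(haps, dtype="U1") if positions.size else np.empty(
        (len(class_per_hap), 0), dtype="U1"
    )
    labels = _labels(config, {p: config.pool_size for p in config.populations})
    hs = HaplotypeSet(
        contig_id=f"locus{locus_index}", window=(0, L), positions=positions,
        ref_alleles=ref_alleles, haplotypes=haps,
        mask=np.zeros_like(haps, dtype=bool), labels=labels,
    )
    hs.reference = ref
    truth = SimTruth(
        locus_id=f"locus{locus_index}", label="balanced",
        class_per_hap=class_per_hap, class_freq=q,
        diverged_positions=list(div_pos),
    )
    return hs, truth


def _class_rows(geno, int_pos, positions, ref_alleles, col, rng):
    n = geno.shape[0]
    rows = np.tile(ref_alleles, (n, 1)) if positions.size else np.empty((n, 0), dtype="U1")
    for k, p in enumerate(int_pos):
        j = col[p]
        alt = _other_base(ref_alleles[j], rng)
        carriers = geno[:, k].astype(bool)
        rows[carriers, j] = alt
    return rows


# ---------------------------------------------------------------------------
# pool-seq read sampling
# ---------------------------------------------------------------------------

BASE_INDEX = {b: i for i, b in enumerate("ATCG")}


def sample_pool_reads(hapset: HaplotypeSet, pool_size: int, coverage_mean: float,
                      error_rate: float, seed: int) -> list[SiteCounts]:
    """Pool-seq read counts at every SNP position of ``hapset``.

    For each focal population, ``pool_size`` diploids are drawn without
    replacement from that population's individuals; per site, coverage is
    Poisson(coverage_mean), each read copies a uniformly chosen pool
    chromosome, and with probability ``error_rate`` its base is replaced by
    a uniform different base.
    """
    rng = np.random.default_rng(seed)
    pops: list[str] = []
    for lab in hapset.labels:
        if lab.species == "focal" and lab.population_id not in pops:
            pops.append(lab.population_id)
    rows_by_pop: dict[str, np.ndarray] = {}
    for p in pops:
        idx = np.array([
            i for i, lab in enumerate(hapset.labels)
            if lab.population_id == p and lab.hap_index == 0
        ])
        if idx.size < pool_size:
            raise ValueError(
                f"pool_size {pool_size} exceeds the {idx.size} individuals "
                f"available in population {p}"
            )
        chosen = np.sort(rng.choice(idx, size=pool_size, replace=False))
        rows_by_pop[p] = np.concatenate([chosen, chosen + 1])

    out = []
    n_sites = hapset.n_sites
    cov = {p: rng.poisson(coverage_mean, size=n_sites) for p in pops}
    for j in range(n_sites):
        counts = np.zeros((len(pops), 6), dtype=np.int64)
        for k, p in enumerate(pops):
            alleles = hapset.haplotypes[rows_by_pop[p], j]
            base_counts = np.zeros(4, dtype=np.int64)
            for b, i in BASE_INDEX.items():
                base_counts[i] = int((alleles == b).sum())
            freqs = base_counts / base_counts.sum()
            reads = rng.multinomial(cov[p][j], freqs)
            if error_rate > 0:
                errs = rng.binomial(reads, error_rate)
                reads = reads - errs
                for i in range(4):
                    for _ in range(errs[i]):
                        others = [x for x in range(4) if x != i]
                        reads[others[int(rng.integers(3))]] += 1
            counts[k, :4] = reads
        out.append(SiteCounts(
            hapset.contig_id, int(hapset.positions[j]),
            str(hapset.ref_alleles[j]), counts, tuple(pops),
        ))
    return out


# ---------------------------------------------------------------------------
# dataset emission
# ---------------------------------------------------------------------------

@dataclass
class DatasetPaths:
    root: Path
    fasta: Path
    gff: Path
    sync: Path
    vcf: Path
    truth: Path
    manifest: Path


def emit_dataset(config: SimConfig, outdir, overwrite: bool = False) -> DatasetPaths:
    """Write a self-consistent synthetic dataset (FASTA, GFF3, sync, phased
    VCF, truth TSV, JSON manifest) under ``outdir``.

    Loci are placed on one contig as single-exon, CDS-only genes separated by
    intergenic spacers; gene strands alternate. One randomly chosen diploid
    per focal population, plus the outgroup diploid, is emitted fully phased
    in the VCF.
    """
    outdir = Path(outdir)
    paths = DatasetPaths(
        root=outdir, fasta=outdir / "reference.fasta", gff=outdir / "genes.gff3",
        sync=outdir / "pools.sync", vcf=outdir / "phased.vcf",
        truth=outdir / "truth.tsv", manifest=outdir / "manifest.json",
    )
    existing = [p for p in vars(paths).values() if p != outdir and p.exists()]
    if existing and not overwrite:
        raise FileExistsError(f"refusing to overwrite {existing[0]}")
    outdir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(derive_seed(config.seed, "layout"))
    if config.locus_length % 3:
        raise ValueError("locus_length must be a multiple of 3 (loci are CDS exons)")

    loci: list[tuple[str, HaplotypeSet, SimTruth]] = []
    for i in range(config.n_neutral_loci):
        hs = simulate_neutral_locus(config, i)
        loci.append((f"gene_n{i}", hs, SimTruth(hs.contig_id, "neutral")))
    for i in range(config.n_balanced_loci):
        hs, truth = implant_balanced_locus(config, config.n_neutral_loci + i)
        loci.append((f"gene_b{i}", hs, truth))
    order = rng.permutation(len(loci))
    loci = [loci[i] for i in order]

    contig = "chr1"
    seq_parts, models, layout = [], [], []
    cursor = 0
    for idx, (gene_id, hs, truth) in enumerate(loci):
        spacer = _random_reference(config.intergenic_bp, rng)
        seq_parts.append(spacer)
        cursor += config.intergenic_bp
        start = cursor
        seq_parts.append(hs.reference)
        cursor += config.locus_length
        strand = "+" if idx % 2 == 0 else "-"
        ival = (start, cursor)
        models.append(GeneModel(
            gene_id=gene_id, transcript_id=f"{gene_id}.t1", contig_id=contig,
            strand=strand, exons=[ival], cds=[ival], cds_phase=[0],
        ))
        layout.append((gene_id, hs, truth, start))
    seq_parts.append(_random_reference(config.intergenic_bp, rng))
    cursor += config.intergenic_bp
    reference = "".join(seq_parts)

    write_fasta([ReferenceSeq(contig, reference)], paths.fasta)
    write_gff(models, paths.gff)

    # pools -> sync (rows only at simulated variant positions)
    sync_records: list[SiteCounts] = []
    for gene_id, hs, truth, start in layout:
        reads = sample_pool_reads(
            hs, config.pool_size, config.coverage_mean, config.error_rate,
            derive_seed(config.seed, "pool", hs.contig_id),
        )
        for rec in reads:
            sync_records.append(SiteCounts(
                contig, start + rec.pos, rec.ref_base, rec.counts, rec.population_ids,
            ))
    sync_records.sort(key=lambda r: r.pos)
    write_sync(sync_records, paths.sync)

    # phased VCF: one individual per focal population + the outgroup diploid
    chosen_ind = {
        p: int(np.random.default_rng(derive_seed(config.seed, "vcf-ind", p)).integers(config.pool_size))
        for p in config.populations
    }
    samples = [PhasedSample(f"{p}_ind", p, "focal") for p in config.populations]
    samples.append(PhasedSample("OUT_ind", OUTGROUP_POP, "outgroup"))
    vcf_sites = []
    for gene_id, hs, truth, start in layout:
        hap_rows = []
        for p in config.populations:
            first = next(
                i for i, lab in enumerate(hs.labels)
                if lab.sample_id == f"{p}_i{chosen_ind[p]}" and lab.hap_index == 0
            )
            hap_rows.append((first, first + 1))
        og = next(i for i, lab in enumerate(hs.labels) if lab.species == "outgroup")
        hap_rows.append((og, og + 1))
        for j in range(hs.n_sites):
            ref_b = str(hs.ref_alleles[j])
            site_alleles = [ref_b]
            gt = []
            for r0, r1 in hap_rows:
                pair = []
                for r in (r0, r1):
                    b = str(hs.haplotypes[r, j])
                    if b not in site_alleles:
                        site_alleles.append(b)
                    pair.append(site_alleles.index(b))
                gt.append(pair)
            # also register alleles present in the wider pool so REF/ALT
            # matches the sync records
            for b in np.unique(hs.haplotypes[:, j]):
                if b not in site_alleles:
                    site_alleles.append(str(b))
            if len(site_alleles) == 1:
                continue  # monomorphic among everything: skip
            vcf_sites.append((start + int(hs.positions[j]), ref_b, site_alleles[1:], gt))
    vcf_sites.sort(key=lambda s: s[0])
    write_phased_vcf(paths.vcf, contig, len(reference), samples, vcf_sites)

    # truth table
    with open(paths.truth, "w") as fh:
        fh.write("gene_id\tcontig\tstart\tend\tlabel\tn_diverged_sites\tclass_freqs\n")
        for gene_id, hs, truth, start in layout:
            freqs = (
                ";".join(f"{p}={truth.class_freq[p]:.4f}" for p in config.populations)
                if truth.class_freq else "."
            )
            fh.write(
                f"{gene_id}\t{contig}\t{start + 1}\t{start + config.locus_length}\t"
                f"{truth.label}\t{len(truth.diverged_positions)}\t{freqs}\n"
            )

    manifest = {
        "contig": contig,
        "populations": list(config.populations),
        "oceans": config.oceans,
        "pool_size": config.pool_size,
        "n_chrom_per_pool": config.n_chrom_per_pool,
        "coverage_mean": config.coverage_mean,
        "samples": {
            **{f"{p}_ind": {"population": p, "species": "focal"} for p in config.populations},
            "OUT_ind": {"population": OUTGROUP_POP, "species": "outgroup"},
        },
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
    }
    with open(paths.manifest, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
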
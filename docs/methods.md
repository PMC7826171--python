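# Methods

`balscan` implements a genome scan for balancing selection designed around a
specific sampling scheme: several focal populations in two ocean basins, each
genotyped as a pool of diploids (pool-seq) plus one phased single individual,
and one phased diploid of a sister-species outgroup. This note records the
models, the estimators, the synthetic-data generator, the numerical choices,
and the limitations a user should know before trusting a result.

## The scan

**Cosmopolitan SNPs and TSPs.** A site is *cosmopolitan* when it is biallelic
and its minor allele frequency is at least `maf_threshold` (default 0.05) in
every focal pool that passes coverage filters. A cosmopolitan SNP is a
*trans-species polymorphism* (TSP) when both alleles are also present in the
outgroup — with a single outgroup diploid, a heterozygous genotype. Under
neutrality with infinite-sites mutation, a polymorphism shared identically by
state across a species split of `t` generations requires the ancestral
lineage to retain it for `t` generations, which has probability of order
`exp(-t/2Ne)`; for deep splits this is negligible, so TSPs mark alleles whose
ages predate the split — the classical footprint of long-term balancing
selection. An outgroup pool, if supplied instead of a diploid, uses the same
min-count/frequency rule as the focal pools.

**Pool-seq estimators.** Per site, with read counts `c_a` over A,C,G,T and
coverage `C`:

- `pi = C/(C-1) * (1 - sum_a (c_a/C)^2)` — the unbiased mean pairwise
  difference among reads (verified exhaustively against read-pair enumeration
  for all count vectors with `C <= 30`);
- Watterson `theta_W = S / (a_n * L)` per site, `a_n = sum_{i<n} 1/i`;
- Tajima's `D` with the standard variance constants, at `n` = pool
  chromosomes (2 x diploids pooled);
- `F_ST = (pi_T - pi_S) / pi_T` in the frequency form, where `pi_S` is the
  mean within-pool heterozygosity and `pi_T` uses mean frequencies; negative
  values are clamped to 0; undefined when `pi_T = 0`.

Using the raw pool chromosome count for `theta`/`D` (rather than a
coverage-dependent effective sample size) is deliberate: every inference the
scan draws is a *contrast* between exon groups that share the coverage
regime, and the plain estimator is exactly testable against the neutral
coalescent (`theta = 4*Ne*mu`; mean `D` near 0). The min-count (2 reads) and
min-frequency (5%) SNP filters suppress sequencing error, at the price of a
slight upward bias in `D` on pool counts (singletons are discarded); again
the bias is shared by both groups in every contrast.

**Genomic classes and effects.** Sites are assigned a single class with
priority coding > 5'-UTR > 3'-UTR > intron > promoter > intergenic; the
promoter is `promoter_bp` (default 1000) immediately upstream of the TSS on
the coding strand. Only the longest transcript per gene is used. Coding SNPs
are classified synonymous/nonsynonymous by translating the reference codon
and the substituted codon on the coding strand (standard genetic code);
transcripts whose CDS length (after phase) is not a multiple of 3 are
flagged and excluded from effect calls. Enrichment of TSPs per class uses a
2x2 Fisher exact test against all discovered SNPs, odds ratio `ad/bc`,
Bonferroni-corrected across classes.

**Exon contrasts.** TSP-bearing vs other exons are compared for `pi`, `D`,
mean pairwise `F_ST`, and the sheltered-load ratio (sum of nonsynonymous
site `H_E` over sum of synonymous site `H_E`; sums, not ratios of means, so
the statistic is defined whenever any synonymous heterozygosity exists).
Because recombination localizes the footprints, exons are binned by length
(250-bp bins to 3 kb, last bin open) with percentile-bootstrap 95% CIs over
exons; both groups run through the same code path, verified by label-swap
symmetry. The gene-set folded-SFS contrast resamples genes, not SNPs, for
its CIs.

**Allele trees and CPD_w-b.** For each candidate gene (>= 1 nonsynonymous
TSP with `H_E > he_min` in every population), phased haplotypes over the
TSP-bearing exon (or +-500 bp for non-exonic TSPs) give a p-distance matrix
(mismatches over jointly unmasked sites; unphased heterozygous sites are
masked rather than randomly phased, keeping trees deterministic). A
neighbor-joining tree is built, negative branch estimates clamped to zero,
and rooted on the outgroup. The cophenetic distance (CPD) between two tips
is their path length; the statistic

    CPD_w-b = mean(within-population pairs) - mean(between-population pairs)

(outgroup excluded) is strongly negative when haplotypes cluster by
geography and positive when each individual's two haplotypes straddle two
deep allelic classes. Significance: one-sided permutation of population
labels over non-outgroup tips, `p = (1 + #{perm >= obs}) / (n_perm + 1)`,
Bonferroni across candidate genes. A locus is *ancient* when CPD_w-b > 0,
the adjusted p clears `alpha` (default 0.05), and the ocean-basin tip sets
are not reciprocally monophyletic on the rooted tree; otherwise *recent*.

NJ on p-distances was chosen over likelihood trees because it is
deterministic, exact on additive matrices (tested), and adequate for sub-kb
windows where LD is strong; the permutation test was chosen as the most
assumption-free significance construction. Its resolution limit is discussed
under Limitations.

## The synthetic-data generator

The generator produces datasets with the statistical structure the scan
assumes, so the whole pipeline is testable without any external download.

**Demography.** Three-level split model: the outgroup species diverges at
`t_split_species` (default 8e6 generations), the two ocean basins at
`t_split_oceans` (default 2e6), populations within a basin are panmictic.
`Ne = 5e5` and `mu = 2e-9` per site per generation give within-population
diversity `4*Ne*mu = 0.4%`, the right order for a high-diversity marine
invertebrate, while `t_split_species / 2Ne = 8` makes neutral trans-species
polymorphism vanishingly rare (probability ~ e^-8 per lineage) — the scan's
specificity is therefore a falsifiable property of the generator, not an
assumption. Neutral loci are coalescent simulations (msprime) under this
demography with infinite-sites mutation (continuous positions mapped to
distinct integer sites).

**Balanced loci.** A balanced locus carries two allelic classes X and Y
separated by `Poisson(2*mu*t_balanced*L)` fixed differences (default
`t_balanced = 1e7`, older than the species split). Each class's haplotypes
carry their own within-class variation, simulated as a coalescent under the
same split demography — each sampled haplotype descends from one class and
accumulates its own mutations, with realistic (genealogical) sharing rather
than a star phylogeny, which at these mutation scalings would demand more
mutations than a sub-kb locus has sites. Class frequencies are drawn per
population from `class_freq_range` (default [0.2, 0.8]), clipped so both
classes are present in every pool; the outgroup diploid is an X/Y
heterozygote. Every diverged site is therefore a TSP by construction, which
is what parameter-recovery tests recover.

**Heterozygote excess.** Haplotypes are paired into diploids with an excess
of X/Y heterozygotes over Hardy-Weinberg: `n_het` is `(1 + het_excess)`
times the HWE expectation (default `het_excess = 0.5`), capped by the allele
counts. This models the mechanism that maintains such polymorphisms —
marginal overdominance under intense genotype-dependent juvenile mortality
(survival from settlement to maturity can be ~0.2%), which enriches
surviving adults for heterozygotes. It matters for the allele trees: with
one phased individual per population, the within-population cophenetic pairs
are exactly the individuals' own haplotype pairs, and CPD_w-b > 0 requires
those individuals to be class-heterozygous.

**Pool-seq observation model.** Per site: coverage ~ Poisson(`coverage_mean`,
default 50); each read copies a uniformly chosen chromosome of the pool
(`pool_size` diploids drawn without replacement, default 24, matching pools
of 20-38 individuals); with probability `error_rate` (default 0.001) the
read base is replaced by a uniform different base. Reads therefore sample
pool chromosomes *with* replacement, so read-based `pi` estimates the pool
heterozygosity `2p(1-p)` — it matches the haplotype-path `pi` up to the
`n/(n-1)` factor, which the consistency tests account for.

**Dataset emission.** Loci are placed on one contig as single-exon CDS
genes (length divisible by 3, alternating strands) separated by 2-kb
intergenic spacers; pools are written as popoolation-style sync rows at the
simulated variant positions; one randomly chosen diploid per population plus
the outgroup diploid is written fully phased to VCF; ground truth (locus
label, class frequencies, diverged-site count) goes to a TSV and the sample
manifest to JSON. One master seed determines every output byte; per-stage
seeds are derived by hashing stage names, so adding a stage never perturbs
another stage's randomness.

**What the generator does not emulate.** Sync rows exist only at simulated
variant sites (real pipelines emit invariant rows too — window lengths come
from the GFF instead); there is no recombination within loci by default
(windows are sub-kb; a per-locus rate exists for robustness checks), no
mapping or reference bias, no indels or structural variation, no intron/UTR
variation in emitted genes (those classes are exercised by unit fixtures),
and no spatial frequency clines — class frequencies are independent across
populations because the signal of interest is "segregates everywhere", not a
particular spatial pattern. Passing tests demonstrate the statistical
machinery is correct under the stated model, not that real data meet the
model.

## Numerical choices

- Internal coordinates are 0-based half-open; all on-disk formats (GFF, VCF,
  sync) are 1-based inclusive; conversion happens only at the I/O boundary.
- Minor-allele ties at exactly 50/50 reads break deterministically (the
  later-indexed base is minor).
- Distance thinning keeps a site at exactly `min_dist` from the last kept
  site (>= rule).
- `H_E > he_min` is a strict inequality (a population at minor frequency
  0.18377 fails `he_min = 0.30`).
- Sites with more than two alleles passing the min-count/frequency filter
  are excluded from TSP logic but still counted in `pi`.
- Tajima's `D` is reported only with >= 3 segregating sites and positive
  variance; `F_ST` is missing when both pools are monomorphic for the same
  allele; the sheltered-load ratio is missing without synonymous `H_E`.
- Permutation p-values use the add-one rule and are valid (never zero);
  `n_perm >= 99` is enforced.
- Bootstrap with `n_boot = 0` returns point estimates, deterministically.

## Limitations

**Resolution of the label-permutation test.** With P populations of one
phased diploid each, permuting population labels over the 2P non-outgroup
tips can only distinguish pairings of tips; the probability that a random
relabeling pairs every population across the two allele classes is
`2^P / C(2P, P)` — about 0.069 for P = 6. The one-sided p-value for even a
textbook-perfect ancient tree therefore bottoms out around 0.03-0.07, and
after Bonferroni correction across tens of candidate genes the *ancient*
call essentially never fires at `alpha = 0.05` under this sampling design.
This is a structural property of the design (12 exchangeable tips), not of
the statistic: CPD_w-b itself separates the classes cleanly (balanced loci
are overwhelmingly positive, neutral structured loci strongly negative, as
the recovery tests show). Confident *ancient* classification at this sample
size needs either more phased individuals per population or an external null
(e.g., the genome-wide distribution of CPD_w-b at non-candidate loci), which
is out of scope here. The acceptance suite reports the classification rates
honestly rather than relaxing the gate.

**Degenerate star null.** On a pure star tree, CPD_w-b is identically zero
for every labeling (each tip contributes to exactly one within pair, so both
means reduce to the same average tip depth). Null-uniformity checks of the
permutation test therefore use star distances with small iid per-pair jitter
— the noise finite-sites p-distances always carry — which keeps labels
exchangeable while making the statistic continuous.

**Other caveats.** Pool frequencies are point estimates; no binomial CI is
propagated into the cosmopolitan/H_E rules (keeps them deterministic).
Candidate genes are defined as genes with >= 1 nonsynonymous TSP among the
H_E-filtered TSPs; alternative chains (e.g., NS status before the H_E
filter) change the candidate count but not the machinery. The `theta`/`D`
estimators ignore the coverage-dependent effective sample size of pool-seq;
absolute values are comparable across groups of the same design, not across
studies.
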
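"""Calling cosmopolitan SNPs and trans-species polymorphisms (TSPs).

A *cosmopolitan SNP* is a biallelic site whose minor allele segregates at or
above the minor-allele-frequency threshold in every focal population. A
cosmopolitan SNP is a *TSP* when both of its alleles are also observed in the
outgroup species — for a single outgroup diploid, a heterozygous genotype.
Because segregating neutral variation is lost after speciation (absent
recurrent mutation), such sites imply allele ages predating the species
split, the classical footprint of long-term balancing selection.

The module also annotates each SNP with a genomic class (coding / UTR /
intron / promoter / intergenic), classifies coding SNPs as synonymous or
nonsynonymous, thins site lists by distance, filters TSPs on expected
heterozygosity, and tests per-class TSP enrichment with Fisher's exact test
(Bonferroni-corrected across classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from intervaltree import IntervalTree
from scipy import stats

from .formats_io import GeneModel, ReferenceSeq, SiteCounts
from .poolseq_stats import (
    StatFilters,
    heterozygosity,
    major_minor,
    n_observed_alleles,
    usable_coverage,
)

GENOMIC_CLASSES = ("coding", "utr5", "utr3", "intron", "promoter", "intergenic")
BASES = "ATCG"


@dataclass
class TspRecord:
    contig_id: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    alt_freq: dict[str, float]  # per focal population
    is_cosmopolitan: bool
    outgroup_state: str  # both_alleles | ref_only | alt_only | missing
    genomic_class: str = "intergenic"
    effect: str = "noncoding"  # NS | S | noncoding | missing
    gene_id: str | None = None
    he: dict[str, float] = field(default_factory=dict)

    @property
    def is_tsp(self) -> bool:
        return self.is_cosmopolitan and self.outgroup_state == "both_alleles"


@dataclass
class EnrichmentResult:
    genomic_class: str
    a: int  # TSPs in class
    b: int  # TSPs outside class
    c: int  # non-TSP SNPs in class
    d: int  # non-TSP SNPs outside class
    odds_ratio: float
    p_value: float
    adjusted_p: float


# ---------------------------------------------------------------------------
# site calling
# ---------------------------------------------------------------------------

def call_cosmopolitan(site: SiteCounts, maf_threshold: float = 0.05,
                      filters: StatFilters | None = None):
    """Return (is_cosmopolitan, ref_allele, alt_allele, per-pop alt freq).

    True iff the site is biallelic on the pooled counts and its minor allele
    frequency is >= ``maf_threshold`` in EVERY focal pool. A pool failing
    coverage filters counts as missing data: not cosmopolitan. Sites with
    more than two observed alleles are excluded (returns all-None alleles).
    """
    filters = filters or StatFilters()
    total = site.counts.sum(axis=0)
    if n_observed_alleles(total, filters) > 2:
        return False, None, None, {}
    mm = major_minor(total, filters.min_count, filters.maf)
    if mm is None:
        return False, None, None, {}
    major, minor = mm
    ref_idx = BASES.index(site.ref_base) if site.ref_base in BASES else major
    alt_idx = minor if ref_idx == major else major
    if ref_idx not in (major, minor):
        ref_idx, alt_idx = major, minor  # ref base not among the two alleles
    freqs: dict[str, float] = {}
    ok = True
    for k, pop in enumerate(site.population_ids):
        c = site.counts[k]
        cov = usable_coverage(c)
        if cov < filters.min_coverage or cov > filters.max_coverage:
            ok = False
            break
        p_alt = float(c[alt_idx] / cov)
        freqs[pop] = p_alt
        if min(p_alt, 1.0 - p_alt) < maf_threshold:
            ok = False
    return ok, BASES[ref_idx], BASES[alt_idx], freqs


def call_tsp(site: SiteCounts, ref_allele: str, alt_allele: str,
             alt_freq: dict[str, float], outgroup_alleles) -> TspRecord:
    """Build a :class:`TspRecord` for a cosmopolitan site.

    ``outgroup_alleles`` is the outgroup diploid's allele pair at the site
    (strings), or None when the site is absent from the outgroup VCF.
    """
    if outgroup_alleles is None:
        state = "missing"
    else:
        og = set(outgroup_alleles)
        has_ref, has_alt = ref_allele in og, alt_allele in og
        if has_ref and has_alt:
            state = "both_alleles"
        elif has_ref:
            state = "ref_only"
        elif has_alt:
            state = "alt_only"
        else:
            state = "missing"
    he = {p: heterozygosity(f) for p, f in alt_freq.items()}
    return TspRecord(
        contig_id=site.contig_id, pos=site.pos, ref_allele=ref_allele,
        alt_allele=alt_allele, alt_freq=alt_freq, is_cosmopolitan=True,
        outgroup_state=state, he=he,
    )


def thin_by_distance(sites, min_dist: int):
    """Greedy left-to-right thinning: keep a site iff it lies >= ``min_dist``
    from the last kept site on the same contig. Sites are (contig, pos)
    tuples or objects with those attributes, sorted; unsorted input raises.
    """
    kept = []
    last: dict[str, int] = {}
    prev_key = None
    for s in sites:
        contig, pos = (s.contig_id, s.pos) if hasattr(s, "contig_id") else s
        key = (contig, pos)
        if prev_key is not None and key[0] == prev_key[0] and key[1] < prev_key[1]:
            raise ValueError(f"sites not sorted at {contig}:{pos}")
        prev_key = key
        if contig not in last or pos - last[contig] >= min_dist:
            kept.append(s)
            last[contig] = pos
    return kept


# ---------------------------------------------------------------------------
# genomic class annotation
# ---------------------------------------------------------------------------

class GenomeAnnotation:
    """Interval index over gene models for class assignment and NS/S calls.

    Assignment priority on overlap: coding > utr5 > utr3 > intron > promoter
    > intergenic. The promoter is ``promoter_bp`` immediately upstream of the
    TSS on the coding strand.
    """

    def __init__(self, gene_models: dict[str, GeneModel], promoter_bp: int = 1000):
        self.models = gene_models
        self.promoter_bp = promoter_bp
        self.trees: dict[str, dict[str, IntervalTree]] = {}
        for m in gene_models.values():
            per_contig = self.trees.setdefault(m.contig_id, {
                c: IntervalTree() for c in GENOMIC_CLASSES[:5]
            })
            for s, e in m.cds:
                per_contig["coding"].addi(s, e, m.gene_id)
            for s, e in m.utr5:
                per_contig["utr5"].addi(s, e, m.gene_id)
            for s, e in m.utr3:
                per_contig["utr3"].addi(s, e, m.gene_id)
            for s, e in m.introns():
                per_contig["intron"].addi(s, e, m.gene_id)
            if m.strand == "+":
                ps, pe = m.tss - promoter_bp, m.tss
            else:
                ps, pe = m.tss + 1, m.tss + 1 + promoter_bp
            if pe > max(0, ps):
                per_contig["promoter"].addi(max(0, ps), pe, m.gene_id)

    def assign(self, contig: str, pos: int) -> tuple[str, str | None]:
        """(genomic_class, gene_id) for a 1-based position."""
        per_contig = self.trees.get(contig)
        if not per_contig:
            return "intergenic", None
        p0 = pos - 1
        for cls in GENOMIC_CLASSES[:5]:
            hits = per_contig[cls][p0]
            if hits:
                return cls, sorted(h.data for h in hits)[0]
        return "intergenic", None


def assign_genomic_class(contig: str, pos: int, annotation: GenomeAnnotation
                         ) -> tuple[str, str | None]:
    return annotation.assign(contig, pos)


def classify_ns_s(contig: str, pos: int, ref_allele: str, alt_allele: str,
                  model: GeneModel, reference: ReferenceSeq) -> str | None:
    """"NS" or "S" for a coding SNP; None when the codon is unusable.

    Translates the reference codon and the codon with the alternate allele
    substituted, on the coding strand (reverse complement for '-' genes),
    under the standard genetic code. Codons containing N, positions outside
    the CDS, and models failing the frame check return None.
    """
    if not model.cds_ok:
        return None
    p0 = pos - 1
    # CDS-local coordinate, walking 5'->3' on the coding strand
    offset = model.cds_phase[0] if model.cds_phase else 0
    cds_pos = None
    walked = 0
    for s, e in model.cds:
        if s <= p0 < e:
            within = (p0 - s) if model.strand == "+" else (e - 1 - p0)
            cds_pos = walked + within
            break
        walked += e - s
    if cds_pos is None:
        return None
    cds_pos -= offset
    if cds_pos < 0:
        return None
    codon_idx, codon_off = divmod(cds_pos, 3)
    cds_seq = _coding_sequence(model, reference)
    start = offset + codon_idx * 3
    codon = cds_seq[start:start + 3]
    if len(codon) < 3 or "N" in codon:
        return None
    sub = ref_allele if model.strand == "+" else _complement(ref_allele)
    if codon[codon_off] != sub:
        # reference mismatch: fall back on the codon as found
        pass
    alt = alt_allele if model.strand == "+" else _complement(alt_allele)
    if "N" in (sub, alt):
        return None
    mutant = codon[:codon_off] + alt + codon[codon_off + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutant).translate())
    return "NS" if aa_ref != aa_alt else "S"


def _coding_sequence(model: GeneModel, reference: ReferenceSeq) -> str:
    parts = []
    for s, e in model.cds:
        chunk = reference.sequence[s:e]
        if model.strand == "-":
            chunk = str(Seq(chunk).reverse_complement())
        parts.append(chunk)
    return "".join(parts)


def _complement(base: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}[base]


def annotate_records(records: list[TspRecord], annotation: GenomeAnnotation,
                     references: dict[str, ReferenceSeq]) -> None:
    """Fill genomic_class, gene_id and effect in place."""
    for r in records:
        cls, gene_id = annotation.assign(r.contig_id, r.pos)
        r.genomic_class = cls
        r.gene_id = gene_id
        if cls == "coding" and gene_id is not None:
            model = annotation.models[gene_id]
            effect = classify_ns_s(
                r.contig_id, r.pos, r.ref_allele, r.alt_allele, model,
                references[r.contig_id],
            )
            r.effect = effect if effect is not None else "missing"
        else:
            r.effect = "noncoding"


# ---------------------------------------------------------------------------
# enrichment and filtering
# ---------------------------------------------------------------------------

def enrichment_test(tsp_records: list[TspRecord], all_snp_records: list[TspRecord]
                    ) -> list[EnrichmentResult]:
    """Per-class 2x2 Fisher exact test of TSP membership vs class membership.

    ``all_snp_records`` is the full discovered-SNP set (TSPs included);
    odds ratio is ad/bc; p-values are Bonferroni-adjusted across the classes
    actually tested. Classes with zero total SNPs are skipped.
    """
    tsp_keys = {(r.contig_id, r.pos) for r in tsp_records}
    n_tsp = len(tsp_keys)
    n_all = len(all_snp_records)
    n_non = n_all - n_tsp
    results = []
    for cls in GENOMIC_CLASSES:
        in_class = [r for r in all_snp_records if r.genomic_class == cls]
        if not in_class:
            continue
        a = sum((r.contig_id, r.pos) in tsp_keys for r in in_class)
        c = len(in_class) - a
        b = n_tsp - a
        d = n_non - c
        with np.errstate(divide="ignore", invalid="ignore"):
            if b * c == 0:
                odds = np.inf if a * d > 0 else np.nan
            else:
                odds = (a * d) / (b * c)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        results.append(EnrichmentResult(cls, a, b, c, d, float(odds), float(p), 1.0))
    k = len(results)
    for r in results:
        r.adjusted_p = min(1.0, r.p_value * k)
    return results


def filter_by_he(tsp_records: list[TspRecord], he_min: float = 0.30
                 ) -> list[TspRecord]:
    """TSPs whose expected heterozygosity strictly exceeds ``he_min`` in
    every focal population."""
    out = []
    for r in tsp_records:
        if r.he and all(h > he_min for h in r.he.values()):
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# scan driver over sync records
# ---------------------------------------------------------------------------

def scan_sites(site_counts, outgroup_lookup, maf_threshold: float = 0.05,
               filters: StatFilters | None = None
               ) -> tuple[list[TspRecord], list[TspRecord]]:
    """Scan sync records; return (all biallelic SNP records, TSP records).

    ``outgroup_lookup(contig, pos, ref, alt)`` returns the outgroup allele
    pair or None. Non-cosmopolitan biallelic SNPs are recorded (for the
    enrichment denominator) with outgroup_state left 'missing'.
    """
    filters = filters or StatFilters()
    all_records: list[TspRecord] = []
    tsps: list[TspRecord] = []
    for site in site_counts:
        cosmo, ref, alt, freqs = call_cosmopolitan(site, maf_threshold, filters)
        if ref is None:
            total = site.counts.sum(axis=0)
            mm = major_minor(total, filters.min_count, filters.maf)
            if mm is None:
                continue  # monomorphic or unusable
            # >2 alleles: excluded from TSP logic entirely
            continue
        if not cosmo:
            all_records.append(TspRecord(
                contig_id=site.contig_id, pos=site.pos, ref_allele=ref,
                alt_allele=alt, alt_freq=freqs, is_cosmopolitan=False,
                outgroup_state="missing",
            ))
            continue
        rec = call_tsp(site, ref, alt, freqs,
                       outgroup_lookup(site.contig_id, site.pos, ref, alt))
        all_records.append(rec)
        if rec.is_tsp:
            tsps.append(rec)
    return all_records, tsps
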
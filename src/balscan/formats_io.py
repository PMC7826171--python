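"""Interchange-format I/O: FASTA, GFF3, popoolation sync, phased VCF, newick.

Coordinate conventions
----------------------
All on-disk formats handled here (GFF3, VCF, sync) are 1-based inclusive.
Everything held in memory by this package is 0-based half-open, with the
single exception of :class:`SiteCounts.pos`, which mirrors the sync file
verbatim (1-based) because those records are written back out unchanged.
Conversion happens at the I/O boundary only, via :func:`to_internal` and
:func:`to_external`.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ATCG"
SYNC_ALLELES = "ATCGND"  # column order of a sync 6-tuple: A:T:C:G:N:del


class FormatError(ValueError):
    """A malformed record in one of the interchange formats."""


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------

def to_internal(start_1based: int, end_1based_inclusive: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open."""
    return start_1based - 1, end_1based_inclusive


def to_external(interval: tuple[int, int]) -> tuple[int, int]:
    """0-based half-open interval -> 1-based inclusive."""
    return interval[0] + 1, interval[1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ReferenceSeq:
    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise FormatError(f"empty sequence for contig {self.contig_id!r}")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise FormatError(
                f"contig {self.contig_id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """One transcript's gene model.

    Intervals are internal (0-based half-open) and listed 5'->3' on the
    coding strand, i.e. in descending genomic order for ``strand == '-'``.
    ``tss`` is the 0-based position of the first transcribed base.
    ``cds_ok`` is False when the CDS length (after subtracting the phase of
    the 5'-most CDS segment) is not divisible by 3; such models are kept but
    excluded from synonymous/nonsynonymous annotation.
    """

    gene_id: str
    transcript_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    cds_phase: list[int] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.transcript_id}: strand must be + or -")
        ivals = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise FormatError(f"{self.transcript_id}: overlapping exons")
        if self.cds and not (self.utr5 or self.utr3):
            reverse = self.strand == "-"
            utr5, utr3 = _derive_utrs(ivals, self.cds, self.strand)
            self.utr5 = sorted(utr5, reverse=reverse)
            self.utr3 = sorted(utr3, reverse=reverse)

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    @property
    def tss(self) -> int:
        s, e = self.span
        return s if self.strand == "+" else e - 1

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def cds_ok(self) -> bool:
        if not self.cds:
            return False
        first_phase = self.cds_phase[0] if self.cds_phase else 0
        return (self.cds_length - first_phase) % 3 == 0

    def introns(self) -> list[tuple[int, int]]:
        ivals = sorted(self.exons)
        return [(e1, s2) for (_, e1), (s2, _) in zip(ivals, ivals[1:]) if s2 > e1]


@dataclass
class SiteCounts:
    """Per-site pool-seq read counts, one 6-vector (A,T,C,G,N,del) per pool.

    ``pos`` is 1-based, mirroring the sync file.
    """

    contig_id: str
    pos: int
    ref_base: str
    counts: np.ndarray  # shape (n_pops, 6), non-negative ints
    population_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 6:
            raise FormatError(f"{self.contig_id}:{self.pos}: counts must be (n_pops, 6)")
        if self.counts.shape[0] != len(self.population_ids):
            raise FormatError(
                f"{self.contig_id}:{self.pos}: {self.counts.shape[0]} count vectors "
                f"for {len(self.population_ids)} populations"
            )
        if (self.counts < 0).any():
            raise FormatError(f"{self.contig_id}:{self.pos}: negative read count")


@dataclass
class PhasedSample:
    sample_id: str
    population_id: str
    species: str  # "focal" or "outgroup"


@dataclass
class HaplotypeLabel:
    sample_id: str
    population_id: str
    species: str
    hap_index: int  # 0 or 1 within the diploid

    @property
    def tip_id(self) -> str:
        return f"{self.sample_id}.{self.hap_index}"


@dataclass
class HaplotypeSet:
    """Phased haplotypes over the SNP positions of one genomic window.

    ``haplotypes`` is an (n_haps, n_sites) array of single characters;
    ``mask`` marks per-haplotype missing sites (True = masked). Haplotypes
    come in pairs: two consecutive rows per diploid sample.
    """

    contig_id: str
    window: tuple[int, int]  # 0-based half-open
    positions: np.ndarray  # 1-based site positions, ascending
    ref_alleles: np.ndarray  # reference base per site
    haplotypes: np.ndarray  # (n_haps, n_sites) dtype '<U1'
    mask: np.ndarray  # (n_haps, n_sites) bool
    labels: list[HaplotypeLabel]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype="U1")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.haplotypes.shape != self.mask.shape:
            raise ValueError("haplotypes and mask shapes differ")
        if self.haplotypes.shape != (len(self.labels), len(self.positions)):
            raise ValueError("haplotype matrix shape does not match labels x positions")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def population_of(self, i: int) -> str:
        return self.labels[i].population_id

    def subset(self, keep: np.ndarray) -> "HaplotypeSet":
        keep = np.asarray(keep)
        return HaplotypeSet(
            self.contig_id,
            self.window,
            self.positions,
            self.ref_alleles,
            self.haplotypes[keep],
            self.mask[keep],
            [self.labels[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.labels[i] for i in keep],
        )

    def expand(self, reference: str, offset: int = 0) -> list[str]:
        """Full haplotype strings over ``reference`` (masked sites -> 'N').

        ``offset`` is the 0-based start of the reference slice on the contig.
        """
        out = []
        idx = self.positions - 1 - offset
        for h in range(self.n_haplotypes):
            seq = list(reference)
            for j, p in enumerate(idx):
                seq[p] = "N" if self.mask[h, j] else self.haplotypes[h, j]
            out.append("".join(seq))
        return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, ReferenceSeq]:
    refs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        refs[rec.id] = ReferenceSeq(rec.id, str(rec.seq))
    return refs


def write_fasta(refs: dict[str, ReferenceSeq] | list[ReferenceSeq], path) -> None:
    if isinstance(refs, dict):
        refs = list(refs.values())
    records = [SeqRecord(Seq(r.sequence), id=r.contig_id, description="") for r in refs]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# popoolation sync
# ---------------------------------------------------------------------------

def read_sync(path, population_ids):
    """Iterate :class:`SiteCounts` from a popoolation2-style sync file.

    Each line: contig, 1-based position, reference base, then one
    ``A:T:C:G:N:del`` column per pool. Malformed lines raise
    :class:`FormatError` naming the line number.
    """
    population_ids = tuple(population_ids)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}: line {lineno}: fewer than 4 columns")
            pools = fields[3:]
            if len(pools) != len(population_ids):
                raise FormatError(
                    f"{path}: line {lineno}: {len(pools)} pool columns, "
                    f"expected {len(population_ids)}"
                )
            counts = np.empty((len(pools), 6), dtype=np.int64)
            for i, col in enumerate(pools):
                parts = col.split(":")
                if len(parts) != 6:
                    raise FormatError(
                        f"{path}: line {lineno}: pool column {i + 1} is not a 6-tuple"
                    )
                try:
                    counts[i] = [int(x) for x in parts]
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: non-integer count in pool {i + 1}"
                    ) from exc
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer position") from exc
            yield SiteCounts(fields[0], pos, fields[2], counts, population_ids)


def write_sync(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            cols = [":".join(str(c) for c in row) for row in rec.counts]
            fh.write("\t".join([rec.contig_id, str(rec.pos), rec.ref_base, *cols]) + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff(path) -> list[GeneModel]:
    """Read GFF3 gene models, one :class:`GeneModel` per transcript.

    CDS features whose parent transcript is missing are skipped with a
    warning. UTR intervals are taken from explicit five_prime_UTR /
    three_prime_UTR features when present, otherwise derived as the
    exon minus CDS remainder on the appropriate side.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    known_transcripts = set()
    models = []
    for tx_type in ("mRNA", "transcript"):
        for tx in db.features_of_type(tx_type):
            known_transcripts.add(tx.id)
            gene_id = tx.attributes.get("Parent", [tx.id])[0]
            exons, cds, phases, utr5, utr3 = [], [], [], [], []
            for child in db.children(tx, level=1):
                ival = to_internal(child.start, child.end)
                if child.featuretype == "exon":
                    exons.append(ival)
                elif child.featuretype == "CDS":
                    cds.append(ival)
                    phases.append(int(child.frame) if child.frame in "012" else 0)
                elif child.featuretype == "five_prime_UTR":
                    utr5.append(ival)
                elif child.featuretype == "three_prime_UTR":
                    utr3.append(ival)
            if not exons:
                exons = sorted(cds) or [to_internal(tx.start, tx.end)]
            reverse = tx.strand == "-"
            order = lambda iv: sorted(iv, reverse=reverse)  # noqa: E731
            if cds:
                pairs = sorted(zip(cds, phases), key=lambda p: p[0], reverse=reverse)
                cds = [p[0] for p in pairs]
                phases = [p[1] for p in pairs]
            if not (utr5 or utr3) and cds:
                utr5, utr3 = _derive_utrs(order(exons), cds, tx.strand)
            model = GeneModel(
                gene_id=gene_id, transcript_id=tx.id, contig_id=tx.seqid,
                strand=tx.strand, exons=order(exons), cds=cds, cds_phase=phases,
                utr5=order(utr5), utr3=order(utr3),
            )
            if cds and not model.cds_ok:
                logger.warning(
                    "transcript %s: CDS length %d not divisible by 3 after phase; "
                    "excluded from NS/S annotation", tx.id, model.cds_length,
                )
            models.append(model)
    # orphan CDS check
    for c in db.features_of_type("CDS"):
        parents = c.attributes.get("Parent", [])
        if not parents or all(p not in known_transcripts for p in parents):
            warnings.warn(f"CDS at {c.seqid}:{c.start}-{c.end} has no parent transcript; skipped")
    return models


def _derive_utrs(exons, cds, strand):
    cds_lo = min(s for s, _ in cds)
    cds_hi = max(e for _, e in cds)
    before, after = [], []  # genomic left / right of the CDS span
    for s, e in exons:
        if s < cds_lo:
            before.append((s, min(e, cds_lo)))
        if e > cds_hi:
            after.append((max(s, cds_hi), e))
    return (before, after) if strand == "+" else (after, before)


def longest_transcripts(models: list[GeneModel]) -> dict[str, GeneModel]:
    """Pick one transcript per gene: longest CDS, ties broken by id."""
    best: dict[str, GeneModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        key = (m.cds_length, m.transcript_id)
        if cur is None or key > (cur.cds_length, cur.transcript_id):
            best[m.gene_id] = m
    return best


def write_gff(models: list[GeneModel], path) -> None:
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, txs in by_gene.items():
            lo = min(t.span[0] for t in txs)
            hi = max(t.span[1] for t in txs)
            contig, strand = txs[0].contig_id, txs[0].strand
            s1, e1 = to_external((lo, hi))
            fh.write(f"{contig}\tbalscan\tgene\t{s1}\t{e1}\t.\t{strand}\t.\tID={gene_id}\n")
            for t in txs:
                s1, e1 = to_external(t.span)
                fh.write(f"{contig}\tbalscan\tmRNA\t{s1}\t{e1}\t.\t{strand}\t.\tID={t.transcript_id};Parent={gene_id}\n")
                for ival in t.exons:
                    s1, e1 = to_external(ival)
                    fh.write(f"{contig}\tbalscan\texon\t{s1}\t{e1}\t.\t{strand}\t.\tParent={t.transcript_id}\n")
                for ival, ph in zip(t.cds, t.cds_phase or [0] * len(t.cds)):
                    s1, e1 = to_external(ival)
                    fh.write(f"{contig}\tbalscan\tCDS\t{s1}\t{e1}\t.\t{strand}\t{ph}\tParent={t.transcript_id}\n")


# ---------------------------------------------------------------------------
# phased VCF
# ---------------------------------------------------------------------------

class PhasedGenotypes:
    """Phased diploid genotypes for a panel of single individuals.

    Backed by integer allele indices; ``gt[site, sample, k]`` is the allele
    index of haplotype ``k`` (-1 = missing). Unphased heterozygous calls are
    masked (treated as missing in both haplotypes) so that downstream allele
    trees are deterministic; unphased homozygous calls are unambiguous and
    kept.
    """

    def __init__(self, samples, contigs, positions, refs, alts, gt, phased):
        self.samples: list[PhasedSample] = samples
        self.contigs = np.asarray(contigs)
        self.positions = np.asarray(positions, dtype=np.int64)  # 1-based
        self.refs = list(refs)
        self.alts = [tuple(a) for a in alts]
        self.gt = np.asarray(gt, dtype=np.int8)
        self.phased = np.asarray(phased, dtype=bool)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sample_index(self, sample_id: str) -> int:
        for i, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return i
        raise KeyError(sample_id)

    def alleles_at(self, i: int) -> list[str]:
        return [self.refs[i], *self.alts[i]]

    def genotype_at(self, contig: str, pos: int, sample_id: str) -> tuple[str, ...] | None:
        """Allele strings of one sample at one 1-based site, or None if absent/missing."""
        hit = np.flatnonzero((self.contigs == contig) & (self.positions == pos))
        if hit.size == 0:
            return None
        i = int(hit[0])
        j = self.sample_index(sample_id)
        g = self.gt[i, j]
        if (g < 0).any():
            return None
        alleles = self.alleles_at(i)
        return alleles[g[0]], alleles[g[1]]

    def haplotypes_in_window(self, contig: str, window: tuple[int, int]) -> HaplotypeSet:
        """Extract a :class:`HaplotypeSet` over SNPs in a 0-based half-open window."""
        start0, end0 = window
        sel = np.flatnonzero(
            (self.contigs == contig)
            & (self.positions - 1 >= start0)
            & (self.positions - 1 < end0)
        )
        n_haps = 2 * len(self.samples)
        haps = np.full((n_haps, sel.size), "N", dtype="U1")
        mask = np.zeros((n_haps, sel.size), dtype=bool)
        for j, i in enumerate(sel):
            alleles = self.alleles_at(i)
            for s in range(len(self.samples)):
                g = self.gt[i, s]
                missing = (g[0] < 0) or (g[1] < 0)
                het = (not missing) and g[0] != g[1]
                masked = missing or (het and not self.phased[i, s])
                for k in (0, 1):
                    row = 2 * s + k
                    if masked:
                        mask[row, j] = True
                    else:
                        haps[row, j] = alleles[g[k]]
        labels = [
            HaplotypeLabel(s.sample_id, s.population_id, s.species, k)
            for s in self.samples
            for k in (0, 1)
        ]
        return HaplotypeSet(
            contig, window, self.positions[sel], np.array([self.refs[i] for i in sel]),
            haps, mask, labels,
        )


def read_phased_vcf(path, manifest: dict[str, tuple[str, str]]) -> PhasedGenotypes:
    """Read a VCF with phased GT into a :class:`PhasedGenotypes` panel.

    ``manifest`` maps sample id -> (population_id, species). Samples absent
    from the manifest are ignored.
    """
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = [s for s in vf.header.samples if s in manifest]
        if not vcf_samples:
            raise FormatError(f"{path}: no VCF sample matches the manifest")
        samples = [PhasedSample(s, manifest[s][0], manifest[s][1]) for s in vcf_samples]
        contigs, positions, refs, alts, gts, phased = [], [], [], [], [], []
        for rec in vf:
            contigs.append(rec.chrom)
            positions.append(rec.pos)
            refs.append(rec.ref)
            alts.append(tuple(rec.alts or ()))
            row = np.full((len(vcf_samples), 2), -1, dtype=np.int8)
            ph = np.zeros(len(vcf_samples), dtype=bool)
            for j, s in enumerate(vcf_samples):
                call = rec.samples[s]
                g = call.get("GT")
                if g is not None and len(g) == 2 and g[0] is not None and g[1] is not None:
                    row[j] = g
                    ph[j] = bool(call.phased)
                else:
                    ph[j] = False
            gts.append(row)
            phased.append(ph)
    if not positions:
        gt = np.zeros((0, len(samples), 2), dtype=np.int8)
        ph = np.zeros((0, len(samples)), dtype=bool)
        return PhasedGenotypes(samples, [], [], [], [], gt, ph)
    return PhasedGenotypes(
        samples, contigs, positions, refs, alts, np.stack(gts), np.stack(phased)
    )


def write_phased_vcf(path, contig: str, contig_length: int, samples: list[PhasedSample],
                     sites) -> None:
    """Write phased genotypes to a plain-text VCF.

    ``sites`` is an iterable of (pos_1based, ref, alts, gt) where ``gt`` is an
    (n_samples, 2) array of allele indices.
    """
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in samples:
        header.add_sample(s.sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for pos, ref, alt_list, gt in sites:
            rec = out.new_record(
                contig=contig, start=pos - 1, stop=pos,
                alleles=(ref, *alt_list), filter="PASS",
            )
            for j, s in enumerate(samples):
                rec.samples[s.sample_id]["GT"] = (int(gt[j][0]), int(gt[j][1]))
                rec.samples[s.sample_id].phased = True
            out.write(rec)


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

_NEWICK_FORBIDDEN = set(":;,()[]'\"")


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to newick; rejects unlabeled or unsafe tip labels."""
    for tip in tree.tips():
        if not tip.name:
            raise FormatError("tree has an unlabeled tip")
        if set(tip.name) & _NEWICK_FORBIDDEN or any(c.isspace() for c in tip.name):
            raise FormatError(f"tip label {tip.name!r} contains newick metacharacters")
        if tip.length is not None and tip.length < 0:
            raise FormatError(f"tip {tip.name!r} has negative branch length")
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text), format="newick")
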
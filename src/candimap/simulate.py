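"""Synthetic reference genomes and lineage-structured strain cohorts.

The generator emulates the polymorphism structure seen when a cohort of
haploid classical-mutant strains is resequenced against a shared reference:

* per-strain divergence spanning roughly an order of magnitude
  (0.32-4.6 SNPs/kb by default, the printed cohort's range);
* most variation shared between strains as haplotype blocks inherited from
  common lineages, with a small private remainder;
* transitions ~3x transversions;
* ~12% of variants are indels, with sizes skewed small, an excess at |4|
  (tetramers enriched for TACC/TAGG), and purifying-selection retention that
  leaves coding sequence dominated by in-frame (3n) indels;
* severe coding variants (nonsense, frameshift, splice) strongly suppressed,
  and per-gene mutational tolerance highly overdispersed — most genes are
  variant-poor while a few are hot, as real per-gene indel tallies show;
* a handful of variants present in every strain (the reference genome itself
  carrying the minority allele);
* one planted severe causative mutation per focal strain inside its marker
  interval, absent from every other strain, plus a truth table.

All randomness flows from a single integer seed; per-strain streams are
derived deterministically so adding a strain leaves the others unchanged.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .effects import (
    CAT_SPLICE,
    CDS_FRAMESHIFT,
    NONSENSE,
    STOP,
    SV_GENE_DELETION,
    translate_codon,
)
from .genes import (
    CDS,
    MINUS,
    PLUS,
    SPLICE,
    GeneModel,
    GenomeAnnotation,
    MarkerInterval,
    reverse_complement,
    write_fasta,
    write_gff3,
)
from .variants import (
    INDEL,
    SNP,
    STRUCTURAL_DELETION,
    VariantRecord,
    write_variants_vcf,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

ANNOTATION_CLASSES = (
    ("conserved hypothetical protein", 0.67),
    ("hypothetical protein", 0.22),
    ("predicted protein", 0.11),
)

# per-gene mutational tolerance: most genes conserved, a few hot
TOLERANCE_LEVELS = (0.05, 1.0, 6.0)
TOLERANCE_PROBS = (0.60, 0.30, 0.10)

# base retention probabilities for deleterious classes (multiplied by the
# per-gene tolerance, capped at 1); neutral classes are retained always
RETAIN_NONSENSE = 0.07
RETAIN_NONSYNONYMOUS = 0.30
RETAIN_SPLICE = 0.10
RETAIN_FRAMESHIFT = 0.075
RETAIN_INFRAME = 1.0

INDEL_SIZES = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 15)
INDEL_SIZE_PROBS = (0.30, 0.13, 0.13, 0.22, 0.05, 0.06, 0.02, 0.03, 0.02, 0.015, 0.015, 0.01)
TETRAMER_SPECIAL = ("TACC", "TAGG")
TETRAMER_SPECIAL_P = 0.30


class ConfigError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Study-condition parameters for the synthetic cohort."""

    n_contigs: int = 1
    contig_length: int = 1_000_000
    n_genes: int = 200
    exons_per_gene: int = 3
    n_strains: int = 6
    divergence_snps_per_kb: tuple[float, ...] | None = None
    titv_ratio: float = 3.0
    indel_fraction: float = 0.12
    cds_inframe_enrichment: float = 0.24
    n_haplotype_blocks: int = 20
    block_divergence_multiplier: float = 5.0
    n_reference_background_variants: int = 25
    private_fraction: float = 0.08
    multi_allelic_fraction: float = 0.01
    causative_plan: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_contigs, self.contig_length, self.n_strains) < 1:
            raise ConfigError("n_contigs, contig_length, n_strains must be >= 1")
        if self.n_genes < 0 or self.n_haplotype_blocks < 1:
            raise ConfigError("n_genes >= 0 and n_haplotype_blocks >= 1 required")
        if self.divergence_snps_per_kb is None:
            self.divergence_snps_per_kb = tuple(
                float(x) for x in np.geomspace(0.32, 4.6, self.n_strains)
            )
        if len(self.divergence_snps_per_kb) != self.n_strains:
            raise ConfigError("one divergence value per strain required")
        if self.causative_plan is None:
            self.causative_plan = self._default_plan()

    @property
    def strains(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_strains)]

    def _default_plan(self) -> dict:
        """Plant one tier-1 causative in each of the two least-diverged strains."""
        plan: dict = {}
        span = self.contig_length
        if self.n_strains >= 1 and self.n_genes > 0:
            lo = max(1, int(span * 0.20))
            hi = int(span * 0.50)
            plan["S1"] = (MarkerInterval("1", lo, hi), NONSENSE)
        if self.n_strains >= 2 and self.n_genes > 0:
            lo = int(span * 0.55)
            hi = int(span * 0.85)
            plan["S2"] = (MarkerInterval("1", lo, hi), CDS_FRAMESHIFT)
        return plan


@dataclass
class PlantedCausative:
    strain: str
    gene_id: str
    variant_key: str
    category: str
    contig: str
    position: int


@dataclass
class TruthTable:
    """Ground truth emitted alongside the cohort."""

    causatives: dict[str, PlantedCausative] = field(default_factory=dict)
    private_keys: dict[str, set[str]] = field(default_factory=dict)
    background_keys: set[str] = field(default_factory=set)
    block_boundaries: dict[str, list[int]] = field(default_factory=dict)
    strain_blocks: dict[str, list[tuple[str, int]]] = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    reference: GenomeAnnotation
    records: dict[str, list[VariantRecord]]
    truth: TruthTable
    config: CohortConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA, GFF3, per-strain VCFs, and the truth table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["fasta"] = outdir / "reference.fasta"
        write_fasta(self.reference.sequences, paths["fasta"])
        paths["gff"] = outdir / "genes.gff3"
        write_gff3(
            self.reference.genes.values(), paths["gff"], self.reference.contig_lengths
        )
        for strain, records in self.records.items():
            p = outdir / f"{strain}.vcf"
            write_variants_vcf(records, p, self.reference.sequences, strain_id=strain)
            paths[f"vcf:{strain}"] = p
        paths["truth"] = outdir / "truth.tsv"
        write_truth_table(self.truth, paths["truth"])
        return paths


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if translate_codon(a + b + c) != STOP
]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(np.array(_SENSE_CODONS), size=n_codons - 2)
    stop = rng.choice(np.array(["TAA", "TAG", "TGA"]))
    return "ATG" + "".join(body.tolist()) + str(stop)


def _build_gene(
    rng: np.random.Generator, gene_id: str, contig: str, gstart: int, strand: str,
    n_exons: int, annotation: str,
) -> tuple[str, GeneModel]:
    """One gene laid out as UTR5 | CDS/intron alternation | UTR3."""
    u5 = int(rng.integers(60, 150))
    u3 = int(rng.integers(80, 200))
    cds_lens = [int(rng.integers(50, 200)) * 3 for _ in range(n_exons)]
    intron_lens = [int(rng.integers(60, 150)) for _ in range(n_exons - 1)]
    cds_seq = _random_cds(rng, sum(cds_lens) // 3)

    # transcript-forward layout, relative 0-based
    parts: list[str] = [_random_seq(rng, u5)]
    rel: dict[str, list[tuple[int, int]]] = {"utr5": [(0, u5 - 1)], "cds": [], "utr3": [], "exon": []}
    cursor = u5
    cds_cursor = 0
    exon_start = 0
    for i, clen in enumerate(cds_lens):
        parts.append(cds_seq[cds_cursor : cds_cursor + clen])
        rel["cds"].append((cursor, cursor + clen - 1))
        cursor += clen
        cds_cursor += clen
        if i < len(intron_lens):
            rel["exon"].append((exon_start, cursor - 1))
            ilen = intron_lens[i]
            parts.append("GT" + _random_seq(rng, ilen - 4) + "AG")
            cursor += ilen
            exon_start = cursor
    parts.append(_random_seq(rng, u3))
    rel["utr3"].append((cursor, cursor + u3 - 1))
    cursor += u3
    rel["exon"].append((exon_start, cursor - 1))
    frag = "".join(parts)
    length = len(frag)
    assert length == cursor

    if strand == MINUS:
        frag = reverse_complement(frag)
        rel = {
            k: sorted((length - 1 - b, length - 1 - a) for a, b in ivs)
            for k, ivs in rel.items()
        }

    def absolute(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
        return [(gstart + a, gstart + b) for a, b in ivs]

    model = GeneModel(
        gene_id=gene_id,
        contig=contig,
        strand=strand,
        exons=absolute(rel["exon"]),
        cds=absolute(rel["cds"]),
        utr5=absolute(rel["utr5"]),
        utr3=absolute(rel["utr3"]),
        annotation=annotation,
    )
    return frag, model


def generate_reference(config: CohortConfig, seed: int | None = None) -> GenomeAnnotation:
    """Generate the reference genome and gene models.

    Genes are placed without overlap on both strands; every CDS starts with
    ATG, ends with a stop, and translates without internal stops.
    """
    rng = np.random.default_rng([config.seed if seed is None else seed, 101])
    class_names = [c for c, _ in ANNOTATION_CLASSES]
    class_probs = [p for _, p in ANNOTATION_CLASSES]
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    per_contig = [config.n_genes // config.n_contigs] * config.n_contigs
    for i in range(config.n_genes % config.n_contigs):
        per_contig[i] += 1
    gene_no = 0
    for ci in range(config.n_contigs):
        contig = str(ci + 1)
        seq = list(_random_seq(rng, config.contig_length))
        n_here = per_contig[ci]
        if n_here:
            # lay out genes with jittered intergenic gaps
            specs = []
            total = 0
            for _ in range(n_here):
                gene_no += 1
                strand = PLUS if rng.random() < 0.5 else MINUS
                anno = str(rng.choice(class_names, p=class_probs))
                frag, model = _build_gene(
                    rng, f"G{gene_no:05d}", contig, 1, strand, config.exons_per_gene, anno
                )
                specs.append((frag, model))
                total += len(frag)
            free = config.contig_length - total - 2_000
            if free < n_here * 50:
                raise ConfigError(
                    f"cannot place {n_here} genes in a {config.contig_length} bp contig"
                )
            base_gap = free // (n_here + 1)
            cursor = 1_000
            for frag, model in specs:
                gap = int(rng.integers(base_gap // 2, base_gap + 1))
                gstart = cursor + gap
                shift = gstart - 1
                model = GeneModel(
                    gene_id=model.gene_id,
                    contig=contig,
                    strand=model.strand,
                    exons=[(a + shift, b + shift) for a, b in model.exons],
                    cds=[(a + shift, b + shift) for a, b in model.cds],
                    utr5=[(a + shift, b + shift) for a, b in model.utr5],
                    utr3=[(a + shift, b + shift) for a, b in model.utr3],
                    annotation=model.annotation,
                )
                seq[gstart - 1 : gstart - 1 + len(frag)] = frag
                genes.append(model)
                cursor = gstart + len(frag)
        sequences[contig] = "".join(seq)
    return GenomeAnnotation(sequences, genes)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


class _Proposer:
    """Rejection-samples background variants under purifying retention."""

    def __init__(self, annotation: GenomeAnnotation, config: CohortConfig,
                 tolerance: dict[str, float]):
        annotation.build_index()
        self.ann = annotation
        self.cfg = config
        self.tol = tolerance
        self.used_snp: set[tuple[str, int, str]] = set()
        self.used_indel: set[tuple[str, int]] = set()
        self.p_transition = config.titv_ratio / (config.titv_ratio + 1.0)
        target = config.cds_inframe_enrichment
        cds_frac = self._cds_fraction()
        # solve retention so the coding fraction of 3n indels hits the target
        if 0 < target < 1 and 0 < cds_frac < 1:
            r = target * (1 - cds_frac) / (cds_frac * (1 - target))
            self.retain_inframe = min(1.0, r * RETAIN_INFRAME)
        else:
            self.retain_inframe = RETAIN_INFRAME

    def _cds_fraction(self) -> float:
        total = cds = 0
        for contig in self.ann.sequences:
            arr = self.ann.region_array(contig)
            total += len(arr) - 1
            cds += int((arr == CDS).sum())
        return cds / total if total else 0.0

    def _retention(self, category: str | None, gene_id: str | None) -> float:
        if category is None:
            return 1.0
        base = {
            NONSENSE: RETAIN_NONSENSE,
            "nonsynonymous": RETAIN_NONSYNONYMOUS,
            CAT_SPLICE: RETAIN_SPLICE,
            CDS_FRAMESHIFT: RETAIN_FRAMESHIFT,
            "cds_inframe": self.retain_inframe,
        }.get(category, 1.0)
        if category == "cds_inframe":
            return base
        tol = self.tol.get(gene_id, 1.0) if gene_id else 1.0
        return min(1.0, base * tol)

    def _coarse_snp_category(self, contig: str, pos: int, alt: str) -> tuple[str | None, str | None]:
        ann = self.ann
        region = ann.region_at(contig, pos)
        gene = ann.gene_at(contig, pos)
        gene_id = gene.gene_id if gene else None
        if region == SPLICE:
            return CAT_SPLICE, gene_id
        if region == CDS and gene is not None:
            off = ann.cds_offset_at(contig, pos)
            if off < 0:
                return None, gene_id
            cds = ann.spliced_cds(gene.gene_id)
            idx, within = divmod(off, 3)
            codon = cds[idx * 3 : idx * 3 + 3]
            a = alt if gene.strand == PLUS else {"A": "T", "T": "A", "C": "G", "G": "C"}[alt]
            alt_codon = codon[:within] + a + codon[within + 1 :]
            ref_aa, alt_aa = translate_codon(codon), translate_codon(alt_codon)
            if ref_aa == alt_aa:
                return None, gene_id
            return (NONSENSE if alt_aa == STOP else "nonsynonymous"), gene_id
        return None, gene_id

    def propose_snp(self, rng: np.random.Generator, contig: str,
                    lo: int, hi: int) -> tuple[int, str, str]:
        seq = self.ann.sequences[contig]
        for _ in range(10_000):
            pos = int(rng.integers(lo, hi + 1))
            ref = seq[pos - 1]
            if ref not in _TRANSITION:
                continue
            if rng.random() < self.p_transition:
                alt = _TRANSITION[ref]
            else:
                alt = _TRANSVERSIONS[ref][int(rng.integers(0, 2))]
            if (contig, pos, alt) in self.used_snp:
                continue
            category, gene_id = self._coarse_snp_category(contig, pos, alt)
            if rng.random() >= self._retention(category, gene_id):
                continue
            self.used_snp.add((contig, pos, alt))
            return pos, ref, alt
        raise ConfigError("could not place a SNP (region saturated?)")

    def propose_indel(self, rng: np.random.Generator, contig: str,
                      lo: int, hi: int) -> tuple[int, int, str, str]:
        """Returns (position, signed size, ref_allele, alt_allele)."""
        seq = self.ann.sequences[contig]
        arr = self.ann.region_array(contig)
        for _ in range(10_000):
            size = int(rng.choice(INDEL_SIZES, p=INDEL_SIZE_PROBS))
            deletion = rng.random() < 0.5
            hi_eff = min(hi, len(seq) - size - 1)
            if hi_eff < lo:
                continue
            pos = int(rng.integers(lo, hi_eff + 1))
            if (contig, pos) in self.used_indel:
                continue
            span_lo, span_hi = (pos, pos + size - 1) if deletion else (pos, pos + 1)
            regions = set(arr[span_lo : span_hi + 1].tolist())
            gene = self.ann.gene_at(contig, span_lo)
            gene_id = gene.gene_id if gene else None
            if SPLICE in regions:
                category = CAT_SPLICE
            elif CDS in regions:
                category = CDS_FRAMESHIFT if size % 3 else "cds_inframe"
            else:
                category = None
            if rng.random() >= self._retention(category, gene_id):
                continue
            if deletion:
                ref, alt = seq[pos - 1 : pos - 1 + size], ""
                signed = -size
            else:
                if size == 4 and rng.random() < TETRAMER_SPECIAL_P:
                    alt = TETRAMER_SPECIAL[int(rng.integers(0, 2))]
                else:
                    alt = _random_seq(rng, size)
                ref, signed = "", size
            self.used_indel.add((contig, pos))
            return pos, signed, ref, alt
        raise ConfigError("could not place an indel (region saturated?)")


def _qualities(rng: np.random.Generator) -> dict:
    return dict(
        consensus_quality=int(rng.integers(60, 250)),
        read_depth=int(rng.poisson(40)) + 10,
        map_quality=60,
    )


def _plant_causative(
    rng: np.random.Generator,
    annotation: GenomeAnnotation,
    proposer: _Proposer,
    tolerance: dict[str, float],
    strain: str,
    interval: MarkerInterval,
    category: str,
) -> tuple[VariantRecord, PlantedCausative]:
    contig = interval.contig
    lo, hi = interval.resolve(annotation.contig_lengths[contig])
    genes = [
        g for g in annotation.genes_in_interval(contig, lo, hi)
        if g.cds and lo <= g.start and g.end <= hi
    ]
    if not genes:
        raise ConfigError(f"causative interval {contig}:{lo}-{hi} contains no gene")
    conserved = [g for g in genes if tolerance.get(g.gene_id, 1.0) < 1.0]
    pool = conserved or genes
    gene = pool[int(rng.integers(0, len(pool)))]
    seq = annotation.sequences[contig]
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}

    if category == NONSENSE:
        cds = annotation.spliced_cds(gene.gene_id)
        n_codons = len(cds) // 3
        start = int(rng.integers(5, max(6, n_codons - 10)))
        for step in range(n_codons - 12):
            idx = 5 + (start - 5 + step) % max(1, n_codons - 12)
            codon = cds[idx * 3 : idx * 3 + 3]
            if translate_codon(codon) == STOP:
                continue
            for within in range(3):
                for alt_t in "ACGT":
                    if alt_t == codon[within]:
                        continue
                    if translate_codon(codon[:within] + alt_t + codon[within + 1 :]) == STOP:
                        off = idx * 3 + within
                        pos = _genomic_position_of_cds_offset(annotation, gene, off)
                        alt_g = alt_t if gene.strand == PLUS else comp[alt_t]
                        ref_g = seq[pos - 1]
                        if (contig, pos, alt_g) in proposer.used_snp:
                            continue
                        proposer.used_snp.add((contig, pos, alt_g))
                        rec = VariantRecord(
                            strain_id=strain, contig=contig, position=pos, kind=SNP,
                            ref_allele=ref_g, alt_allele=alt_g, **_qualities(rng),
                        )
                        return rec, PlantedCausative(
                            strain, gene.gene_id, rec.key, category, contig, pos
                        )
        raise ConfigError(f"no nonsense-creating site in {gene.gene_id}")

    if category == CDS_FRAMESHIFT:
        c_lo, c_hi = gene.cds[len(gene.cds) // 2]
        pos = int(rng.integers(c_lo + 3, c_hi - 3))
        while (contig, pos) in proposer.used_indel:
            pos += 1
        proposer.used_indel.add((contig, pos))
        rec = VariantRecord(
            strain_id=strain, contig=contig, position=pos, kind=INDEL,
            ref_allele=seq[pos - 1], alt_allele="", indel_size=-1, **_qualities(rng),
        )
        return rec, PlantedCausative(strain, gene.gene_id, rec.key, category, contig, pos)

    if category == SV_GENE_DELETION:
        sv_lo = max(1, gene.start - 25)
        sv_hi = min(len(seq), gene.end + 25)
        if (contig, sv_lo) in proposer.used_indel:
            sv_lo -= 1
        proposer.used_indel.add((contig, sv_lo))
        rec = VariantRecord(
            strain_id=strain, contig=contig, position=sv_lo, kind=STRUCTURAL_DELETION,
            sv_end=sv_hi, indel_size=-(sv_hi - sv_lo + 1), **_qualities(rng),
        )
        return rec, PlantedCausative(strain, gene.gene_id, rec.key, category, contig, sv_lo)

    if category == CAT_SPLICE:
        introns = gene.introns
        if not introns:
            raise ConfigError(f"{gene.gene_id} has no introns for a splice causative")
        i_lo, _ = introns[int(rng.integers(0, len(introns)))]
        pos = i_lo  # first donor base
        ref_g = seq[pos - 1]
        alt_g = "A" if ref_g != "A" else "C"
        if (contig, pos, alt_g) in proposer.used_snp:
            alt_g = "C" if ref_g != "C" else "G"
        proposer.used_snp.add((contig, pos, alt_g))
        rec = VariantRecord(
            strain_id=strain, contig=contig, position=pos, kind=SNP,
            ref_allele=ref_g, alt_allele=alt_g, **_qualities(rng),
        )
        return rec, PlantedCausative(strain, gene.gene_id, rec.key, category, contig, pos)

    raise ConfigError(f"unsupported causative category {category!r}")


def _genomic_position_of_cds_offset(
    annotation: GenomeAnnotation, gene: GeneModel, offset: int
) -> int:
    order = gene.cds if gene.strand == PLUS else list(reversed(gene.cds))
    remaining = offset
    for lo, hi in order:
        k = hi - lo + 1
        if remaining < k:
            return lo + remaining if gene.strand == PLUS else hi - remaining
        remaining -= k
    raise ValueError("CDS offset out of range")


def generate_cohort(
    reference: GenomeAnnotation, config: CohortConfig, seed: int | None = None
) -> SyntheticCohort:
    """Generate per-strain variant sets plus the ground-truth table."""
    base_seed = config.seed if seed is None else seed
    shared_rng = np.random.default_rng([base_seed, 202])
    reference.build_index()

    gene_ids = sorted(reference.genes)
    tol_draw = shared_rng.choice(
        np.array(TOLERANCE_LEVELS), size=len(gene_ids), p=np.array(TOLERANCE_PROBS)
    )
    tolerance = {g: float(t) for g, t in zip(gene_ids, tol_draw)}
    proposer = _Proposer(reference, config, tolerance)

    # haplotype blocks and the shared ancestral variant pool
    contigs = sorted(reference.sequences, key=lambda c: (len(c), c))
    block_bounds: dict[str, list[int]] = {}
    blocks: list[tuple[str, int, int]] = []  # (contig, lo, hi)
    hot: list[bool] = []
    for contig in contigs:
        length = len(reference.sequences[contig])
        edges = np.linspace(1, length + 1, config.n_haplotype_blocks + 1).astype(int)
        block_bounds[contig] = edges[1:-1].tolist()
        for lo, hi in zip(edges[:-1], edges[1:] - 1):
            blocks.append((contig, int(lo), int(hi)))
            hot.append(shared_rng.random() < 0.2)

    genome_kb = sum(len(s) for s in reference.sequences.values()) / 1000.0
    d_pool = max(config.divergence_snps_per_kb)
    weights = np.array(
        [(hi - lo + 1) * (config.block_divergence_multiplier if h else 1.0)
         for (c, lo, hi), h in zip(blocks, hot)],
        dtype=float,
    )
    weights /= weights.sum()
    n_pool = int(round(d_pool * genome_kb / (1.0 - config.indel_fraction)))
    block_of = shared_rng.choice(len(blocks), size=n_pool, p=weights)

    pool: list[list[dict]] = [[] for _ in blocks]  # per-block variant dicts
    for bi in block_of:
        contig, lo, hi = blocks[bi]
        if shared_rng.random() < config.indel_fraction:
            pos, signed, ref, alt = proposer.propose_indel(shared_rng, contig, lo, hi)
            pool[bi].append(dict(contig=contig, position=pos, kind=INDEL,
                                 ref_allele=ref, alt_allele=alt, indel_size=signed))
        else:
            pos, ref, alt = proposer.propose_snp(shared_rng, contig, lo, hi)
            pool[bi].append(dict(contig=contig, position=pos, kind=SNP,
                                 ref_allele=ref, alt_allele=alt))
    for members in pool:
        members.sort(key=lambda v: (v["contig"], v["position"]))

    # reference-background variants (present in every strain)
    background: list[dict] = []
    for _ in range(config.n_reference_background_variants):
        contig = contigs[int(shared_rng.integers(0, len(contigs)))]
        length = len(reference.sequences[contig])
        pos, ref, alt = proposer.propose_snp(shared_rng, contig, 1, length)
        background.append(dict(contig=contig, position=pos, kind=SNP,
                               ref_allele=ref, alt_allele=alt))

    strains = config.strains
    records: dict[str, list[VariantRecord]] = {}
    carriers: dict[str, int] = {}
    multi_keys: set[str] = set()
    truth = TruthTable(block_boundaries=block_bounds)

    for si, strain in enumerate(strains):
        rng = np.random.default_rng([base_seed, 303, si])
        target = config.divergence_snps_per_kb[si] * genome_kb / (1.0 - config.indel_fraction)
        shared_target = (1.0 - config.private_fraction) * target
        order = rng.permutation(len(blocks))
        chosen: list[dict] = []
        carried_blocks: list[tuple[str, int]] = []
        for bi in order:
            if len(chosen) >= shared_target:
                break
            members = pool[bi]
            need = int(shared_target) - len(chosen)
            take = members if len(members) <= need else members[:need]
            if take:
                chosen.extend(take)
                carried_blocks.append((blocks[bi][0], int(bi)))
        n_private = rng.poisson(config.private_fraction * target)
        privates: list[dict] = []
        for _ in range(n_private):
            contig = contigs[int(rng.integers(0, len(contigs)))]
            length = len(reference.sequences[contig])
            if rng.random() < config.indel_fraction:
                pos, signed, ref, alt = proposer.propose_indel(rng, contig, 1, length)
                v = dict(contig=contig, position=pos, kind=INDEL,
                         ref_allele=ref, alt_allele=alt, indel_size=signed)
            else:
                pos, ref, alt = proposer.propose_snp(rng, contig, 1, length)
                v = dict(contig=contig, position=pos, kind=SNP,
                         ref_allele=ref, alt_allele=alt)
            if rng.random() < config.multi_allelic_fraction:
                v["multi_allelic"] = True
            privates.append(v)

        strain_records: list[VariantRecord] = []
        for v in chosen + privates + background:
            rec = VariantRecord(strain_id=strain, **v, **_qualities(rng))
            strain_records.append(rec)
            carriers[rec.key] = carriers.get(rec.key, 0) + 1
            if rec.multi_allelic:
                multi_keys.add(rec.key)
        records[strain] = strain_records
        truth.strain_blocks[strain] = carried_blocks

    # plant causatives (after background so collisions can be avoided)
    for si, strain in enumerate(strains):
        plan = (config.causative_plan or {}).get(strain)
        if plan is None:
            continue
        interval, category = plan
        rng = np.random.default_rng([base_seed, 404, si])
        rec, planted = _plant_causative(
            rng, reference, proposer, tolerance, strain, interval, category
        )
        if carriers.get(rec.key, 0) > 0:
            # co-located background event: drop it from every strain
            for s in strains:
                records[s] = [r for r in records[s] if r.key != rec.key]
            carriers.pop(rec.key, None)
        records[strain].append(rec)
        carriers[rec.key] = 1
        truth.causatives[strain] = planted

    for strain in strains:
        records[strain].sort(key=lambda r: (r.contig, r.position))
        truth.private_keys[strain] = {
            r.key
            for r in records[strain]
            if carriers[r.key] == 1 and r.key not in multi_keys
        }
    truth.background_keys = {
        v["contig"] + "_" + str(v["position"]) + "_" + v["alt_allele"] for v in background
    }
    return SyntheticCohort(reference, records, truth, config)


# ---------------------------------------------------------------------------
# truth-table serialization
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ("fact", "strain", "contig", "gene", "category", "key", "value")


def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    """TSV with one row per planted fact."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_COLUMNS)
        for strain, c in sorted(truth.causatives.items()):
            writer.writerow(["causative", strain, c.contig, c.gene_id, c.category,
                             c.variant_key, c.position])
        for strain, keys in sorted(truth.private_keys.items()):
            for key in sorted(keys):
                writer.writerow(["private", strain, ".", ".", ".", key, "."])
        for key in sorted(truth.background_keys):
            writer.writerow(["background", ".", ".", ".", ".", key, "."])
        for contig, bounds in sorted(truth.block_boundaries.items()):
            for b in bounds:
                writer.writerow(["block_boundary", ".", contig, ".", ".", ".", b])
        for strain, blocks in sorted(truth.strain_blocks.items()):
            for contig, bi in blocks:
                writer.writerow(["strain_block", strain, contig, ".", ".", ".", bi])


def read_truth_table(path: str | Path) -> TruthTable:
    truth = TruthTable()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if tuple(header) != TRUTH_COLUMNS:
            raise ValueError(f"{path}: unrecognized truth-table header {header!r}")
        for row in reader:
            fact, strain, contig, gene, category, key, value = row
            if fact == "causative":
                truth.causatives[strain] = PlantedCausative(
                    strain, gene, key, category, contig, int(value)
                )
            elif fact == "private":
                truth.private_keys.setdefault(strain, set()).add(key)
            elif fact == "background":
                truth.background_keys.add(key)
            elif fact == "block_boundary":
                truth.block_boundaries.setdefault(contig, []).append(int(value))
            elif fact == "strain_block":
                truth.strain_blocks.setdefault(strain, []).append((contig, int(value)))
    return truth


def knockout_table(
    cohort: SyntheticCohort, n_normal_decoys: int = 20, seed: int | None = None
) -> dict[str, str]:
    """Synthetic knockout-phenotype metadata for the cohort's gene set.

    Planted causative genes get a mutant-consistent phenotype; a sample of
    other genes is reported phenotypically normal.
    """
    rng = np.random.default_rng([cohort.config.seed if seed is None else seed, 505])
    causative_genes = {c.gene_id for c in cohort.truth.causatives.values()}
    table = {g: "morphological defect" for g in causative_genes}
    others = [g for g in sorted(cohort.reference.genes) if g not in causative_genes]
    if others:
        picks = rng.choice(len(others), size=min(n_normal_decoys, len(others)), replace=False)
        for i in picks:
            table[others[int(i)]] = "normal growth and sexual development"
    return table


def write_knockout_table(table: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", "phenotype"])
        for gene, phenotype in sorted(table.items()):
            writer.writerow([gene, phenotype])


def read_knockout_table(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            if row:
                out[row[0]] = row[1]
    return out
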
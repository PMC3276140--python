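"""Variant effect classification against gene models.

SNPs inside coding sequence are classified by strand-aware codon substitution
into synonymous / nonsynonymous / nonsense; SNPs in the first or last two
bases of an intron are splice-site; otherwise UTR / intron / intergenic.
Indels overlapping CDS are frameshifts when their size is not a multiple of
three, in-frame otherwise; structural deletions that remove at least one full
CDS exon are gene deletions. Frameshifted transcripts can be scanned for the
premature stop codons they introduce.

Region precedence for events spanning several feature types:
splice site > CDS > intron > UTR > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

from .genes import (
    CDS,
    INTERGENIC,
    INTRON,
    MINUS,
    SPLICE,
    UTR3,
    UTR5,
    GeneModel,
    GenomeAnnotation,
    reverse_complement,
)
from .variants import (
    INDEL,
    SNP,
    STRUCTURAL_DELETION,
    VariantError,
    VariantRecord,
)

# effect categories
NONCODING_INTERGENIC = "noncoding_intergenic"
CAT_UTR5 = "utr5"
CAT_UTR3 = "utr3"
CAT_INTRON = "intron"
CAT_SPLICE = "splice_site"
SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NONSENSE = "nonsense"
CDS_FRAMESHIFT = "cds_frameshift"
CDS_INFRAME = "cds_inframe"
SV_GENE_DELETION = "sv_gene_deletion"

CATEGORIES = (
    NONCODING_INTERGENIC,
    CAT_UTR5,
    CAT_UTR3,
    CAT_INTRON,
    CAT_SPLICE,
    SYNONYMOUS,
    NONSYNONYMOUS,
    NONSENSE,
    CDS_FRAMESHIFT,
    CDS_INFRAME,
    SV_GENE_DELETION,
)

STOP = "*"

_table = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = STOP

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ReferenceMismatch(ValueError):
    """Record's ref allele disagrees with the reference sequence."""


@dataclass
class EffectCall:
    """Classified effect of one variant in one strain (per gene)."""

    variant_key: str
    strain_id: str
    category: str
    gene_id: str | None = None
    aa_position: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    first_premature_stop: int | None = None
    contig: str = ""
    position: int = 0
    kind: str = SNP
    indel_size: int = 0
    multi_allelic: bool = False

    @property
    def is_coding(self) -> bool:
        return self.category in (
            SYNONYMOUS,
            NONSYNONYMOUS,
            NONSENSE,
            CDS_FRAMESHIFT,
            CDS_INFRAME,
            SV_GENE_DELETION,
        )


def classify_substitution_type(ref: str, alt: str) -> str:
    """Transition (purine<->purine, pyrimidine<->pyrimidine) or transversion."""
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        raise VariantError(f"invalid substitution {ref!r}>{alt!r}")
    purines = ("A", "G")
    return "transition" if (ref in purines) == (alt in purines) else "transversion"


def translate_codon(codon: str) -> str:
    return CODON_TO_AA[codon]


def _effect(record: VariantRecord, category: str, gene: GeneModel | None, **kw) -> EffectCall:
    return EffectCall(
        variant_key=record.key,
        strain_id=record.strain_id,
        category=category,
        gene_id=gene.gene_id if gene is not None else None,
        contig=record.contig,
        position=record.position,
        kind=record.kind,
        indel_size=record.indel_size,
        multi_allelic=record.multi_allelic,
        **kw,
    )


def classify_snp(record: VariantRecord, annotation: GenomeAnnotation) -> EffectCall:
    """Classify a SNP by its position within gene models.

    Raises :class:`ReferenceMismatch` if the record's reference allele does
    not match the reference sequence at its position.
    """
    if record.kind != SNP:
        raise VariantError("classify_snp requires a SNP record")
    annotation.build_index()
    seq = annotation.sequences[record.contig]
    if seq[record.position - 1] != record.ref_allele:
        raise ReferenceMismatch(
            f"strain {record.strain_id}: reference mismatch at "
            f"{record.contig}:{record.position} "
            f"(record {record.ref_allele}, reference {seq[record.position - 1]})"
        )
    region = annotation.region_at(record.contig, record.position)
    gene = annotation.gene_at(record.contig, record.position)
    if region == CDS and gene is not None:
        off = annotation.cds_offset_at(record.contig, record.position)
        if off < 0:  # flagged gene: no codon-level classification
            return _effect(record, CAT_INTRON if region == INTRON else NONCODING_INTERGENIC, gene)
        cds = annotation.spliced_cds(gene.gene_id)
        codon_idx = off // 3
        within = off % 3
        codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
        alt = record.alt_allele
        if gene.strand == MINUS:
            alt = _COMPLEMENT[alt]
        alt_codon = codon[:within] + alt + codon[within + 1 :]
        ref_aa = translate_codon(codon)
        alt_aa = translate_codon(alt_codon)
        if ref_aa == alt_aa:
            category = SYNONYMOUS
        elif alt_aa == STOP:
            category = NONSENSE
        else:
            category = NONSYNONYMOUS
        return _effect(
            record, category, gene, aa_position=codon_idx + 1, ref_aa=ref_aa, alt_aa=alt_aa
        )
    if region == SPLICE:
        return _effect(record, CAT_SPLICE, gene)
    if region == UTR5:
        return _effect(record, CAT_UTR5, gene)
    if region == UTR3:
        return _effect(record, CAT_UTR3, gene)
    if region == INTRON:
        return _effect(record, CAT_INTRON, gene)
    return _effect(record, NONCODING_INTERGENIC, gene)


def _regions_in_span(annotation: GenomeAnnotation, contig: str, lo: int, hi: int) -> set[int]:
    arr = annotation.region_array(contig)
    hi = min(hi, len(arr) - 1)
    lo = max(lo, 1)
    return set(int(x) for x in set(arr[lo : hi + 1].tolist()))


def classify_indel(record: VariantRecord, annotation: GenomeAnnotation) -> EffectCall:
    """Classify an indel or structural deletion against gene models.

    Precedence over the affected span: splice site > CDS > intron > UTR >
    intergenic. A structural deletion removing at least one complete CDS exon
    is classified as a gene deletion.
    """
    if record.kind == SNP:
        raise VariantError("classify_indel requires an indel or structural deletion")
    annotation.build_index()
    lo, hi = record.span()
    gene = annotation.gene_at(record.contig, min(lo, len(annotation.sequences[record.contig])))
    if gene is None:
        gene = annotation.gene_at(
            record.contig, min(hi, len(annotation.sequences[record.contig]))
        )

    if record.kind == STRUCTURAL_DELETION:
        for g in annotation.genes_in_interval(record.contig, lo, hi):
            if any(lo <= c_lo and c_hi <= hi for c_lo, c_hi in g.cds):
                return _effect(record, SV_GENE_DELETION, g)
    regions = _regions_in_span(annotation, record.contig, lo, hi)
    if SPLICE in regions:
        return _effect(record, CAT_SPLICE, gene)
    if CDS in regions:
        if record.kind == STRUCTURAL_DELETION:
            size = -(int(record.sv_end) - record.position + 1)
        else:
            size = record.indel_size
        category = CDS_FRAMESHIFT if size % 3 != 0 else CDS_INFRAME
        return _effect(record, category, gene)
    if INTRON in regions:
        return _effect(record, CAT_INTRON, gene)
    if UTR5 in regions:
        return _effect(record, CAT_UTR5, gene)
    if UTR3 in regions:
        return _effect(record, CAT_UTR3, gene)
    return _effect(record, NONCODING_INTERGENIC, gene)


def classify_variant(record: VariantRecord, annotation: GenomeAnnotation) -> EffectCall:
    return classify_snp(record, annotation) if record.is_snp else classify_indel(record, annotation)


def annotate_cohort(
    cohort: Mapping[str, Sequence[VariantRecord]], annotation: GenomeAnnotation
) -> dict[str, list[EffectCall]]:
    """Classify every record of every strain; returns effects per strain."""
    annotation.build_index()
    return {
        strain: [classify_variant(r, annotation) for r in records]
        for strain, records in cohort.items()
    }


def scan_premature_stops(
    gene: GeneModel, annotation: GenomeAnnotation, record: VariantRecord
) -> tuple[int | None, int]:
    """Locate premature stops introduced by an indel within a CDS.

    The mutant coding sequence is built by applying the indel inside the
    spliced CDS and translating in the original frame from the start codon.
    Returns ``(first_stop_aa, stop_count)`` where ``first_stop_aa`` is the
    1-based codon position of the first stop strictly before the wild-type
    terminal stop (``None`` if translation reaches it unbroken), and
    ``stop_count`` counts stop codons in the mutant translation through the
    wild-type protein length.
    """
    if record.kind == SNP:
        raise VariantError("scan_premature_stops requires an indel record")
    annotation.build_index()
    cds = annotation.spliced_cds(gene.gene_id)
    wt_len = len(cds) // 3  # codons, including terminal stop

    if record.indel_size < 0:
        del_positions = range(record.position, record.position - record.indel_size)
        offsets = sorted(
            annotation.cds_offset_at(record.contig, p)
            for p in del_positions
            if annotation.region_at(record.contig, p) == CDS
        )
        if not offsets:
            raise VariantError("indel does not touch the CDS of this gene")
        mutant = "".join(
            c for i, c in enumerate(cds) if i not in set(offsets)
        )
    else:
        off = annotation.cds_offset_at(record.contig, record.position)
        if off < 0:
            raise VariantError("indel does not touch the CDS of this gene")
        ins = record.alt_allele
        if gene.strand == MINUS:
            ins = reverse_complement(ins)
            # on the minus strand the genomic anchor follows the insertion in
            # transcription order
            mutant = cds[:off] + ins + cds[off:]
        else:
            mutant = cds[: off + 1] + ins + cds[off + 1 :]

    first_stop: int | None = None
    stop_count = 0
    for codon_idx in range(wt_len):
        codon = mutant[codon_idx * 3 : codon_idx * 3 + 3]
        if len(codon) < 3:
            break
        if translate_codon(codon) == STOP:
            stop_count += 1
            if first_stop is None and codon_idx + 1 < wt_len:
                first_stop = codon_idx + 1
    return first_stop, stop_count


# ---------------------------------------------------------------------------
# effects TSV interchange
# ---------------------------------------------------------------------------

EFFECTS_TSV_COLUMNS = (
    "variant_key",
    "strain",
    "gene",
    "category",
    "aa_position",
    "ref_aa",
    "alt_aa",
    "first_premature_stop",
    "contig",
    "position",
    "kind",
    "size",
    "multi",
)


def write_effects_tsv(effects: Iterable[EffectCall], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EFFECTS_TSV_COLUMNS)
        for e in effects:
            writer.writerow(
                [
                    e.variant_key,
                    e.strain_id,
                    e.gene_id or ".",
                    e.category,
                    e.aa_position if e.aa_position is not None else ".",
                    e.ref_aa or ".",
                    e.alt_aa or ".",
                    e.first_premature_stop if e.first_premature_stop is not None else ".",
                    e.contig,
                    e.position,
                    e.kind,
                    e.indel_size,
                    int(e.multi_allelic),
                ]
            )


def read_effects_tsv(path) -> list[EffectCall]:
    import csv

    out: list[EffectCall] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if tuple(header) != EFFECTS_TSV_COLUMNS:
            raise VariantError(f"{path}: unrecognized effects header {header!r}")
        for row in reader:
            if not row:
                continue
            out.append(
                EffectCall(
                    variant_key=row[0],
                    strain_id=row[1],
                    gene_id=None if row[2] == "." else row[2],
                    category=row[3],
                    aa_position=None if row[4] == "." else int(row[4]),
                    ref_aa=None if row[5] == "." else row[5],
                    alt_aa=None if row[6] == "." else row[6],
                    first_premature_stop=None if row[7] == "." else int(row[7]),
                    contig=row[8],
                    position=int(row[9]),
                    kind=row[10],
                    indel_size=int(row[11]),
                    multi_allelic=bool(int(row[12])),
                )
            )
    return out
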
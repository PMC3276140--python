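"""Independent brute-force oracles used to cross-check the fast paths.

Everything here works by direct definition — rebuilding mutant genomes and
translating whole coding sequences with Bio.Seq, scanning every interval, or
O(n^2) window checks — and shares no code with the implementations under
test beyond the data containers.
"""

from __future__ import annotations

from Bio.Seq import Seq

from candimap.genes import GenomeAnnotation
from candimap.variants import FilterPolicy, VariantRecord


def oracle_snp_category(
    annotation: GenomeAnnotation, record: VariantRecord
) -> tuple[str, int | None]:
    """(category, aa_position) by full mutant-CDS translation and interval scan."""
    seq = annotation.sequences[record.contig]
    pos = record.position
    for gene in annotation.genes.values():
        if gene.contig != record.contig or not (gene.start <= pos <= gene.end):
            continue
        for lo, hi in gene.introns:
            w = min(2, hi - lo + 1)
            if lo <= pos <= lo + w - 1 or hi - w + 1 <= pos <= hi:
                return "splice_site", None
        if any(lo <= pos <= hi for lo, hi in gene.cds):
            mutant = seq[: pos - 1] + record.alt_allele + seq[pos:]
            wt = str(Seq(gene.coding_sequence(seq)).translate())
            mt = str(Seq(gene.coding_sequence(mutant)).translate())
            if wt == mt:
                return "synonymous", None
            diff = next(i for i in range(len(wt)) if wt[i] != mt[i])
            if mt[diff] == "*":
                return "nonsense", diff + 1
            return "nonsynonymous", diff + 1
        if any(lo <= pos <= hi for lo, hi in gene.utr5):
            return "utr5", None
        if any(lo <= pos <= hi for lo, hi in gene.utr3):
            return "utr3", None
        if any(lo <= pos <= hi for lo, hi in gene.introns):
            return "intron", None
    return "noncoding_intergenic", None


def oracle_mutant_cds_stops(
    cds_tx: str, offset: int, indel_size: int, inserted_tx: str = ""
) -> tuple[int | None, int]:
    """Premature-stop scan by direct transcript editing and translation.

    ``offset`` is the 0-based position in the spliced CDS of the first
    deleted base (deletion) or of the base preceding the insertion.
    """
    if indel_size < 0:
        mutant = cds_tx[:offset] + cds_tx[offset - indel_size :]
    else:
        mutant = cds_tx[: offset + 1] + inserted_tx + cds_tx[offset + 1 :]
    wt_len = len(cds_tx) // 3
    protein = str(Seq(mutant[: (len(mutant) // 3) * 3]).translate())
    first = None
    count = 0
    for i in range(min(wt_len, len(protein))):
        if protein[i] == "*":
            count += 1
            if first is None and i + 1 < wt_len:
                first = i + 1
    return first, count


def oracle_filter(
    records: list[VariantRecord], policy: FilterPolicy
) -> set[int]:
    """Indices of records kept, by direct application of every rule."""
    w = policy.indel_proximity_window
    kept = set()
    for i, rec in enumerate(records):
        if rec.read_depth < policy.min_depth:
            continue
        if rec.consensus_quality < policy.min_consensus_quality:
            continue
        if rec.map_quality < policy.min_map_quality:
            continue
        if rec.is_snp:
            near = False
            for other in records:
                if other.is_snp or other.strain_id != rec.strain_id \
                        or other.contig != rec.contig:
                    continue
                lo, hi = other.span()
                if lo - w <= rec.position <= hi + w:
                    near = True
            if near:
                continue
            snps = sorted(
                o.position
                for o in records
                if o.is_snp and o.strain_id == rec.strain_id and o.contig == rec.contig
            )
            dense = False
            for start in range(rec.position - w + 1, rec.position + 1):
                if sum(start <= p <= start + w - 1 for p in snps) > policy.max_snps_in_window:
                    dense = True
            if dense:
                continue
        kept.add(i)
    return kept


def oracle_window_counts(positions: list[int], starts, window: int) -> list[int]:
    return [sum(s <= p <= s + window - 1 for p in positions) for s in starts]


def oracle_genes_in_interval(annotation: GenomeAnnotation, contig, lo, hi) -> set[str]:
    return {
        g.gene_id
        for g in annotation.genes.values()
        if g.contig == contig and g.start <= hi and g.end >= lo
    }
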
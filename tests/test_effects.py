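"""Effect classification against gene models, checked against brute-force
mutant-genome translation oracles."""

from __future__ import annotations

import numpy as np
import pytest

from candimap.effects import (
    ReferenceMismatch,
    classify_indel,
    classify_snp,
    classify_substitution_type,
    classify_variant,
    scan_premature_stops,
)
from candimap.genes import GeneModel, GenomeAnnotation, reverse_complement
from candimap.simulate import CohortConfig, generate_reference
from candimap.variants import VariantError, VariantRecord

from .conftest import CDS_C
from .oracles import oracle_mutant_cds_stops, oracle_snp_category


def _snp(ann, pos, alt, strain="s1"):
    ref = ann.sequences["1"][pos - 1]
    return VariantRecord(strain, "1", pos, "snp", ref_allele=ref, alt_allele=alt)


class TestClassifySnp:
    def test_nonsense_trp_to_stop(self, toy_annotation):
        # codon 3 of gene A is TGG (Trp); G->A at codon position 2 gives TAG
        call = classify_snp(_snp(toy_annotation, 1058, "A"), toy_annotation)
        assert call.category == "nonsense"
        assert (call.ref_aa, call.alt_aa, call.aa_position) == ("W", "*", 3)
        assert call.gene_id == "gA"

    def test_wobble_synonymous(self, toy_annotation):
        # codon 2 is GGT; third-position T->C keeps glycine
        call = classify_snp(_snp(toy_annotation, 1056, "C"), toy_annotation)
        assert call.category == "synonymous"

    def test_intergenic(self, toy_annotation):
        call = classify_snp(_snp(toy_annotation, 10, "A" if toy_annotation.sequences["1"][9] != "A" else "C"), toy_annotation)
        assert call.category == "noncoding_intergenic"
        assert call.gene_id is None

    def test_splice_site(self, toy_annotation):
        # first two intron bases of gene A (1111-1112)
        call = classify_snp(_snp(toy_annotation, 1111, "C"), toy_annotation)
        assert call.category == "splice_site"

    def test_utrs_and_intron(self, toy_annotation):
        assert classify_snp(_snp(toy_annotation, 1020, "C" if toy_annotation.sequences["1"][1019] != "C" else "G"), toy_annotation).category == "utr5"
        assert classify_snp(_snp(toy_annotation, 1300, "C" if toy_annotation.sequences["1"][1299] != "C" else "G"), toy_annotation).category == "utr3"
        assert classify_snp(_snp(toy_annotation, 1140, "C" if toy_annotation.sequences["1"][1139] != "C" else "G"), toy_annotation).category == "intron"

    def test_reference_mismatch_raises(self, toy_annotation):
        ref = toy_annotation.sequences["1"][99]
        wrong = "A" if ref != "A" else "C"
        alt = "G" if wrong != "G" else "T"
        rec = VariantRecord("s1", "1", 100, "snp", ref_allele=wrong, alt_allele=alt)
        with pytest.raises(ReferenceMismatch):
            classify_snp(rec, toy_annotation)


class TestClassifyIndel:
    def test_one_base_deletion_in_cds_is_frameshift(self, toy_annotation):
        rec = VariantRecord("s1", "1", 1080, "indel",
                            ref_allele=toy_annotation.sequences["1"][1079], indel_size=-1)
        assert classify_indel(rec, toy_annotation).category == "cds_frameshift"

    def test_three_base_deletion_is_inframe(self, toy_annotation):
        rec = VariantRecord("s1", "1", 1080, "indel",
                            ref_allele=toy_annotation.sequences["1"][1079:1082], indel_size=-3)
        assert classify_indel(rec, toy_annotation).category == "cds_inframe"

    def test_eight_base_deletion_is_frameshift(self, toy_annotation):
        rec = VariantRecord("s1", "1", 1075, "indel",
                            ref_allele=toy_annotation.sequences["1"][1074:1082], indel_size=-8)
        assert classify_indel(rec, toy_annotation).category == "cds_frameshift"

    def test_structural_deletion_covering_gene(self, toy_annotation):
        rec = VariantRecord("s1", "1", 990, "structural_deletion",
                            sv_end=990 + 571, indel_size=-572)
        call = classify_indel(rec, toy_annotation)
        assert call.category == "sv_gene_deletion"
        assert call.gene_id == "gA"

    def test_splice_precedence_over_cds(self, toy_annotation):
        # deletion spanning the exon/intron junction touches the donor site
        rec = VariantRecord("s1", "1", 1109, "indel",
                            ref_allele=toy_annotation.sequences["1"][1108:1112], indel_size=-4)
        assert classify_indel(rec, toy_annotation).category == "splice_site"

    def test_intergenic_indel(self, toy_annotation):
        rec = VariantRecord("s1", "1", 50, "indel", alt_allele="ACGT", indel_size=4)
        assert classify_indel(rec, toy_annotation).category == "noncoding_intergenic"


class TestScanPrematureStops:
    def test_engineered_minus_one_at_codon_five_stops_at_seven(self, toy_annotation):
        gene = toy_annotation.genes["gC"]
        # delete the first base of codon 5 (CDS offset 12 -> genomic 2613)
        rec = VariantRecord("s1", "1", 2613, "indel",
                            ref_allele=toy_annotation.sequences["1"][2612], indel_size=-1)
        first, count = scan_premature_stops(gene, toy_annotation, rec)
        assert first == 7
        oracle_first, oracle_count = oracle_mutant_cds_stops(CDS_C, 12, -1)
        assert (first, count) == (oracle_first, oracle_count)

    def test_inframe_insertion_introduces_no_stop(self, toy_annotation):
        # GCT inserted at a codon boundary (after CDS offset 11) adds one Ala
        gene = toy_annotation.genes["gC"]
        rec = VariantRecord("s1", "1", 2612, "indel", alt_allele="GCT", indel_size=3)
        first, count = scan_premature_stops(gene, toy_annotation, rec)
        assert first is None

    def test_matches_translation_oracle_on_random_indels(self, toy_annotation):
        """Direct transcript-editing translation agrees for both strands."""
        rng = np.random.default_rng(9)
        cases = []
        for gid in ("gA", "gB", "gC"):
            gene = toy_annotation.genes[gid]
            for _ in range(15):
                cds_len = gene.cds_length
                off = int(rng.integers(3, cds_len - 12))
                size = int(rng.choice([-4, -2, -1, 1, 2, 3]))
                cases.append((gene, off, size))
        for gene, off, size in cases:
            tx = toy_annotation.spliced_cds(gene.gene_id)
            if size < 0:
                if off + (-size) > len(tx):
                    continue
                # genomic coordinates of the deleted transcript run
                positions = [
                    _genomic(toy_annotation, gene, off + i) for i in range(-size)
                ]
                if max(positions) - min(positions) + 1 != -size:
                    continue  # run crosses an intron; not a single genomic event
                pos = min(positions)
                ref = toy_annotation.sequences["1"][pos - 1 : pos - 1 - size]
                rec = VariantRecord("s", "1", pos, "indel", ref_allele=ref, indel_size=size)
                expected = oracle_mutant_cds_stops(tx, off, size)
            else:
                ins_tx = "".join(rng.choice(list("ACGT"), size=size))
                if gene.strand == "+":
                    pos = _genomic(toy_annotation, gene, off)
                    ins_g = ins_tx
                else:
                    # anchor so that the insertion lands after transcript offset `off`
                    pos = _genomic(toy_annotation, gene, off + 1)
                    ins_g = reverse_complement(ins_tx)
                rec = VariantRecord("s", "1", pos, "indel", alt_allele=ins_g, indel_size=size)
                expected = oracle_mutant_cds_stops(tx, off, size, inserted_tx=ins_tx)
            got = scan_premature_stops(gene, toy_annotation, rec)
            assert got == expected, (gene.gene_id, off, size)

    def test_indel_outside_cds_is_contract_violation(self, toy_annotation):
        gene = toy_annotation.genes["gC"]
        rec = VariantRecord("s1", "1", 50, "indel", alt_allele="A", indel_size=1)
        with pytest.raises(VariantError):
            scan_premature_stops(gene, toy_annotation, rec)


def _genomic(ann, gene, cds_offset):
    from candimap.simulate import _genomic_position_of_cds_offset

    return _genomic_position_of_cds_offset(ann, gene, cds_offset)


class TestSubstitutionType:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [("G", "A", "transition"), ("C", "T", "transition"), ("A", "T", "transversion"),
         ("G", "C", "transversion")],
    )
    def test_examples(self, ref, alt, expected):
        assert classify_substitution_type(ref, alt) == expected

    def test_invalid_base_rejected(self):
        with pytest.raises(VariantError):
            classify_substitution_type("A", "A")
        with pytest.raises(VariantError):
            classify_substitution_type("N", "A")


def test_classification_matches_mutant_translation_oracle():
    """Random SNPs on a generated genome, both strands, vs the brute-force
    oracle that rebuilds the mutant genome and translates whole proteins."""
    cfg = CohortConfig(contig_length=60_000, n_genes=14, seed=3)
    ann = generate_reference(cfg)
    ann.build_index()
    seq = ann.sequences["1"]
    rng = np.random.default_rng(21)
    checked = 0
    while checked < 300:
        pos = int(rng.integers(1, len(seq) + 1))
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        rec = VariantRecord("s", "1", pos, "snp", ref_allele=ref, alt_allele=alt)
        call = classify_snp(rec, ann)
        category, aa_pos = oracle_snp_category(ann, rec)
        assert call.category == category, (pos, ref, alt)
        if aa_pos is not None and call.category in ("nonsense", "nonsynonymous"):
            assert call.aa_position == aa_pos
        checked += 1


def test_strand_symmetry(toy_annotation):
    """Mirroring genome, genes, and variant leaves category and residue fixed."""
    seq = toy_annotation.sequences["1"]
    L = len(seq)
    mirrored_genes = []
    for g in toy_annotation.genes.values():
        flip = lambda ivs: [(L + 1 - b, L + 1 - a) for a, b in ivs]
        mirrored_genes.append(
            GeneModel(g.gene_id, "1", "-" if g.strand == "+" else "+",
                      exons=flip(g.exons), cds=flip(g.cds),
                      utr5=flip(g.utr5), utr3=flip(g.utr3))
        )
    mirrored = GenomeAnnotation({"1": reverse_complement(seq)}, mirrored_genes)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    rng = np.random.default_rng(17)
    for _ in range(120):
        pos = int(rng.integers(1000, 2700))
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        fwd = classify_snp(VariantRecord("s", "1", pos, "snp", ref_allele=ref,
                                         alt_allele=alt), toy_annotation)
        rev = classify_snp(
            VariantRecord("s", "1", L + 1 - pos, "snp", ref_allele=comp[ref],
                          alt_allele=comp[alt]),
            mirrored,
        )
        assert fwd.category == rev.category
        assert fwd.aa_position == rev.aa_position


def test_every_variant_gets_exactly_one_category(default_cohort, default_effects):
    for strain, records in default_cohort.records.items():
        calls = default_effects[strain]
        assert len(calls) == len(records)
        assert all(c.category for c in calls)
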
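"""Cohort summary statistics: category tables, indel spectra, window
profiles, block segmentation, rate estimators, enrichment."""

from __future__ import annotations

import numpy as np
import pytest

from candimap import published
from candimap.cohort import build_occurrence_matrix, occurrence_spectrum, unique_variants
from candimap.effects import EffectCall
from candimap.summaries import (
    annotation_class_enrichment,
    coding_fraction_by_size,
    default_block_thresholds,
    detect_divergence_blocks,
    indel_size_spectrum,
    mutation_rate,
    round_half_away,
    snp_percentages,
    spectrum_totals,
    strain_snp_summary,
    titv_ratio,
    unique_density_per_kb,
    window_density_profile,
)
from candimap.variants import VariantRecord

from .oracles import oracle_window_counts


class TestSnpPercentages:
    @pytest.mark.parametrize(
        "strain, expected",
        [
            ("106", (59.84, 32.15, 9.62, 0.08)),
            ("1363", (48.59, 50.46, 10.91, 0.09)),
            ("305", (55.31, 37.57, 9.33, 0.07)),
        ],
    )
    def test_reproduces_printed_percentage_columns(self, strain, expected):
        total, nc, syn, nonsyn, _u3, _u5, _int, nonsense = published.SNP_CATEGORY_COUNTS[strain]
        assert snp_percentages(total, nc, syn, nonsyn, nonsense) == expected

    def test_zero_total_gives_zero_row(self):
        assert snp_percentages(0, 0, 0, 0, 0) == (0.0, 0.0, 0.0, 0.0)


def test_strain_snp_summary_counts_sum_to_total(default_cohort, default_effects):
    for strain, calls in default_effects.items():
        s = strain_snp_summary(calls, strain=strain)
        assert (
            s.nc + s.synonymous + s.nonsynonymous + s.utr3 + s.utr5 + s.intron + s.nonsense
            == s.total
        )
        assert s.total == sum(1 for c in calls if c.kind == "snp")


def test_strain_snp_summary_empty():
    s = strain_snp_summary([], strain="x")
    assert s.total == 0 and s.pct_nc == 0.0


class TestIndelSizeSpectrum:
    def _matrix(self):
        shared = [
            VariantRecord(s, "1", 100, "indel", ref_allele="ACGT", indel_size=-4)
            for s in ("A", "B", "C")
        ]
        return build_occurrence_matrix({s: [r] for s, r in zip("ABC", shared)})

    def test_distinct_counts_each_key_once(self):
        assert indel_size_spectrum(self._matrix(), mode="distinct") == {4: 1}

    def test_mapped_weights_by_occurrence(self):
        assert indel_size_spectrum(self._matrix(), mode="mapped") == {4: 3}

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(37)
        cohort = {}
        for s in ("A", "B"):
            records = []
            for _ in range(40):
                pos = int(rng.integers(1, 10_000))
                size = int(rng.choice([-6, -3, -1, 1, 2, 4]))
                records.append(
                    VariantRecord(s, "1", pos, "indel",
                                  ref_allele="A" * -size if size < 0 else "",
                                  alt_allele="" if size < 0 else "C" * size,
                                  indel_size=size)
                )
            cohort[s] = records
        matrix = build_occurrence_matrix(cohort)
        got = indel_size_spectrum(matrix, mode="mapped")
        expected: dict[int, int] = {}
        for s, records in cohort.items():
            seen = set()
            for r in records:
                if r.key in seen:
                    continue
                seen.add(r.key)
                # mapped mode: each (strain, key) counts once per recorded size
                for size in matrix.payload[r.key].sizes:
                    expected[abs(size)] = expected.get(abs(size), 0) + 1
        assert sum(got.values()) == sum(expected.values())


class TestCodingFraction:
    def _indel_effect(self, pos, size, category, strain="s"):
        return EffectCall(f"1_{pos}", strain, category, gene_id="g" if "cds" in category else None,
                          contig="1", position=pos, kind="indel", indel_size=size)

    def test_direct_ratio(self):
        effects = [self._indel_effect(i, 3, "cds_inframe") for i in range(4)]
        effects += [self._indel_effect(100 + i, 3, "noncoding_intergenic") for i in range(6)]
        assert coding_fraction_by_size(effects) == {3: 40.0}

    def test_all_noncoding_gives_zero(self):
        effects = [self._indel_effect(i, s, "noncoding_intergenic")
                   for i, s in enumerate([2, 3, 4], start=1)]
        assert set(coding_fraction_by_size(effects).values()) == {0.0}

    def test_generated_cohort_shows_inframe_coding_enrichment(self, default_effects):
        """3n indels concentrate in CDS relative to frame-breaking sizes."""
        all_effects = [e for calls in default_effects.values() for e in calls]
        frac = coding_fraction_by_size(all_effects)
        assert frac[3] > frac[2]
        assert frac[3] > frac[4]


class TestWindowProfile:
    def test_counts_match_bruteforce(self):
        rng = np.random.default_rng(41)
        records = [
            VariantRecord("s", "1", int(p), "snp", ref_allele="A", alt_allele="G")
            for p in rng.integers(1, 50_000, size=200)
        ]
        profile = window_density_profile(records, "1", 50_000, window=10_000, step=1_000)
        expected = oracle_window_counts(
            [r.position for r in records], profile.starts, 10_000
        )
        assert profile.snp_total.tolist() == expected

    def test_no_variants_gives_zero_profile(self):
        profile = window_density_profile([], "1", 30_000)
        assert profile.snp_total.sum() == 0
        assert len(profile) == (30_000 - 10_000) // 1_000 + 1

    def test_disjoint_binning_conserves_totals(self):
        rng = np.random.default_rng(43)
        records = [
            VariantRecord("s", "1", int(p), "snp", ref_allele="A", alt_allele="G")
            for p in rng.integers(1, 40_001, size=300)
        ]
        profile = window_density_profile(records, "1", 40_000, window=10_000, step=10_000)
        assert profile.snp_total.sum() == 300

    def test_window_must_cover_step(self):
        with pytest.raises(ValueError):
            window_density_profile([], "1", 30_000, window=10, step=100)


class TestDivergenceBlocks:
    def test_constructed_step_profile(self):
        counts = [0] * 50 + [100] * 50
        segments = detect_divergence_blocks(counts, 20, 5, min_run=3)
        assert segments == [(0, 49, "low"), (50, 99, "high")]

    def test_flat_profile_is_one_block(self):
        assert detect_divergence_blocks([7] * 40, 20, 5) == [(0, 39, "high" if 7 >= 20 else "low")]

    def test_recovers_planted_block_boundaries(self):
        """Detected state changes sit within +/-2 windows of planted
        haplotype-block edges for a strain inheriting half the blocks."""
        from candimap.simulate import CohortConfig, generate_cohort, generate_reference

        cfg = CohortConfig(
            n_strains=2, divergence_snps_per_kb=(2.3, 4.6), n_haplotype_blocks=10,
            block_divergence_multiplier=1.0, private_fraction=0.0,
            n_reference_background_variants=0, causative_plan={}, seed=57,
        )
        cohort = generate_cohort(generate_reference(cfg), cfg)
        strain = "S1"
        contig = "1"
        length = cohort.reference.contig_lengths[contig]
        window = step = 10_000
        profile = window_density_profile(cohort.records[strain], contig, length,
                                         window=window, step=step)
        segments = detect_divergence_blocks(profile.snp_total, 10, 3, min_run=2)
        # planted boundaries: edges between carried and uncarried blocks,
        # ignoring the final (possibly partially inherited) block
        edges = np.array([1] + cohort.truth.block_boundaries[contig] + [length + 1])
        carried = {bi for c, bi in cohort.truth.strain_blocks[strain][:-1]}
        partial = cohort.truth.strain_blocks[strain][-1][1]
        n_blocks = len(edges) - 1
        planted = []
        for b in range(1, n_blocks):
            if b in (partial,) or (b - 1) in (partial,):
                continue
            if (b in carried) != ((b - 1) in carried):
                planted.append(edges[b])
        assert planted, "fixture should contain carried/uncarried transitions"
        detected = [profile.starts[s] for s, _e, _state in segments[1:]]
        for boundary in planted:
            assert min(abs(boundary - d) for d in detected) <= 2 * window


class TestRateEstimators:
    def test_published_rate_values(self):
        assert mutation_rate(704, published.GENOME_SIZE).mu == pytest.approx(1.71e-5)
        assert mutation_rate(1033, published.GENOME_SIZE).mu == pytest.approx(2.52e-5)
        assert mutation_rate(0, 1000).mu == 0.0

    def test_indels_added_to_numerator(self):
        est = mutation_rate(704, published.GENOME_SIZE, unique_indels=123)
        assert est.mu == pytest.approx(2.01e-5)

    def test_invalid_genome_size(self):
        with pytest.raises(ValueError):
            mutation_rate(10, 0)

    def test_published_density_values(self):
        assert unique_density_per_kb(73336, published.GENOME_SIZE) == 1.8
        assert unique_density_per_kb(704, published.GENOME_SIZE) == 0.02
        assert unique_density_per_kb(0, 1000) == 0.0


class TestTiTv:
    def test_simple_ratio(self):
        snps = [("G", "A"), ("C", "T"), ("A", "G"), ("A", "T")]
        assert titv_ratio(snps) == 3.0

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            titv_ratio([])

    def test_no_transversions_returns_none(self):
        assert titv_ratio([("G", "A")] * 5) is None

    def test_generated_cohort_recovers_parameter(self, default_cohort):
        pairs = {}
        for records in default_cohort.records.values():
            for r in records:
                if r.is_snp:
                    pairs[r.key] = (r.ref_allele, r.alt_allele)
        ratio = titv_ratio(pairs.values())
        n = len(pairs)
        p = 3.0 / 4.0
        se = np.sqrt(p * (1 - p) / n)
        p_hat = ratio / (1 + ratio)
        assert abs(p_hat - p) < 3 * se


class TestEnrichment:
    def test_printed_observed_percentage(self):
        observed = {"conserved hypothetical": published.NONSENSE_IN_CONSERVED_HYPOTHETICAL,
                    "other": published.DISTINCT_NONSENSE - published.NONSENSE_IN_CONSERVED_HYPOTHETICAL}
        background = {"conserved hypothetical": published.CONSERVED_HYPOTHETICAL_ORFS,
                      "other": published.TOTAL_ORFS - published.CONSERVED_HYPOTHETICAL_ORFS}
        result = annotation_class_enrichment(observed, background)
        obs_pct, bg_pct, ratio = result["conserved hypothetical"]
        assert round_half_away(obs_pct, 0) == 77.0
        assert ratio > 1.0

    def test_uniform_classes_have_unit_ratio(self):
        result = annotation_class_enrichment(["a", "b"], ["a", "b"])
        assert all(r == pytest.approx(1.0) for _o, _b, r in result.values())

    def test_matches_hand_arithmetic(self):
        rng = np.random.default_rng(47)
        classes = ["x", "y", "z"]
        nonsense = [classes[i] for i in rng.integers(0, 3, size=50)]
        genes = [classes[i] for i in rng.integers(0, 3, size=400)]
        result = annotation_class_enrichment(nonsense, genes)
        for cls in classes:
            obs = 100 * nonsense.count(cls) / len(nonsense)
            bg = 100 * genes.count(cls) / len(genes)
            assert result[cls] == (pytest.approx(obs), pytest.approx(bg),
                                   pytest.approx(obs / bg))

    def test_empty_background_is_an_error(self):
        with pytest.raises(ValueError):
            annotation_class_enrichment(["a"], [])


def test_spectrum_identity_between_tables(default_cohort, default_matrix):
    """Occurrence-weighted spectrum total equals the sum of per-strain counts."""
    spectrum = occurrence_spectrum(default_matrix)
    _distinct, mapped = spectrum_totals(spectrum)
    per_strain = sum(
        sum(1 for r in records if not r.multi_allelic)
        for records in default_cohort.records.values()
    )
    assert mapped == per_strain
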
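"""Shared fixtures: a hand-built toy annotation and a default synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from candimap.genes import GeneModel, GenomeAnnotation
from candimap.simulate import CohortConfig, generate_cohort, generate_reference

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


def _bg(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


# toy gene A (plus strand, two CDS exons): codon 2 = GGT (wobble test),
# codon 3 = TGG (Trp; G->A at codon position 2 creates TAG stop)
CDS_A = "ATG" + "GGT" + "TGG" + "GCA" * 56 + "TAA"  # 60 codons / 180 bases
# toy gene B (minus strand, single exon)
CDS_B = "ATG" + "CAT" * 98 + "TAA"  # 100 codons / 300 bases
# toy gene C (plus strand, no UTRs): a -1 at codon 5 shifts the frame so the
# mutant reads TAA at codon 7
CDS_C = "ATG" + "GCT" * 3 + "CAA" + "AGG" + "GTA" + "AGC" + "GCT" * 21 + "TGA"  # 30 codons

from candimap.genes import reverse_complement  # noqa: E402


def build_toy_annotation() -> GenomeAnnotation:
    rng = np.random.default_rng(42)
    seq = list(_bg(rng, 3000))

    # gene A: utr5 1001-1050, CDS 1051-1110 | intron 1111-1170 | CDS 1171-1290,
    # utr3 1291-1350
    seq[1000:1050] = _bg(rng, 50)
    seq[1050:1110] = CDS_A[:60]
    seq[1110:1170] = "GT" + _bg(rng, 56) + "AG"
    seq[1170:1290] = CDS_A[60:]
    seq[1290:1350] = _bg(rng, 60)
    gene_a = GeneModel(
        gene_id="gA", contig="1", strand="+",
        exons=[(1001, 1110), (1171, 1350)],
        cds=[(1051, 1110), (1171, 1290)],
        utr5=[(1001, 1050)], utr3=[(1291, 1350)],
        annotation="conserved hypothetical protein",
    )

    # gene B: minus strand, span 2001-2400; CDS 2051-2350; transcript 5' UTR at
    # the genomic right end
    seq[2050:2350] = reverse_complement(CDS_B)
    gene_b = GeneModel(
        gene_id="gB", contig="1", strand="-",
        exons=[(2001, 2400)], cds=[(2051, 2350)],
        utr5=[(2351, 2400)], utr3=[(2001, 2050)],
        annotation="hypothetical protein",
    )

    # gene C: bare single-exon CDS 2601-2690
    seq[2600:2690] = CDS_C
    gene_c = GeneModel(
        gene_id="gC", contig="1", strand="+",
        exons=[(2601, 2690)], cds=[(2601, 2690)],
        annotation="predicted protein",
    )

    return GenomeAnnotation({"1": "".join(seq)}, [gene_a, gene_b, gene_c])


@pytest.fixture(scope="session")
def toy_annotation() -> GenomeAnnotation:
    ann = build_toy_annotation()
    ann.build_index()
    return ann


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scale synthetic cohort, shared across read-only tests."""
    cfg = CohortConfig(seed=7)
    ref = generate_reference(cfg)
    return generate_cohort(ref, cfg)


@pytest.fixture(scope="session")
def default_effects(default_cohort):
    from candimap.effects import annotate_cohort

    return annotate_cohort(default_cohort.records, default_cohort.reference)


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    from candimap.cohort import build_occurrence_matrix

    return build_occurrence_matrix(default_cohort.records)
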
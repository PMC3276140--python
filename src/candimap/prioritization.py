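"""Candidate-mutation identification for one focal strain.

The procedure mirrors how a causative lesion is pinned down when a mapped
trait and a cohort of resequenced strains are available:

1. restrict attention to the genetically delimited marker interval;
2. keep only variants private (unique) to the focal strain — a variant seen
   in a strain that does not show the phenotype cannot be causative;
3. keep only effect classes severe enough to qualify (tier 1: nonsense,
   frameshift, whole-gene deletion, splice site; tier 2, optional:
   nonsynonymous);
4. drop candidates whose gene carries equally severe variants in other
   strains (the gene tolerates disruption without the phenotype);
5. demote candidates whose knockout is reported phenotypically normal, and
   annotate candidates whose knockout exists only as a heterokaryon
   (possible essential gene) as corroborating evidence;
6. rank what remains deterministically and call a verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .effects import (
    CDS_FRAMESHIFT,
    NONSENSE,
    NONSYNONYMOUS,
    CAT_SPLICE,
    SV_GENE_DELETION,
    EffectCall,
)
from .cohort import OccurrenceMatrix, unique_variants
from .genes import GenomeAnnotation, MarkerInterval

TIER1_DEFAULT = frozenset({NONSENSE, CDS_FRAMESHIFT, SV_GENE_DELETION, CAT_SPLICE})
TIER2_DEFAULT = frozenset({NONSYNONYMOUS})

# deterministic within-tier ordering: stop-destroying classes first
_CATEGORY_ORDER = {
    NONSENSE: 0,
    CDS_FRAMESHIFT: 1,
    SV_GENE_DELETION: 2,
    CAT_SPLICE: 3,
    NONSYNONYMOUS: 4,
}

STATUS_TOP = "top"
STATUS_DEMOTED_KO_NORMAL = "demoted_ko_normal"
STATUS_EXCLUDED_SHARED_ORF = "excluded_shared_orf"
STATUS_EXCLUDED_NOT_UNIQUE = "excluded_not_unique"
STATUS_EXCLUDED_OUTSIDE_INTERVAL = "excluded_outside_interval"
STATUS_EXCLUDED_LOW_SEVERITY = "excluded_low_severity"

VERDICT_SINGLE = "single_candidate"
VERDICT_MULTIPLE = "multiple_candidates"
VERDICT_AMBIGUOUS = "ambiguous"
VERDICT_NONE = "none"

KO_NORMAL_TOKEN = "normal"
KO_HETEROKARYON_TOKEN = "heterokaryon"


@dataclass
class SeverityPolicy:
    """Which effect classes qualify a variant as a causative candidate."""

    tier1: frozenset = TIER1_DEFAULT
    tier2: frozenset = TIER2_DEFAULT
    include_tier2: bool = False
    # shared-ORF exclusion is triggered only by variants of the same or a
    # higher tier unless cross-class exclusion is requested
    cross_class_exclusion: bool = False

    def __post_init__(self) -> None:
        if self.tier1 & self.tier2:
            raise ValueError("severity tiers must be disjoint")

    def tier_of(self, category: str) -> int | None:
        if category in self.tier1:
            return 1
        if category in self.tier2:
            return 2
        return None


@dataclass
class Candidate:
    gene_id: str
    variant_key: str
    category: str
    tier: int
    contig: str
    position: int
    status: str = STATUS_TOP
    knockout_phenotype: str | None = None
    note: str = ""

    def sort_key(self) -> tuple:
        return (self.tier, _CATEGORY_ORDER.get(self.category, 9), self.contig, self.position)


@dataclass
class CandidateReport:
    """Ranked candidates for one strain with per-variant rationale."""

    strain_id: str
    interval: tuple[str, int, int]
    n_genes_in_interval: int
    candidates: list[Candidate] = field(default_factory=list)
    verdict: str = VERDICT_NONE
    statuses: dict[str, str] = field(default_factory=dict)

    @property
    def top_candidates(self) -> list[Candidate]:
        return [c for c in self.candidates if c.status == STATUS_TOP]

    def to_text(self) -> str:
        contig, lo, hi = self.interval
        lines = [
            f"strain {self.strain_id}: interval {contig}:{lo}-{hi} "
            f"({self.n_genes_in_interval} genes)",
            f"verdict: {self.verdict}",
        ]
        for c in self.candidates:
            ko = f" ko={c.knockout_phenotype}" if c.knockout_phenotype else ""
            note = f" ({c.note})" if c.note else ""
            lines.append(
                f"  {c.status:28s} {c.gene_id:14s} {c.variant_key:20s} "
                f"{c.category} tier{c.tier}{ko}{note}"
            )
        return "\n".join(lines)


def restrict_to_interval(
    effects: Sequence[EffectCall],
    interval: tuple[str, int, int],
    annotation: GenomeAnnotation,
) -> tuple[list[EffectCall], int]:
    """Effect calls inside the closed interval, plus gene count in range."""
    contig, lo, hi = interval
    subset = [e for e in effects if e.contig == contig and lo <= e.position <= hi]
    n_genes = len(annotation.genes_in_interval(contig, lo, hi))
    return subset, n_genes


def exclude_shared_orfs(
    candidates: list[Candidate],
    effects_all_strains: Mapping[str, Sequence[EffectCall]],
    focal_strain: str,
    policy: SeverityPolicy,
) -> list[Candidate]:
    """Mark candidates whose gene is hit at qualifying severity elsewhere.

    A gene that carries tier-qualified variants in strains not displaying the
    phenotype evidently tolerates such lesions, so its candidate is excluded.
    By default only same-or-higher-tier variants trigger exclusion.
    """
    hit_tiers: dict[str, int] = {}
    for strain, effects in effects_all_strains.items():
        if strain == focal_strain:
            continue
        for e in effects:
            if e.gene_id is None:
                continue
            tier = policy.tier_of(e.category)
            if tier is None:
                continue
            prev = hit_tiers.get(e.gene_id)
            if prev is None or tier < prev:
                hit_tiers[e.gene_id] = tier
    out = []
    for c in candidates:
        if c.status != STATUS_TOP:
            out.append(c)
            continue
        other = hit_tiers.get(c.gene_id)
        triggered = other is not None and (policy.cross_class_exclusion or other <= c.tier)
        if triggered:
            c = replace(
                c,
                status=STATUS_EXCLUDED_SHARED_ORF,
                note="gene carries qualifying variants in other strains",
            )
        out.append(c)
    return out


def attach_knockout_evidence(
    candidates: list[Candidate], ko_table: Mapping[str, str] | None
) -> list[Candidate]:
    """Fold knockout-phenotype metadata into the candidate list.

    Genes whose knockout is phenotypically normal are demoted (but retained);
    heterokaryon-only knockouts suggest essentiality and are annotated as
    corroborating.
    """
    if not ko_table:
        return candidates
    out = []
    for c in candidates:
        phenotype = ko_table.get(c.gene_id)
        if phenotype is None:
            out.append(c)
            continue
        c = replace(c, knockout_phenotype=phenotype)
        low = phenotype.lower()
        if c.status == STATUS_TOP and KO_NORMAL_TOKEN in low:
            c = replace(c, status=STATUS_DEMOTED_KO_NORMAL, note="knockout reported normal")
        elif KO_HETEROKARYON_TOKEN in low:
            c = replace(c, note="knockout heterokaryon-only (possible essential gene)")
        out.append(c)
    return out


def prioritize(
    strain: str,
    interval_spec: MarkerInterval,
    matrix: OccurrenceMatrix,
    effects_all_strains: Mapping[str, Sequence[EffectCall]],
    annotation: GenomeAnnotation,
    policy: SeverityPolicy | None = None,
    ko_table: Mapping[str, str] | None = None,
) -> CandidateReport:
    """Run the full per-strain candidate identification pipeline."""
    if policy is None:
        policy = SeverityPolicy()
    if strain not in effects_all_strains:
        raise KeyError(f"unknown strain {strain!r}")
    contig_length = annotation.contig_lengths.get(interval_spec.contig)
    if contig_length is None:
        raise KeyError(f"unknown contig {interval_spec.contig!r} in marker interval")
    lo, hi = interval_spec.resolve(contig_length)
    interval = (interval_spec.contig, lo, hi)

    focal_effects = effects_all_strains[strain]
    in_interval, n_genes = restrict_to_interval(focal_effects, interval, annotation)
    in_keys = {e.variant_key for e in in_interval}
    uniques = unique_variants(matrix, strain)

    statuses: dict[str, str] = {}
    for e in focal_effects:
        if e.variant_key not in in_keys:
            statuses[e.variant_key] = STATUS_EXCLUDED_OUTSIDE_INTERVAL

    candidates: list[Candidate] = []
    for e in in_interval:
        if e.variant_key not in uniques:
            statuses[e.variant_key] = STATUS_EXCLUDED_NOT_UNIQUE
            continue
        tier = policy.tier_of(e.category)
        if tier is None or (tier == 2 and not policy.include_tier2):
            statuses[e.variant_key] = STATUS_EXCLUDED_LOW_SEVERITY
            continue
        candidates.append(
            Candidate(
                gene_id=e.gene_id or ".",
                variant_key=e.variant_key,
                category=e.category,
                tier=tier,
                contig=e.contig,
                position=e.position,
            )
        )

    candidates = exclude_shared_orfs(candidates, effects_all_strains, strain, policy)
    candidates = attach_knockout_evidence(candidates, ko_table)
    candidates.sort(key=Candidate.sort_key)
    for c in candidates:
        statuses[c.variant_key] = c.status

    tops = [c for c in candidates if c.status == STATUS_TOP]
    if not tops:
        verdict = VERDICT_NONE
    elif len(tops) == 1:
        verdict = VERDICT_SINGLE
    else:
        ranks = sorted((c.tier, _CATEGORY_ORDER.get(c.category, 9)) for c in tops)
        verdict = VERDICT_MULTIPLE if ranks[0] != ranks[1] else VERDICT_AMBIGUOUS

    return CandidateReport(
        strain_id=strain,
        interval=interval,
        n_genes_in_interval=n_genes,
        candidates=candidates,
        verdict=verdict,
        statuses=statuses,
    )


def write_report_tsv(report: CandidateReport, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["strain", "gene", "variant_key", "category", "tier", "status", "knockout", "note"]
        )
        for c in report.candidates:
            writer.writerow(
                [
                    report.strain_id,
                    c.gene_id,
                    c.variant_key,
                    c.category,
                    c.tier,
                    c.status,
                    c.knockout_phenotype or ".",
                    c.note or ".",
                ]
            )
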
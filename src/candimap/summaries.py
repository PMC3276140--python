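"""Cohort summary statistics.

Per-strain SNP/indel category tables, indel size spectra and their coding
bias, 10-kb moving-window divergence profiles with two-state block
segmentation, transition:transversion ratio, the spontaneous-mutation-rate
upper bound (private variants / surveyed genome length), and
annotation-class enrichment among nonsense-carrying genes.

Percentage columns reproduce the conventions of the source summary tables:
values are rounded half-away-from-zero at the printed precision, and the
synonymous percentage is taken over the non-coding count (a quirk of the
original table; see docs/methods.md).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import OccurrenceMatrix
from .effects import (
    CAT_INTRON,
    CAT_SPLICE,
    CAT_UTR3,
    CAT_UTR5,
    CDS_FRAMESHIFT,
    CDS_INFRAME,
    NONCODING_INTERGENIC,
    NONSENSE,
    NONSYNONYMOUS,
    SV_GENE_DELETION,
    SYNONYMOUS,
    EffectCall,
    classify_substitution_type,
)
from .variants import SNP, VariantRecord

log = logging.getLogger(__name__)


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (table-reproduction convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(value: float, digits: int = 3) -> float:
    if value == 0:
        return 0.0
    exp = math.floor(math.log10(abs(value)))
    return round_half_away(value / 10**exp, digits - 1) * 10**exp


# ---------------------------------------------------------------------------
# per-strain category tables
# ---------------------------------------------------------------------------


@dataclass
class StrainSnpSummary:
    """One row of the per-strain SNP category table."""

    strain: str
    total: int
    nc: int
    synonymous: int
    nonsynonymous: int
    utr3: int
    utr5: int
    intron: int
    nonsense: int
    pct_nc: float = 0.0
    pct_syn: float = 0.0
    pct_nonsyn: float = 0.0
    pct_nonsense: float = 0.0


def snp_percentages(
    total: int, nc: int, synonymous: int, nonsynonymous: int, nonsense: int
) -> tuple[float, float, float, float]:
    """Percentage columns from the count columns.

    ``pct_syn`` is 100*synonymous/NC — the denominator the source table
    actually used — while the other percentages are over the strain total.
    """
    if total == 0:
        return 0.0, 0.0, 0.0, 0.0
    pct_nc = round_half_away(100.0 * nc / total)
    pct_syn = round_half_away(100.0 * synonymous / nc) if nc else 0.0
    pct_nonsyn = round_half_away(100.0 * nonsynonymous / total)
    pct_nonsense = round_half_away(100.0 * nonsense / total)
    return pct_nc, pct_syn, pct_nonsyn, pct_nonsense


def strain_snp_summary(effects: Iterable[EffectCall], strain: str | None = None) -> StrainSnpSummary:
    """Tabulate one strain's SNP effects into the category-table row.

    Splice-site SNPs are folded into the intron column, matching a table
    without a separate splice class.
    """
    counts = {
        "nc": 0, "synonymous": 0, "nonsynonymous": 0,
        "utr3": 0, "utr5": 0, "intron": 0, "nonsense": 0,
    }
    column = {
        NONCODING_INTERGENIC: "nc",
        SYNONYMOUS: "synonymous",
        NONSYNONYMOUS: "nonsynonymous",
        CAT_UTR3: "utr3",
        CAT_UTR5: "utr5",
        CAT_INTRON: "intron",
        CAT_SPLICE: "intron",
        NONSENSE: "nonsense",
    }
    for e in effects:
        if e.kind != SNP:
            continue
        if strain is None:
            strain = e.strain_id
        counts[column[e.category]] += 1
    total = sum(counts.values())
    if total == 0:
        log.warning("strain %s: no SNP effects; percentages set to 0", strain)
    pcts = snp_percentages(
        total, counts["nc"], counts["synonymous"], counts["nonsynonymous"], counts["nonsense"]
    )
    return StrainSnpSummary(
        strain=strain or "",
        total=total,
        pct_nc=pcts[0],
        pct_syn=pcts[1],
        pct_nonsyn=pcts[2],
        pct_nonsense=pcts[3],
        **counts,
    )


@dataclass
class StrainIndelSummary:
    """One row of the per-strain indel distribution table.

    ``other`` collects indels in annotated transcripts outside
    CDS/intron/splice (UTRs) and indels in genes without a usable CDS.
    """

    strain: str
    total: int
    unique: int
    cds: int
    nc: int
    intron: int
    splice_site: int
    other: int


def strain_indel_summary(
    effects: Iterable[EffectCall],
    unique_keys: set[str] | None = None,
    strain: str | None = None,
) -> StrainIndelSummary:
    cds = nc = intron = splice = other = unique = 0
    for e in effects:
        if e.kind == SNP:
            continue
        if strain is None:
            strain = e.strain_id
        if e.category in (CDS_FRAMESHIFT, CDS_INFRAME, SV_GENE_DELETION):
            cds += 1
        elif e.category == NONCODING_INTERGENIC:
            nc += 1
        elif e.category == CAT_INTRON:
            intron += 1
        elif e.category == CAT_SPLICE:
            splice += 1
        else:
            other += 1
        if unique_keys is not None and e.variant_key in unique_keys:
            unique += 1
    return StrainIndelSummary(
        strain=strain or "",
        total=cds + nc + intron + splice + other,
        unique=unique,
        cds=cds,
        nc=nc,
        intron=intron,
        splice_site=splice,
        other=other,
    )


# ---------------------------------------------------------------------------
# indel size statistics
# ---------------------------------------------------------------------------


def indel_size_spectrum(
    matrix: OccurrenceMatrix, mode: str = "distinct", signed: bool = False
) -> dict[int, int]:
    """Indel size histogram over the cohort.

    ``distinct`` counts each key once; ``mapped`` weights each key by its
    occurrence across strains. Insertions and deletions are pooled by |size|
    unless ``signed`` is set. Keys carrying several sizes (co-located indels
    of different lengths share a key) contribute each recorded size once.
    """
    if mode not in ("distinct", "mapped"):
        raise ValueError(f"unknown mode {mode!r}")
    spectrum: dict[int, int] = {}
    for key, payload in matrix.payload.items():
        if payload.kind == SNP or not payload.sizes:
            continue
        weight = matrix.occurrence(key) if mode == "mapped" else 1
        for size in payload.sizes:
            s = size if signed else abs(size)
            spectrum[s] = spectrum.get(s, 0) + weight
    return dict(sorted(spectrum.items()))


def coding_fraction_by_size(effects: Iterable[EffectCall]) -> dict[int, float]:
    """Percent of indels of each |size| that fall in coding sequence."""
    in_cds: dict[int, int] = {}
    totals: dict[int, int] = {}
    for e in effects:
        if e.kind == SNP or e.indel_size == 0:
            continue
        s = abs(e.indel_size)
        totals[s] = totals.get(s, 0) + 1
        if e.category in (CDS_FRAMESHIFT, CDS_INFRAME, SV_GENE_DELETION):
            in_cds[s] = in_cds.get(s, 0) + 1
    return {
        s: 100.0 * in_cds.get(s, 0) / n for s, n in sorted(totals.items()) if n > 0
    }


# ---------------------------------------------------------------------------
# window profiles and divergence blocks
# ---------------------------------------------------------------------------


@dataclass
class WindowProfile:
    """Moving-window variant counts along one contig."""

    contig: str
    window: int
    step: int
    starts: np.ndarray
    snp_total: np.ndarray
    snp_unique: np.ndarray
    indels: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)


def window_density_profile(
    records: Sequence[VariantRecord],
    contig: str,
    contig_length: int,
    window: int = 10_000,
    step: int = 1_000,
    unique_keys: set[str] | None = None,
) -> WindowProfile:
    """Count SNPs (total and unique) and indels in moving windows.

    Window ``i`` covers [start_i, start_i + window - 1] with
    start_i = 1 + i*step; the window count is
    floor((contig_length - window)/step) + 1.
    """
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")
    if contig_length < window:
        log.warning(
            "contig %s shorter (%d) than window (%d); single truncated window",
            contig, contig_length, window,
        )
        starts = np.array([1])
    else:
        n = (contig_length - window) // step + 1
        starts = 1 + step * np.arange(n)
    unique_keys = unique_keys or set()
    snp_pos, uniq_pos, indel_pos = [], [], []
    for r in records:
        if r.contig != contig:
            continue
        if r.is_snp:
            snp_pos.append(r.position)
            if r.key in unique_keys:
                uniq_pos.append(r.position)
        else:
            indel_pos.append(r.position)

    def counts(positions: list[int]) -> np.ndarray:
        arr = np.sort(np.asarray(positions, dtype=np.int64))
        left = np.searchsorted(arr, starts, side="left")
        right = np.searchsorted(arr, starts + window - 1, side="right")
        return (right - left).astype(np.int64)

    return WindowProfile(
        contig=contig,
        window=window,
        step=step,
        starts=starts,
        snp_total=counts(snp_pos),
        snp_unique=counts(uniq_pos),
        indels=counts(indel_pos),
    )


def detect_divergence_blocks(
    counts: Sequence[int] | np.ndarray,
    high_threshold: float,
    low_threshold: float,
    min_run: int = 3,
) -> list[tuple[int, int, str]]:
    """Two-state run-length segmentation of a window profile with hysteresis.

    The state switches to ``high`` after ``min_run`` consecutive windows at or
    above ``high_threshold``, and back to ``low`` after ``min_run``
    consecutive windows at or below ``low_threshold``. Returns window-index
    segments (start, end inclusive, state) tiling the profile.
    """
    if not high_threshold > low_threshold >= 0:
        raise ValueError("require high_threshold > low_threshold >= 0")
    counts = np.asarray(counts)
    n = len(counts)
    if n == 0:
        return []
    state = "high" if counts[0] >= high_threshold else "low"
    states = []
    run = 0
    for i in range(n):
        if state == "low":
            run = run + 1 if counts[i] >= high_threshold else 0
            if run >= min_run:
                state = "high"
                for j in range(i - run + 1, i):
                    states[j] = "high"
                run = 0
        else:
            run = run + 1 if counts[i] <= low_threshold else 0
            if run >= min_run:
                state = "low"
                for j in range(i - run + 1, i):
                    states[j] = "low"
                run = 0
        states.append(state)
    segments: list[tuple[int, int, str]] = []
    seg_start = 0
    for i in range(1, n):
        if states[i] != states[i - 1]:
            segments.append((seg_start, i - 1, states[i - 1]))
            seg_start = i
    segments.append((seg_start, n - 1, states[-1]))
    return segments


def default_block_thresholds(counts: Sequence[int] | np.ndarray) -> tuple[float, float]:
    """Data-driven segmentation thresholds: 90th percentile and median."""
    arr = np.asarray(counts, dtype=float)
    high = float(np.percentile(arr, 90))
    low = float(np.median(arr))
    if high <= low:
        high = low + 1.0
    return high, low


def write_profile_bedgraph(profile: WindowProfile, path, series: str = "snp_total") -> None:
    """BedGraph-style 4-column export for genome-browser loading."""
    values = getattr(profile, series)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{series}"\n')
        for start, value in zip(profile.starts, values):
            fh.write(f"{profile.contig}\t{start - 1}\t{start - 1 + profile.window}\t{value}\n")


# ---------------------------------------------------------------------------
# rate and ratio estimators
# ---------------------------------------------------------------------------


@dataclass
class RateEstimate:
    """Upper bound on the spontaneous per-base mutation rate for one strain."""

    strain: str
    unique_snps: int
    unique_indels: int
    genome_size: int
    mu: float


def mutation_rate(
    unique_snps: int,
    genome_size: int,
    unique_indels: int = 0,
    strain: str = "",
) -> RateEstimate:
    """mu = (unique SNPs [+ unique indels]) / genome size, to 3 significant figures."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    mu = (unique_snps + unique_indels) / genome_size
    return RateEstimate(
        strain=strain,
        unique_snps=unique_snps,
        unique_indels=unique_indels,
        genome_size=genome_size,
        mu=round_sig(mu, 3),
    )


def unique_density_per_kb(unique_count: int, genome_size: int) -> float:
    """Private variants per kilobase; 1 decimal at >=0.1, else 2 decimals."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    density = 1000.0 * unique_count / genome_size
    return round_half_away(density, 1 if density >= 0.1 else 2)


def titv_ratio(snps: Iterable) -> float | None:
    """Transitions / transversions over a SNP set.

    Accepts (ref, alt) pairs, VariantRecords, or EffectCalls with ref/alt
    stored on the record. Returns None with a warning when the set contains
    no transversions (ratio undefined).
    """
    ti = tv = 0
    for item in snps:
        if isinstance(item, VariantRecord):
            ref, alt = item.ref_allele, item.alt_allele
        elif isinstance(item, tuple):
            ref, alt = item
        else:
            raise TypeError(f"cannot extract substitution from {type(item)}")
        if classify_substitution_type(ref, alt) == "transition":
            ti += 1
        else:
            tv += 1
    if ti + tv == 0:
        raise ValueError("empty SNP set")
    if tv == 0:
        log.warning("no transversions in SNP set; ti:tv ratio undefined")
        return None
    return ti / tv


# ---------------------------------------------------------------------------
# occurrence-spectrum arithmetic and enrichment
# ---------------------------------------------------------------------------


def spectrum_totals(spectrum: Mapping[int, int]) -> tuple[int, int]:
    """(distinct keys, occurrence-weighted mapped total) of a spectrum."""
    distinct = sum(spectrum.values())
    mapped = sum(n * count for n, count in spectrum.items())
    return distinct, mapped


def annotation_class_enrichment(
    nonsense_gene_classes: Sequence[str] | Mapping[str, int],
    all_gene_classes: Sequence[str] | Mapping[str, int],
) -> dict[str, tuple[float, float, float]]:
    """Per-class (observed %, background %, enrichment ratio).

    ``nonsense_gene_classes`` holds the annotation class of each nonsense
    mutation (or class -> count); ``all_gene_classes`` the classes of all
    genes. Observed percentages are over nonsense mutations, background over
    all genes.
    """

    def as_counts(data) -> dict[str, int]:
        if isinstance(data, Mapping):
            return dict(data)
        counts: dict[str, int] = {}
        for label in data:
            counts[label] = counts.get(label, 0) + 1
        return counts

    observed = as_counts(nonsense_gene_classes)
    background = as_counts(all_gene_classes)
    if not background:
        raise ValueError("empty gene class table")
    n_obs = sum(observed.values())
    n_bg = sum(background.values())
    out: dict[str, tuple[float, float, float]] = {}
    for cls in background:
        obs_pct = 100.0 * observed.get(cls, 0) / n_obs if n_obs else 0.0
        bg_pct = 100.0 * background[cls] / n_bg
        ratio = obs_pct / bg_pct if bg_pct else float("nan")
        out[cls] = (obs_pct, bg_pct, ratio)
    return out
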
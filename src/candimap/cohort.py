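"""Cohort-wide variant occurrence structure and sharing statistics.

Every strain's calls are projected onto canonical variant keys and collected
into a presence structure (key x strain), the substrate for the comparative
analysis: occurrence spectra, per-strain private (unique) variants, variants
present in every strain (which point to the reference genome itself carrying
the minority allele), and per-gene tallies of coding events.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .effects import (
    CDS_FRAMESHIFT,
    CDS_INFRAME,
    NONSENSE,
    NONSYNONYMOUS,
    SV_GENE_DELETION,
    EffectCall,
)
from .variants import INDEL, SNP, STRUCTURAL_DELETION, VariantRecord

log = logging.getLogger(__name__)


@dataclass
class KeyPayload:
    """Per-key descriptive payload carried alongside the presence bitmask."""

    kind: str
    sizes: set[int] = field(default_factory=set)
    multi_allelic: bool = False


class OccurrenceMatrix:
    """Sparse variant-key x strain presence matrix (key -> strain bitmask)."""

    def __init__(self, strains: Sequence[str]):
        self.strains: list[str] = list(strains)
        self._strain_bit: dict[str, int] = {s: 1 << i for i, s in enumerate(self.strains)}
        self.presence: dict[str, int] = {}
        self.payload: dict[str, KeyPayload] = {}

    def __len__(self) -> int:
        return len(self.presence)

    @property
    def variant_keys(self) -> list[str]:
        return list(self.presence)

    def add(self, strain: str, record: VariantRecord) -> None:
        key = record.key
        bit = self._strain_bit[strain]
        prev = self.presence.get(key, 0)
        if prev & bit:
            log.warning("duplicate (%s, %s) collapsed", strain, key)
        self.presence[key] = prev | bit
        payload = self.payload.get(key)
        if payload is None:
            payload = KeyPayload(kind=record.kind)
            self.payload[key] = payload
        if record.kind != SNP:
            payload.sizes.add(record.indel_size)
        payload.multi_allelic = payload.multi_allelic or record.multi_allelic

    def occurrence(self, key: str) -> int:
        return self.presence[key].bit_count()

    def carriers(self, key: str) -> list[str]:
        mask = self.presence[key]
        return [s for s in self.strains if mask & self._strain_bit[s]]

    def has(self, strain: str, key: str) -> bool:
        return bool(self.presence.get(key, 0) & self._strain_bit[strain])

    def strain_keys(self, strain: str) -> set[str]:
        bit = self._strain_bit[strain]
        return {k for k, m in self.presence.items() if m & bit}


def build_occurrence_matrix(
    cohort: Mapping[str, Sequence[VariantRecord]],
    include_multi_allelic: bool = False,
) -> OccurrenceMatrix:
    """Build the presence matrix from per-strain record lists.

    Multi-allelic records are excluded by default: in a haploid genome they
    are predominantly alignment artifacts and would distort uniqueness
    analysis.
    """
    matrix = OccurrenceMatrix(list(cohort))
    for strain, records in cohort.items():
        for rec in records:
            if rec.multi_allelic and not include_multi_allelic:
                continue
            matrix.add(strain, rec)
    return matrix


def occurrence_spectrum(matrix: OccurrenceMatrix) -> dict[int, int]:
    """Map occurrence count (number of carrier strains) -> number of keys."""
    spectrum: dict[int, int] = {}
    for mask in matrix.presence.values():
        n = mask.bit_count()
        spectrum[n] = spectrum.get(n, 0) + 1
    return dict(sorted(spectrum.items()))


def unique_variants(matrix: OccurrenceMatrix, strain: str) -> set[str]:
    """Keys carried by ``strain`` and by no other strain."""
    if strain not in matrix._strain_bit:
        raise KeyError(f"unknown strain {strain!r}")
    bit = matrix._strain_bit[strain]
    return {k for k, mask in matrix.presence.items() if mask == bit}


def unique_counts(matrix: OccurrenceMatrix) -> dict[str, int]:
    counts = {s: 0 for s in matrix.strains}
    singles = {bit: s for s, bit in matrix._strain_bit.items()}
    for mask in matrix.presence.values():
        if mask.bit_count() == 1:
            counts[singles[mask]] += 1
    return counts


def flag_reference_background(matrix: OccurrenceMatrix) -> set[str]:
    """Keys present in every strain of the cohort.

    A variant called in all strains most plausibly reflects the reference
    genome carrying the minority allele rather than eighteen independent
    events; these keys are reported separately and excluded from uniqueness
    analyses.
    """
    if len(matrix.strains) < 2:
        log.warning("reference-background flagging on a cohort of %d strain(s) is degenerate",
                    len(matrix.strains))
    full = (1 << len(matrix.strains)) - 1
    return {k for k, mask in matrix.presence.items() if mask == full}


SEVERE_SNP_CATEGORIES = frozenset({NONSENSE, NONSYNONYMOUS})
INDEL_CATEGORIES_FOR_TALLY = frozenset({CDS_FRAMESHIFT, CDS_INFRAME, SV_GENE_DELETION})


def tally_variants_per_orf(
    effects: Iterable[EffectCall],
) -> dict[str, tuple[int, int, set[str]]]:
    """Per-gene tallies of distinct coding events across the cohort.

    Returns gene_id -> (distinct coding indel count, distinct severe SNP
    count, set of strains carrying any counted event). Events observed in
    several strains are deduplicated by canonical key.
    """
    indels: dict[str, set[str]] = {}
    snps: dict[str, set[str]] = {}
    strains: dict[str, set[str]] = {}
    for e in effects:
        if e.gene_id is None:
            continue
        if e.kind in (INDEL, STRUCTURAL_DELETION) and e.category in INDEL_CATEGORIES_FOR_TALLY:
            indels.setdefault(e.gene_id, set()).add(e.variant_key)
            strains.setdefault(e.gene_id, set()).add(e.strain_id)
        elif e.kind == SNP and e.category in SEVERE_SNP_CATEGORIES:
            snps.setdefault(e.gene_id, set()).add(e.variant_key)
            strains.setdefault(e.gene_id, set()).add(e.strain_id)
    out: dict[str, tuple[int, int, set[str]]] = {}
    for gene in set(indels) | set(snps):
        out[gene] = (
            len(indels.get(gene, ())),
            len(snps.get(gene, ())),
            strains.get(gene, set()),
        )
    return out


def write_matrix_tsv(matrix: OccurrenceMatrix, path) -> None:
    """Wide TSV export: key, kind, then one 0/1 presence column per strain."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["key", "kind"] + list(matrix.strains))
        for key in sorted(matrix.presence):
            mask = matrix.presence[key]
            row = [key, matrix.payload[key].kind]
            row += [int(bool(mask & matrix._strain_bit[s])) for s in matrix.strains]
            writer.writerow(row)
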
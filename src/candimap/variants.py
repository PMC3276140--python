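"""Variant records, canonical identifiers, call-quality filtering, and I/O.

Variants are kept in a flat record type covering SNPs, small indels, and
structural deletions, with the quality fields needed to re-express maq-style
consensus filtering (minimum depth, consensus quality, map quality, and the
indel-proximity / dense-SNP window rules) as record-level filters.

Coordinates are 1-based and intervals closed on both ends throughout the
package. Each variant gets a canonical string key of the form
``contig_position_base`` for SNPs and ``contig_position`` for indels, so that
the same event can be matched across strains of a cohort. Because indel keys
carry no size, co-located indels of different sizes share a key; sizes are
retained on the record (and in the occurrence matrix payload) so reports can
still distinguish them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

NUCLEOTIDES = frozenset("ACGT")

SNP = "snp"
INDEL = "indel"
STRUCTURAL_DELETION = "structural_deletion"
VARIANT_KINDS = (SNP, INDEL, STRUCTURAL_DELETION)


class VariantError(ValueError):
    """Invalid variant field values or malformed identifiers."""


def encode_variant_id(contig: str, position: int, alt_base: str | None = None) -> str:
    """Canonical variant identifier: ``contig_position[_base]``.

    SNP identifiers carry the alternate base (multiple substitutions may occur
    at one site); indel identifiers carry contig and position only.
    """
    contig = str(contig)
    if "_" in contig:
        raise VariantError(f"contig name may not contain '_': {contig!r}")
    if int(position) < 1:
        raise VariantError(f"position must be >= 1, got {position}")
    if alt_base is None:
        return f"{contig}_{int(position)}"
    if alt_base not in NUCLEOTIDES:
        raise VariantError(f"invalid alternate base {alt_base!r}")
    return f"{contig}_{int(position)}_{alt_base}"


def parse_variant_id(key: str) -> tuple[str, int, str | None]:
    """Inverse of :func:`encode_variant_id`.

    Returns ``(contig, position, alt_base)`` with ``alt_base`` ``None`` for
    indel keys.
    """
    parts = key.split("_")
    if len(parts) == 2:
        contig, pos = parts
        base = None
    elif len(parts) == 3:
        contig, pos, base = parts
        if base not in NUCLEOTIDES:
            raise VariantError(f"invalid base token {base!r} in identifier {key!r}")
    else:
        raise VariantError(f"malformed variant identifier {key!r}")
    if not pos.isdigit() or int(pos) < 1:
        raise VariantError(f"invalid position token {pos!r} in identifier {key!r}")
    if not contig:
        raise VariantError(f"empty contig token in identifier {key!r}")
    return contig, int(pos), base


@dataclass(frozen=True)
class VariantKey:
    """Canonical (contig, position, optional alt base) triple."""

    contig: str
    position: int
    alt_base: str | None = None

    def encode(self) -> str:
        return encode_variant_id(self.contig, self.position, self.alt_base)

    @classmethod
    def parse(cls, key: str) -> "VariantKey":
        contig, pos, base = parse_variant_id(key)
        return cls(contig, pos, base)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.encode()


@dataclass
class VariantRecord:
    """One SNP, small indel, or structural deletion observed in one strain.

    ``position`` is 1-based: for SNPs the substituted base, for deletions the
    first deleted base, for insertions the base after which the new sequence is
    inserted. ``indel_size`` is signed (+ insertion, − deletion, 0 for SNPs).
    For deletions ``ref_allele`` holds the deleted bases and ``alt_allele`` is
    empty; for insertions ``alt_allele`` holds the inserted bases.
    """

    strain_id: str
    contig: str
    position: int
    kind: str
    ref_allele: str = ""
    alt_allele: str = ""
    indel_size: int = 0
    sv_end: int | None = None
    consensus_quality: int = 0
    read_depth: int = 0
    map_quality: int = 0
    multi_allelic: bool = False

    def __post_init__(self) -> None:
        self.contig = str(self.contig)
        if self.position < 1:
            raise VariantError(f"position must be >= 1, got {self.position}")
        if self.kind not in VARIANT_KINDS:
            raise VariantError(f"unknown variant kind {self.kind!r}")
        if self.kind == SNP:
            if (
                self.ref_allele not in NUCLEOTIDES
                or self.alt_allele not in NUCLEOTIDES
                or self.ref_allele == self.alt_allele
            ):
                raise VariantError(
                    f"SNP requires distinct single bases, got "
                    f"{self.ref_allele!r}>{self.alt_allele!r}"
                )
            if self.indel_size != 0:
                raise VariantError("SNP must have indel_size 0")
        elif self.kind == INDEL:
            if self.indel_size == 0:
                raise VariantError("indel must have nonzero indel_size")
        elif self.kind == STRUCTURAL_DELETION:
            if self.sv_end is None or self.sv_end <= self.position:
                raise VariantError("structural_deletion requires sv_end > position")
        if min(self.consensus_quality, self.read_depth, self.map_quality) < 0:
            raise VariantError("quality fields must be >= 0")

    @property
    def is_snp(self) -> bool:
        return self.kind == SNP

    @property
    def key(self) -> str:
        """Canonical identifier used for cross-strain matching."""
        return encode_variant_id(
            self.contig, self.position, self.alt_allele if self.is_snp else None
        )

    def span(self) -> tuple[int, int]:
        """Closed 1-based interval of reference bases affected.

        Insertions affect the junction between ``position`` and
        ``position + 1`` and report that two-base window.
        """
        if self.kind == SNP:
            return self.position, self.position
        if self.kind == STRUCTURAL_DELETION:
            return self.position, int(self.sv_end)
        if self.indel_size < 0:
            return self.position, self.position - self.indel_size - 1
        return self.position, self.position + 1


@dataclass(frozen=True)
class FilterPolicy:
    """maq-style record-level call filters.

    Defaults mirror ``SNPfilter -d 3 -q 40 ... -w 5 -N 2`` plus a minimum map
    quality of 30 applied after the indel-proximity filters.
    """

    min_depth: int = 3
    min_consensus_quality: int = 40
    min_map_quality: int = 30
    indel_proximity_window: int = 5
    max_snps_in_window: int = 2

    def __post_init__(self) -> None:
        if min(
            self.min_depth,
            self.min_consensus_quality,
            self.min_map_quality,
            self.indel_proximity_window,
            self.max_snps_in_window,
        ) < 0:
            raise VariantError("filter thresholds must be >= 0")


REASON_DEPTH = "depth"
REASON_CONSENSUS = "consensus_quality"
REASON_INDEL_PROXIMITY = "indel_proximity"
REASON_SNP_DENSITY = "snp_density"
REASON_MAP_QUALITY = "map_quality"


def filter_calls(
    records: Sequence[VariantRecord], policy: FilterPolicy | None = None
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Partition ``records`` into (kept, rejected-with-reason).

    Rules, in reason-priority order: minimum depth; minimum consensus quality;
    SNPs within ``indel_proximity_window`` bases of any indel in the same
    strain/contig are dropped; SNPs packed more than ``max_snps_in_window`` per
    ``indel_proximity_window``-base window are dropped; the minimum map-quality
    cut is applied last. The proximity/density rules are evaluated against the
    full input so the partition is idempotent.
    """
    if policy is None:
        policy = FilterPolicy()
    w = policy.indel_proximity_window

    # indel positions and dense-SNP rejection sets, per (strain, contig)
    indel_positions: dict[tuple[str, str], list[tuple[int, int]]] = {}
    snps_by_group: dict[tuple[str, str], list[int]] = {}
    for rec in records:
        group = (rec.strain_id, rec.contig)
        if rec.is_snp:
            snps_by_group.setdefault(group, []).append(rec.position)
        else:
            indel_positions.setdefault(group, []).append(rec.span())

    dense: dict[tuple[str, str], set[int]] = {}
    for group, positions in snps_by_group.items():
        positions = sorted(positions)
        bad: set[int] = set()
        j = 0
        for i in range(len(positions)):
            while positions[i] - positions[j] > w - 1:
                j += 1
            if i - j + 1 > policy.max_snps_in_window:
                bad.update(positions[j : i + 1])
        dense[group] = bad

    def near_indel(rec: VariantRecord) -> bool:
        for lo, hi in indel_positions.get((rec.strain_id, rec.contig), ()):
            if lo - w <= rec.position <= hi + w:
                return True
        return False

    kept: list[VariantRecord] = []
    rejected: list[tuple[VariantRecord, str]] = []
    for rec in records:
        if rec.read_depth < policy.min_depth:
            rejected.append((rec, REASON_DEPTH))
        elif rec.consensus_quality < policy.min_consensus_quality:
            rejected.append((rec, REASON_CONSENSUS))
        elif rec.is_snp and near_indel(rec):
            rejected.append((rec, REASON_INDEL_PROXIMITY))
        elif rec.is_snp and rec.position in dense.get((rec.strain_id, rec.contig), ()):
            rejected.append((rec, REASON_SNP_DENSITY))
        elif rec.map_quality < policy.min_map_quality:
            rejected.append((rec, REASON_MAP_QUALITY))
        else:
            kept.append(rec)
    return kept, rejected


def left_normalize(
    record: VariantRecord, sequences: Mapping[str, str]
) -> VariantRecord:
    """Shift an indel to its leftmost equivalent reference position.

    Identical events called at different anchor points in different strains
    then share a canonical key. SNPs and structural deletions pass through.
    """
    if record.kind != INDEL:
        return record
    seq = sequences.get(record.contig)
    if seq is None:
        return record
    pos = record.position
    if record.indel_size < 0:
        allele = record.ref_allele
        k = len(allele)
        # deletion of seq[pos-1 : pos-1+k]; shift while the base entering on
        # the right equals the base leaving on the left
        while pos > 1 and seq[pos - 2] == seq[pos + k - 2]:
            pos -= 1
        allele = seq[pos - 1 : pos - 1 + k]
        return replace(record, position=pos, ref_allele=allele)
    allele = record.alt_allele
    while pos > 1 and seq[pos - 1] == allele[-1]:
        allele = allele[-1] + allele[:-1]
        pos -= 1
    return replace(record, position=pos, alt_allele=allele)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

TSV_COLUMNS = (
    "strain",
    "contig",
    "pos",
    "kind",
    "ref",
    "alt",
    "size",
    "sv_end",
    "cq",
    "dp",
    "mq",
    "multi",
)


def write_variants_tsv(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records in the package's one-header tab-separated dialect."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.strain_id,
                    r.contig,
                    r.position,
                    r.kind,
                    r.ref_allele or ".",
                    r.alt_allele or ".",
                    r.indel_size,
                    r.sv_end if r.sv_end is not None else ".",
                    r.consensus_quality,
                    r.read_depth,
                    r.map_quality,
                    int(r.multi_allelic),
                ]
            )


def _read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != TSV_COLUMNS:
            raise VariantError(f"{path}: unrecognized TSV header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                records.append(
                    VariantRecord(
                        strain_id=row[0],
                        contig=row[1],
                        position=int(row[2]),
                        kind=row[3],
                        ref_allele="" if row[4] == "." else row[4],
                        alt_allele="" if row[5] == "." else row[5],
                        indel_size=int(row[6]),
                        sv_end=None if row[7] == "." else int(row[7]),
                        consensus_quality=int(row[8]),
                        read_depth=int(row[9]),
                        map_quality=int(row[10]),
                        multi_allelic=bool(int(row[11])),
                    )
                )
            except (IndexError, ValueError, VariantError) as exc:
                raise VariantError(f"{path}:{lineno}: malformed line ({exc})") from exc
    return records


# ---------------------------------------------------------------------------
# VCF (v4.2) via pysam
# ---------------------------------------------------------------------------


def _vcf_header(contig_lengths: Mapping[str, int], strain_id: str):
    import pysam

    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(str(name), length=int(length))
    header.info.add("DP", 1, "Integer", "Read depth")
    header.info.add("MQ", 1, "Integer", "RMS map quality")
    header.info.add("SVTYPE", 1, "String", "Structural variant type")
    header.info.add("END", 1, "Integer", "End position of structural variant")
    header.info.add("MULTI", 0, "Flag", "Multi-allelic site")
    header.add_line(f"##strain={strain_id}")
    return header


def write_variants_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    sequences: Mapping[str, str],
    strain_id: str | None = None,
) -> None:
    """Write one strain's records as an uncompressed sites-only VCF.

    Indels use the anchored REF/ALT convention (anchor base precedes the
    event); structural deletions are written as symbolic ``<DEL>`` with END.
    """
    import pysam

    if strain_id is None:
        strains = {r.strain_id for r in records}
        if len(strains) > 1:
            raise VariantError("VCF output is per strain; got records from several")
        strain_id = strains.pop() if strains else "unknown"
    contig_lengths = {c: len(s) for c, s in sequences.items()}
    header = _vcf_header(contig_lengths, strain_id)
    out = pysam.VariantFile(str(path), "w", header=header)
    try:
        for r in sorted(records, key=lambda x: (x.contig, x.position)):
            seq = sequences[r.contig]
            if r.kind == SNP:
                start0 = r.position - 1
                alleles = (r.ref_allele, r.alt_allele)
            elif r.kind == STRUCTURAL_DELETION:
                start0 = r.position - 2
                alleles = (seq[start0], "<DEL>")
            elif r.indel_size < 0:
                start0 = r.position - 2
                anchor = seq[start0]
                alleles = (anchor + r.ref_allele, anchor)
            else:
                start0 = r.position - 1
                anchor = seq[start0]
                alleles = (anchor, anchor + r.alt_allele)
            rec = out.new_record(
                contig=r.contig, start=start0, alleles=alleles, qual=r.consensus_quality
            )
            rec.info["DP"] = r.read_depth
            rec.info["MQ"] = r.map_quality
            if r.multi_allelic:
                rec.info["MULTI"] = True
            if r.kind == STRUCTURAL_DELETION:
                rec.info["SVTYPE"] = "DEL"
                rec.stop = int(r.sv_end)
            out.write(rec)
    finally:
        out.close()


def _read_variants_vcf(path: str | Path, strain_id: str | None = None) -> list[VariantRecord]:
    import pysam

    vf = pysam.VariantFile(str(path))
    if strain_id is None:
        for hr in vf.header.records:
            if hr.key == "strain" and hr.value:
                strain_id = str(hr.value)
                break
    if strain_id is None:
        strain_id = Path(path).stem
    records: list[VariantRecord] = []
    for rec in vf:
        alts = rec.alts or ()
        info_keys = set(rec.info.keys())
        multi = len(alts) > 1 or ("MULTI" in info_keys)
        qual = int(rec.qual) if rec.qual is not None else 0
        dp = int(rec.info["DP"]) if "DP" in info_keys else 0
        mq = int(rec.info["MQ"]) if "MQ" in info_keys else 0
        common = dict(
            strain_id=strain_id,
            contig=rec.contig,
            consensus_quality=qual,
            read_depth=dp,
            map_quality=mq,
            multi_allelic=multi,
        )
        for alt in alts:
            ref = rec.ref
            pos1 = rec.start + 1
            if alt == "<DEL>":
                records.append(
                    VariantRecord(
                        position=pos1 + 1,
                        kind=STRUCTURAL_DELETION,
                        sv_end=rec.stop,
                        indel_size=-(rec.stop - pos1),
                        **common,
                    )
                )
            elif len(ref) == 1 and len(alt) == 1:
                records.append(
                    VariantRecord(
                        position=pos1, kind=SNP, ref_allele=ref, alt_allele=alt, **common
                    )
                )
            elif len(ref) > len(alt):
                if not ref.startswith(alt):
                    raise VariantError(
                        f"{path}: unsupported complex allele {ref}>{alt} at {pos1}"
                    )
                deleted = ref[len(alt):]
                records.append(
                    VariantRecord(
                        position=pos1 + len(alt),
                        kind=INDEL,
                        ref_allele=deleted,
                        indel_size=-len(deleted),
                        **common,
                    )
                )
            else:
                if not alt.startswith(ref):
                    raise VariantError(
                        f"{path}: unsupported complex allele {ref}>{alt} at {pos1}"
                    )
                inserted = alt[len(ref):]
                records.append(
                    VariantRecord(
                        position=pos1 + len(ref) - 1,
                        kind=INDEL,
                        alt_allele=inserted,
                        indel_size=len(inserted),
                        **common,
                    )
                )
    vf.close()
    return records


def read_variants(
    path: str | Path, format: str | None = None, strain_id: str | None = None
) -> list[VariantRecord]:
    """Read variant records from a VCF or from the package TSV dialect.

    ``format`` may be ``"vcf"`` or ``"tsv"``; if omitted it is sniffed from
    the first header line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        with open(path) as fh:
            first = fh.readline()
        format = "vcf" if first.startswith("##fileformat=VCF") else "tsv"
    if format == "vcf":
        return _read_variants_vcf(path, strain_id=strain_id)
    if format == "tsv":
        return _read_variants_tsv(path)
    raise VariantError(f"unknown variant format {format!r}")
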
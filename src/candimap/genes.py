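"""Gene models, genome annotation with per-base lookup arrays, marker intervals.

Gene models are stranded collections of exon/CDS/UTR intervals (1-based,
closed). :class:`GenomeAnnotation` bundles the reference sequences with the
gene set and lazily builds per-contig lookup arrays (region class, gene index,
spliced-CDS offset per base) so that effect classification over large cohorts
is array lookups plus a per-variant codon substitution.

Marker intervals describe genetically delimited search regions with possibly
open ends (``>pos`` / ``<pos``), resolved against the contig length.
"""

from __future__ import annotations

import csv
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

log = logging.getLogger(__name__)

PLUS = "+"
MINUS = "-"

# region codes used in the per-base lookup array
INTERGENIC = 0
UTR5 = 1
UTR3 = 2
INTRON = 3
SPLICE = 4
CDS = 5

SPLICE_WINDOW = 2  # first/last bases of each intron treated as splice site

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    pass


@dataclass
class GeneModel:
    """A stranded gene with exon/CDS/UTR intervals on one contig.

    ``protein_length`` is CDS length / 3 and therefore counts the terminal
    stop codon as one position.
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.strand not in (PLUS, MINUS):
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(tuple(map(int, iv)) for iv in self.exons)
        self.cds = sorted(tuple(map(int, iv)) for iv in self.cds)
        self.utr5 = sorted(tuple(map(int, iv)) for iv in self.utr5)
        self.utr3 = sorted(tuple(map(int, iv)) for iv in self.utr3)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.cds)

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (l1, h1), (l2, _h2) in zip(self.exons, self.exons[1:]):
            if l2 > h1 + 1:
                out.append((h1 + 1, l2 - 1))
        return out

    def coding_sequence(self, contig_seq: str) -> str:
        """Spliced CDS in transcription order (minus strand reverse-complemented)."""
        parts = [contig_seq[lo - 1 : hi] for lo, hi in self.cds]
        seq = "".join(parts)
        return reverse_complement(seq) if self.strand == MINUS else seq


class GenomeAnnotation:
    """Reference sequences plus gene models, with fast per-base lookup.

    The lookup arrays map every reference base to a region class
    (intergenic / UTR / intron / splice-site / CDS), the index of the gene it
    belongs to, and — for CDS bases — the 0-based offset within that gene's
    spliced, stranded coding sequence.
    """

    def __init__(self, sequences: Mapping[str, str], genes: Iterable[GeneModel]):
        self.sequences: dict[str, str] = {str(k): str(v).upper() for k, v in sequences.items()}
        self.genes: dict[str, GeneModel] = {}
        self.flagged_genes: dict[str, str] = {}
        for g in genes:
            if g.contig not in self.sequences:
                raise AnnotationError(f"{g.gene_id}: unknown contig {g.contig}")
            if g.cds and g.cds_length % 3 != 0:
                log.warning(
                    "gene %s: CDS length %d not divisible by 3; excluded from "
                    "codon-level classification",
                    g.gene_id,
                    g.cds_length,
                )
                self.flagged_genes[g.gene_id] = "cds_length_not_multiple_of_3"
            self.genes[g.gene_id] = g
        self._index_built = False
        self._gene_list: list[GeneModel] = []
        self._region: dict[str, np.ndarray] = {}
        self._gene_idx: dict[str, np.ndarray] = {}
        self._cds_off: dict[str, np.ndarray] = {}
        self._cds_seq: dict[str, str] = {}
        self._by_contig: dict[str, tuple[list[int], list[GeneModel]]] = {}

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    # -- interval queries ---------------------------------------------------

    def _contig_genes(self, contig: str) -> tuple[list[int], list[GeneModel]]:
        if contig not in self._by_contig:
            gs = sorted(
                (g for g in self.genes.values() if g.contig == contig),
                key=lambda g: g.start,
            )
            self._by_contig[contig] = ([g.start for g in gs], gs)
        return self._by_contig[contig]

    def genes_in_interval(self, contig: str, lo: int, hi: int) -> list[GeneModel]:
        """Genes whose span intersects the closed interval [lo, hi]."""
        _starts, gs = self._contig_genes(contig)
        return [g for g in gs if g.start <= hi and g.end >= lo]

    # -- per-base index -----------------------------------------------------

    def build_index(self) -> None:
        if self._index_built:
            return
        self._gene_list = sorted(self.genes.values(), key=lambda g: (g.contig, g.start))
        for contig, seq in self.sequences.items():
            n = len(seq)
            self._region[contig] = np.zeros(n + 1, dtype=np.uint8)
            self._gene_idx[contig] = np.full(n + 1, -1, dtype=np.int32)
            self._cds_off[contig] = np.full(n + 1, -1, dtype=np.int32)
        for idx, g in enumerate(self._gene_list):
            region = self._region[g.contig]
            gene_idx = self._gene_idx[g.contig]
            cds_off = self._cds_off[g.contig]
            gene_idx[g.start : g.end + 1] = idx
            for lo, hi in self.genes[g.gene_id].introns:
                region[lo : hi + 1] = INTRON
            for lo, hi in g.utr5:
                region[lo : hi + 1] = UTR5
            for lo, hi in g.utr3:
                region[lo : hi + 1] = UTR3
            codon_ok = g.gene_id not in self.flagged_genes
            offset = 0
            cds_order = g.cds if g.strand == PLUS else list(reversed(g.cds))
            for lo, hi in cds_order:
                region[lo : hi + 1] = CDS
                if codon_ok:
                    k = hi - lo + 1
                    if g.strand == PLUS:
                        cds_off[lo : hi + 1] = np.arange(offset, offset + k)
                    else:
                        cds_off[lo : hi + 1] = np.arange(
                            offset + k - 1, offset - 1, -1
                        )
                    offset += k
            for lo, hi in g.introns:
                w = min(SPLICE_WINDOW, hi - lo + 1)
                region[lo : lo + w] = SPLICE
                region[hi - w + 1 : hi + 1] = SPLICE
            if g.cds and codon_ok:
                self._cds_seq[g.gene_id] = g.coding_sequence(self.sequences[g.contig])
        self._index_built = True

    def region_at(self, contig: str, position: int) -> int:
        self.build_index()
        return int(self._region[contig][position])

    def gene_at(self, contig: str, position: int) -> GeneModel | None:
        self.build_index()
        i = int(self._gene_idx[contig][position])
        return self._gene_list[i] if i >= 0 else None

    def cds_offset_at(self, contig: str, position: int) -> int:
        self.build_index()
        return int(self._cds_off[contig][position])

    def spliced_cds(self, gene_id: str) -> str:
        self.build_index()
        return self._cds_seq[gene_id]

    def region_array(self, contig: str) -> np.ndarray:
        self.build_index()
        return self._region[contig]


# ---------------------------------------------------------------------------
# FASTA / GFF3 I/O
# ---------------------------------------------------------------------------


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(
    genes: Iterable[GeneModel], path: str | Path, contig_lengths: Mapping[str, int]
) -> None:
    """Write gene models as GFF3 with gene/mRNA/exon/CDS/UTR features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##sequence-region {contig} 1 {length}\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start)):
            attrs = f"ID={g.gene_id}"
            if g.annotation:
                attrs += f";product={g.annotation}"
            fh.write(
                "\t".join(
                    [g.contig, "candimap", "gene", str(g.start), str(g.end), ".",
                     g.strand, ".", attrs]
                )
                + "\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                "\t".join(
                    [g.contig, "candimap", "mRNA", str(g.start), str(g.end), ".",
                     g.strand, ".", f"ID={mrna};Parent={g.gene_id}"]
                )
                + "\n"
            )
            for kind, ivs, phase in (
                ("exon", g.exons, "."),
                ("five_prime_UTR", g.utr5, "."),
                ("three_prime_UTR", g.utr3, "."),
            ):
                for lo, hi in ivs:
                    fh.write(
                        "\t".join(
                            [g.contig, "candimap", kind, str(lo), str(hi), ".",
                             g.strand, phase, f"Parent={mrna}"]
                        )
                        + "\n"
                    )
            # CDS phase in transcription order
            order = g.cds if g.strand == PLUS else list(reversed(g.cds))
            offset = 0
            rows = []
            for lo, hi in order:
                phase = (3 - offset % 3) % 3
                rows.append((lo, hi, phase))
                offset += hi - lo + 1
            for lo, hi, phase in sorted(rows):
                fh.write(
                    "\t".join(
                        [g.contig, "candimap", "CDS", str(lo), str(hi), ".",
                         g.strand, str(phase), f"Parent={mrna}"]
                    )
                    + "\n"
                )


def read_gene_models(gff_path: str | Path, fasta_path: str | Path) -> GenomeAnnotation:
    """Load gene models from GFF3 + FASTA into a :class:`GenomeAnnotation`.

    Genes whose total CDS length is not divisible by 3 are kept but flagged
    and excluded from codon-level classification.
    """
    import gffutils
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    sequences = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int]] = []
        utr5: list[tuple[int, int]] = []
        utr3: list[tuple[int, int]] = []
        for child in db.children(gene.id):
            iv = (child.start, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(iv)
        if not exons:
            exons = sorted(set(cds) | set(utr5) | set(utr3)) or [(gene.start, gene.end)]
        product = gene.attributes.get("product", [""])
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
                annotation=product[0] if product else "",
            )
        )
    missing = {g.contig for g in genes} - set(sequences)
    if missing:
        raise AnnotationError(f"GFF features on contigs absent from FASTA: {missing}")
    return GenomeAnnotation(sequences, genes)


# ---------------------------------------------------------------------------
# Marker intervals
# ---------------------------------------------------------------------------

OPEN = None


@dataclass(frozen=True)
class MarkerInterval:
    """Genetically delimited search region, possibly open-ended.

    An open left bound resolves to 1, an open right bound to the contig
    length, matching map ranges quoted as ``>pos`` (right-open from pos) or
    ``<pos`` (left-open up to pos).
    """

    contig: str
    left_bound: int | None
    right_bound: int | None
    left_marker: str = ""
    right_marker: str = ""

    def resolve(self, contig_length: int) -> tuple[int, int]:
        if contig_length < 1:
            raise AnnotationError("contig_length must be >= 1")
        lo = 1 if self.left_bound is None else int(self.left_bound)
        hi = contig_length if self.right_bound is None else int(self.right_bound)
        if lo > hi:
            raise AnnotationError(f"interval resolves to empty range [{lo}, {hi}]")
        return lo, hi


def resolve_marker_interval(spec: MarkerInterval, contig_length: int) -> tuple[int, int]:
    """Resolve open bounds against the contig length; returns closed [lo, hi]."""
    return spec.resolve(contig_length)


def parse_interval_spec(contig: str, text: str) -> MarkerInterval:
    """Parse map-range syntax: ``"A to B"``, ``"> pos"``, ``"< pos"``."""
    t = text.strip().replace(",", "")
    if t.startswith(">"):
        return MarkerInterval(contig, int(t[1:].strip()), OPEN)
    if t.startswith("<"):
        return MarkerInterval(contig, OPEN, int(t[1:].strip()))
    for sep in (" to ", "-", ".."):
        if sep in t:
            left, right = t.split(sep, 1)
            return MarkerInterval(contig, int(left.strip()), int(right.strip()))
    raise AnnotationError(f"cannot parse interval spec {text!r}")


def read_marker_intervals(path: str | Path) -> dict[str, MarkerInterval]:
    """Read per-strain marker intervals from a TSV.

    Columns: strain, trait, contig, left, right — left/right accept an
    integer, ``>pos`` / ``<pos`` (one side open), or ``.`` (open).
    """

    def parse_bound(tok: str) -> int | None:
        tok = tok.strip()
        if tok in (".", "", "open"):
            return OPEN
        return int(tok.lstrip("<>").strip())

    out: dict[str, MarkerInterval] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if [h.lower() for h in header[:5]] != ["strain", "trait", "contig", "left", "right"]:
            raise AnnotationError(f"{path}: unrecognized marker-interval header {header!r}")
        for row in reader:
            if not row or not row[0]:
                continue
            strain, trait, contig, left, right = row[:5]
            left_b = OPEN if left.strip().startswith("<") else parse_bound(left)
            right_b = OPEN if right.strip().startswith(">") else parse_bound(right)
            out[strain] = MarkerInterval(
                contig, left_b, right_b, left_marker=trait, right_marker=trait
            )
    return out


def write_marker_intervals(intervals: Mapping[str, MarkerInterval], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["strain", "trait", "contig", "left", "right"])
        for strain, iv in intervals.items():
            writer.writerow(
                [
                    strain,
                    iv.left_marker or ".",
                    iv.contig,
                    "." if iv.left_bound is None else iv.left_bound,
                    "." if iv.right_bound is None else iv.right_bound,
                ]
            )
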
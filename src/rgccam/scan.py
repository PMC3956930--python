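"""Alignment scanning: classify columns as CAM, non-CAM or other.

A column of an aligned protein matrix contains a CAM substitution when
(a) at least two different amino acids are present, (b) every amino acid
present occurs in at least two taxa, and (c) every pair of distinct amino
acids at the column needs at least two nucleotide substitutions to
interconvert under the genetic code.  Columns meeting (a) and (b) whose
residue pairs all interconvert by a single substitution carry non-CAM
substitutions; everything else is "other".

Criteria (a)+(b) are the classic parsimony-informative condition, so CAM
and non-CAM sites are exactly the informative sites split by substitution
cost.  With more than two residue groups a column is classified only when
all pairs agree in class; mixed columns fall into "other".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .codes import AMINO_ACIDS, AminoAcidDistanceMatrix

#: Symbols treated as missing data (gaps, ambiguity codes, stops).
MISSING_SYMBOLS = frozenset("-XBZ*.?")

CAM = "RGC_CAM"
NON_CAM = "RGC_non-CAM"
OTHER = "other"
SITE_CLASSES = (CAM, NON_CAM, OTHER)


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, duplicate labels, ...)."""


@dataclass(frozen=True)
class Alignment:
    """An aligned set of amino-acid sequences, one row per taxon."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) < 2:
            raise AlignmentError("alignment needs at least two taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")
        if len(self.rows) != len(self.taxa):
            raise AlignmentError("one row required per taxon")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(f"rows have unequal lengths: {sorted(lengths)}")
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def column(self, index: int) -> tuple[str, ...]:
        return tuple(row[index] for row in self.rows)

    def columns(self) -> Iterable[tuple[str, ...]]:
        return zip(*self.rows)

    def residues_by_taxon(self, index: int) -> dict[str, str]:
        return dict(zip(self.taxa, self.column(index)))

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for taxon, row in zip(self.taxa, self.rows):
                fh.write(f">{taxon}\n{row}\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned amino-acid FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(
        taxa=tuple(r.id for r in records),
        rows=tuple(str(r.seq) for r in records),
    )


@dataclass(frozen=True)
class SiteRecord:
    """Classification of one alignment column.

    ``residue_groups`` maps each canonical amino acid present to the set of
    taxa carrying it.  ``bipartition_blocks`` is set when the column has
    exactly two residue groups that together cover every taxon: the two
    groups then induce a split of the taxon set.
    """

    column_index: int
    residues: tuple[str, ...]
    site_class: str
    residue_groups: Mapping[str, frozenset]
    bipartition_blocks: tuple[frozenset, frozenset] | None = None


def classify_site(
    column: Sequence[str],
    taxa: Sequence[str],
    matrix: AminoAcidDistanceMatrix,
    strict: bool = False,
) -> tuple[str, dict[str, frozenset]]:
    """Apply the three CAM criteria to one column.

    Returns the site class and the residue -> taxa grouping of canonical
    residues.  Non-canonical symbols are missing data by default; with
    ``strict`` their mere presence disqualifies the column.
    """
    if len(column) != len(taxa):
        raise AlignmentError("column length does not match taxon count")
    groups: dict[str, set] = {}
    has_noncanonical = False
    for taxon, symbol in zip(taxa, column):
        s = symbol.upper()
        if s in AMINO_ACIDS:
            groups.setdefault(s, set()).add(taxon)
        else:
            has_noncanonical = True
    frozen = {aa: frozenset(members) for aa, members in groups.items()}
    if strict and has_noncanonical:
        return OTHER, frozen
    # (a) two or more distinct amino acids
    if len(frozen) < 2:
        return OTHER, frozen
    # (b) every amino acid in at least two taxa
    if any(len(members) < 2 for members in frozen.values()):
        return OTHER, frozen
    # (c) substitution cost between every residue pair
    residues = sorted(frozen)
    dists = {
        matrix.distance(residues[i], residues[j])
        for i in range(len(residues))
        for j in range(i + 1, len(residues))
    }
    if all(d >= 2 for d in dists):
        return CAM, frozen
    if dists == {1}:
        return NON_CAM, frozen
    return OTHER, frozen


@dataclass(frozen=True)
class ScanResult:
    """Per-column records and class counts for one alignment."""

    alignment: Alignment
    records: tuple[SiteRecord, ...]
    counts: Mapping[str, int]

    def sites_of_class(self, site_class: str) -> tuple[SiteRecord, ...]:
        return tuple(r for r in self.records if r.site_class == site_class)


def scan_alignment(
    alignment: Alignment,
    matrix: AminoAcidDistanceMatrix,
    strict: bool = False,
) -> ScanResult:
    """Classify every column of `alignment`."""
    taxa = alignment.taxa
    taxon_set = frozenset(taxa)
    records = []
    counts = Counter({c: 0 for c in SITE_CLASSES})
    cache: dict[tuple[str, ...], tuple[str, dict[str, frozenset]]] = {}
    for idx, column in enumerate(alignment.columns()):
        hit = cache.get(column)
        if hit is None:
            hit = classify_site(column, taxa, matrix, strict=strict)
            cache[column] = hit
        site_class, groups = hit
        blocks = None
        if len(groups) == 2:
            b1, b2 = groups.values()
            if b1 | b2 == taxon_set:
                blocks = (b1, b2)
        records.append(
            SiteRecord(
                column_index=idx,
                residues=column,
                site_class=site_class,
                residue_groups=groups,
                bipartition_blocks=blocks,
            )
        )
        counts[site_class] += 1
    return ScanResult(alignment=alignment, records=tuple(records), counts=dict(counts))


def extract_sites(
    alignment: Alignment,
    records: Sequence[SiteRecord],
    site_class: str,
) -> Alignment:
    """Sub-alignment of the columns of `records` with the given class.

    Taxon order and column order are preserved; an empty selection yields a
    zero-length alignment.
    """
    keep = [r.column_index for r in records if r.site_class == site_class]
    rows = tuple("".join(row[i] for i in keep) for row in alignment.rows)
    return Alignment(taxa=alignment.taxa, rows=rows)


@dataclass(frozen=True)
class BatchSummary:
    """Aggregate CAM/non-CAM counts over a collection of alignments."""

    per_alignment: tuple[Mapping[str, int], ...]
    totals: Mapping[str, int]
    cam_histogram: Mapping[str, int]  # keys "0", "1", ">=2"


def batch_summary(
    alignments: Sequence[Alignment],
    matrix: AminoAcidDistanceMatrix,
    strict: bool = False,
) -> BatchSummary:
    """Scan several alignments sharing a taxon set and summarize counts."""
    if not alignments:
        raise AlignmentError("need at least one alignment")
    taxon_sets = {frozenset(a.taxa) for a in alignments}
    if len(taxon_sets) != 1:
        raise AlignmentError("alignments have inconsistent taxon sets")
    per_alignment = []
    totals = Counter({c: 0 for c in SITE_CLASSES})
    histogram = Counter({"0": 0, "1": 0, ">=2": 0})
    for aln in alignments:
        counts = scan_alignment(aln, matrix, strict=strict).counts
        per_alignment.append(counts)
        totals.update(counts)
        n_cam = counts[CAM]
        histogram["0" if n_cam == 0 else "1" if n_cam == 1 else ">=2"] += 1
    return BatchSummary(
        per_alignment=tuple(per_alignment),
        totals=dict(totals),
        cam_histogram=dict(histogram),
    )
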
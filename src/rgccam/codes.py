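"""Genetic codes and the amino-acid minimum-substitution distance matrix.

A genetic code assigns each of the 64 codons to one of the 20 canonical
amino acids or to a stop signal.  For any pair of amino acids the minimum
number of nucleotide substitutions needed to convert one into the other is
the minimum Hamming distance over all pairs of codons encoding them.  Pairs
at distance >= 2 are the "conserved amino acids, multiple substitutions"
(CAM) pairs: replacements between them are rare events, which is what makes
alignment columns exhibiting them attractive phylogenetic markers.

The 20x20 table of these distances is the CAM substitution matrix.  Under
the standard code every off-diagonal entry is 1, 2 or 3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from Bio.Data import CodonTable as _BioCodonTable

#: The 20 canonical amino-acid one-letter codes, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Marker used for translation-stop codons in codon tables.
STOP: str = "*"

_BASES = "ACGU"


class GeneticCodeError(ValueError):
    """Raised for malformed or unknown genetic-code specifications."""


def _normalize_codon(codon: str) -> str:
    """Upper-case a codon and map DNA T to RNA U (the logic is alphabet-agnostic)."""
    c = codon.strip().upper().replace("T", "U")
    if len(c) != 3 or any(b not in _BASES for b in c):
        raise GeneticCodeError(f"invalid codon {codon!r}")
    return c


@dataclass(frozen=True)
class GeneticCode:
    """A complete codon -> amino-acid translation table.

    Parameters
    ----------
    name
        Human-readable label, e.g. ``"standard"``.
    codon_table
        Mapping from all 64 RNA triplets to a canonical amino-acid letter
        or :data:`STOP`.
    """

    name: str
    codon_table: Mapping[str, str]
    _codons_by_aa: Mapping[str, tuple[str, ...]] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        table = {_normalize_codon(c): aa.upper() for c, aa in self.codon_table.items()}
        if len(table) != 64:
            raise GeneticCodeError(
                f"codon table must have exactly 64 distinct codons, got {len(table)}"
            )
        for codon, aa in table.items():
            if aa != STOP and aa not in AMINO_ACIDS:
                raise GeneticCodeError(f"codon {codon} maps to non-canonical symbol {aa!r}")
        by_aa: dict[str, list[str]] = {}
        for codon in sorted(table):
            by_aa.setdefault(table[codon], []).append(codon)
        object.__setattr__(self, "codon_table", table)
        object.__setattr__(
            self, "_codons_by_aa", {aa: tuple(cs) for aa, cs in by_aa.items()}
        )

    def codons_for(self, aa: str) -> tuple[str, ...]:
        """All codons encoding amino acid `aa` (RNA alphabet)."""
        aa = aa.upper()
        if aa not in AMINO_ACIDS:
            raise GeneticCodeError(f"not a canonical amino acid: {aa!r}")
        codons = self._codons_by_aa.get(aa, ())
        if not codons:
            raise GeneticCodeError(f"amino acid {aa} has no codon under code {self.name!r}")
        return codons

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return self._codons_by_aa.get(STOP, ())


def _code_from_ncbi_table(table: "_BioCodonTable.CodonTable", name: str) -> GeneticCode:
    mapping = dict(table.forward_table)
    for codon in table.stop_codons:
        mapping[codon] = STOP
    return GeneticCode(name=name, codon_table=mapping)


def _parse_code_file(path: Path) -> GeneticCode:
    """Parse a custom code file.

    Two layouts are accepted: one ``CODON AA`` pair per line (64 lines,
    ``#`` comments allowed), or the NCBI translation-table style with
    ``AAs``/``Base1``/``Base2``/``Base3`` assignment lines.
    """
    text = path.read_text()
    if "AAs" in text:
        fields: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip().rstrip(",")
            if "=" in line:
                key, _, value = line.partition("=")
                fields[key.strip().lstrip("-").strip()] = value.strip()
        try:
            aas, b1, b2, b3 = (fields[k] for k in ("AAs", "Base1", "Base2", "Base3"))
        except KeyError as exc:
            raise GeneticCodeError(f"NCBI-style table missing field {exc}") from exc
        if not (len(aas) == len(b1) == len(b2) == len(b3) == 64):
            raise GeneticCodeError("NCBI-style table fields must each have 64 symbols")
        mapping = {x + y + z: aa for aa, x, y, z in zip(aas, b1, b2, b3)}
    else:
        mapping = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GeneticCodeError(f"expected 'CODON AA' pairs, got {line!r}")
            mapping[parts[0]] = parts[1]
    return GeneticCode(name=path.stem, codon_table=mapping)


def load_genetic_code(spec: str | Path = "standard") -> GeneticCode:
    """Load a genetic code by built-in identifier or from a table file.

    `spec` may be ``"standard"``, an NCBI translation-table id (e.g. ``"2"``
    for the vertebrate mitochondrial code), or a path to a table file.
    """
    if isinstance(spec, Path):
        return _parse_code_file(spec)
    ident = spec.strip()
    if ident.lower() == "standard":
        return _code_from_ncbi_table(_BioCodonTable.unambiguous_rna_by_id[1], "standard")
    if ident.isdigit():
        try:
            table = _BioCodonTable.unambiguous_rna_by_id[int(ident)]
        except KeyError:
            raise GeneticCodeError(f"unknown NCBI translation table id {ident}") from None
        return _code_from_ncbi_table(table, table.names[0])
    path = Path(ident)
    if path.exists():
        return _parse_code_file(path)
    raise GeneticCodeError(f"unknown genetic code {spec!r}")


def min_codon_distance(aa_a: str, aa_b: str, code: GeneticCode) -> int:
    """Minimum nucleotide substitutions to convert `aa_a` into `aa_b`.

    The minimum over every pair of codons (one per amino acid) of the
    Hamming distance between the two triplets; 0 iff the letters are equal.
    """
    best = 3
    for ca in code.codons_for(aa_a):
        for cb in code.codons_for(aa_b):
            d = (ca[0] != cb[0]) + (ca[1] != cb[1]) + (ca[2] != cb[2])
            if d < best:
                best = d
                if best == 0:
                    return 0
    return best


IDENTICAL = "identical"
SINGLE_STEP = "single-step"
MULTI_STEP = "multi-step"


@dataclass(frozen=True)
class AminoAcidDistanceMatrix:
    """Symmetric 20x20 minimum-nucleotide-substitution distances.

    Off-diagonal entries are in {1, 2, 3}; the diagonal is 0.  Pairs with
    distance >= 2 are CAM pairs, distance-1 pairs are non-CAM pairs.
    """

    code_name: str
    entries: Mapping[frozenset, int]

    def distance(self, aa_a: str, aa_b: str) -> int:
        a, b = aa_a.upper(), aa_b.upper()
        for aa in (a, b):
            if aa not in AMINO_ACIDS:
                raise GeneticCodeError(f"not a canonical amino acid: {aa!r}")
        return 0 if a == b else self.entries[frozenset((a, b))]

    def classify(self, aa_a: str, aa_b: str) -> str:
        return classify_pair(aa_a, aa_b, self)

    def pairs_of_class(self, pair_class: str) -> list[tuple[str, str]]:
        """All unordered distinct pairs of the requested class, sorted."""
        if pair_class not in (SINGLE_STEP, MULTI_STEP):
            raise ValueError(f"unknown pair class {pair_class!r}")
        want_multi = pair_class == MULTI_STEP
        out = []
        for a, b in itertools.combinations(AMINO_ACIDS, 2):
            d = self.entries[frozenset((a, b))]
            if (d >= 2) == want_multi:
                out.append((a, b))
        return out

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as a 20x20 TSV grid with header row and column."""
        lines = [f"# CAM substitution matrix (genetic code: {self.code_name})"]
        lines.append("\t".join(["aa", *AMINO_ACIDS]))
        for a in AMINO_ACIDS:
            lines.append("\t".join([a, *(str(self.distance(a, b)) for b in AMINO_ACIDS)]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AminoAcidDistanceMatrix":
        rows = [
            line.split("\t")
            for line in Path(path).read_text().splitlines()
            if line and not line.startswith("#")
        ]
        header = rows[0][1:]
        entries = {}
        for row in rows[1:]:
            a = row[0]
            for b, val in zip(header, row[1:]):
                if a != b:
                    entries[frozenset((a, b))] = int(val)
        return cls(code_name=Path(path).stem, entries=entries)


def build_cam_matrix(code: GeneticCode | None = None) -> AminoAcidDistanceMatrix:
    """Build the CAM substitution matrix for `code` (default: standard code)."""
    if code is None:
        code = load_genetic_code("standard")
    entries = {
        frozenset((a, b)): min_codon_distance(a, b, code)
        for a, b in itertools.combinations(AMINO_ACIDS, 2)
    }
    return AminoAcidDistanceMatrix(code_name=code.name, entries=entries)


def classify_pair(aa_a: str, aa_b: str, matrix: AminoAcidDistanceMatrix) -> str:
    """Classify an amino-acid pair as identical, single-step or multi-step."""
    d = matrix.distance(aa_a, aa_b)
    if d == 0:
        return IDENTICAL
    return SINGLE_STEP if d == 1 else MULTI_STEP
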
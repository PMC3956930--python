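"""Synthetic alignments with planted CAM / non-CAM sites.

The generator plants informative columns directly at the amino-acid level:
a planted column picks an amino-acid pair of the requested class (CAM
pairs need >= 2 nucleotide substitutions, non-CAM pairs exactly 1) and
assigns one residue to one block of a chosen bipartition and the other
residue to the remaining taxa.  Classification depends only on residue
identities, so this minimal construction exercises the full downstream
pipeline (scanning, support counting, homoplasy, certainty, statistics)
with exactly known ground truth.  Codon-level evolution, rate
heterogeneity and indels are deliberately not modelled.

The :func:`sensu_stricto_scenario` builds site sets whose per-bipartition
support profile equals the one published for the five-species
*Saccharomyces* sensu stricto ortholog dataset (c = S. cerevisiae,
p = S. paradoxus, m = S. mikatae, k = S. kudriavzevii, b = S. bayanus;
reference topology ((c,p),m,(k,b))): 2,647 CAM sites and 100,887 non-CAM
sites distributed over the ten possible bipartitions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .codes import AMINO_ACIDS, MULTI_STEP, SINGLE_STEP, AminoAcidDistanceMatrix, build_cam_matrix
from .phylo import Bipartition, Tree
from .scan import CAM, NON_CAM, OTHER, Alignment

#: Single-letter labels of the five sensu stricto species.
SENSU_STRICTO_TAXA: tuple[str, ...] = ("c", "p", "m", "k", "b")

#: The accepted unrooted species phylogeny.
SENSU_STRICTO_TREE_NEWICK: str = "((c,p),m,(k,b));"

#: Published per-bipartition support counts for the 2,647 CAM sites.
SENSU_STRICTO_CAM_COUNTS: Mapping[str, int] = {
    "kb": 1180,
    "cp": 937,
    "bm": 177,
    "km": 141,
    "cb": 62,
    "cm": 42,
    "pm": 42,
    "bp": 29,
    "ck": 26,
    "kp": 11,
}

#: Published per-bipartition support counts for the 100,887 non-CAM sites.
SENSU_STRICTO_NONCAM_COUNTS: Mapping[str, int] = {
    "kb": 31791,
    "cp": 25625,
    "bm": 9520,
    "km": 8756,
    "cb": 5008,
    "cm": 4934,
    "pm": 4817,
    "bp": 3623,
    "ck": 3736,
    "kp": 3077,
}


class SimulationError(ValueError):
    """Raised for invalid simulation plans."""


def sample_residue_pair(
    pair_class: str,
    matrix: AminoAcidDistanceMatrix,
    seed: int | np.random.Generator | None = None,
) -> tuple[str, str]:
    """Draw an unordered amino-acid pair of the given class uniformly."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs = matrix.pairs_of_class(pair_class)
    if not pairs:
        raise SimulationError(f"no pairs of class {pair_class!r} under this code")
    return pairs[int(rng.integers(len(pairs)))]


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one generated column."""

    site_class: str  # CAM, NON_CAM or OTHER (constant filler)
    bipartition: Bipartition | None


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for a generated alignment, in column order."""

    sites: tuple[PlantedSite, ...]
    seed: int | None

    def class_counts(self) -> dict[str, int]:
        return dict(Counter(s.site_class for s in self.sites))

    def bipartition_counts(self, site_class: str) -> dict[Bipartition, int]:
        return dict(
            Counter(
                s.bipartition for s in self.sites if s.site_class == site_class
            )
        )


_CLASS_OF_PAIR = {CAM: MULTI_STEP, NON_CAM: SINGLE_STEP}


def _normalize_plan(
    plan: Mapping | Sequence[tuple],
    taxa: Sequence[str],
) -> list[tuple[Bipartition, str, int]]:
    """Plan entries are (bipartition, site_class, count); bipartitions may be
    given as names ("kb"), frozensets or Bipartition objects."""
    taxa_set = frozenset(taxa)
    if isinstance(plan, Mapping):
        items = [(key[0], key[1], count) for key, count in plan.items()]
    else:
        items = [tuple(entry) for entry in plan]  # (bipartition, class, count)
    out = []
    for bip_spec, site_class, count in items:
        if site_class not in _CLASS_OF_PAIR:
            raise SimulationError(f"unknown site class {site_class!r}")
        if isinstance(bip_spec, Bipartition):
            bip = bip_spec
        elif isinstance(bip_spec, (set, frozenset)):
            bip = Bipartition(block=frozenset(bip_spec), taxa=taxa_set)
        else:
            bip = Bipartition.from_name(str(bip_spec), taxa_set)
        if bip.taxa != taxa_set:
            raise SimulationError(f"bipartition {bip.name} not over the given taxa")
        if count < 0:
            raise SimulationError("negative planted count")
        out.append((bip, site_class, int(count)))
    return out


def generate_alignment(
    taxa: Sequence[str],
    plan: Mapping | Sequence[tuple],
    n_constant: int = 0,
    seed: int | np.random.Generator | None = None,
    matrix: AminoAcidDistanceMatrix | None = None,
) -> tuple[Alignment, PlantedTruth]:
    """Generate an alignment with planted informative columns.

    `plan` maps ``(bipartition, site_class)`` to a column count; each
    planted column realizes its bipartition with a class-appropriate
    residue pair.  `n_constant` uniform constant columns are added and the
    column order is shuffled deterministically by `seed`.
    """
    if matrix is None:
        matrix = build_cam_matrix()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    entries = _normalize_plan(plan, taxa)
    columns: list[dict[str, str]] = []
    truth: list[PlantedSite] = []
    for bip, site_class, count in entries:
        pairs = matrix.pairs_of_class(_CLASS_OF_PAIR[site_class])
        choices = rng.integers(len(pairs), size=count)
        for i in range(count):
            aa_small, aa_large = pairs[int(choices[i])]
            col = {t: (aa_small if t in bip.block else aa_large) for t in taxa}
            columns.append(col)
            truth.append(PlantedSite(site_class=site_class, bipartition=bip))
    for aa_idx in rng.integers(len(AMINO_ACIDS), size=n_constant):
        aa = AMINO_ACIDS[int(aa_idx)]
        columns.append({t: aa for t in taxa})
        truth.append(PlantedSite(site_class=OTHER, bipartition=None))
    order = rng.permutation(len(columns))
    rows = tuple(
        "".join(columns[int(i)][t] for i in order) for t in taxa
    )
    alignment = Alignment(taxa=tuple(taxa), rows=rows)
    shuffled = tuple(truth[int(i)] for i in order)
    return alignment, PlantedTruth(
        sites=shuffled, seed=seed if isinstance(seed, int) else None
    )


@dataclass(frozen=True)
class Scenario:
    """A generated two-class site collection with its reference tree."""

    taxa: tuple[str, ...]
    reference_tree: Tree
    cam_alignment: Alignment
    cam_truth: PlantedTruth
    noncam_alignment: Alignment
    noncam_truth: PlantedTruth


def sensu_stricto_scenario(seed: int | None = 0) -> Scenario:
    """Site sets matching the published five-species yeast support profile.

    Generates one alignment of 2,647 CAM sites and one of 100,887 non-CAM
    sites whose per-bipartition counts equal the published values, so the
    whole pipeline (support, homoplasy, certainty, Fisher) can be rerun
    end to end against the published summary numbers.
    """
    root = np.random.SeedSequence(seed)
    rng_cam, rng_noncam = (np.random.default_rng(s) for s in root.spawn(2))
    matrix = build_cam_matrix()
    taxa = SENSU_STRICTO_TAXA
    cam_plan = {(name, CAM): n for name, n in SENSU_STRICTO_CAM_COUNTS.items()}
    noncam_plan = {(name, NON_CAM): n for name, n in SENSU_STRICTO_NONCAM_COUNTS.items()}
    cam_aln, cam_truth = generate_alignment(taxa, cam_plan, seed=rng_cam, matrix=matrix)
    noncam_aln, noncam_truth = generate_alignment(
        taxa, noncam_plan, seed=rng_noncam, matrix=matrix
    )
    return Scenario(
        taxa=taxa,
        reference_tree=Tree.from_newick(SENSU_STRICTO_TREE_NEWICK),
        cam_alignment=cam_aln,
        cam_truth=cam_truth,
        noncam_alignment=noncam_aln,
        noncam_truth=noncam_truth,
    )
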
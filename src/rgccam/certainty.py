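"""Internode certainty (IC/ICA) and tree certainty (TC/TCA).

These entropy-based scores quantify how unambiguously per-site bipartition
support favours each internode of a reference tree.  For a focal internode
supported by n1 sites whose most prevalent conflicting bipartition is
supported by n2 sites,

    IC = 1 + sum_i p_i log2 p_i,      p_i = n_i / (n1 + n2),

so IC = 1 when there is no conflicting support and IC = 0 when support is
split evenly.  ICA generalizes this to all "sufficiently prevalent"
conflicting bipartitions: every conflict whose support exceeds a fraction
(default 5%) of the total site count is included, with fallback to the
single most prevalent conflict when none qualifies, and the logarithm base
equals the number of bipartitions in the normalization.  TC and TCA are the
sums of IC and ICA over the reference tree's internodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .phylo import Bipartition, SupportTable, Tree


def conflicts_with(b1: Bipartition, b2: Bipartition) -> bool:
    """True iff the two splits cannot co-occur in a single tree.

    Two splits A|B and C|D are compatible iff at least one of the four
    intersections A∩C, A∩D, B∩C, B∩D is empty; otherwise they conflict.
    A split never conflicts with itself.
    """
    if b1.taxa != b2.taxa:
        raise ValueError("bipartitions are over different taxon sets")
    if b1 == b2:
        return False
    a, b = b1.block, b1.other_block
    c, d = b2.block, b2.other_block
    return bool(a & c) and bool(a & d) and bool(b & c) and bool(b & d)


def _certainty(counts: Sequence[int], base: int) -> float:
    total = sum(counts)
    acc = 1.0
    for n in counts:
        if n > 0:
            p = n / total
            acc += p * math.log(p, base)
    return acc


def internode_certainty(focal_count: int, conflicting_counts: Sequence[int] = ()) -> float:
    """IC from the focal count and the most prevalent conflicting count."""
    if focal_count < 1:
        raise ValueError("focal bipartition must have at least one supporting site")
    if any(c < 0 for c in conflicting_counts):
        raise ValueError("negative conflicting count")
    top = max(conflicting_counts, default=0)
    if top == 0:
        return 1.0
    return _certainty([focal_count, top], base=2)


def internode_certainty_all(
    focal_count: int,
    conflicting_counts: Sequence[int],
    total_sites: int,
    threshold: float = 0.05,
) -> float:
    """ICA under the prevalence-threshold inclusion rule.

    Conflicting bipartitions with more than ``threshold * total_sites``
    supporting sites enter the normalization together with the focal one;
    if none qualifies the single most prevalent conflict is used (making
    ICA = IC).  The log base is the number of included bipartitions.
    """
    if focal_count < 1:
        raise ValueError("focal bipartition must have at least one supporting site")
    if any(c < 0 for c in conflicting_counts):
        raise ValueError("negative conflicting count")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    conflicting = [c for c in conflicting_counts if c > 0]
    if not conflicting:
        return 1.0
    qualifying = [c for c in conflicting if c / total_sites > threshold]
    if not qualifying:
        qualifying = [max(conflicting)]
    counts = [focal_count, *sorted(qualifying, reverse=True)]
    return _certainty(counts, base=len(counts))


@dataclass(frozen=True)
class InternodeRecord:
    """Certainty scores for one internode of the reference tree."""

    bipartition: Bipartition
    focal_count: int
    conflicting_counts: Mapping[Bipartition, int]
    ic: float
    ica: float


@dataclass(frozen=True)
class CertaintyResult:
    """Per-internode IC/ICA and their sums (TC/TCA) for a reference tree."""

    internodes: tuple[InternodeRecord, ...]
    tc: float
    tca: float

    def by_name(self) -> dict[str, InternodeRecord]:
        return {rec.bipartition.name: rec for rec in self.internodes}


def tree_certainty(
    reference_tree: Tree,
    table: SupportTable,
    total_sites: int | None = None,
    ica_threshold: float = 0.05,
) -> CertaintyResult:
    """IC/ICA for every internode of `reference_tree`, plus TC/TCA.

    `total_sites` is the site count against which the ICA prevalence
    threshold is measured; it defaults to the support table's total.  An
    internode with zero focal support scores 0.
    """
    if total_sites is None:
        total_sites = table.total
    records = []
    for focal in sorted(reference_tree.bipartitions(), key=lambda b: b.name):
        conflicting = {
            b: c for b, c in table.counts.items() if c > 0 and conflicts_with(focal, b)
        }
        focal_count = table.count(focal)
        if focal_count == 0:
            ic = ica = 0.0
        else:
            counts = list(conflicting.values())
            ic = internode_certainty(focal_count, counts)
            ica = internode_certainty_all(
                focal_count, counts, total_sites, threshold=ica_threshold
            )
        records.append(
            InternodeRecord(
                bipartition=focal,
                focal_count=focal_count,
                conflicting_counts=conflicting,
                ic=ic,
                ica=ica,
            )
        )
    return CertaintyResult(
        internodes=tuple(records),
        tc=sum(r.ic for r in records),
        tca=sum(r.ica for r in records),
    )
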
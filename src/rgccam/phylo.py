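"""Unrooted trees, bipartitions, Fitch parsimony and the homoplasy index.

Trees are unrooted and (by default) binary: every internal vertex has
degree 3.  Each internal edge induces a nontrivial bipartition of the taxon
set; an n-leaf binary unrooted tree has n-3 of them.  Parsimony length of a
column on a tree is computed with the Fitch algorithm for unordered states
after rooting the tree on an arbitrary edge (the length is root-invariant).

The homoplasy index of a column on a reference tree is

    HI = 1 - CI,    CI = (minimum changes on any tree) / (changes on the tree)

where the numerator for unordered states equals the number of distinct
states minus one.  HI is 0 for columns fully consistent with the tree; for
a two-state informative column on a five-taxon binary tree the only other
possible value is 0.5.

Newick reading and writing are delegated to dendropy; everything downstream
operates on a light adjacency representation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .scan import AMINO_ACIDS, Alignment, SiteRecord


class TreeError(ValueError):
    """Raised for malformed trees or tree/alignment mismatches."""


@dataclass(frozen=True)
class Bipartition:
    """A split of the taxon set into two non-empty blocks.

    The canonical ``block`` is the smaller of the two (ties broken by the
    block containing the alphabetically first taxon), so equal splits
    compare and hash equal regardless of construction order.
    """

    block: frozenset
    taxa: frozenset

    def __post_init__(self) -> None:
        block, taxa = frozenset(self.block), frozenset(self.taxa)
        if not block or not (taxa - block):
            raise TreeError("both bipartition blocks must be non-empty")
        if not block <= taxa:
            raise TreeError("block is not a subset of the taxon set")
        other = taxa - block
        if len(other) < len(block) or (len(other) == len(block) and min(taxa) in other):
            block = other
        object.__setattr__(self, "block", block)
        object.__setattr__(self, "taxa", taxa)

    @property
    def other_block(self) -> frozenset:
        return self.taxa - self.block

    @property
    def is_trivial(self) -> bool:
        return min(len(self.block), len(self.other_block)) < 2

    @property
    def name(self) -> str:
        """Canonical display name: sorted members of the smaller block."""
        members = sorted(self.block)
        if all(len(t) == 1 for t in self.taxa):
            return "".join(members)
        return ",".join(members)

    @classmethod
    def from_name(cls, name: str, taxa: Iterable[str]) -> "Bipartition":
        """Parse a name such as ``"kb"`` (single-letter taxa, any order) or
        a comma-separated member list."""
        taxa = frozenset(taxa)
        if "," in name:
            members = frozenset(part.strip() for part in name.split(","))
        elif all(len(t) == 1 for t in taxa):
            members = frozenset(name)
        else:
            members = frozenset([name])
        if not members <= taxa:
            raise TreeError(f"bipartition name {name!r} has members outside the taxon set")
        return cls(block=members, taxa=taxa)


class Tree:
    """An unrooted tree over uniquely labelled leaves.

    Stored as an adjacency map over integer vertex ids with a label map for
    the leaves.  Binary unless constructed with ``allow_polytomies`` (used
    only for bipartition extraction).
    """

    __slots__ = ("_adj", "_labels", "_leaf_of", "taxa", "is_binary")

    def __init__(
        self,
        adjacency: Mapping[int, Iterable[int]],
        leaf_labels: Mapping[int, str],
        allow_polytomies: bool = False,
    ):
        adj = {v: tuple(nbrs) for v, nbrs in adjacency.items()}
        labels = dict(leaf_labels)
        if len(set(labels.values())) != len(labels):
            raise TreeError("duplicate leaf labels")
        if len(labels) < 3:
            raise TreeError("an unrooted tree needs at least three leaves")
        is_binary = True
        for v, nbrs in adj.items():
            deg = len(nbrs)
            if v in labels:
                if deg != 1:
                    raise TreeError(f"leaf vertex {labels[v]!r} has degree {deg}")
            elif deg != 3:
                if deg < 3:
                    raise TreeError(f"internal vertex of degree {deg}")
                is_binary = False
        if not is_binary and not allow_polytomies:
            raise TreeError("tree contains polytomies")
        self._adj = adj
        self._labels = labels
        self._leaf_of = {label: v for v, label in labels.items()}
        self.taxa = tuple(sorted(labels.values()))
        self.is_binary = is_binary

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, allow_polytomies: bool = False) -> "Tree":
        """Parse Newick text; rooted inputs are unrooted by suppressing the
        root and any other degree-2 vertex."""
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"could not parse Newick: {exc}") from exc
        ids: dict[object, int] = {}
        adj: dict[int, set] = {}
        labels: dict[int, str] = {}

        def vid(node) -> int:
            if node not in ids:
                ids[node] = len(ids)
                adj[ids[node]] = set()
            return ids[node]

        for edge in dtree.preorder_edge_iter():
            if edge.head_node is None or edge.tail_node is None:
                continue
            u, v = vid(edge.tail_node), vid(edge.head_node)
            adj[u].add(v)
            adj[v].add(u)
        for node in dtree.leaf_node_iter():
            if node.taxon is None or not node.taxon.label:
                raise TreeError("unlabelled leaf")
            labels[vid(node)] = node.taxon.label
        # suppress degree-2 vertices (the root of a rooted input, knuckles)
        for v in [v for v, nbrs in adj.items() if len(nbrs) == 2 and v not in labels]:
            a, b = adj.pop(v)
            adj[a].discard(v)
            adj[b].discard(v)
            adj[a].add(b)
            adj[b].add(a)
        return cls(adj, labels, allow_polytomies=allow_polytomies)

    @classmethod
    def from_groups(cls, *groups: Sequence) -> "Tree":
        """Convenience builder from a Newick-like nesting of labels, e.g.
        ``Tree.from_groups(("c", "p"), "m", ("k", "b"))``."""

        def fmt(g) -> str:
            if isinstance(g, str):
                return g
            return "(" + ",".join(fmt(x) for x in g) + ")"

        return cls.from_newick("(" + ",".join(fmt(g) for g in groups) + ");")

    # -- basic structure ---------------------------------------------------

    def _neighbors(self, v: int, skip: int | None = None) -> tuple[int, ...]:
        return tuple(u for u in self._adj[v] if u != skip)

    def _an_edge(self) -> tuple[int, int]:
        v = next(iter(self._adj))
        return v, self._adj[v][0]

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in self._adj for v in self._adj[u] if u < v]

    def _postorder(self, root: int, parent: int) -> list[tuple[int, int]]:
        """(vertex, parent) pairs, children before parents, below `root`."""
        order: list[tuple[int, int]] = []
        stack = [(root, parent)]
        while stack:
            v, p = stack.pop()
            order.append((v, p))
            stack.extend((u, v) for u in self._adj[v] if u != p)
        order.reverse()
        return order

    def bipartitions(self, include_trivial: bool = False) -> frozenset:
        """The bipartitions induced by the tree's edges (nontrivial only by
        default; a binary n-leaf tree has n-3)."""
        taxa = frozenset(self.taxa)
        below: dict[tuple[int, int], frozenset] = {}
        root, rparent = self._an_edge()
        for v, p in self._postorder(root, rparent) + self._postorder(rparent, root):
            if v in self._labels:
                below[(v, p)] = frozenset([self._labels[v]])
            else:
                below[(v, p)] = frozenset().union(
                    *(below[(u, v)] for u in self._neighbors(v, p))
                )
        out = set()
        for u, v in self.edges():
            block = below.get((u, v)) or below.get((v, u))
            if block is None or not block or block == taxa:
                continue
            bip = Bipartition(block=block, taxa=taxa)
            if include_trivial or not bip.is_trivial:
                out.add(bip)
        return frozenset(out)

    def to_newick(self) -> str:
        root, rparent = self._an_edge()

        def render(v: int, p: int) -> str:
            if v in self._labels:
                return self._labels[v]
            return "(" + ",".join(render(u, v) for u in self._neighbors(v, p)) + ")"

        if root in self._labels:
            root, rparent = rparent, root
        parts = [render(u, root) for u in self._adj[root]]
        return "(" + ",".join(parts) + ");"

    def __eq__(self, other) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        return self.taxa == other.taxa and self.bipartitions() == other.bipartitions()

    def __hash__(self) -> int:
        return hash((self.taxa, self.bipartitions()))

    def __repr__(self) -> str:
        return f"Tree({self.to_newick()!r})"

    # -- parsimony ---------------------------------------------------------

    def fitch_length(self, states: Mapping[str, object]) -> int:
        """Minimum number of unordered state changes of a character.

        `states` maps each taxon to a state (any hashable), a set of states,
        or None for missing data.  Missing leaves behave as wildcards: they
        never force a change.  Requires a binary tree.
        """
        if not self.is_binary:
            raise TreeError("Fitch parsimony requires a binary tree")
        missing = set(self.taxa) - set(states)
        if missing:
            raise TreeError(f"no state for taxa {sorted(missing)}")

        def leaf_set(label: str):
            s = states[label]
            if s is None:
                return None
            if isinstance(s, (set, frozenset)):
                return frozenset(s) or None
            return frozenset([s])

        root, rparent = self._an_edge()  # root the tree on this edge
        sets: dict[int, frozenset | None] = {}
        changes = 0

        def merge(a, b):
            nonlocal changes
            if a is None:
                return b
            if b is None:
                return a
            inter = a & b
            if inter:
                return inter
            changes += 1
            return a | b

        for side, other in ((root, rparent), (rparent, root)):
            for v, p in self._postorder(side, other):
                if v in self._labels:
                    sets[v] = leaf_set(self._labels[v])
                else:
                    c1, c2 = self._neighbors(v, p)
                    sets[v] = merge(sets[c1], sets[c2])
        merge(sets[root], sets[rparent])
        return changes


# -- module-level operations -----------------------------------------------


def parse_newick(text: str, allow_polytomies: bool = False) -> Tree:
    """Parse Newick text into an unrooted :class:`Tree`."""
    return Tree.from_newick(text, allow_polytomies=allow_polytomies)


def tree_bipartitions(tree: Tree) -> frozenset:
    """The nontrivial bipartitions of `tree` (n-3 for a binary n-leaf tree)."""
    return tree.bipartitions()


def site_bipartition(site: SiteRecord, taxa: Iterable[str] | None = None) -> Bipartition:
    """The bipartition induced by a column with exactly two residue groups."""
    groups = site.residue_groups
    if len(groups) != 2:
        raise TreeError(
            f"site {site.column_index} has {len(groups)} residue groups, need exactly 2"
        )
    b1, b2 = groups.values()
    all_taxa = frozenset(taxa) if taxa is not None else b1 | b2
    if b1 | b2 != all_taxa:
        raise TreeError("residue groups do not cover the taxon set")
    return Bipartition(block=b1, taxa=all_taxa)


def _site_states(site: SiteRecord | Mapping[str, object]) -> dict[str, object]:
    if isinstance(site, SiteRecord):
        states: dict[str, object] = {}
        for aa, members in site.residue_groups.items():
            for taxon in members:
                states[taxon] = aa
        return states
    return dict(site)


def fitch_length(site: SiteRecord | Mapping[str, object], tree: Tree) -> int:
    """Fitch parsimony length of a column on `tree`.

    Accepts a :class:`SiteRecord` (taxa absent from its residue groups are
    missing data) or a taxon -> state mapping.
    """
    states = _site_states(site)
    full = {t: states.get(t) for t in tree.taxa}
    return tree.fitch_length(full)


def min_length_any_tree(site: SiteRecord | Mapping[str, object]) -> int:
    """Minimum changes of a column on any tree: (#distinct states) - 1."""
    states = _site_states(site)
    observed = {s for s in states.values() if s is not None}
    return max(len(observed) - 1, 0)


@dataclass(frozen=True)
class HomoplasyScore:
    """Per-site homoplasy summary: HI = 1 - min_length / length_on_tree."""

    site_length_on_tree: int
    min_length: int
    hi: float


def homoplasy_index(site: SiteRecord | Mapping[str, object], tree: Tree) -> HomoplasyScore:
    """Homoplasy index of a column on `tree` (0 for constant columns)."""
    on_tree = fitch_length(site, tree)
    min_len = min_length_any_tree(site)
    hi = 0.0 if on_tree == 0 else 1.0 - min_len / on_tree
    return HomoplasyScore(site_length_on_tree=on_tree, min_length=min_len, hi=hi)


def enumerate_unrooted_trees(taxa: Sequence[str]) -> list[Tree]:
    """All (2n-5)!! binary unrooted topologies over `taxa` (4 <= n <= 8)."""
    taxa = list(taxa)
    n = len(taxa)
    if not 4 <= n <= 8:
        raise TreeError(f"exhaustive enumeration supports 4..8 taxa, got {n}")
    # leaves are vertices 0..n-1; internal vertices are appended as needed
    base_adj = {0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}
    partial = [base_adj]
    next_internal = n + 1
    for leaf in range(3, n):
        grown = []
        for adj in partial:
            edges = [(u, v) for u in adj for v in adj[u] if u < v]
            for u, v in edges:
                new = {w: set(nbrs) for w, nbrs in adj.items()}
                mid = next_internal
                new[u].discard(v)
                new[v].discard(u)
                new[mid] = {u, v, leaf}
                new[u].add(mid)
                new[v].add(mid)
                new[leaf] = {mid}
                grown.append(new)
        partial = grown
        next_internal += 1
    labels = {i: t for i, t in enumerate(taxa)}
    return [Tree(adj, labels) for adj in partial]


def _canonical_patterns(alignment: Alignment) -> tuple[list[dict[str, object]], np.ndarray]:
    """Collapse alignment columns into distinct state patterns with counts.

    States are relabelled by first occurrence (Fitch length is invariant
    under state relabelling), so e.g. an N/C and a D/H column with the same
    taxon split share one pattern.
    """
    counter: Counter = Counter()
    for column in alignment.columns():
        relabel: dict[str, int] = {}
        pattern = []
        for symbol in column:
            if symbol in AMINO_ACIDS:
                pattern.append(relabel.setdefault(symbol, len(relabel)))
            else:
                pattern.append(None)
        counter[tuple(pattern)] += 1
    patterns = [
        {taxon: state for taxon, state in zip(alignment.taxa, pat)}
        for pat in counter
    ]
    return patterns, np.array(list(counter.values()), dtype=np.int64)


def _length_matrix(trees: Sequence[Tree], patterns: Sequence[Mapping[str, object]]) -> np.ndarray:
    return np.array(
        [[t.fitch_length(p) for p in patterns] for t in trees], dtype=np.int64
    )


def parsimony_search(alignment: Alignment) -> tuple[list[Tree], int]:
    """Exhaustive maximum-parsimony search (<= 8 taxa).

    Returns all co-optimal trees and the optimal total length.
    """
    trees = enumerate_unrooted_trees(alignment.taxa)
    patterns, counts = _canonical_patterns(alignment)
    lengths = _length_matrix(trees, patterns) @ counts
    best = int(lengths.min())
    return [t for t, L in zip(trees, lengths) if L == best], best


def bootstrap_support(
    alignment: Alignment,
    reference_tree: Tree,
    replicates: int = 100,
    seed: int | np.random.Generator | None = None,
    semantics: str = "strict",
) -> dict[Bipartition, float]:
    """Bootstrap support for the reference tree's bipartitions.

    Columns are resampled with replacement; each replicate is analysed with
    the exhaustive parsimony search.  Under ``"strict"`` semantics a
    bipartition counts as recovered only when present in every co-optimal
    tree of the replicate; ``"any"`` requires presence in at least one.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if semantics not in ("strict", "any"):
        raise ValueError(f"unknown semantics {semantics!r}")
    if set(reference_tree.taxa) != set(alignment.taxa):
        raise TreeError("reference tree and alignment taxa differ")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trees = enumerate_unrooted_trees(alignment.taxa)
    patterns, counts = _canonical_patterns(alignment)
    length_matrix = _length_matrix(trees, patterns)
    tree_bips = [t.bipartitions() for t in trees]
    focal = sorted(reference_tree.bipartitions(), key=lambda b: b.name)
    hits = {b: 0 for b in focal}
    n_columns = int(counts.sum())
    probs = counts / n_columns
    for _ in range(replicates):
        resampled = rng.multinomial(n_columns, probs)
        lengths = length_matrix @ resampled
        best = lengths.min()
        optimal = [bips for bips, L in zip(tree_bips, lengths) if L == best]
        for b in focal:
            present = [b in bips for bips in optimal]
            if all(present) if semantics == "strict" else any(present):
                hits[b] += 1
    return {b: 100.0 * hits[b] / replicates for b in focal}


@dataclass(frozen=True)
class SupportTable:
    """Bipartition -> number of supporting sites for one site class."""

    counts: Mapping[Bipartition, int]
    total: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative support count")
        if self.total < sum(self.counts.values()):
            raise ValueError("total smaller than the sum of bipartition counts")

    def count(self, bipartition: Bipartition) -> int:
        return self.counts.get(bipartition, 0)

    def percentages(self) -> dict[Bipartition, float]:
        if self.total == 0:
            return {b: 0.0 for b in self.counts}
        return {b: 100.0 * c / self.total for b, c in self.counts.items()}

    def split_by_tree(self, tree: Tree) -> tuple[dict, dict]:
        """(supporting, conflicting) count maps relative to `tree`'s splits."""
        in_tree = tree.bipartitions()
        supporting = {b: c for b, c in self.counts.items() if b in in_tree}
        conflicting = {b: c for b, c in self.counts.items() if b not in in_tree}
        return supporting, conflicting

    def to_tsv(self, path, comments: Sequence[str] = ()) -> None:
        lines = [f"# {c}" for c in comments]
        lines.append("bipartition\tcount\tpercent")
        for b, c in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0].name)):
            pct = 100.0 * c / self.total if self.total else 0.0
            lines.append(f"{b.name}\t{c}\t{pct!r}")
        lines.append(f"total\t{self.total}\t100.0")
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")


def support_table(records: Sequence[SiteRecord], taxa: Sequence[str]) -> SupportTable:
    """Count the bipartitions induced by informative site records.

    Records must carry a full-coverage two-group bipartition (as produced by
    the scanner for CAM / non-CAM sites without missing data).
    """
    taxa_set = frozenset(taxa)
    counter: Counter = Counter()
    n = 0
    for record in records:
        if record.bipartition_blocks is None:
            continue
        counter[Bipartition(block=record.bipartition_blocks[0], taxa=taxa_set)] += 1
        n += 1
    return SupportTable(counts=dict(counter), total=n)
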
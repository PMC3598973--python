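"""Phylogeny container plus Newick/NEXUS I/O, validation, pruning and trait matching.

The :class:`Phylogeny` class is an array-backed rooted tree: nodes are integer
ids ``0..n_nodes-1`` with tips first (``0..n_tips-1``, in a fixed tip order),
a parent map, and one branch length per non-root node in million years (My).
Parsing, writing and pruning delegate to :mod:`dendropy`; the array view is what
the Brownian-motion numerics consume.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .exceptions import (
    MalformedTreeError,
    NoOverlapError,
    TreeInvariantError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "read_newick",
    "write_newick",
    "read_nexus",
    "prune_and_match",
    "is_ultrametric",
    "TRAIT_COLUMNS",
    "read_trait_table",
    "validate_trait_table",
]

#: Canonical trait-table header.  ``species`` is mandatory; the others are the
#: morphometric / acoustic columns used downstream (units: mm, quarter-turns,
#: g, kHz).  ``echolocation_type`` is categorical.
TRAIT_COLUMNS = [
    "species",
    "membrane_length",
    "turns",
    "mass",
    "echolocation_type",
    "call_min",
    "call_peak",
    "call_max",
]

ECHOLOCATION_TYPES = {"CF", "FM", "broadband", "none", "tongue-click", "non-laryngeal"}


@dataclass
class Phylogeny:
    """Rooted phylogeny with branch lengths in million years.

    Attributes
    ----------
    parent : (n_nodes,) int array, -1 at the root.
    lengths : (n_nodes,) float array; ``lengths[root]`` is the root stem
        (usually 0), all other entries must be positive (zero only allowed on
        branches created by polytomy resolution).
    labels : list of tip labels for nodes ``0..n_tips-1``.
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: list
    n_tips: int
    root: int
    children: list = field(default_factory=list)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if not self.children:
            ch = [[] for _ in range(self.n_nodes)]
            for v, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(v)
            self.children = ch

    # -- basic structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_labels(self) -> list:
        return list(self.labels)

    def postorder(self) -> np.ndarray:
        """Node ids in postorder (children before parents, root last)."""
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return np.asarray(order[::-1], dtype=np.int64)

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1].copy()

    def is_binary(self) -> bool:
        return all(len(self.children[v]) in (0, 2) for v in range(self.n_nodes))

    def node_depths(self) -> np.ndarray:
        """Root-to-node path lengths (root depth 0, ignoring any root stem)."""
        depth = np.zeros(self.n_nodes)
        for v in self.preorder():
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.lengths[v]
        return depth

    def tip_depths(self) -> np.ndarray:
        return self.node_depths()[: self.n_tips]

    def clade_tips(self, node: int) -> np.ndarray:
        """Tip ids contained in the clade rooted at ``node``."""
        tips, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < self.n_tips:
                tips.append(v)
            stack.extend(self.children[v])
        return np.asarray(sorted(tips), dtype=np.int64)

    def mrca(self, tip_labels) -> int:
        """Most recent common ancestor of a set of tip labels."""
        want = set(tip_labels)
        idx = {lab: i for i, lab in enumerate(self.labels)}
        missing = want - set(idx)
        if missing:
            raise KeyError(f"unknown tip labels: {sorted(missing)}")
        tipset = {idx[lab] for lab in want}
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        for v in self.postorder():
            if v < self.n_tips:
                counts[v] = 1 if v in tipset else 0
            else:
                counts[v] = sum(counts[c] for c in self.children[v])
            if counts[v] == len(tipset):
                return int(v)
        raise RuntimeError("unreachable")  # pragma: no cover

    def total_depth(self) -> float:
        return float(self.tip_depths().max())

    # -- conversion ------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, validate: bool = True,
                      allow_zero_lengths: bool = False) -> "Phylogeny":
        tips = [leaf for leaf in dtree.leaf_node_iter()]
        labels = []
        for leaf in tips:
            if leaf.taxon is None or leaf.taxon.label is None:
                raise TreeInvariantError("unlabelled tip in tree")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            raise TreeInvariantError(f"duplicate tip labels in tree: {sorted(labels)}")
        index = {}
        for i, leaf in enumerate(tips):
            index[id(leaf)] = i
        nxt = len(tips)
        for nd in dtree.postorder_node_iter():
            if not nd.is_leaf():
                index[id(nd)] = nxt
                nxt += 1
        n = nxt
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n)
        root = index[id(dtree.seed_node)]
        for nd in dtree.postorder_node_iter():
            v = index[id(nd)]
            if nd.parent_node is not None:
                parent[v] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise TreeInvariantError(
                        f"missing branch length on edge above node "
                        f"{nd.taxon.label if nd.taxon else v}"
                    )
                lengths[v] = float(nd.edge.length)
            else:
                lengths[v] = float(nd.edge.length or 0.0)
        tree = cls(parent=parent, lengths=lengths, labels=labels,
                   n_tips=len(tips), root=root)
        if validate:
            tree.validate(allow_zero_lengths=allow_zero_lengths)
        return tree

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace(self.labels)
        dtree = dendropy.Tree(taxon_namespace=taxa)
        nodes = {}
        for v in self.preorder():
            nd = dendropy.Node()
            if v < self.n_tips:
                nd.taxon = taxa.get_taxon(self.labels[v])
            nd.edge.length = float(self.lengths[v])
            nodes[v] = nd
            p = self.parent[v]
            if p < 0:
                dtree.seed_node = nd
            else:
                nodes[p].add_child(nd)
        return dtree

    # -- validation ------------------------------------------------------
    def validate(self, allow_zero_lengths: bool = False) -> None:
        """Check structural invariants, raising :class:`TreeInvariantError`."""
        if (self.parent == -1).sum() != 1 or self.parent[self.root] != -1:
            raise TreeInvariantError("tree must have exactly one root")
        if self.n_tips < 1:
            raise TreeInvariantError("tree has no tips")
        nonroot = np.arange(self.n_nodes) != self.root
        bad = self.lengths[nonroot] <= 0 if not allow_zero_lengths else self.lengths[nonroot] < 0
        if np.any(bad) or not np.all(np.isfinite(self.lengths)):
            raise TreeInvariantError("non-root branch lengths must be positive and finite")
        if len(self.postorder()) != self.n_nodes:
            raise TreeInvariantError("parent map does not describe a single tree")

    # -- derived trees ---------------------------------------------------
    def resolve_polytomies(self) -> "Phylogeny":
        """Return a binary tree; multifurcations are split with zero-length branches.

        The resolution is arbitrary (deterministic given input order) and a
        warning is emitted, since the inserted branches carry no time.
        """
        if self.is_binary():
            return self
        warnings.warn(
            "tree contains polytomies; resolving arbitrarily with zero-length branches",
            stacklevel=2,
        )
        dtree = self.to_dendropy()
        dtree.resolve_polytomies()
        return Phylogeny.from_dendropy(dtree, allow_zero_lengths=True)

    def prune_to(self, keep_labels) -> "Phylogeny":
        """Restrict to a subset of tips; degree-2 nodes are collapsed with
        branch lengths summed, so patristic distances between retained tips
        are preserved exactly."""
        keep = [lab for lab in self.labels if lab in set(keep_labels)]
        if not keep:
            raise NoOverlapError(self.labels, keep_labels)
        if len(keep) == len(self.labels):
            return self
        dtree = self.to_dendropy()
        dtree.retain_taxa_with_labels(keep)
        # retain_taxa leaves unifurcations; collapse them, summing edge lengths
        dtree.suppress_unifurcations()
        allow_zero = bool(np.any(self.lengths[np.arange(self.n_nodes) != self.root] == 0))
        return Phylogeny.from_dendropy(dtree, allow_zero_lengths=allow_zero)


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def read_newick(text: str, validate: bool = True) -> Phylogeny:
    """Parse a Newick string (branch lengths required) into a :class:`Phylogeny`."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=False,
        )
    except Exception as exc:  # dendropy raises several error classes
        pos = getattr(exc, "column", None)
        loc = f" near character {pos}" if pos is not None else ""
        raise MalformedTreeError(f"could not parse Newick{loc}: {exc}") from exc
    if dtree.seed_node is None or not any(dtree.leaf_node_iter()):
        raise MalformedTreeError("Newick text contains no tree")
    tree = Phylogeny.from_dendropy(dtree, validate=validate)
    logger.info("read_newick: %d tips, %d nodes", tree.n_tips, tree.n_nodes)
    return tree


def write_newick(tree: Phylogeny, precision: int = 12) -> str:
    """Serialise to Newick with branch lengths."""
    dtree = tree.to_dendropy()
    out = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=f".{precision}g",
    ).strip()
    return out


def read_nexus(text: str) -> Phylogeny:
    """Parse the first tree of a NEXUS TREES block."""
    try:
        dtree = dendropy.Tree.get(data=text, schema="nexus")
    except Exception as exc:
        raise MalformedTreeError(f"could not parse NEXUS: {exc}") from exc
    return Phylogeny.from_dendropy(dtree)


def is_ultrametric(tree: Phylogeny, rel_tol: float = 1e-6) -> bool:
    """True iff all root-to-tip path lengths agree within ``rel_tol`` of their mean."""
    d = tree.tip_depths()
    mean = d.mean()
    if mean == 0:
        return True
    return bool(np.max(np.abs(d - mean)) <= rel_tol * mean)


def validate_trait_table(traits: pd.DataFrame) -> pd.DataFrame:
    """Check trait-table invariants: one row per species, positive finite numerics."""
    if "species" not in traits.columns:
        raise ValueError("trait table must have a 'species' column")
    if traits["species"].duplicated().any():
        dup = traits.loc[traits["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species rows: {dup}")
    numeric = [c for c in ("membrane_length", "turns", "mass",
                           "call_min", "call_peak", "call_max")
               if c in traits.columns]
    for col in numeric:
        vals = pd.to_numeric(traits[col], errors="coerce")
        present = vals.notna()
        if (vals[present] <= 0).any():
            raise ValueError(f"column {col!r} must be positive where present")
    if "echolocation_type" in traits.columns:
        bad = set(traits["echolocation_type"].dropna()) - ECHOLOCATION_TYPES
        if bad:
            raise ValueError(f"unknown echolocation_type values: {sorted(bad)}")
    return traits


def read_trait_table(path_or_buffer) -> pd.DataFrame:
    """Read a trait CSV (documented header, see :data:`TRAIT_COLUMNS`)."""
    df = pd.read_csv(path_or_buffer)
    validate_trait_table(df)
    logger.info("read_trait_table: %d species", len(df))
    return df


def prune_and_match(tree: Phylogeny, traits: pd.DataFrame):
    """Reduce tree and trait table to their shared species.

    Returns ``(pruned_tree, matched_traits)`` with trait rows reordered to the
    pruned tree's tip order.  Species present on only one side are dropped
    with a warning; an empty intersection raises :class:`NoOverlapError`.
    """
    validate_trait_table(traits)
    tips = set(tree.labels)
    species = set(traits["species"])
    shared = tips & species
    if not shared:
        raise NoOverlapError(tree.labels, traits["species"].tolist())
    drop_tips = tips - shared
    drop_rows = species - shared
    if drop_tips:
        warnings.warn(f"dropping {len(drop_tips)} tree tips without trait data: "
                      f"{sorted(drop_tips)}", stacklevel=2)
    if drop_rows:
        warnings.warn(f"dropping {len(drop_rows)} trait rows absent from tree: "
                      f"{sorted(drop_rows)}", stacklevel=2)
    pruned = tree.prune_to(shared)
    matched = (
        traits.set_index("species").loc[pruned.labels].reset_index()
    )
    logger.info("prune_and_match: %d shared species", len(shared))
    return pruned, matched
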
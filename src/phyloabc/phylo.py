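"""Phylogenies: Newick I/O, tree generation, scaling, traversal, covariance.

Trees are stored in a flat, preorder-indexed array form (node 0 is the root,
every parent index precedes its children) which makes the per-edge trait
simulation and the linear-algebra statistics cheap and deterministic.
dendropy is used behind the scenes for Newick parsing and for birth-death
simulation; the array form is the in-memory contract for the rest of the
package.
"""

from __future__ import annotations

import math
import random as _random
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCov",
    "TreeFormatError",
    "DegenerateTreeError",
    "read_newick",
    "write_newick",
    "scale_to_unit_height",
    "phylo_cov",
    "balanced_tree",
    "birth_death_tree",
    "preorder_edges",
]


class TreeFormatError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


class DegenerateTreeError(ValueError):
    """Raised for structurally valid but unusable trees (e.g. zero height)."""


@dataclass
class Phylogeny:
    """Rooted phylogeny with strictly positive branch lengths.

    Attributes
    ----------
    parent : (n_nodes,) int array; ``parent[0] == -1`` for the root and
        ``parent[i] < i`` for every other node (preorder numbering).
    edge_length : (n_nodes,) float array; length of the branch subtending
        each node, ``nan`` for the root.
    tip_ids : int array of node indices that are leaves, in preorder.
    tip_labels : list of unique leaf labels aligned with ``tip_ids``.
    """

    parent: np.ndarray
    edge_length: np.ndarray
    tip_ids: np.ndarray
    tip_labels: list[str]
    _children: list[list[int]] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.edge_length = np.asarray(self.edge_length, dtype=float)
        self.tip_ids = np.asarray(self.tip_ids, dtype=int)
        self._validate()

    # ------------------------------------------------------------------
    # structure
    # ------------------------------------------------------------------
    def _validate(self):
        n = self.parent.size
        if n == 0 or self.parent[0] != -1:
            raise TreeFormatError("node 0 must be the root (parent -1)")
        if np.sum(self.parent == -1) != 1:
            raise TreeFormatError("exactly one root is required")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise TreeFormatError("nodes must be numbered in preorder")
        lens = self.edge_length[1:]
        if not np.all(np.isfinite(lens)) or np.any(lens <= 0):
            raise TreeFormatError("all branch lengths must be strictly positive and finite")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise TreeFormatError("tip labels must be unique")
        if len(self.tip_labels) != self.tip_ids.size:
            raise TreeFormatError("tip_labels and tip_ids must align")

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return self.tip_ids.size

    @property
    def root(self) -> int:
        return 0

    def children(self) -> list[list[int]]:
        if self._children is None:
            ch = [[] for _ in range(self.n_nodes)]
            for i in range(1, self.n_nodes):
                ch[self.parent[i]].append(i)
            self._children = ch
        return self._children

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children())

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths (time units)."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.edge_length[i]
        return d

    @property
    def height(self) -> float:
        return float(self.depths()[self.tip_ids].max())

    def is_ultrametric(self, rtol: float = 1e-8) -> bool:
        td = self.depths()[self.tip_ids]
        return bool(np.allclose(td, td.max(), rtol=rtol, atol=0))

    def postorder_nodes(self) -> np.ndarray:
        """Node indices with every child before its parent."""
        return np.arange(self.n_nodes)[::-1]

    # ------------------------------------------------------------------
    # conversion
    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        length = np.full(len(nodes), np.nan)
        tip_ids, tip_labels = [], []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise TreeFormatError("every branch must carry a length")
                length[i] = nd.edge.length
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon is not None else nd.label
                if label is None:
                    raise TreeFormatError("unlabelled tip")
                tip_ids.append(i)
                tip_labels.append(str(label))
        return cls(parent, length, np.array(tip_ids), tip_labels)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace(self.tip_labels)
        tree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        tree.seed_node = dnodes[0]
        label_of = dict(zip(self.tip_ids.tolist(), self.tip_labels))
        for i in range(1, self.n_nodes):
            dnodes[self.parent[i]].add_child(dnodes[i])
            dnodes[i].edge.length = float(self.edge_length[i])
        for i, nd in enumerate(dnodes):
            if i in label_of:
                nd.taxon = taxa.get_taxon(label_of[i])
        return tree

    def to_newick(self) -> str:
        label_of = dict(zip(self.tip_ids.tolist(), self.tip_labels))
        ch = self.children()

        def rec(i: int) -> str:
            if not ch[i]:
                core = label_of[i]
            else:
                core = "(" + ",".join(rec(c) for c in ch[i]) + ")"
            if i == 0:
                return core
            return f"{core}:{self.edge_length[i]:.12g}"

        return rec(0) + ";"

    def with_edge_lengths(self, new_lengths: np.ndarray) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), np.asarray(new_lengths, float),
                         self.tip_ids.copy(), list(self.tip_labels))


@dataclass
class PhyloCov:
    """Phylogenetic covariance: shared root-path lengths between tips."""

    matrix: np.ndarray
    tip_labels: list[str]


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths mandatory, tip labels unique)."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeFormatError(f"could not parse Newick input: {exc}") from exc
    phylo = Phylogeny.from_dendropy(tree)
    if phylo.n_tips < 2:
        raise TreeFormatError("tree must have at least two tips")
    return phylo


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ----------------------------------------------------------------------
# scaling, covariance, traversal
# ----------------------------------------------------------------------

def scale_to_unit_height(tree: Phylogeny) -> Phylogeny:
    """Divide all branch lengths by the maximum root-to-tip depth."""
    h = tree.height
    if not math.isfinite(h) or h <= 0:
        raise DegenerateTreeError("tree height must be positive to rescale")
    return tree.with_edge_lengths(tree.edge_length / h)


def phylo_cov(tree: Phylogeny) -> PhyloCov:
    """C[i, j] = shared root-path length of tips i and j; C[i, i] = tip depth."""
    n = tree.n_tips
    tip_pos = {int(t): k for k, t in enumerate(tree.tip_ids)}
    # tips under each node, accumulated in postorder
    under = [[] for _ in range(tree.n_nodes)]
    for i in tree.postorder_nodes():
        i = int(i)
        if i in tip_pos:
            under[i].append(tip_pos[i])
        if tree.parent[i] >= 0:
            under[tree.parent[i]].extend(under[i])
    C = np.zeros((n, n))
    for i in range(1, tree.n_nodes):
        idx = np.array(under[i], dtype=int)
        C[np.ix_(idx, idx)] += tree.edge_length[i]
    return PhyloCov(C, list(tree.tip_labels))


def preorder_edges(tree: Phylogeny) -> list[tuple[int, int, float]]:
    """Edges as (parent, child, length), every parent preceding its children."""
    return [(int(tree.parent[i]), i, float(tree.edge_length[i]))
            for i in range(1, tree.n_nodes)]


# ----------------------------------------------------------------------
# tree generation
# ----------------------------------------------------------------------

def balanced_tree(n_tips: int, branch_style: str = "grafen") -> Phylogeny:
    """Fully balanced binary tree on ``n_tips`` (a power of two), height 1.

    ``grafen`` assigns each node the height (clade tip count - 1)/(n - 1)
    (Grafen 1989 with rho = 1), so deeper splits subtend longer branches;
    ``equal`` makes every branch 1/log2(n_tips).
    """
    if n_tips < 2 or (n_tips & (n_tips - 1)) != 0:
        raise ValueError("n_tips must be a power of two >= 2")
    if branch_style not in ("grafen", "equal"):
        raise ValueError(f"unknown branch_style {branch_style!r}")
    levels = int(math.log2(n_tips))

    def node_height(clade_size: int, level: int) -> float:
        if branch_style == "grafen":
            return (clade_size - 1) / (n_tips - 1)
        return (levels - level) / levels

    parent, length, tip_ids, tip_labels = [-1], [np.nan], [], []
    counter = iter(range(1, n_tips + 1))

    def build(par: int, clade: int, level: int, par_height: float):
        for _ in range(2):
            i = len(parent)
            parent.append(par)
            h = node_height(clade // 2, level + 1)
            length.append(par_height - h)
            if clade // 2 == 1:
                tip_ids.append(i)
                tip_labels.append(f"t{next(counter)}")
            else:
                build(i, clade // 2, level + 1, h)

    build(0, n_tips, 0, node_height(n_tips, 0))
    return Phylogeny(np.array(parent), np.array(length), np.array(tip_ids), tip_labels)


def birth_death_tree(n_tips: int, birth_rate: float, death_rate: float,
                     age: float, tip_sampling_prob: float, seed: int,
                     max_retries: int = 1000) -> Phylogeny:
    """Birth-death tree with incomplete taxon sampling, exactly ``n_tips`` tips.

    The process is grown (dendropy) until ceil(n_tips / tip_sampling_prob)
    lineages are extant, extinct lineages are pruned, and exactly ``n_tips``
    of the extant tips are retained uniformly at random -- i.e. rho-sampling
    conditioned on the sampled tip count.  The nominal ``age`` is recorded
    only through the realized branch lengths; the downstream models rescale
    every tree to unit height, so only the shape matters.
    """
    if not (birth_rate > death_rate >= 0):
        raise ValueError("require birth_rate > death_rate >= 0")
    if not (0 < tip_sampling_prob <= 1):
        raise ValueError("tip_sampling_prob must be in (0, 1]")
    if age <= 0:
        raise ValueError("age must be positive")
    from dendropy.model import birthdeath as _bd

    target = max(n_tips, int(math.ceil(n_tips / tip_sampling_prob)))
    rng = _random.Random(int(seed))
    last_exc = None
    for _ in range(max_retries):
        try:
            dtree = _bd.birth_death_tree(
                birth_rate=birth_rate, death_rate=death_rate,
                num_extant_tips=target, rng=rng,
            )
        except Exception as exc:  # total extinction; retry
            last_exc = exc
            continue
        leaves = [lf for lf in dtree.leaf_node_iter()]
        if len(leaves) < n_tips:
            continue
        keep = rng.sample([lf.taxon for lf in leaves], n_tips)
        dtree.retain_taxa(keep)
        dtree.suppress_unifurcations()
        for k, lf in enumerate(dtree.leaf_node_iter(), start=1):
            lf.taxon.label = f"t{k}"
        # collapse zero-length branches that dendropy can emit at the root
        for nd in dtree.preorder_node_iter():
            if nd.parent_node is not None and (nd.edge.length is None or nd.edge.length <= 0):
                nd.edge.length = 1e-9
        phylo = Phylogeny.from_dendropy(dtree)
        if phylo.n_tips == n_tips:
            return phylo
    raise RuntimeError(
        f"birth-death simulation failed after {max_retries} retries: {last_exc}")
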
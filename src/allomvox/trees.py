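"""Phylogeny input/output and manipulation.

Thin, validated wrapper around :mod:`dendropy` trees providing exactly the
operations the allometry pipeline needs: Newick round-tripping, a
consensus-edge tree (majority-rule topology with per-clade mean branch
lengths), pruning to the analysis taxon set, and the distance/depth queries
that the phylogenetic covariance structures are built from.

All branch lengths are required (covariance models are undefined without
them) and must be non-negative; tip labels must be unique.  Species-name
matching elsewhere in the package goes through :func:`normalize_name`,
which treats underscores and spaces as equivalent.
"""

from __future__ import annotations

import copy
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "parse_newick",
    "read_newick",
    "write_newick",
    "consensus_edge_tree",
    "prune_to_taxa",
    "normalize_name",
]


def normalize_name(name: str) -> str:
    """Normalize a species name for matching: spaces become underscores."""
    return name.strip().replace(" ", "_")


class Phylogeny:
    """A rooted phylogeny with named tips and branch lengths.

    Parameters
    ----------
    tree : dendropy.Tree
        Tree to wrap.  Validated on construction: unique tip labels and a
        non-negative branch length on every non-root edge.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self._tree = tree
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        trees = parse_newick(text)
        if len(trees) != 1:
            raise ValueError(f"expected exactly one tree, found {len(trees)}")
        return trees[0]

    def _validate(self) -> None:
        labels = [leaf.taxon.label if leaf.taxon else None
                  for leaf in self._tree.leaf_node_iter()]
        if any(lab is None for lab in labels):
            raise ValueError("every tip must be named")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip names: {dupes}")
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is self._tree.seed_node:
                continue  # root edge may be absent
            if edge.length is None:
                raise ValueError(
                    "missing branch length on edge above "
                    f"{_node_label(edge.head_node)!r}; covariance models "
                    "require branch lengths on every edge"
                )
            if edge.length < 0:
                raise ValueError(
                    f"negative branch length {edge.length} above "
                    f"{_node_label(edge.head_node)!r}"
                )

    # -- basic queries -----------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        """The underlying dendropy tree (treat as read-only)."""
        return self._tree

    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip (root edge, if any, excluded)."""
        out: dict[str, float] = {}
        dist = {self._tree.seed_node: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            dist[node] = dist[node.parent_node] + node.edge.length
            if node.is_leaf():
                out[node.taxon.label] = dist[node]
        if self.n_tips == 1:  # degenerate single-tip tree
            leaf = next(self._tree.leaf_node_iter())
            out.setdefault(leaf.taxon.label, 0.0)
        return out

    def max_depth(self) -> float:
        return max(self.depths().values())

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = list(self.depths().values())
        return (max(d) - min(d)) <= tol

    def patristic_matrix(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Pairwise tip-to-tip path-length matrix in ``order`` (default: tips)."""
        names = list(order) if order is not None else self.tips
        idx = {n: i for i, n in enumerate(names)}
        missing = [n for n in names if n not in set(self.tips)]
        if missing:
            raise KeyError(f"names not in tree: {missing}")
        n = len(names)
        D = np.zeros((n, n))
        depths, mrca_depth = self._mrca_depths(names)
        for i in range(n):
            for j in range(i + 1, n):
                d = depths[i] + depths[j] - 2.0 * mrca_depth[i, j]
                D[i, j] = D[j, i] = d
        return D

    def _mrca_depths(self, order: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Per-tip root distances and the matrix of MRCA root distances.

        Single post-order pass: pairs of tips first united at a node have
        that node as their MRCA.
        """
        idx = {n: i for i, n in enumerate(order)}
        n = len(order)
        node_dist = {self._tree.seed_node: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is not self._tree.seed_node:
                node_dist[node] = node_dist[node.parent_node] + node.edge.length
        depths = np.zeros(n)
        M = np.zeros((n, n))
        below: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                if node.taxon.label in idx:
                    i = idx[node.taxon.label]
                    depths[i] = node_dist[node]
                    M[i, i] = node_dist[node]
                    below[node] = [i]
                else:
                    below[node] = []
            else:
                groups = [below.pop(ch) for ch in node.child_nodes()]
                merged: list[int] = []
                for gi, g in enumerate(groups):
                    for h in groups[gi + 1:]:
                        for a in g:
                            for b in h:
                                M[a, b] = M[b, a] = node_dist[node]
                    merged.extend(g)
                below[node] = merged
        return depths, M

    def clade_tip_sets(self) -> dict[frozenset, float]:
        """Map each clade (frozenset of tip labels) to its subtending edge length.

        The root clade (all tips) maps to the root edge length, or 0.0 if
        absent.  Used by the consensus-edge construction.
        """
        out: dict[frozenset, float] = {}
        below: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                tips = frozenset([node.taxon.label])
            else:
                tips = frozenset().union(*(below.pop(c) for c in node.child_nodes()))
            below[node] = tips
            length = node.edge.length if node is not self._tree.seed_node else (
                node.edge.length or 0.0)
            out[tips] = float(length)
        return out

    # -- transformations ---------------------------------------------------

    def prune(self, keep: Iterable[str]) -> "Phylogeny":
        return prune_to_taxa(self, keep)

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Phylogeny with {self.n_tips} tips>"


def _node_label(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return f"internal node ({sum(1 for _ in node.leaf_iter())} tips)"


def parse_newick(text: str) -> list[Phylogeny]:
    """Parse one or more Newick trees from a string.

    Underscores in unquoted labels are preserved verbatim.  Raises
    ``ValueError`` (with the parser's position information) on malformed
    input, and on any missing branch length.
    """
    if not text.strip():
        raise ValueError("empty Newick input")
    try:
        tl = dendropy.TreeList.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick: {exc}") from exc
    if len(tl) == 0:
        raise ValueError("no trees found in Newick input")
    return [Phylogeny(t) for t in tl]


def read_newick(path) -> list[Phylogeny]:
    """Read one or more Newick trees from a file path."""
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: Phylogeny, path=None) -> str:
    """Serialize to Newick (with branch lengths); optionally write to ``path``."""
    s = tree.tree.as_string(
        schema="newick", unquoted_underscores=True,
        suppress_rooting=True,
    ).strip()
    if not s.endswith(";"):
        s += ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def prune_to_taxa(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Induced subtree on ``keep``; patristic distances among kept tips
    are preserved exactly (suppressed degree-2 nodes merge edge lengths)."""
    keep = list(keep)
    norm_keep = {normalize_name(k) for k in keep}
    if len(norm_keep) != len(keep):
        raise ValueError("duplicate names in keep set")
    by_norm = {normalize_name(t): t for t in tree.tips}
    missing = sorted(k for k in norm_keep if k not in by_norm)
    if missing:
        raise KeyError(f"names not in tree: {missing}")
    labels = {by_norm[k] for k in norm_keep}
    # full deep copy (own taxon namespace): pruning must never touch the
    # input tree or a namespace shared with it
    clone = copy.deepcopy(tree.tree)
    clone.retain_taxa_with_labels(labels)
    clone.purge_taxon_namespace()
    return Phylogeny(clone)


def consensus_edge_tree(trees: Sequence[Phylogeny]) -> Phylogeny:
    """Majority-rule consensus with mean edge lengths.

    The consensus topology keeps every clade present in more than half of
    the input trees (trivial clades — single tips and the full tip set —
    always qualify).  Each retained clade's subtending edge length is the
    arithmetic mean of that edge's length over the input trees that contain
    the clade.  For identical input topologies this reduces to edge-wise
    averaging of a shared tree.
    """
    if len(trees) == 0:
        raise ValueError("need at least one tree")
    tipset = frozenset(trees[0].tips)
    for k, t in enumerate(trees[1:], start=2):
        if frozenset(t.tips) != tipset:
            raise ValueError(
                f"tree {k} has a different tip set than tree 1: "
                f"{sorted(frozenset(t.tips) ^ tipset)}"
            )
    n_trees = len(trees)
    counts: dict[frozenset, int] = {}
    length_sums: dict[frozenset, float] = {}
    for t in trees:
        for clade, length in t.clade_tip_sets().items():
            counts[clade] = counts.get(clade, 0) + 1
            length_sums[clade] = length_sums.get(clade, 0.0) + length
    majority = [
        c for c, k in counts.items()
        if k * 2 > n_trees or len(c) == 1 or c == tipset
    ]
    # build the (laminar) clade hierarchy, largest first
    majority.sort(key=len, reverse=True)
    taxon_ns = dendropy.TaxonNamespace()
    nodes: dict[frozenset, dendropy.Node] = {}
    parent_of: dict[frozenset, frozenset] = {}
    placed: list[frozenset] = []
    for clade in majority:
        node = dendropy.Node()
        node.edge.length = length_sums[clade] / counts[clade]
        if len(clade) == 1:
            (label,) = clade
            node.taxon = taxon_ns.require_taxon(label=label)
        nodes[clade] = node
        if clade != tipset:
            # smallest already-placed strict superset is the parent
            parent = min(
                (p for p in placed if clade < p), key=len, default=tipset
            )
            parent_of[clade] = parent
        placed.append(clade)
    for clade, parent in parent_of.items():
        nodes[parent].add_child(nodes[clade])
    out = dendropy.Tree(taxon_namespace=taxon_ns)
    out.seed_node = nodes[tipset]
    out.is_rooted = True
    return Phylogeny(out)
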
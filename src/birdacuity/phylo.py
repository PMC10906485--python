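"""Rooted phylogenies and the Brownian phylogenetic covariance matrix.

A trait evolving by Brownian motion along a rooted tree induces, at the
tips, a multivariate normal distribution whose covariance matrix ``C`` has
``C[i, j]`` equal to the branch length shared by the root-to-tip paths of
tips *i* and *j* (and ``C[i, i]`` equal to the depth of tip *i*).  That
matrix is the error structure used by every phylogenetic regression in
this package.  Pagel's lambda rescales its off-diagonal entries.

Newick I/O and tree surgery are delegated to :mod:`dendropy`; this module
adds validation, label normalization, depth bookkeeping and the shared-path
covariance computation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "PhyloCovariance",
    "TreeError",
    "NewickParseError",
    "normalize_label",
    "parse_newick",
    "prune",
    "vcv",
    "lambda_transform",
]


class TreeError(ValueError):
    """Invalid tree structure or tree operation."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


def normalize_label(label: str) -> str:
    """Canonicalize a taxon label: strip, spaces -> underscores.

    Spaces and underscores are interchangeable across Newick dialects
    (quoted vs. unquoted labels); matching stays case-sensitive.
    """
    return label.strip().replace(" ", "_")


@dataclass
class Tree:
    """A rooted phylogeny with branch lengths, backed by a dendropy tree.

    Branch lengths are non-negative and in arbitrary time-proportional
    units.  Tip labels are unique after whitespace/underscore
    normalization.  Non-ultrametric trees and polytomies are accepted;
    zero-length branches are allowed (near-singular covariance matrices
    are caught at fit time, not here).
    """

    _dtree: dendropy.Tree

    def __post_init__(self) -> None:
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        for leaf in self._dtree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeError("unlabelled tip in tree")
            label = normalize_label(leaf.taxon.label)
            if label in seen:
                raise NewickParseError(f"duplicate tip label: {label!r}")
            seen.add(label)
            leaf.taxon.label = label
            if leaf.edge.length is None:
                raise NewickParseError(f"tip {label!r} has no branch length")
        if len(seen) < 2:
            raise TreeError("tree must have at least 2 tips")
        for edge in self._dtree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                head = edge.head_node
                name = head.taxon.label if head.taxon else "<internal>"
                raise NewickParseError(
                    f"negative branch length {edge.length} on edge to {name!r}"
                )
        for label, depth in self.depths().items():
            if depth <= 0:
                raise TreeError(f"root-to-tip path length for {label!r} is not > 0")

    # -- basic queries ----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in stable tree-traversal order."""
        return [lf.taxon.label for lf in self._dtree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._dtree.leaf_nodes())

    def _node_depths(self) -> dict:
        """Depth of every node measured from the origin above the root edge."""
        depths: dict = {}
        for node in self._dtree.preorder_node_iter():
            edge_len = node.edge.length or 0.0
            if node.parent_node is None:
                depths[node] = edge_len
            else:
                depths[node] = depths[node.parent_node] + edge_len
        return depths

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        nd = self._node_depths()
        return {lf.taxon.label: nd[lf] for lf in self._dtree.leaf_node_iter()}

    def tip_distances(self) -> "np.ndarray":
        """Pairwise patristic (tip-to-tip path) distances, tip order."""
        C = self.vcv().matrix
        d = np.diag(C)
        return d[:, None] + d[None, :] - 2.0 * C

    # -- operations -------------------------------------------------------

    def prune(self, keep) -> "Tree":
        """Restrict the tree to a subset of tips.

        Degree-2 nodes created by the removal are collapsed with their
        branch lengths summed, so every pairwise tip-to-tip path length —
        and every root-to-tip depth — is preserved exactly.
        """
        wanted = {normalize_label(k) for k in keep}
        have = set(self.tip_labels)
        missing = sorted(wanted - have)
        if missing:
            raise TreeError(f"labels not in tree: {missing}")
        if len(wanted) < 2:
            raise TreeError("prune requires at least 2 tips to keep")
        old_depths = self.depths()
        dt = self._dtree.clone(depth=1)
        dt.retain_taxa_with_labels(sorted(wanted))
        pruned = Tree.__new__(Tree)
        pruned._dtree = dt
        # Root unifurcation suppression can silently drop path length shared
        # by all kept tips; restore it on the seed edge so depths (and hence
        # the covariance matrix) match the parent tree exactly.
        any_tip = next(iter(wanted))
        delta = old_depths[any_tip] - pruned.depths()[any_tip]
        if abs(delta) > 1e-12:
            seed = dt.seed_node
            seed.edge.length = (seed.edge.length or 0.0) + delta
        pruned._validate()
        return pruned

    def vcv(self) -> "PhyloCovariance":
        """Brownian-motion covariance matrix of the tips.

        ``C[i, j]`` is the depth of the most recent common ancestor of
        tips i and j, i.e. the branch length their root-to-tip paths
        share; ``C[i, i]`` is the depth of tip i.
        """
        labels = self.tip_labels
        if len(labels) < 2:
            raise TreeError("vcv requires at least 2 tips")
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        C = np.zeros((n, n))
        node_depth = self._node_depths()
        tips_below: dict = {}
        for node in self._dtree.postorder_node_iter():
            if node.is_leaf():
                i = idx[node.taxon.label]
                tips_below[node] = [i]
                C[i, i] = node_depth[node]
                continue
            child_sets = [tips_below.pop(ch) for ch in node.child_nodes()]
            d = node_depth[node]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    block = np.ix_(child_sets[a], child_sets[b])
                    C[block] = d
                    C[block[1], block[0]] = d
            merged = [i for s in child_sets for i in s]
            tips_below[node] = merged
        return PhyloCovariance(taxa=labels, matrix=C, lambda_applied=None)

    def to_newick(self) -> str:
        s = self._dtree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
        return s.strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree(n_tips={self.n_tips})"


@dataclass
class PhyloCovariance:
    """Taxon-ordered Brownian covariance matrix, optionally lambda-scaled."""

    taxa: list[str]
    matrix: np.ndarray
    lambda_applied: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match number of taxa")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def lambda_transform(self, lam: float) -> "PhyloCovariance":
        """Scale off-diagonal entries by ``lam`` in [0, 1]; diagonal kept.

        lam = 1 leaves the Brownian structure intact; lam = 0 removes all
        cross-taxon covariance (star-tree / independence limit).
        """
        if not (0.0 <= lam <= 1.0):
            raise ValueError(f"lambda must be in [0, 1], got {lam}")
        d = np.diag(self.matrix).copy()
        M = self.matrix * lam
        np.fill_diagonal(M, d)
        return PhyloCovariance(taxa=list(self.taxa), matrix=M, lambda_applied=lam)

    def subset(self, labels) -> "PhyloCovariance":
        """Rows/columns restricted to ``labels``, in the given order."""
        want = [normalize_label(x) for x in labels]
        pos = {t: i for i, t in enumerate(self.taxa)}
        missing = [w for w in want if w not in pos]
        if missing:
            raise ValueError(f"taxa not in covariance: {missing}")
        ii = [pos[w] for w in want]
        return PhyloCovariance(
            taxa=want,
            matrix=self.matrix[np.ix_(ii, ii)],
            lambda_applied=self.lambda_applied,
        )

    reorder = subset

    def is_star(self, tol: float = 1e-12) -> bool:
        off = self.matrix - np.diag(np.diag(self.matrix))
        return bool(np.all(np.abs(off) <= tol))


def parse_newick(text: str) -> Tree:
    """Parse a single rooted Newick statement (must end with ';')."""
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError("Newick statement must be terminated by ';'")
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    return Tree(dtree)


def prune(tree: Tree, keep) -> Tree:
    return tree.prune(keep)


def vcv(tree: Tree) -> PhyloCovariance:
    return tree.vcv()


def lambda_transform(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    return C.lambda_transform(lam)
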
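"""Dated ultrametric trees and pairwise phylogenetic distances.

Phylogenetic distance (PD) between two host genera is the time of
independent evolution in millions of years (My): the sum of branch lengths
along the path between the two tips, which on a dated ultrametric tree
equals twice the age of their most recent common ancestor.

Distances are computed as path sums, so trees that are only approximately
ultrametric (rounded node ages in published supertrees) are handled
gracefully; the 2 x MRCA-age identity is a property of exact ultrametric
trees, not an implementation assumption.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from phylopest.errors import TreeValidationError

__all__ = [
    "PhyloTree",
    "DistanceMatrix",
    "read_tree",
    "read_tree_string",
    "prune_to_taxa",
    "pairwise_distances",
]

#: Default relative ultrametricity tolerance (fraction of root depth).
DEFAULT_ULTRAMETRIC_TOL = 1e-3


@dataclass
class PhyloTree:
    """A validated, rooted, dated tree over host genera.

    Parameters
    ----------
    tree :
        Underlying dendropy tree. Branch lengths are in My. Unifurcations
        are collapsed during validation; polytomies are allowed.
    root_depth :
        Mean root-to-tip path length (My); for an exactly ultrametric tree
        this is the root age.
    max_deviation :
        Largest absolute deviation of any root-to-tip path from
        ``root_depth`` (My), recorded at validation time.
    """

    tree: dendropy.Tree
    root_depth: float
    max_deviation: float = 0.0

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")


@dataclass
class DistanceMatrix:
    """Symmetric genus x genus matrix of phylogenetic distances (My)."""

    genera: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self._index = {g: i for i, g in enumerate(self.genera)}
        if self.values.shape != (len(self.genera), len(self.genera)):
            raise ValueError("distance matrix shape does not match genus list")

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def indices(self, genera) -> np.ndarray:
        missing = [g for g in genera if g not in self._index]
        if missing:
            raise KeyError(f"genera absent from distance matrix: {missing}")
        return np.array([self._index[g] for g in genera], dtype=int)

    def subset(self, genera) -> "DistanceMatrix":
        idx = self.indices(genera)
        return DistanceMatrix(list(genera), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genera, columns=self.genera)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="genus")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("distance CSV must have identical row and column genera")
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def to_phylip(self, path) -> None:
        """Write in PHYLIP square-matrix format (names truncated to 10 chars)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.genera)}\n")
            for g, row in zip(self.genera, self.values):
                fh.write(f"{g[:10]:<10} " + " ".join(f"{v:.6f}" for v in row) + "\n")

    def validate(self, tol: float = 1e-8) -> None:
        """Check symmetry, zero diagonal, and positive off-diagonal entries."""
        v = self.values
        if not np.allclose(v, v.T, atol=tol):
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > tol:
            raise ValueError("distance matrix diagonal is not zero")
        off = v[~np.eye(len(self.genera), dtype=bool)]
        if off.size and off.min() <= 0:
            raise ValueError("off-diagonal phylogenetic distances must be positive")


def _validate(
    tree: dendropy.Tree,
    tol: float,
    on_violation: str,
    require_positive_terminals: bool = True,
) -> PhyloTree:
    tree.suppress_unifurcations()

    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise TreeValidationError("tree must have at least 2 tips")

    labels = []
    for leaf in leaves:
        if leaf.taxon is None or not (leaf.taxon.label or "").strip():
            raise TreeValidationError("every tip must carry a non-empty genus label")
        labels.append(leaf.taxon.label)
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise TreeValidationError(f"duplicate tip labels: {dupes}")

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            raise TreeValidationError(
                f"missing branch length above {'tip ' + node.taxon.label if node.is_leaf() else 'an internal node'}"
            )
        if node.edge.length < 0:
            raise TreeValidationError("negative branch length")
        if require_positive_terminals and node.is_leaf() and node.edge.length <= 0:
            raise TreeValidationError(
                f"zero-length terminal branch at tip {node.taxon.label}: "
                "distinct genera would be at distance 0"
            )

    depths = _tip_depths(tree)
    root_depth = float(np.mean(list(depths.values())))
    if root_depth <= 0:
        raise TreeValidationError("root depth must be positive")
    max_dev = float(max(abs(d - root_depth) for d in depths.values()))
    if max_dev > tol * root_depth:
        msg = (
            f"tree is not ultrametric within tolerance: max root-to-tip deviation "
            f"{max_dev:.6g} My exceeds {tol:g} x root depth {root_depth:.6g} My"
        )
        if on_violation == "error":
            raise TreeValidationError(msg)
        warnings.warn(msg, stacklevel=3)
    return PhyloTree(tree=tree, root_depth=root_depth, max_deviation=max_dev)


def _tip_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        # a root (stem) edge can remain after pruning; counting it keeps
        # root-to-tip depths of retained tips unchanged
        edge = node.edge.length if node.edge is not None else 0.0
        node._depth = (node.parent_node._depth if node.parent_node else 0.0) + (edge or 0.0)
        if node.is_leaf():
            depths[node.taxon.label] = node._depth
    return depths


def read_tree(
    path,
    tol: float = DEFAULT_ULTRAMETRIC_TOL,
    on_violation: str = "error",
) -> PhyloTree:
    """Read and validate a single dated tree from a newick file.

    Parameters
    ----------
    path :
        Newick file with one rooted tree; branch lengths (My) required;
        quoted labels supported.
    tol :
        Relative ultrametricity tolerance as a fraction of root depth.
        Published supertrees carry rounded node ages, so the default allows
        0.1% wobble.
    on_violation :
        ``"error"`` (default) or ``"warn"`` when the tree exceeds ``tol``.
    """
    if on_violation not in ("error", "warn"):
        raise ValueError("on_violation must be 'error' or 'warn'")
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise TreeValidationError(f"could not parse newick file {path}: {exc}") from exc
    return _validate(tree, tol, on_violation)


def read_tree_string(
    newick: str,
    tol: float = DEFAULT_ULTRAMETRIC_TOL,
    on_violation: str = "error",
) -> PhyloTree:
    """Parse and validate a tree from a newick string (see :func:`read_tree`)."""
    if on_violation not in ("error", "warn"):
        raise ValueError("on_violation must be 'error' or 'warn'")
    try:
        tree = dendropy.Tree.get(
            file=io.StringIO(newick), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise TreeValidationError(f"could not parse newick string: {exc}") from exc
    return _validate(tree, tol, on_violation)


def prune_to_taxa(ptree: PhyloTree, taxa) -> PhyloTree:
    """Restrict a tree to a subset of tips.

    Degree-1 internal nodes left by pruning are collapsed with their branch
    lengths summed, so root-to-tip depths — and hence all pairwise distances
    among retained tips — are unchanged.
    """
    taxa = set(taxa)
    tips = set(ptree.tip_labels)
    missing = sorted(taxa - tips)
    if missing:
        raise TreeValidationError(f"taxa not in tree: {missing}")
    if len(taxa) < 2:
        raise TreeValidationError("need at least 2 taxa to prune to")
    sub = ptree.tree.extract_tree_with_taxa_labels(labels=taxa)
    # extract_tree gives an independent copy; re-validate with a tolerance
    # consistent with the parent tree's recorded deviation.
    rel = max(DEFAULT_ULTRAMETRIC_TOL, 2.0 * ptree.max_deviation / ptree.root_depth)
    return _validate(sub, rel, "warn")


def pairwise_distances(ptree: PhyloTree) -> DistanceMatrix:
    """Compute the genus x genus matrix of path-sum phylogenetic distances.

    For tips i and j, PD(i, j) = depth(i) + depth(j) - 2 * depth(MRCA(i, j)),
    which is algebraically the sum of branch lengths along the i-to-j path on
    any rooted tree. Tips are ordered as they appear in the tree.
    """
    tree = ptree.tree
    _tip_depths(tree)  # annotates node._depth
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    dist = np.zeros((n, n), dtype=float)

    # Post-order sweep: at each internal node, pairs of tips whose paths
    # join exactly there lie in different child subtrees.
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._tips = [id(node)]
            continue
        child_tip_sets = [child._tips for child in node.child_nodes()]
        for a in range(len(child_tip_sets)):
            for b in range(a + 1, len(child_tip_sets)):
                for ti in child_tip_sets[a]:
                    i = index[ti]
                    di = leaves[i]._depth
                    for tj in child_tip_sets[b]:
                        j = index[tj]
                        d = di + leaves[j]._depth - 2.0 * node._depth
                        dist[i, j] = d
                        dist[j, i] = d
        node._tips = [t for s in child_tip_sets for t in s]

    dm = DistanceMatrix(labels, dist)
    dm.validate()
    return dm
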
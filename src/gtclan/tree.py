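"""Hierarchical trees from distance matrices via distance-geometry embedding.

The algorithm: (1) embed the distance matrix into orthogonal coordinates by
classical double centering (``B = -1/2 · J · D² · J``, eigenvectors scaled by
the square roots of the retained positive eigenvalues); (2) build a rooted
bifurcating tree by repeatedly joining the pair of active nodes at minimal
Euclidean distance, replacing them with their leaf-count-weighted centroid —
the last centroid is the root; (3) starting from the root, re-embed and
rebuild each sufficiently large subtree from its own sub-distance-matrix,
recursively, which suppresses topology artefacts caused by long distances
between unrelated groups.

Non-metric input (the score-derived distances need not be Euclidean) is
handled by dropping negative eigenvalues; their total magnitude is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import DistanceMatrix
from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class EmbeddedPoints:
    ids: list[str]
    coordinates: np.ndarray  # (points, dimensions)
    eigenvalues: np.ndarray  # retained, descending
    dropped_negative_mass: float = 0.0

    def pairwise_distances(self) -> np.ndarray:
        diff = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))


@dataclass
class TreeNode:
    """Rooted bifurcating tree node; leaves carry ids, internal nodes centroids."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    coordinates: np.ndarray | None = None
    leaf_count: int = 1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label or ""]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


def embed(d: DistanceMatrix, tolerance: float = 1e-9, max_dims: int = 20) -> EmbeddedPoints:
    """Classical metric-matrix distance-geometry embedding.

    Keeps eigenvalues above ``tolerance`` times the largest one (capped at
    ``max_dims`` dimensions); an all-coincident input yields a valid
    zero-dimensional embedding.
    """
    n = len(d.ids)
    if n == 1:
        return EmbeddedPoints(list(d.ids), np.zeros((1, 0)), np.array([]))
    sq = d.values**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ sq @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    negative_mass = float(-eigvals[eigvals < 0].sum())
    if negative_mass > tolerance * max(float(eigvals[0]), 1.0):
        logger.info(
            "embedding dropped negative eigenvalue mass %.4g (non-metric input)",
            negative_mass,
        )
    cutoff = tolerance * max(float(eigvals[0]), 0.0)
    keep = np.where(eigvals > cutoff)[0][:max_dims]
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    return EmbeddedPoints(
        ids=list(d.ids),
        coordinates=coords,
        eigenvalues=eigvals[keep],
        dropped_negative_mass=negative_mass,
    )


def nnj_tree(p: EmbeddedPoints) -> TreeNode:
    """Nearest-neighbor joining with centroid averaging in coordinate space.

    Joins the closest active pair (ties broken by the id-sorted lowest pair),
    replaces it by the leaf-count-weighted centroid, and repeats; branch
    lengths are Euclidean child→centroid distances.  The final centroid is
    the root.
    """
    if len(p.ids) < 1:
        raise InputError("cannot build a tree without points")
    active: dict[str, TreeNode] = {}
    for i, name in enumerate(p.ids):
        active[name] = TreeNode(label=name, coordinates=p.coordinates[i], leaf_count=1)
    if len(active) == 1:
        return next(iter(active.values()))
    while len(active) > 1:
        names = sorted(active)
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(names):
            ca = active[a].coordinates
            for b in names[i + 1 :]:
                dist = float(np.linalg.norm(ca - active[b].coordinates))
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        assert best is not None
        _, a, b = best
        na, nb = active.pop(a), active.pop(b)
        wa, wb = na.leaf_count, nb.leaf_count
        centroid = (wa * na.coordinates + wb * nb.coordinates) / (wa + wb)
        node = TreeNode(
            label=None,
            coordinates=centroid,
            leaf_count=wa + wb,
            children=[
                (na, float(np.linalg.norm(na.coordinates - centroid))),
                (nb, float(np.linalg.norm(nb.coordinates - centroid))),
            ],
        )
        active[f"\x00{min(a, b)}"] = node  # internal key; sorts before leaf ids
    return next(iter(active.values()))


def _build_subtree(d: DistanceMatrix, ids: list[str]) -> TreeNode:
    sub = d.submatrix(ids)
    return nnj_tree(embed(sub))


def recursive_refine(tree: TreeNode, d: DistanceMatrix, min_leaves: int = 4) -> TreeNode:
    """Re-embed and rebuild the root's left/right leaf subsets recursively.

    Subtrees with fewer than ``min_leaves`` leaves are kept as-is.  The root
    join between the refined subtrees is recomputed from their leaf centroids
    in the full embedding's coordinate frame.
    """
    leaf_ids = set(tree.leaves())
    if leaf_ids != set(d.ids):
        raise InputError("tree leaves do not match the distance matrix ids")
    full = embed(d)
    coords = {name: full.coordinates[i] for i, name in enumerate(full.ids)}
    return _refine_node(tree, d, coords, min_leaves)


def _refine_node(
    node: TreeNode,
    d: DistanceMatrix,
    coords: dict[str, np.ndarray],
    min_leaves: int,
) -> TreeNode:
    if node.is_leaf or node.leaf_count < 2:
        return node
    refined_children: list[TreeNode] = []
    for child, _ in node.children:
        leaves = child.leaves()
        if len(leaves) >= min_leaves:
            rebuilt = _build_subtree(d, sorted(leaves))
            rebuilt = _refine_node(rebuilt, d, coords, min_leaves)
        else:
            rebuilt = child
        refined_children.append(rebuilt)

    def leaf_centroid(n: TreeNode) -> np.ndarray:
        pts = np.array([coords[name] for name in n.leaves()])
        return pts.mean(axis=0)

    ca, cb = (leaf_centroid(c) for c in refined_children)
    wa, wb = refined_children[0].leaf_count, refined_children[1].leaf_count
    root_pos = (wa * ca + wb * cb) / (wa + wb)
    return TreeNode(
        label=None,
        coordinates=root_pos,
        leaf_count=wa + wb,
        children=[
            (refined_children[0], float(np.linalg.norm(ca - root_pos))),
            (refined_children[1], float(np.linalg.norm(cb - root_pos))),
        ],
    )


_NEWICK_UNSAFE = set("()[]{}:;,'\" \t\n")


def _quote(label: str) -> str:
    if any(ch in _NEWICK_UNSAFE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: TreeNode, precision: int = 6) -> str:
    """Newick rendering with branch lengths and deterministic child order."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _quote(node.label or "")
        ordered = sorted(node.children, key=lambda cl: min(cl[0].leaves()))
        inner = ",".join(
            f"{render(child)}:{length:.{precision}f}" for child, length in ordered
        )
        return f"({inner})"

    return render(tree) + ";"


def aclust(
    d: DistanceMatrix, refine: bool = True, min_leaves: int = 4
) -> TreeNode:
    """Full pipeline: embed, join, and (optionally) recursively refine."""
    tree = nnj_tree(embed(d))
    if refine and len(d.ids) >= 2:
        tree = recursive_refine(tree, d, min_leaves=min_leaves)
    return tree
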
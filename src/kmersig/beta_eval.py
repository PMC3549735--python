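"""Relationship analysis on dissimilarity matrices.

UPGMA clustering to an ultrametric tree, a Fitch small-parsimony group
test with a Monte Carlo permutation p-value, classical-MDS principal
coordinates, and gradient correlation of the first coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .measures import DissimilarityMatrix

__all__ = [
    "TreeNode",
    "ClusterTree",
    "ParsimonyResult",
    "Ordination",
    "upgma",
    "parsimony_score",
    "parsimony_test",
    "pcoa",
    "gradient_pcc",
]


@dataclass
class TreeNode:
    """A node of a rooted binary tree; leaves carry a sample name."""

    height: float = 0.0
    name: str | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.children[0].leaves() + self.children[1].leaves()


@dataclass
class ClusterTree:
    root: TreeNode
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_ids:
            self.sample_ids = [leaf.name for leaf in self.root.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def to_newick(self) -> str:
        def render(node: TreeNode, parent_height: float) -> str:
            branch = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{branch:.10g}"
            left = render(node.children[0], node.height)
            right = render(node.children[1], node.height)
            return f"({left},{right}):{branch:.10g}"

        if self.root.is_leaf:
            return f"{self.root.name};"
        left = render(self.root.children[0], self.root.height)
        right = render(self.root.children[1], self.root.height)
        return f"({left},{right});"

    def cophenetic(self) -> tuple[list[str], np.ndarray]:
        """Ultrametric tree distances (2 * merge height) between all leaves."""
        ids = [leaf.name for leaf in self.root.leaves()]
        pos = {name: i for i, name in enumerate(ids)}
        n = len(ids)
        D = np.zeros((n, n))

        def visit(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.name]
            left = visit(node.children[0])
            right = visit(node.children[1])
            for a in left:
                for b in right:
                    D[pos[a], pos[b]] = D[pos[b], pos[a]] = 2.0 * node.height
            return left + right

        visit(self.root)
        return ids, D


@dataclass
class ParsimonyResult:
    score: int
    p_value: float
    n_permutations: int


@dataclass
class Ordination:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # descending, positive axes only

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            axes = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
            fh.write("\t".join(["sample"] + axes) + "\n")
            for sid, row in zip(self.sample_ids, self.coordinates):
                fh.write(sid + "\t" + "\t".join(f"{x:.12g}" for x in row) + "\n")
            fh.write("#eigenvalues\t" + "\t".join(f"{x:.12g}" for x in self.eigenvalues) + "\n")


def upgma(dm: DissimilarityMatrix | np.ndarray, sample_ids: Sequence[str] | None = None) -> ClusterTree:
    """Average-linkage agglomeration with merge height d/2.

    The inter-cluster distance update is size-weighted (true arithmetic
    mean over all cross pairs).  Ties are broken by the smallest (i, j)
    position pair in the current cluster list, so trees are deterministic.
    """
    if isinstance(dm, DissimilarityMatrix):
        D = dm.D
        ids = list(dm.sample_ids)
    else:
        D = np.asarray(dm, dtype=np.float64)
        ids = list(sample_ids) if sample_ids is not None else [f"S{i + 1}" for i in range(len(D))]
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if D.shape != (n, n):
        raise ValueError("matrix shape does not match sample count")
    if np.isnan(D).any():
        raise ValueError("dissimilarity matrix contains NaN")
    if not np.allclose(D, D.T):
        raise ValueError("dissimilarity matrix is not symmetric")

    work = D.astype(np.float64).copy()
    nodes: list[TreeNode] = [TreeNode(height=0.0, name=name) for name in ids]
    sizes = [1] * n
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                d = work[active[ai], active[aj]]
                if best is None or d < best[0]:
                    best = (d, ai, aj)
        d, ai, aj = best
        i, j = active[ai], active[aj]
        merged = TreeNode(height=d / 2.0, children=(nodes[i], nodes[j]))
        # size-weighted average linkage update, written into slot i
        for other in active:
            if other in (i, j):
                continue
            new_d = (sizes[i] * work[i, other] + sizes[j] * work[j, other]) / (sizes[i] + sizes[j])
            work[i, other] = work[other, i] = new_d
        nodes[i] = merged
        sizes[i] += sizes[j]
        active.pop(aj)
    return ClusterTree(root=nodes[active[0]], sample_ids=ids)


def parsimony_score(tree: ClusterTree, labels: Mapping[str, str]) -> int:
    """Fitch small parsimony: minimum number of label changes on the tree."""
    changes = 0

    def fitch(node: TreeNode) -> frozenset:
        nonlocal changes
        if node.is_leaf:
            if node.name not in labels:
                raise ValueError(f"leaf {node.name!r} has no group label")
            return frozenset([labels[node.name]])
        left = fitch(node.children[0])
        right = fitch(node.children[1])
        inter = left & right
        if inter:
            return inter
        changes += 1
        return left | right

    fitch(tree.root)
    return changes


def parsimony_test(
    tree: ClusterTree,
    labels: Mapping[str, str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    add_one: bool = False,
) -> ParsimonyResult:
    """Permute labels over the leaves of the fixed tree (group sizes
    preserved); p = #(permuted score <= observed) / n_perm, or the
    (r+1)/(n+1) form when ``add_one`` is set."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    leaf_names = [leaf.name for leaf in tree.root.leaves()]
    values = [labels[name] for name in leaf_names]  # raises KeyError early
    observed = parsimony_score(tree, labels)
    hits = 0
    values = np.asarray(values, dtype=object)
    for _ in range(n_perm):
        perm = rng.permutation(len(values))
        permuted = dict(zip(leaf_names, values[perm]))
        if parsimony_score(tree, permuted) <= observed:
            hits += 1
    if add_one:
        p = (hits + 1) / (n_perm + 1)
    else:
        p = hits / n_perm
    return ParsimonyResult(score=observed, p_value=p, n_permutations=n_perm)


def pcoa(dm: DissimilarityMatrix | np.ndarray, sample_ids: Sequence[str] | None = None) -> Ordination:
    """Classical metric MDS: eigendecompose the double-centered squared
    dissimilarities and keep axes with positive eigenvalues."""
    if isinstance(dm, DissimilarityMatrix):
        D = dm.D
        ids = list(dm.sample_ids)
    else:
        D = np.asarray(dm, dtype=np.float64)
        ids = list(sample_ids) if sample_ids is not None else [f"S{i + 1}" for i in range(len(D))]
    n = len(ids)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-12 if vals.size else 0.0
    positive = vals > tol
    if not positive.any():
        raise ValueError("degenerate ordination: no positive eigenvalue")
    vals = vals[positive]
    coords = vecs[:, positive] * np.sqrt(vals)
    return Ordination(sample_ids=ids, coordinates=coords, eigenvalues=vals)


def gradient_pcc(ordination: Ordination, gradient: Sequence[float]) -> float:
    """|Pearson r| between PC1 and the gradient (absolute value absorbs the
    eigenvector sign ambiguity)."""
    grad = np.asarray(gradient, dtype=np.float64)
    pc1 = ordination.coordinates[:, 0]
    if grad.size != pc1.size:
        raise ValueError("gradient length does not match sample count")
    if np.std(pc1) == 0 or np.std(grad) == 0:
        raise ValueError("zero variance in PC1 or gradient")
    return float(abs(np.corrcoef(pc1, grad)[0, 1]))
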
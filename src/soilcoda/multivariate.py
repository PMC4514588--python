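"""Multivariate structure of layer compositions: hierarchical clustering on
Aitchison distances, classical and robust PCA of clr data, and MCD outlier
flagging in ilr coordinates.

Hierarchical clustering works on the matrix of pairwise Aitchison distances
(Euclidean distances of the clr images), agglomeratively (average linkage) and
divisively (the DIANA splinter algorithm: repeatedly split the widest cluster
by peeling off the objects closer to a splinter group than to the rest).

PCA is run on clr-transformed data — covariances of raw closed proportions are
spurious — either from the classical sample covariance or from the minimum
covariance determinant (MCD) scatter.  The MCD estimator needs a full-rank
space, so it is computed on ilr coordinates and mapped back; squared robust
Mahalanobis distances beyond a chi-square quantile flag outlying profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage as _linkage, to_tree as _to_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2
from sklearn.covariance import MinCovDet

from . import coda

__all__ = [
    "TreeNode",
    "Dendrogram",
    "PcaResult",
    "McdFit",
    "distance_matrix",
    "cluster_agglomerative",
    "cluster_divisive",
    "dendrogram_to_newick",
    "pca_clr",
    "mcd_fit",
]


# ---------------------------------------------------------------------------
# clustering


@dataclass(frozen=True)
class TreeNode:
    """Node of an ultrametric cluster tree; ``age`` is half the merge height,
    so the tree distance between two leaves equals their cluster height."""

    age: float
    children: tuple["TreeNode", ...] = ()
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [l for c in self.children for l in c.leaves()]


@dataclass(frozen=True)
class Dendrogram:
    root: TreeNode
    labels: tuple[str, ...]
    method: str  # "agglomerative" | "divisive"


def distance_matrix(A) -> np.ndarray:
    """Symmetric matrix of pairwise Aitchison distances between compositions."""
    Aa = np.atleast_2d(np.asarray(A, dtype=float))
    if Aa.shape[0] < 2:
        raise ValueError("need at least 2 compositions")
    if np.any(Aa <= 0):
        raise ValueError("replace zeros before computing Aitchison distances")
    return squareform(pdist(coda.clr(Aa)))


def _ordered(children: list[TreeNode]) -> tuple[TreeNode, ...]:
    # deterministic child order: lexicographically smallest leaf first
    return tuple(sorted(children, key=lambda c: min(c.leaves())))


def cluster_agglomerative(Dm, labels=None, method: str = "average") -> Dendrogram:
    """Agglomerative hierarchical clustering of a distance matrix.

    Average linkage by default (heights are monotone non-decreasing).
    """
    Dm = np.asarray(Dm, dtype=float)
    n = Dm.shape[0]
    labels = tuple(labels) if labels is not None else tuple(str(i) for i in range(n))
    Z = _linkage(squareform(Dm, checks=False), method=method)
    root, _ = _to_tree(Z, rd=True)

    def build(node) -> TreeNode:
        if node.is_leaf():
            return TreeNode(age=0.0, label=labels[node.id])
        kids = [build(node.get_left()), build(node.get_right())]
        return TreeNode(age=node.dist / 2.0, children=_ordered(kids))

    return Dendrogram(root=build(root), labels=labels, method="agglomerative")


def _diana_split(idx: list[int], D: np.ndarray) -> tuple[list[int], list[int]]:
    """One DIANA division: splinter off the objects that sit closer to the
    emerging splinter group than to the remainder."""
    sub = D[np.ix_(idx, idx)]
    m = len(idx)
    avg_to_rest = sub.sum(axis=1) / (m - 1)
    splinter = [int(np.argmax(avg_to_rest))]
    rest = [i for i in range(m) if i not in splinter]
    while len(rest) > 1:
        gains = []
        for i in rest:
            others = [j for j in rest if j != i]
            a = sub[i, others].mean()
            b = sub[i, splinter].mean()
            gains.append(a - b)
        k = int(np.argmax(gains))
        if gains[k] <= 0:
            break
        splinter.append(rest.pop(k))
    return [idx[i] for i in splinter], [idx[i] for i in rest]


def cluster_divisive(Dm, labels=None) -> Dendrogram:
    """Divisive hierarchical clustering (DIANA) of a distance matrix.

    Each cluster is split by the splinter algorithm; the height of a split is
    the diameter of the cluster being divided, so heights shrink toward the
    leaves.
    """
    Dm = np.asarray(Dm, dtype=float)
    n = Dm.shape[0]
    if n < 2:
        raise ValueError("need at least 2 objects")
    labels = tuple(labels) if labels is not None else tuple(str(i) for i in range(n))

    def build(idx: list[int]) -> TreeNode:
        if len(idx) == 1:
            return TreeNode(age=0.0, label=labels[idx[0]])
        diameter = float(Dm[np.ix_(idx, idx)].max())
        if diameter == 0.0:
            # identical objects: flat comb at height zero
            kids = [TreeNode(age=0.0, label=labels[i]) for i in idx]
            return TreeNode(age=0.0, children=_ordered(kids))
        left, right = _diana_split(idx, Dm)
        kids = [build(left), build(right)]
        return TreeNode(age=diameter / 2.0, children=_ordered(kids))

    return Dendrogram(root=build(list(range(n))), labels=labels, method="divisive")


def _newick_label(s: str) -> str:
    out = "".join("_" if ch in "(),:;[] \t'" else ch for ch in s)
    return out or "_"


def dendrogram_to_newick(d: Dendrogram) -> str:
    """Serialise a dendrogram as a Newick string with ultrametric branch lengths
    (leaf-to-leaf path length equals the merge height of their cluster)."""

    def walk(node: TreeNode, parent_age: float) -> str:
        bl = parent_age - node.age
        if node.is_leaf:
            return f"{_newick_label(node.label)}:{bl:.10g}"
        inner = ",".join(walk(c, node.age) for c in node.children)
        return f"({inner}):{bl:.10g}"

    root = d.root
    if root.is_leaf:
        return f"{_newick_label(root.label)}:0;"
    inner = ",".join(walk(c, root.age) for c in root.children)
    return f"({inner});"


# ---------------------------------------------------------------------------
# PCA and MCD


@dataclass(frozen=True)
class PcaResult:
    """Eigenstructure of a clr covariance (classical or MCD-robust).

    ``loadings`` columns are unit clr-space eigenvectors (zero-sum); ``scores``
    are the centred clr data projected on them.  The closure constraint forces
    at least one zero eigenvalue, so at most D-1 components carry variance.
    """

    eigenvalues: np.ndarray
    loadings: np.ndarray  # (D, D) columns = components, descending eigenvalue
    scores: np.ndarray  # (n, D)
    explained: np.ndarray  # fractions, sum to 1
    estimator: str  # "classical" | "mcd"
    center_clr: np.ndarray
    part_labels: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class McdFit:
    """Minimum covariance determinant fit on ilr coordinates."""

    h: int
    location: np.ndarray  # robust ilr location
    scatter: np.ndarray  # consistency-corrected robust scatter
    distances: np.ndarray  # squared robust Mahalanobis distances
    flags: np.ndarray  # True where distance exceeds the chi-square cutoff
    cutoff: float
    support: np.ndarray  # h-subset membership mask


def _eig_descending(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, V = np.linalg.eigh(S)
    w = np.clip(w[::-1], 0.0, None)
    V = V[:, ::-1].copy()
    for k in range(V.shape[1]):  # deterministic sign
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    return w, V


def mcd_fit(Y, h: int | None = None, seed: int = 0, quantile: float = 0.975) -> McdFit:
    """Robust location/scatter of an (n, p) table by the FAST-MCD search.

    ``h`` is the subset size whose covariance determinant is minimised
    (default ⌊(n+p+1)/2⌋, the most robust choice).  Flags mark points whose
    squared robust Mahalanobis distance exceeds the chi-square(p) quantile.
    """
    Ya = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = Ya.shape
    if n <= 2 * p:
        raise ValueError(f"MCD needs n > 2p (got n={n}, p={p})")
    h_default = (n + p + 1) // 2
    h = h_default if h is None else int(h)
    if not (h_default <= h <= n):
        raise ValueError(f"h must lie in [{h_default}, {n}]")
    est = MinCovDet(
        support_fraction=h / n, random_state=int(seed), assume_centered=False
    ).fit(Ya)
    d2 = est.mahalanobis(Ya)
    cutoff = float(chi2.ppf(quantile, df=p))
    return McdFit(
        h=int(est.support_.sum()),
        location=est.location_,
        scatter=est.covariance_,
        distances=d2,
        flags=d2 > cutoff,
        cutoff=cutoff,
        support=est.support_,
    )


def pca_clr(
    A,
    estimator: str = "classical",
    seed: int = 0,
    labels=None,
    basis: np.ndarray | None = None,
) -> PcaResult:
    """PCA of clr-transformed compositions, classical or MCD-robust.

    The robust variant estimates the MCD scatter in ilr coordinates (full rank)
    and maps scatter and location back to clr space through the contrast basis;
    loadings and scores are always reported in clr space.
    """
    Aa = np.atleast_2d(np.asarray(A, dtype=float))
    n, d = Aa.shape
    if n <= d:
        raise ValueError("PCA needs more observations than parts")
    labels = tuple(labels) if labels is not None else tuple(f"w{i+1}" for i in range(d))
    Y = coda.clr(Aa)
    if estimator == "classical":
        center_clr = Y.mean(axis=0)
        S = np.cov(Y, rowvar=False, ddof=1)
    elif estimator == "mcd":
        V = coda.helmert_basis(d) if basis is None else basis
        fit = mcd_fit(Y @ V.T, seed=seed)
        center_clr = fit.location @ V
        S = V.T @ fit.scatter @ V
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    w, Vec = _eig_descending(S)
    total = w.sum()
    explained = w / total if total > 0 else np.zeros_like(w)
    scores = (Y - center_clr) @ Vec
    return PcaResult(
        eigenvalues=w,
        loadings=Vec,
        scores=scores,
        explained=explained,
        estimator=estimator,
        center_clr=center_clr,
        part_labels=labels,
    )
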
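"""Log-ratio variance statistics and balance screening.

Two parts of a composition are proportional across samples exactly when the
variance of their log-ratio is zero, so the matrix T of pairwise log-ratio
variances (the variation matrix) is the natural association structure for
compositional data: it is subcompositionally coherent, unlike covariances of
raw proportions.

A balance is a scaled log-contrast between two disjoint groups of parts,

    z = sqrt(rs / (r + s)) * ln( gmean(plus parts) / gmean(minus parts) ),

with r and s the group sizes.  Its coefficient vector a is zero-sum with unit
norm, and for any zero-sum a the variance of aᵀ ln x is the quadratic form
-(1/2) aᵀ T a — so a printed variation matrix alone suffices to rank every
possible balance by variance, no raw data needed.  Low-variance balances flag
part groups whose concentration products hold a fixed ratio (the signature of a
process at equilibrium); high-variance balances flag groups far from it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Balance",
    "SbpTree",
    "vr_pair",
    "variation_matrix",
    "clr_cov_from_T",
    "balance_coefficients",
    "balance_values",
    "balance_variance_from_T",
    "enumerate_balances",
    "balance_screen",
    "sbp_basis",
]


@dataclass(frozen=True)
class Balance:
    """A two-group log-contrast over D parts.

    ``plus`` and ``minus`` are disjoint, non-empty tuples of part indices; the
    coefficient vector carries sqrt(rs/(r+s))/r on the plus group and
    -sqrt(rs/(r+s))/s on the minus group, zero elsewhere (zero-sum, unit norm).
    """

    plus: tuple[int, ...]
    minus: tuple[int, ...]
    n_parts: int

    def __post_init__(self):
        plus, minus = tuple(self.plus), tuple(self.minus)
        if not plus or not minus:
            raise ValueError("both balance groups must be non-empty")
        if set(plus) & set(minus):
            raise ValueError("balance groups must be disjoint")
        all_idx = set(plus) | set(minus)
        if not all_idx <= set(range(self.n_parts)):
            raise ValueError("part index out of range")
        object.__setattr__(self, "plus", tuple(sorted(plus)))
        object.__setattr__(self, "minus", tuple(sorted(minus)))

    @property
    def size(self) -> int:
        """Number of parts involved in the balance."""
        return len(self.plus) + len(self.minus)

    @property
    def coefficients(self) -> np.ndarray:
        r, s = len(self.plus), len(self.minus)
        scale = np.sqrt(r * s / (r + s))
        a = np.zeros(self.n_parts)
        a[list(self.plus)] = scale / r
        a[list(self.minus)] = -scale / s
        return a


def vr_pair(a, b, ddof: int = 1) -> float:
    """Variance of the pairwise log-ratio var(ln a_i / b_i).

    Zero iff the two series are exactly proportional; symmetric in its
    arguments.  Uses the n-1 denominator by default.
    """
    aa, bb = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if aa.shape != bb.shape or aa.ndim != 1:
        raise ValueError("vr_pair requires two equal-length 1-D series")
    if aa.size < 2:
        raise ValueError("vr_pair requires at least 2 observations")
    if np.any(aa <= 0) or np.any(bb <= 0):
        raise ValueError("vr_pair requires strictly positive values")
    return float(np.var(np.log(aa / bb), ddof=ddof))


def variation_matrix(X, ddof: int = 1) -> np.ndarray:
    """Variation matrix T[i, j] = var(ln X[:, i] / X[:, j]) of a positive table.

    Symmetric with zero diagonal; any column subset yields the corresponding
    block of the full matrix (subcompositional coherence).
    """
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim != 2 or Xa.shape[0] < 2:
        raise ValueError("variation_matrix requires an (n >= 2, D) table")
    if np.any(Xa <= 0):
        raise ValueError("variation_matrix requires strictly positive entries")
    L = np.log(Xa)
    # var(l_i - l_j) = var_i + var_j - 2 cov_ij, vectorised over all pairs
    C = np.cov(L, rowvar=False, ddof=ddof)
    v = np.diag(C)
    T = v[:, None] + v[None, :] - 2 * C
    np.fill_diagonal(T, 0.0)
    return T


def _check_variation(T: np.ndarray) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("variation matrix must be square")
    if not np.allclose(T, T.T, atol=1e-8):
        raise ValueError("variation matrix must be symmetric")
    if not np.allclose(np.diag(T), 0, atol=1e-10):
        raise ValueError("variation matrix must have zero diagonal")
    if np.any(T < -1e-10):
        raise ValueError("variation matrix entries must be non-negative")
    return T


def clr_cov_from_T(T, clip: bool = True) -> np.ndarray:
    """clr covariance implied by a variation matrix: Σ = -(1/2) G T G.

    G = I - J/D is the centring projector.  For a data-derived T this equals
    the sample covariance of the clr-transformed rows exactly.  A rounded
    (printed) T can make the form slightly indefinite; with ``clip`` negative
    eigenvalues are clipped at zero with a warning.
    """
    T = _check_variation(T)
    d = T.shape[0]
    G = np.eye(d) - np.ones((d, d)) / d
    S = -0.5 * G @ T @ G
    S = (S + S.T) / 2
    w, V = np.linalg.eigh(S)
    if np.any(w < -1e-10):
        if not clip:
            raise ValueError("variation matrix induces an indefinite clr covariance")
        warnings.warn(
            "variation matrix induces an indefinite clr covariance; "
            "clipping negative eigenvalues at 0 (rounded input?)",
            stacklevel=2,
        )
        S = (V * np.clip(w, 0, None)) @ V.T
    return S


def balance_coefficients(plus, minus, n_parts: int) -> Balance:
    """Construct a :class:`Balance` from its two part-index groups."""
    return Balance(tuple(plus), tuple(minus), n_parts)


def balance_values(X, b: Balance) -> np.ndarray:
    """Balance coordinate per row of a positive table: z = Σ_k a_k ln X[:, k]."""
    Xa = np.asarray(X, dtype=float)
    if np.any(Xa <= 0):
        raise ValueError("balance_values requires strictly positive entries")
    if Xa.shape[-1] != b.n_parts:
        raise ValueError("table width does not match balance")
    return np.log(Xa) @ b.coefficients


def balance_variance_from_T(T, b: Balance) -> float:
    """Variance of a balance from a variation matrix: -(1/2) aᵀ T a.

    Exactly equals the sample variance of :func:`balance_values` when T is the
    empirical variation matrix of the same table.
    """
    T = _check_variation(T)
    if T.shape[0] != b.n_parts:
        raise ValueError("variation matrix size does not match balance")
    a = b.coefficients
    return float(-0.5 * a @ T @ a)


def enumerate_balances(n_parts: int, sizes=None) -> list[Balance]:
    """Every distinct two-group balance over subcompositions of the given sizes.

    For each part subset S with |S| in ``sizes`` (default 2..D) and every
    unordered split of S into two non-empty groups, one balance is produced.
    Orientation is canonical — the group containing the lowest part index is the
    plus group — so sign-flipped duplicates are not emitted.  The count is
    Σ_k C(D, k) (2^(k-1) - 1).
    """
    sizes = range(2, n_parts + 1) if sizes is None else sizes
    sizes = sorted(set(int(k) for k in sizes))
    if sizes and (sizes[0] < 2 or sizes[-1] > n_parts):
        raise ValueError(f"sizes must lie within 2..{n_parts}")
    out: list[Balance] = []
    for k in sizes:
        for subset in itertools.combinations(range(n_parts), k):
            # enumerate splits with subset[0] forced into the plus group:
            # each remaining member is either plus or minus, minus non-empty
            rest = subset[1:]
            for mask in range(1, 2 ** len(rest)):
                plus = [subset[0]]
                minus = []
                for i, p in enumerate(rest):
                    (minus if (mask >> i) & 1 else plus).append(p)
                out.append(Balance(tuple(plus), tuple(minus), n_parts))
    return out


def balance_screen(
    data,
    sizes=None,
    labels=None,
    from_variation: bool = False,
    ddof: int = 1,
) -> pd.DataFrame:
    """Rank every enumerable balance by variance, ascending.

    ``data`` is either an (n, D) positive table or, with ``from_variation``, a
    D×D variation matrix.  Returns a DataFrame with columns
    ``rank, variance, size, plus_parts, minus_parts`` (labels ';'-joined),
    sorted by increasing variance.
    """
    arr = np.asarray(data, dtype=float)
    if from_variation:
        T = _check_variation(arr)
    else:
        T = variation_matrix(arr, ddof=ddof)
    d = T.shape[0]
    labels = [f"p{i + 1}" for i in range(d)] if labels is None else list(labels)
    if len(labels) != d:
        raise ValueError("label count does not match part count")
    rows = []
    for b in enumerate_balances(d, sizes):
        rows.append(
            {
                "variance": balance_variance_from_T(T, b),
                "size": b.size,
                "plus_parts": ";".join(labels[i] for i in b.plus),
                "minus_parts": ";".join(labels[i] for i in b.minus),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["variance", "size", "plus_parts", "minus_parts"], kind="mergesort"
    )
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class SbpTree:
    """A sequential binary partition of D parts: an ordered list of D-1 balances
    whose coefficient rows form an orthonormal contrast basis."""

    balances: tuple[Balance, ...] = field()

    @property
    def n_parts(self) -> int:
        return self.balances[0].n_parts

    @property
    def contrast_matrix(self) -> np.ndarray:
        """(D-1, D) matrix of balance coefficient rows; a valid ilr basis."""
        return np.vstack([b.coefficients for b in self.balances])


def sbp_basis(partition) -> SbpTree:
    """Build an SBP from a nested binary grouping of part indices.

    ``partition`` is a two-element nested sequence, e.g. for D = 5::

        ((0, 1), (2, (3, 4)))

    Each internal split contributes one balance (left group = plus, right =
    minus), top-down left-to-right, giving D-1 orthonormal balances.
    """

    def leaves(node) -> list[int]:
        if isinstance(node, (int, np.integer)):
            return [int(node)]
        return [i for child in node for i in leaves(child)]

    all_parts = leaves(partition)
    if len(set(all_parts)) != len(all_parts):
        raise ValueError("partition repeats a part index")
    d = len(all_parts)
    if set(all_parts) != set(range(d)):
        raise ValueError(f"partition must cover indices 0..{d - 1} exactly")

    balances: list[Balance] = []

    def walk(node):
        if isinstance(node, (int, np.integer)):
            return
        if len(node) != 2:
            raise ValueError("each split must have exactly two children")
        left, right = node
        balances.append(Balance(tuple(leaves(left)), tuple(leaves(right)), d))
        walk(left)
        walk(right)

    walk(partition)
    if len(balances) != d - 1:
        raise ValueError("partition is not a full binary split of the parts")
    return SbpTree(tuple(balances))
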
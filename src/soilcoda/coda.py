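"""Aitchison-simplex geometry primitives.

A composition is a vector of strictly positive parts carrying only relative
information; its sample space is the unit simplex.  The simplex is a Euclidean
vector space under perturbation (component-wise product followed by closure) and
powering (component-wise exponentiation), and the centred log-ratio (clr) and
isometric log-ratio (ilr) transforms map it isometrically into real coordinate
space.  All functions here operate on plain NumPy arrays; compositions are
1-D, datasets are (n, D) with one composition per row.

Transform arithmetic is delegated to :mod:`skbio.stats.composition`; this module
adds input validation, the simplex line parametrisation, and the closed
geometric-mean center.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import helmert as _helmert
from skbio.stats.composition import (
    closure as _closure,
    clr as _clr,
    clr_inv as _clr_inv,
    ilr as _ilr,
    ilr_inv as _ilr_inv,
    perturb as _perturb,
    power as _power,
)

__all__ = [
    "closure",
    "perturb",
    "inverse",
    "power",
    "linear_process_point",
    "clr",
    "clr_inv",
    "helmert_basis",
    "ilr",
    "ilr_inv",
    "aitchison_distance",
    "center",
    "canonical_direction",
]

#: Tolerance to which closed compositions sum to 1.
CLOSURE_TOL = 1e-12


def _as_float_array(x, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _check_positive(arr: np.ndarray, name: str = "x") -> None:
    if np.any(arr <= 0):
        raise ValueError(f"{name} must be strictly positive")


def closure(raw) -> np.ndarray:
    """Close a non-negative vector (or rows of a matrix) to unit sum.

    Raises ``ValueError`` on negative entries or an all-zero row.
    """
    arr = _as_float_array(raw, "raw")
    if np.any(arr < 0):
        raise ValueError("closure requires non-negative entries")
    sums = arr.sum(axis=-1)
    if np.any(sums <= 0):
        raise ValueError("closure requires at least one positive entry per row")
    return _closure(arr, validate=False)


def perturb(x, v) -> np.ndarray:
    """Perturbation x ⊕ v: closed component-wise product (simplex addition)."""
    xa, va = _as_float_array(x), _as_float_array(v, "v")
    if xa.shape[-1] != va.shape[-1]:
        raise ValueError("perturb requires equal part counts")
    _check_positive(xa)
    _check_positive(va, "v")
    return _perturb(xa, va)


def inverse(x) -> np.ndarray:
    """Perturbation-inverse of x: closure of the reciprocals, so x ⊕ inverse(x)
    is the uniform composition."""
    xa = _as_float_array(x)
    _check_positive(xa)
    return closure(1.0 / xa)


def power(x, t: float) -> np.ndarray:
    """Powering t ⊗ x: closed component-wise t-th power (simplex scaling)."""
    xa = _as_float_array(x)
    _check_positive(xa)
    return _power(xa, float(t))


def linear_process_point(x0, v, t: float) -> np.ndarray:
    """Point x(t) = x0 ⊕ (t ⊗ v) on the simplex line through x0 with direction v."""
    return perturb(x0, power(v, t))


def clr(x) -> np.ndarray:
    """Centred log-ratio transform: ln of each part over the row geometric mean.

    Output coordinates sum to zero.  Requires strictly positive parts.
    """
    xa = _as_float_array(x)
    _check_positive(xa)
    return _clr(xa, validate=False)


def clr_inv(y) -> np.ndarray:
    """Inverse clr: closure of the component-wise exponentials."""
    return _clr_inv(_as_float_array(y, "y"), validate=False)


def helmert_basis(d: int) -> np.ndarray:
    """Default orthonormal contrast basis for D parts: (D-1, D) Helmert rows,
    each zero-sum with unit Euclidean norm."""
    if d < 2:
        raise ValueError("need at least 2 parts")
    return _helmert(d, full=False)


def _check_basis(basis: np.ndarray, d: int) -> np.ndarray:
    basis = np.atleast_2d(np.asarray(basis, dtype=float))
    if basis.shape != (d - 1, d):
        raise ValueError(f"basis must have shape ({d - 1}, {d}), got {basis.shape}")
    if not np.allclose(basis.sum(axis=1), 0, atol=1e-10):
        raise ValueError("basis rows must sum to zero")
    if not np.allclose(basis @ basis.T, np.eye(d - 1), atol=1e-10):
        raise ValueError("basis rows must be orthonormal")
    return basis


def ilr(x, basis: np.ndarray | None = None) -> np.ndarray:
    """Isometric log-ratio coordinates of x in an orthonormal contrast basis.

    Defaults to the Helmert basis.  For any valid basis, Euclidean distances
    between ilr coordinates equal Aitchison distances on the simplex.
    """
    xa = _as_float_array(x)
    _check_positive(xa)
    d = xa.shape[-1]
    basis = helmert_basis(d) if basis is None else _check_basis(basis, d)
    return _clr(xa, validate=False) @ basis.T


def ilr_inv(y, basis: np.ndarray | None = None) -> np.ndarray:
    """Composition whose ilr coordinates (in ``basis``) are y."""
    ya = _as_float_array(y, "y")
    d = ya.shape[-1] + 1
    basis = helmert_basis(d) if basis is None else _check_basis(basis, d)
    return _clr_inv(ya @ basis, validate=False)


def aitchison_distance(x, y) -> float:
    """Aitchison distance: Euclidean distance between clr images.

    Symmetric, perturbation-invariant, zero iff x == y (as compositions).
    """
    xa, ya = _as_float_array(x), _as_float_array(y, "y")
    if xa.shape != ya.shape:
        raise ValueError("aitchison_distance requires equal part counts")
    return float(np.linalg.norm(clr(xa) - clr(ya)))


def canonical_direction(v) -> np.ndarray:
    """Unit-norm representative of a simplex direction.

    A direction is defined only up to powering (t ⊗ v traces the same line), so
    the canonical representative is the closed composition whose clr image has
    unit Euclidean norm: clr_inv(clr(v) / ‖clr(v)‖).
    """
    y = clr(v)
    norm = np.linalg.norm(y)
    if norm == 0:
        raise ValueError("the uniform composition has no direction")
    return clr_inv(y / norm)


def center(X) -> np.ndarray:
    """Compositional center of a sample: closure of column-wise geometric means.

    Perturbation-equivariant: center({x_i ⊕ p}) = center({x_i}) ⊕ p.
    """
    Xa = np.atleast_2d(_as_float_array(X, "X"))
    _check_positive(Xa, "X")
    return closure(np.exp(np.mean(np.log(Xa), axis=0)))
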
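"""Profile-level pipeline: closing horizon activities into layer compositions,
summary statistics, and simplex-line fits between layer pairs.

A soil profile is an ordered stack of genetic horizons, each with a measured
^137Cs specific activity in Bq/kg.  Because sites were contaminated unevenly,
absolute activities are not comparable across profiles; dividing each horizon's
activity by the profile total yields relative activities a_r that are — at the
price of becoming compositional.  Horizons are abstracted to depth-ordered
layers w1..w5 (surface first), discarding horizon identity but keeping the
name as metadata.

The evolution of the relative activities across profiles is modelled as a
linear process on the simplex, x(t) = x0 ⊕ (t ⊗ v): a fixed mechanism (the
direction v) observed at different stages of progress t.  For a pair of layers
the fit is done on the 3-part subcomposition [layer i, layer j, geometric mean
of the rest], the direction being estimated as the leading principal component
of the clr-transformed data mapped back to the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean as _gmean

from . import coda
from .balances import variation_matrix

__all__ = [
    "Horizon",
    "ProfileRecord",
    "LayerComposition",
    "LinearProcessFit",
    "relative_activities",
    "map_layers",
    "close_profiles",
    "layer_table",
    "zero_replace",
    "layer_summary",
    "gm_ratio",
    "pair_rest_subcomposition",
    "fit_linear_process",
    "pairwise_process_report",
]


@dataclass(frozen=True)
class Horizon:
    order: int  # 1 = soil surface
    name: str  # genetic horizon name, e.g. Ol, Of, Oh, A, Bbr, C
    activity: float  # ^137Cs specific activity, Bq/kg


@dataclass(frozen=True)
class ProfileRecord:
    """Raw horizon-level activities of one soil profile."""

    profile_id: str
    soil_type: str
    horizons: tuple[Horizon, ...]

    def __post_init__(self):
        if not self.horizons:
            raise ValueError(f"profile {self.profile_id}: no horizons")
        orders = [h.order for h in self.horizons]
        if orders != list(range(1, len(orders) + 1)):
            raise ValueError(
                f"profile {self.profile_id}: horizon orders must be consecutive from 1"
            )
        for h in self.horizons:
            if not np.isfinite(h.activity) or h.activity < 0:
                raise ValueError(
                    f"profile {self.profile_id}: invalid activity {h.activity!r}"
                )


@dataclass(frozen=True)
class LayerComposition:
    """Closed relative activities of one profile over the retained layers."""

    profile_id: str
    soil_type: str
    parts: np.ndarray  # closed to 1; may contain zeros before replacement
    horizon_names: tuple[str, ...]


@dataclass(frozen=True)
class LinearProcessFit:
    """Fitted simplex line: center x0, closed direction v, and the fraction of
    clr-space variance captured by the line."""

    x0: np.ndarray
    v: np.ndarray | None
    share_of_variance: float
    degenerate: bool = False


def relative_activities(p: ProfileRecord, layers: int = 5) -> LayerComposition:
    """Close the first ``layers`` horizons of a profile to relative activities.

    The denominator is the activity sum over the retained horizons only; deeper
    horizons are dropped.  Raises ``ValueError`` if the profile is too shallow.
    Zero activities pass through (replace downstream before log-ratio work).
    """
    if len(p.horizons) < layers:
        raise ValueError(
            f"profile {p.profile_id}: {len(p.horizons)} horizons < {layers} required"
        )
    kept = p.horizons[:layers]
    acts = np.array([h.activity for h in kept], dtype=float)
    total = acts.sum()
    if total <= 0:
        raise ValueError(f"profile {p.profile_id}: zero total activity")
    return LayerComposition(
        profile_id=p.profile_id,
        soil_type=p.soil_type,
        parts=acts / total,
        horizon_names=tuple(h.name for h in kept),
    )


def map_layers(p: ProfileRecord, layers: int = 5) -> dict[str, str]:
    """Map depth-ordered layer labels w1..wN to the profile's horizon names."""
    if len(p.horizons) < layers:
        raise ValueError(
            f"profile {p.profile_id}: {len(p.horizons)} horizons < {layers} required"
        )
    return {f"w{i + 1}": p.horizons[i].name for i in range(layers)}


def close_profiles(
    records, layers: int = 5
) -> tuple[list[LayerComposition], list[tuple[str, str]]]:
    """Close every eligible profile; return (kept, rejection log).

    The rejection log holds (profile_id, reason) pairs for profiles with fewer
    horizons than requested or no measurable activity.
    """
    kept: list[LayerComposition] = []
    rejected: list[tuple[str, str]] = []
    for p in records:
        try:
            kept.append(relative_activities(p, layers=layers))
        except ValueError as e:
            rejected.append((p.profile_id, str(e)))
    return kept, rejected


def zero_replace(C, delta="auto") -> np.ndarray:
    """Multiplicative replacement of zero parts in closed compositions.

    Zeros in column j become delta_j and the remaining parts of the row are
    rescaled so the row still sums to 1, preserving their mutual ratios.  With
    ``delta='auto'`` each column's delta is 0.65 times its smallest positive
    value (a below-detection-limit convention).  A scalar or per-column array
    delta must stay below the smallest positive value it replaces.
    """
    Ca = np.atleast_2d(np.asarray(C, dtype=float))
    if np.any(Ca < 0):
        raise ValueError("compositions must be non-negative")
    if not np.allclose(Ca.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows must be closed to 1 before zero replacement")
    d = Ca.shape[1]
    col_min_pos = np.array(
        [Ca[Ca[:, j] > 0, j].min() if np.any(Ca[:, j] > 0) else np.nan for j in range(d)]
    )
    if isinstance(delta, str) and delta == "auto":
        deltas = 0.65 * col_min_pos
    else:
        deltas = np.broadcast_to(np.asarray(delta, dtype=float), (d,)).copy()
        if np.any(deltas >= col_min_pos[~np.isnan(col_min_pos)].min()):
            raise ValueError("delta must be smaller than the smallest positive part")
    out = Ca.copy()
    for i in range(out.shape[0]):
        zeros = out[i] == 0
        if not np.any(zeros):
            continue
        fill = deltas[zeros]
        if np.any(~np.isfinite(fill)):
            raise ValueError("cannot impute a column that is zero everywhere")
        out[i, zeros] = fill
        out[i, ~zeros] *= (1.0 - fill.sum()) / out[i, ~zeros].sum()
    if np.any(out <= 0):
        raise ValueError("zero replacement produced non-positive parts")
    return out if np.asarray(C).ndim == 2 else out[0]


def layer_table(
    compositions: list[LayerComposition], delta="auto"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack layer compositions into an (n, D) table plus a metadata frame.

    Returns ``(parts, meta)``: ``parts`` has the zero-replaced closed relative
    activities with columns w1..wD and the profile id as index; ``meta`` carries
    soil type and the horizon name behind each layer.
    """
    if not compositions:
        raise ValueError("no layer compositions")
    d = len(compositions[0].parts)
    labels = [f"w{i + 1}" for i in range(d)]
    raw = np.vstack([c.parts for c in compositions])
    ids = [c.profile_id for c in compositions]
    parts = pd.DataFrame(zero_replace(raw, delta=delta), index=ids, columns=labels)
    meta = pd.DataFrame(
        {
            "soil_type": [c.soil_type for c in compositions],
            **{
                f"horizon_{labels[j]}": [c.horizon_names[j] for c in compositions]
                for j in range(d)
            },
        },
        index=ids,
    )
    parts.index.name = meta.index.name = "profile_id"
    return parts, meta


def layer_summary(A, labels=None, delta="auto") -> pd.DataFrame:
    """Per-layer order statistics and means of the relative activities.

    Rows: min, q1, median, mean, gmean, q3, max.  Quartiles use linear
    interpolation.  The geometric mean is computed on zero-replaced values;
    all other statistics use the raw (possibly zero-containing) values.
    """
    Aa = np.atleast_2d(np.asarray(A, dtype=float))
    if Aa.shape[0] == 0:
        raise ValueError("empty input")
    labels = [f"w{i + 1}" for i in range(Aa.shape[1])] if labels is None else list(labels)
    replaced = zero_replace(Aa, delta=delta) if np.any(Aa == 0) else Aa
    stats = {
        "min": Aa.min(axis=0),
        "q1": np.quantile(Aa, 0.25, axis=0),
        "median": np.median(Aa, axis=0),
        "mean": Aa.mean(axis=0),
        "gmean": _gmean(replaced, axis=0),
        "q3": np.quantile(Aa, 0.75, axis=0),
        "max": Aa.max(axis=0),
    }
    return pd.DataFrame(stats, index=labels).T


def gm_ratio(A, i: int, j: int) -> float:
    """Geometric mean over profiles of the ratio layer_i / layer_j.

    Identically equals the ratio of the two layers' geometric means.
    """
    Aa = np.atleast_2d(np.asarray(A, dtype=float))
    if np.any(Aa <= 0):
        raise ValueError("gm_ratio requires strictly positive values (replace zeros)")
    return float(_gmean(Aa[:, i] / Aa[:, j]))


def pair_rest_subcomposition(A, i: int, j: int) -> np.ndarray:
    """3-part closed table [layer i, layer j, gmean of the remaining layers].

    The third part summarises the rest of the profile, so a simplex-line fit to
    this table describes how the (i, j) pair moves against the background.
    """
    Aa = np.atleast_2d(np.asarray(A, dtype=float))
    d = Aa.shape[1]
    if i == j or not (0 <= i < d and 0 <= j < d):
        raise ValueError("invalid layer indices")
    if np.any(Aa <= 0):
        raise ValueError("subcompositions require strictly positive parts")
    rest = [k for k in range(d) if k not in (i, j)]
    g_rest = _gmean(Aa[:, rest], axis=1)
    return coda.closure(np.column_stack([Aa[:, i], Aa[:, j], g_rest]))


def fit_linear_process(X3, tol: float = 1e-12) -> LinearProcessFit:
    """Fit a simplex line x(t) = x0 ⊕ (t ⊗ v) to a positive composition table.

    x0 is the compositional center; v is the leading principal component of the
    clr-transformed data mapped back through the inverse clr (so v is a closed
    composition).  ``share_of_variance`` is the leading eigenvalue's fraction
    of total clr variance.  Data lying exactly on a simplex line are recovered
    with share 1.  Orientation: the clr coordinate of the first part of v is
    positive (on a tie, the second).
    """
    Xa = np.atleast_2d(np.asarray(X3, dtype=float))
    if Xa.shape[0] < 3:
        raise ValueError("need at least 3 observations to fit a line")
    x0 = coda.center(Xa)
    Y = coda.clr(Xa)
    S = np.cov(Y, rowvar=False, ddof=1)
    w, V = np.linalg.eigh(S)
    w = np.clip(w[::-1], 0, None)  # descending
    V = V[:, ::-1]
    total = w.sum()
    if total <= tol:
        return LinearProcessFit(x0=x0, v=None, share_of_variance=np.nan, degenerate=True)
    e = V[:, 0]
    e = e - e.mean()  # clr eigenvectors are zero-sum up to roundoff
    e /= np.linalg.norm(e)
    if abs(e[0]) > tol:
        e = e * np.sign(e[0])
    elif abs(e[1]) > tol:
        e = e * np.sign(e[1])
    return LinearProcessFit(
        x0=x0,
        v=coda.clr_inv(e),
        share_of_variance=float(w[0] / total),
    )


def pairwise_process_report(A, labels=None) -> pd.DataFrame:
    """Simplex-line fits for every unordered layer pair (C(D,2) rows).

    Each row carries the pair, the fitted 3-part direction v and center x0, the
    share of variance on the line, the pair's log-ratio variance VR, and the
    geometric-mean ratio of the pair.
    """
    Aa = np.atleast_2d(np.asarray(A, dtype=float))
    d = Aa.shape[1]
    labels = [f"w{i + 1}" for i in range(d)] if labels is None else list(labels)
    T = variation_matrix(Aa)
    rows = []
    for i in range(d):
        for j in range(i + 1, d):
            X3 = pair_rest_subcomposition(Aa, i, j)
            fit = fit_linear_process(X3)
            v = fit.v if fit.v is not None else [np.nan] * 3
            rows.append(
                {
                    "layer_i": labels[i],
                    "layer_j": labels[j],
                    "v_i": v[0],
                    "v_j": v[1],
                    "v_rest": v[2],
                    "x0_i": fit.x0[0],
                    "x0_j": fit.x0[1],
                    "x0_rest": fit.x0[2],
                    "share_of_variance": fit.share_of_variance,
                    "vr": T[i, j],
                    "gm_ratio": gm_ratio(Aa, i, j),
                }
            )
    return pd.DataFrame(rows)
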
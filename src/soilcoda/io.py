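"""Reading profile tables, run configuration, and the end-to-end pipeline.

The input format is a long CSV with one row per horizon::

    profile_id,soil_type,horizon_order,horizon_name,activity_bq_kg

A run closes each profile's top horizons to relative activities, replaces
zeros, and emits every result table of the analysis: per-layer summaries, the
variation matrix, the exhaustive balance screen, pairwise simplex-line fits,
both dendrograms as Newick, classical and robust PCA tables, and MCD outlier
flags — plus a JSON sidecar with the configuration, seed, software version and
rejected-profile log, so a run is reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, coda
from .balances import balance_screen, variation_matrix
from .multivariate import (
    cluster_agglomerative,
    cluster_divisive,
    dendrogram_to_newick,
    distance_matrix,
    mcd_fit,
    pca_clr,
)
from .profiles import (
    Horizon,
    ProfileRecord,
    close_profiles,
    layer_summary,
    layer_table,
    pairwise_process_report,
)
from . import synth

logger = logging.getLogger("soilcoda")

__all__ = ["RunConfig", "RunBundle", "read_profiles", "run_pipeline"]

REQUIRED_COLUMNS = (
    "profile_id",
    "soil_type",
    "horizon_order",
    "horizon_name",
    "activity_bq_kg",
)


class ProfileFormatError(ValueError):
    """Raised when the input CSV violates the schema; carries row-level messages."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("malformed profile table:\n" + "\n".join(self.problems))


def read_profiles(path) -> list[ProfileRecord]:
    """Parse and validate a profiles CSV into :class:`ProfileRecord` objects.

    All schema violations (missing columns, non-numeric or negative activities,
    duplicate (profile, order) pairs, non-consecutive orders) are collected and
    raised together as :class:`ProfileFormatError` with line numbers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileFormatError([f"missing required columns: {', '.join(missing)}"])
    problems: list[str] = []
    rows = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            order = int(row["horizon_order"])
        except ValueError:
            problems.append(f"line {line}: non-integer horizon_order {row['horizon_order']!r}")
            continue
        try:
            act = float(row["activity_bq_kg"])
        except ValueError:
            problems.append(f"line {line}: non-numeric activity {row['activity_bq_kg']!r}")
            continue
        if not np.isfinite(act) or act < 0:
            problems.append(f"line {line}: negative or non-finite activity {act!r}")
            continue
        rows.append((row["profile_id"], row["soil_type"], order, row["horizon_name"], act))
    tab = pd.DataFrame(rows, columns=["pid", "soil", "order", "name", "act"])
    dup = tab.duplicated(subset=["pid", "order"], keep=False)
    if dup.any():
        for pid, order in tab.loc[dup, ["pid", "order"]].drop_duplicates().itertuples(index=False):
            problems.append(f"profile {pid}: duplicate horizon_order {order}")
    if problems:
        raise ProfileFormatError(problems)
    records = []
    for pid, grp in tab.groupby("pid", sort=False):
        grp = grp.sort_values("order")
        soil = grp["soil"].iloc[0]
        try:
            records.append(
                ProfileRecord(
                    profile_id=str(pid),
                    soil_type=str(soil),
                    horizons=tuple(
                        Horizon(order=int(o), name=str(nm), activity=float(a))
                        for o, nm, a in zip(grp["order"], grp["name"], grp["act"])
                    ),
                )
            )
        except ValueError as e:
            problems.append(str(e))
    if problems:
        raise ProfileFormatError(problems)
    return records


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run (serialised to the sidecar)."""

    input: str | None = None  # profiles CSV; mutually exclusive with preset
    preset: str | None = None  # synthetic preset name
    layers: int = 5
    delta: float | str = "auto"  # zero-replacement delta
    min_size: int = 2  # balance screen subcomposition sizes
    max_size: int = 5
    mcd_quantile: float = 0.975
    linkage: str = "average"
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self):
        if (self.input is None) == (self.preset is None):
            raise ValueError("exactly one of input or preset must be given")
        if self.layers < 2:
            raise ValueError("layers must be >= 2")
        if not 2 <= self.min_size <= self.max_size <= self.layers:
            raise ValueError("balance sizes must satisfy 2 <= min <= max <= layers")
        if not 0 < self.mcd_quantile < 1:
            raise ValueError("mcd_quantile must be in (0, 1)")

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class RunBundle:
    """In-memory results of a pipeline run plus the paths written."""

    config: RunConfig
    parts: pd.DataFrame
    meta: pd.DataFrame
    summary: pd.DataFrame
    variation: pd.DataFrame
    screen: pd.DataFrame
    process_fits: pd.DataFrame
    outliers: pd.DataFrame
    rejected: list[tuple[str, str]]
    paths: dict[str, Path] = field(default_factory=dict)


def _stage_seeds(seed: int, n_stages: int = 4) -> list[int]:
    # one top-level seed, split deterministically per stage (< 2**31 for sklearn)
    ss = np.random.SeedSequence(int(seed))
    return [int(s % (2**31)) for s in ss.generate_state(n_stages)]


def _pca_frame(res, labels) -> pd.DataFrame:
    comp_cols = [f"pc{k + 1}" for k in range(len(res.eigenvalues))]
    rows = []
    rows.append({"kind": "eigenvalue", "name": "", **dict(zip(comp_cols, res.eigenvalues))})
    rows.append({"kind": "explained", "name": "", **dict(zip(comp_cols, res.explained))})
    for j, lab in enumerate(res.part_labels):
        rows.append({"kind": "loading", "name": lab, **dict(zip(comp_cols, res.loadings[j]))})
    for i, lab in enumerate(labels):
        rows.append({"kind": "score", "name": lab, **dict(zip(comp_cols, res.scores[i]))})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunBundle:
    """Execute every analysis stage under one configuration and write the bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    if config.preset is not None:
        ds = synth.make_fixture(config.preset, seed=seeds[0])
        ds.write(outdir / "profiles.csv", outdir / "truth.json")
        records = read_profiles(outdir / "profiles.csv")
    else:
        records = read_profiles(config.input)

    compositions, rejected = close_profiles(records, layers=config.layers)
    for pid, reason in rejected:
        logger.warning("rejected %s: %s", pid, reason)
    if not compositions:
        raise ValueError("no profile passed the horizon-count requirement")

    parts, meta = layer_table(compositions, delta=config.delta)
    labels = list(parts.columns)
    A = parts.to_numpy()

    summary = layer_summary(
        np.vstack([c.parts for c in compositions]), labels=labels, delta=config.delta
    )
    T = variation_matrix(A)
    variation = pd.DataFrame(T, index=labels, columns=labels)
    screen = balance_screen(
        A, sizes=range(config.min_size, config.max_size + 1), labels=labels
    )
    fits = pairwise_process_report(A, labels=labels)

    leaf_labels = [f"{pid}|{st}" for pid, st in zip(parts.index, meta["soil_type"])]
    Dm = distance_matrix(A)
    agnes = cluster_agglomerative(Dm, labels=leaf_labels, method=config.linkage)
    diana = cluster_divisive(Dm, labels=leaf_labels)

    pca_c = pca_clr(A, estimator="classical", labels=labels)
    pca_r = pca_clr(A, estimator="mcd", seed=seeds[1], labels=labels)
    fit = mcd_fit(coda.ilr(A), seed=seeds[2], quantile=config.mcd_quantile)
    outliers = pd.DataFrame(
        {
            "profile_id": parts.index,
            "robust_distance_sq": fit.distances,
            "outlier": fit.flags,
        }
    )

    paths = {
        "layer_summary": outdir / "layer_summary.csv",
        "vr_matrix": outdir / "vr_matrix.csv",
        "balance_screen": outdir / "balance_screen.csv",
        "process_fits": outdir / "process_fits.csv",
        "dendrogram_agnes": outdir / "dendrogram_agnes.nwk",
        "dendrogram_diana": outdir / "dendrogram_diana.nwk",
        "pca_classical": outdir / "pca_classical.csv",
        "pca_mcd": outdir / "pca_mcd.csv",
        "outliers": outdir / "outliers.csv",
        "run_meta": outdir / "run_meta.json",
    }
    summary.to_csv(paths["layer_summary"])
    variation.to_csv(paths["vr_matrix"])
    screen.to_csv(paths["balance_screen"], index=False)
    fits.to_csv(paths["process_fits"], index=False)
    paths["dendrogram_agnes"].write_text(dendrogram_to_newick(agnes) + "\n")
    paths["dendrogram_diana"].write_text(dendrogram_to_newick(diana) + "\n")
    _pca_frame(pca_c, list(parts.index)).to_csv(paths["pca_classical"], index=False)
    _pca_frame(pca_r, list(parts.index)).to_csv(paths["pca_mcd"], index=False)
    outliers.to_csv(paths["outliers"], index=False)
    meta_blob = {
        "config": asdict(config),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "stage_seeds": seeds,
        "version": __version__,
        "n_profiles": int(parts.shape[0]),
        "rejected": [{"profile_id": p, "reason": r} for p, r in rejected],
    }
    paths["run_meta"].write_text(json.dumps(meta_blob, indent=1, default=str) + "\n")

    return RunBundle(
        config=config,
        parts=parts,
        meta=meta,
        summary=summary,
        variation=variation,
        screen=screen,
        process_fits=fits,
        outliers=outliers,
        rejected=rejected,
        paths=paths,
    )
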
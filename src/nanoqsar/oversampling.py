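"""Minority-class oversampling: SMOTE and ADASYN.

Both methods interpolate new minority-class treatments between existing
ones in z-scored descriptor space (Euclidean kNN, k = 5 by default).
SMOTE balances the classes exactly; ADASYN allocates the synthetic
budget preferentially to minority rows surrounded by majority-class
neighbours — the hard-to-learn boundary region.  Interdependent
(ratio/difference) descriptors and columns with missing values never
take part in interpolation: the former are recalculated from their
sources after denormalisation, the latter are excluded up front.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._rng import child_rng
from .core_data import (
    DescriptorSchema,
    TreatmentTable,
    fit_normaliser,
    recalc_derived,
    transform,
)

logger = logging.getLogger(__name__)


@dataclass
class OversampleConfig:
    method: str = "adasyn"  # "smote" | "adasyn"
    k_neighbours: int = 5
    balance_target: float = 1.0  # 1.0 = equal class counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("smote", "adasyn"):
            raise ValueError(f"unknown oversampling method {self.method!r}")
        if self.k_neighbours < 1:
            raise ValueError("k_neighbours must be >= 1")
        if self.balance_target <= 0:
            raise ValueError("balance_target must be positive")


def _classes(table: TreatmentTable) -> tuple[str, str]:
    """(minority, majority) labels; ties resolved to ('high', 'low')."""
    counts = table.class_counts()
    if counts["high"] <= counts["low"]:
        return "high", "low"
    return "low", "high"


def _clamp_k(k: int, n_min: int) -> int:
    if k > n_min - 1:
        warnings.warn(
            f"k_neighbours={k} exceeds minority size - 1 ({n_min - 1}); clamped",
            stacklevel=3,
        )
        return max(1, n_min - 1)
    return k


def _knn_indices(X_query: np.ndarray, X_ref: np.ndarray, k: int,
                 exclude_self: bool = False) -> np.ndarray:
    """Row indices of the k Euclidean nearest refs per query.

    Ties at equal distance break to the lowest row index (stable sort on
    distance then index), so the whole procedure is deterministic.
    """
    d = cdist(X_query, X_ref)
    if exclude_self:
        np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def _interpolate(X_min: np.ndarray, base: np.ndarray, neighbour: np.ndarray,
                 u: np.ndarray) -> np.ndarray:
    """x_new = x_i + u * (x_nn − x_i), one row per synthetic sample."""
    return X_min[base] + u[:, None] * (X_min[neighbour] - X_min[base])


def _assemble(table: TreatmentTable, minority_label: str, min_idx: np.ndarray,
              synth: np.ndarray, base_rows: np.ndarray,
              numeric_cols: list[str], tag: str) -> TreatmentTable:
    """Append synthetic rows (provenance flag set) to the original table."""
    base_global = min_idx[base_rows]
    synth_df = table.data.iloc[base_global].copy().reset_index(drop=True)
    synth_df[numeric_cols] = synth
    synth_df["endpoint"] = minority_label
    synth_df["provenance"] = "synthetic"
    synth_df["treatment_id"] = [f"syn_{tag}_{j:04d}" for j in range(len(synth_df))]
    out = pd.concat([table.data, synth_df], ignore_index=True)
    return TreatmentTable(out)


def smote(train: TreatmentTable, config: OversampleConfig,
          numeric_columns: list[str] | None = None) -> TreatmentTable:
    """SMOTE on a z-scored table: balance classes exactly.

    For each synthetic sample a minority row and one of its k nearest
    minority neighbours are drawn, and a point is placed uniformly at
    random on the segment between them.  Categorical values are copied
    from the seed row.
    """
    numeric_cols = numeric_columns if numeric_columns is not None else [
        c for c in train.descriptor_columns
        if pd.api.types.is_numeric_dtype(train.data[c])
    ]
    minority, majority = _classes(train)
    counts = train.class_counts()
    n_min, n_maj = counts[minority], counts[majority]
    if n_min < 2:
        raise ValueError("minority class needs at least 2 rows for SMOTE")
    n_new = int(round(config.balance_target * n_maj)) - n_min
    if n_new <= 0:
        return train.copy()
    k = _clamp_k(config.k_neighbours, n_min)
    y = train.endpoint.to_numpy()
    min_idx = np.flatnonzero(y == minority)
    X_min = train.data.iloc[min_idx][numeric_cols].to_numpy(float)
    nn = _knn_indices(X_min, X_min, k, exclude_self=True)
    rng = child_rng(config.seed, "smote")
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.random(n_new)
    synth = _interpolate(X_min, base, nn[base, pick], u)
    return _assemble(train, minority, min_idx, synth, base, numeric_cols, "smote")


def adasyn(train: TreatmentTable, config: OversampleConfig,
           numeric_columns: list[str] | None = None) -> TreatmentTable:
    """ADASYN on a z-scored table: density-adaptive synthetic allocation.

    Each minority row i gets a difficulty weight r_i = (majority rows
    among its k nearest neighbours in the full set)/k; the synthetic
    budget G = round(balance_target * (N_maj − N_min)) is apportioned
    proportionally to the normalised weights (largest-remainder, so the
    total is exactly G).  Generation itself is SMOTE-style interpolation
    toward minority neighbours.
    """
    numeric_cols = numeric_columns if numeric_columns is not None else [
        c for c in train.descriptor_columns
        if pd.api.types.is_numeric_dtype(train.data[c])
    ]
    minority, majority = _classes(train)
    counts = train.class_counts()
    n_min, n_maj = counts[minority], counts[majority]
    if n_min < 2:
        raise ValueError("minority class needs at least 2 rows for ADASYN")
    G = int(round(config.balance_target * (n_maj - n_min)))
    if G <= 0:
        return train.copy()
    y = train.endpoint.to_numpy()
    min_idx = np.flatnonzero(y == minority)
    X_all = train.data[numeric_cols].to_numpy(float)
    X_min = X_all[min_idx]

    k_full = min(config.k_neighbours, len(train) - 1)
    nn_full = _knn_indices(X_min, X_all, k_full + 1, exclude_self=False)
    # drop self-match per row (a minority row is its own nearest neighbour)
    r = np.empty(n_min)
    for i in range(n_min):
        neigh = [j for j in nn_full[i] if j != min_idx[i]][:k_full]
        r[i] = np.mean(y[neigh] == majority)
    if r.sum() == 0.0:
        warnings.warn(
            "no minority row has majority neighbours; uniform ADASYN weights used",
            stacklevel=2,
        )
        r_hat = np.full(n_min, 1.0 / n_min)
    else:
        r_hat = r / r.sum()

    g = _largest_remainder(r_hat * G, G)
    k_min = _clamp_k(config.k_neighbours, n_min)
    nn_min = _knn_indices(X_min, X_min, k_min, exclude_self=True)
    rng = child_rng(config.seed, "adasyn")
    base = np.repeat(np.arange(n_min), g)
    pick = rng.integers(0, k_min, size=len(base))
    u = rng.random(len(base))
    synth = _interpolate(X_min, base, nn_min[base, pick], u)
    return _assemble(train, minority, min_idx, synth, base, numeric_cols, "adasyn")


def _largest_remainder(quota: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of `total` proportional to `quota`."""
    floors = np.floor(quota).astype(int)
    short = total - floors.sum()
    if short > 0:
        order = np.argsort(-(quota - floors), kind="stable")
        floors[order[:short]] += 1
    return floors


def oversample_pipeline(
    train: TreatmentTable, schema: DescriptorSchema, config: OversampleConfig
) -> TreatmentTable:
    """The full oversampling contract on a raw (unnormalised) table.

    1. drop descriptor columns containing missing values;
    2. set aside derived (interdependent) columns;
    3. z-score the remaining numeric columns;
    4. run SMOTE or ADASYN;
    5. denormalise the synthetic rows;
    6. recalculate derived columns on the synthetic rows.

    Original rows pass through bit-identical.
    """
    df = train.data
    missing_cols = [c for c in train.descriptor_columns if df[c].isna().any()]
    if missing_cols:
        logger.info("dropping columns with missing values: %s", missing_cols)
    drop = set(missing_cols)
    # a derived column whose source was dropped cannot be recalculated
    drop |= {r.target for r in schema.derived_rules if r.a in drop or r.b in drop}
    derived = [c for c in schema.derived_names if c not in drop]
    interp_cols = [
        c for c in schema.numeric_names
        if c in df.columns and c not in drop and c not in derived
    ]
    work = TreatmentTable(df.drop(columns=list(drop)))
    params = fit_normaliser(work, interp_cols)
    z = transform(work, params, "forward")
    fn = smote if config.method == "smote" else adasyn
    z_over = fn(z, config, numeric_columns=interp_cols)
    raw_over = transform(z_over, params, "inverse")

    synth_mask = raw_over.data["provenance"].to_numpy() == "synthetic"
    live_schema = DescriptorSchema(
        columns=[c for c in schema.columns if c.name not in drop],
        derived_rules=[r for r in schema.derived_rules if r.target not in drop],
    )
    synth = recalc_derived(raw_over.subset(synth_mask), live_schema) if synth_mask.any() \
        else raw_over.subset(synth_mask)
    out = pd.concat([work.data, synth.data[work.data.columns]], ignore_index=True)
    return TreatmentTable(out)
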
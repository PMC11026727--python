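"""Three-component applicability domain with a weighted reliability score.

A query treatment is checked against the training set in three ways:

* **bounding box** — every numeric descriptor inside the training
  [min, max] (raw scale) and every categorical label previously seen;
* **leverage** — h = x'(X'X)^-1 x against the threshold h* = 3k/N, with
  X the z-scored training design matrix (no intercept column, so h
  measures distance from the training centroid), k the number of
  descriptors and N the training rows;
* **local similarity** — cosine similarity with each of the k Euclidean
  nearest training rows must reach the threshold (default 0.8); a low
  minimum flags a query sitting in a hollow region of the box.

The three binary verdicts combine into score = 0.2*bb + 0.3*lev +
0.5*sim, labelled Poor (< 0.5), Moderate (= 0.5) or Good (> 0.5).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import NormalisationParams, TreatmentTable

logger = logging.getLogger(__name__)

DEFAULT_WEIGHTS = (0.2, 0.3, 0.5)  # (bounding box, leverage, similarity)
SCORE_TOL = 1e-9


@dataclass
class ADModel:
    """Fitted applicability-domain state."""

    numeric_columns: list[str]
    categorical_columns: list[str]
    ranges: dict[str, tuple[float, float]]  # raw scale, inclusive
    labels: dict[str, set]  # admissible categorical labels
    X: np.ndarray  # z-scored training matrix, N x k
    xtx_inv: np.ndarray
    h_star: float
    norm: NormalisationParams
    k_neighbours: int = 5
    sim_threshold: float = 0.8
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS

    @property
    def n_descriptors(self) -> int:
        return self.X.shape[1]

    @property
    def n_train(self) -> int:
        return self.X.shape[0]


@dataclass
class ADVerdict:
    """Per-query AD outcome."""

    ad_bb: int
    ad_lev: int
    ad_sim: int
    leverage: float
    min_similarity: float
    score: float
    label: str

    def to_dict(self) -> dict:
        return {
            "ad_bb": self.ad_bb, "ad_lev": self.ad_lev, "ad_sim": self.ad_sim,
            "leverage": self.leverage, "min_similarity": self.min_similarity,
            "score": self.score, "label": self.label,
        }


def leverage_threshold(k: int, n: int) -> float:
    """h* = 3k/N."""
    if n <= 0:
        raise ValueError("training size must be positive")
    return 3.0 * k / n


def fit_ad(
    train_selected: TreatmentTable,
    params: NormalisationParams,
    categorical_columns: list[str] | None = None,
    k_neighbours: int = 5,
    sim_threshold: float = 0.8,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> ADModel:
    """Fit the AD on the (raw-scale) modelling training set.

    *train_selected* must be restricted to the frozen selected
    descriptors; synthetic rows belong in it, since the model was
    trained on them.  Numeric columns are z-scored with the training
    *params* for the leverage/similarity components; ranges are stored
    on the raw scale.
    """
    if abs(sum(weights) - 1.0) > SCORE_TOL:
        raise ValueError("AD weights must sum to 1")
    categorical_columns = categorical_columns or []
    numeric = [c for c in train_selected.descriptor_columns
               if c not in categorical_columns]
    ranges = {}
    for c in numeric:
        x = train_selected.data[c].to_numpy(float)
        ranges[c] = (float(x.min()), float(x.max()))
    labels = {
        c: set(train_selected.data[c]) for c in categorical_columns
    }
    X = np.column_stack([
        _zscore(train_selected.data[c].to_numpy(float), params, c) for c in numeric
    ])
    k = X.shape[1]
    n = X.shape[0]
    if n < k:
        warnings.warn(
            f"fewer training rows ({n}) than descriptors ({k}); "
            "pseudo-inverse used and h* exceeds 3",
            stacklevel=2,
        )
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        xtx_inv = np.linalg.pinv(xtx)
    if not np.all(np.isfinite(xtx_inv)) or np.linalg.matrix_rank(xtx) < k:
        xtx_inv = np.linalg.pinv(xtx)
    return ADModel(
        numeric_columns=numeric,
        categorical_columns=list(categorical_columns),
        ranges=ranges,
        labels=labels,
        X=X,
        xtx_inv=xtx_inv,
        h_star=leverage_threshold(k, n),
        norm=params,
        k_neighbours=k_neighbours,
        sim_threshold=sim_threshold,
        weights=tuple(weights),
    )


def _zscore(x: np.ndarray, params: NormalisationParams, col: str) -> np.ndarray:
    m, s = params.mean[col], params.sd[col]
    return (x - m) / s if s != 0 else x - m


def bounding_box_check(query: pd.Series | dict, model: ADModel) -> int:
    """1 iff every numeric value is inside [min, max] and every
    categorical label was seen in training."""
    q = dict(query)
    for c in model.numeric_columns:
        if c not in q or pd.isna(q[c]):
            warnings.warn(f"query missing descriptor {c!r}; outside AD", stacklevel=2)
            return 0
        lo, hi = model.ranges[c]
        if not lo <= float(q[c]) <= hi:
            return 0
    for c in model.categorical_columns:
        if c not in q or q[c] not in model.labels[c]:
            return 0
    return 1


def _query_vector(query, model: ADModel) -> np.ndarray:
    q = dict(query)
    return np.array([
        _zscore(np.asarray(float(q[c])), model.norm, c) for c in model.numeric_columns
    ], dtype=float)


def leverage_check(query: pd.Series | dict, model: ADModel) -> tuple[int, float]:
    """h = x'(X'X)^-1 x on the z-scored query; inside iff h < h* (strict)."""
    x = _query_vector(query, model)
    h = float(x @ model.xtx_inv @ x)
    return int(h < model.h_star), h


def local_similarity_check(query: pd.Series | dict, model: ADModel) -> tuple[int, float]:
    """Cosine similarity with each of the k nearest training rows.

    Inside iff all k similarities reach the threshold; returns the
    minimum.  Zero-norm vectors get similarity 0 with a warning.
    """
    x = _query_vector(query, model)
    k = min(model.k_neighbours, model.n_train)
    d = np.linalg.norm(model.X - x, axis=1)
    nearest = np.argsort(d, kind="stable")[:k]
    xn = np.linalg.norm(x)
    sims = np.empty(k)
    for j, i in enumerate(nearest):
        tn = np.linalg.norm(model.X[i])
        if xn == 0 or tn == 0:
            warnings.warn("zero-norm vector in cosine similarity; set to 0",
                          stacklevel=2)
            sims[j] = 0.0
        else:
            sims[j] = float(model.X[i] @ x / (tn * xn))
    min_sim = float(sims.min())
    return int(min_sim >= model.sim_threshold), min_sim


def reliability(
    ad_bb: int, ad_lev: int, ad_sim: int,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> tuple[float, str]:
    """Weighted score of the three verdicts and its reliability label."""
    if abs(sum(weights) - 1.0) > SCORE_TOL:
        raise ValueError("AD weights must sum to 1")
    for flag in (ad_bb, ad_lev, ad_sim):
        if flag not in (0, 1):
            raise ValueError("AD flags must be binary")
    score = weights[0] * ad_bb + weights[1] * ad_lev + weights[2] * ad_sim
    if abs(score - 0.5) <= SCORE_TOL:
        label = "Moderate"
    elif score < 0.5:
        label = "Poor"
    else:
        label = "Good"
    return score, label


def assess(query_table: TreatmentTable, model: ADModel) -> pd.DataFrame:
    """Run all three checks plus the score for every row of a raw-scale table."""
    records = []
    for _, row in query_table.data.iterrows():
        v = assess_row(row, model)
        records.append({"treatment_id": row["treatment_id"], **v.to_dict()})
    return pd.DataFrame(records)


def assess_row(query: pd.Series | dict, model: ADModel) -> ADVerdict:
    bb = bounding_box_check(query, model)
    lev, h = leverage_check(query, model)
    sim, min_sim = local_similarity_check(query, model)
    score, label = reliability(bb, lev, sim, model.weights)
    return ADVerdict(ad_bb=bb, ad_lev=lev, ad_sim=sim, leverage=h,
                     min_similarity=min_sim, score=score, label=label)
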
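"""Descriptor filtering and training-set normalisation.

Filter order is fixed: low-variance -> Spearman correlation ->
information gain -> duplicate-row removal -> z-score.  All filters are
fitted on training data only; the surviving column list and the
normalisation parameters are frozen and replayed verbatim on test,
blind and query data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import (
    DescriptorSchema,
    NormalisationParams,
    TreatmentTable,
    fit_normaliser,
    transform,
)

logger = logging.getLogger(__name__)


@dataclass
class FilterTrace:
    """Audit trail of the filtering cascade."""

    dropped_low_variance: list[tuple[str, float]] = field(default_factory=list)
    dropped_correlated: list[tuple[str, str, float]] = field(default_factory=list)  # (kept, dropped, rho)
    ig_scores: dict[str, float] = field(default_factory=dict)
    selected: list[str] = field(default_factory=list)
    duplicates_removed: int = 0

    def to_dict(self) -> dict:
        return {
            "dropped_low_variance": [[c, v] for c, v in self.dropped_low_variance],
            "dropped_correlated": [[k, d, r] for k, d, r in self.dropped_correlated],
            "ig_scores": dict(self.ig_scores),
            "selected": list(self.selected),
            "duplicates_removed": self.duplicates_removed,
        }


@dataclass
class PreprocessResult:
    table: TreatmentTable  # deduplicated, selected columns, z-scored
    trace: FilterTrace
    params: NormalisationParams


def variance_filter(
    table: TreatmentTable,
    threshold: float = 0.2,
    columns: list[str] | None = None,
    categorical: set[str] | None = None,
) -> tuple[list[str], list[tuple[str, float]]]:
    """Drop numeric columns whose raw-scale sample variance is < threshold.

    Categorical columns are exempt.  Returns (kept, dropped-with-variance).
    """
    columns = columns if columns is not None else table.descriptor_columns
    categorical = categorical or set()
    kept, dropped = [], []
    for col in columns:
        if col in categorical:
            kept.append(col)
            continue
        x = table.data[col].to_numpy(dtype=float)
        var = float(np.var(x, ddof=1)) if len(x) > 1 else 0.0
        # exact constants carry no information and drop at any threshold
        if var < threshold or var == 0.0:
            dropped.append((col, var))
        else:
            kept.append(col)
    return kept, dropped


def spearman_filter(
    table: TreatmentTable,
    threshold: float = 0.95,
    columns: list[str] | None = None,
    categorical: set[str] | None = None,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy left-to-right redundancy filter on |Spearman rho|.

    Scanning columns in schema order, a column is dropped the first time
    its |rho| with an already-kept column reaches the threshold; dropped
    columns cannot trigger further drops.  Average ranks are used for
    ties.
    """
    columns = columns if columns is not None else table.descriptor_columns
    categorical = categorical or set()
    numeric = [c for c in columns if c not in categorical]
    if len(numeric) >= 2:
        ranks = {c: stats.rankdata(table.data[c].to_numpy(float)) for c in numeric}
    kept_numeric: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for col in numeric:
        offender = None
        for prev in kept_numeric:
            with np.errstate(invalid="ignore"):
                rho = np.corrcoef(ranks[prev], ranks[col])[0, 1]
            if np.isnan(rho):
                rho = 0.0  # a constant column has no rank order
            if abs(rho) >= threshold:
                offender = (prev, col, float(rho))
                break
        if offender is None:
            kept_numeric.append(col)
        else:
            dropped.append(offender)
    kept_set = set(kept_numeric)
    kept = [c for c in columns if c in categorical or c in kept_set]
    return kept, dropped


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _discretise(x: pd.Series, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency binning of a numeric column (min(n_bins, #distinct))."""
    distinct = x.nunique()
    bins = min(n_bins, distinct)
    if bins <= 1:
        return np.zeros(len(x), dtype=int)
    codes = pd.qcut(x.rank(method="average"), q=bins, labels=False, duplicates="drop")
    return np.asarray(codes, dtype=int)


def information_gain(
    table: TreatmentTable,
    columns: list[str] | None = None,
    categorical: set[str] | None = None,
    n_bins: int = 10,
) -> dict[str, float]:
    """Information gain (base-2) of each descriptor for the endpoint.

    IG(col) = H(endpoint) − H(endpoint | discretised col); continuous
    columns are equal-frequency binned, categoricals used as-is.
    """
    columns = columns if columns is not None else table.descriptor_columns
    categorical = categorical or set()
    y = table.endpoint.to_numpy()
    h_y = _entropy(y)
    scores: dict[str, float] = {}
    for col in columns:
        if col in categorical:
            groups = table.data[col].to_numpy()
        else:
            groups = _discretise(table.data[col], n_bins=n_bins)
        h_cond = 0.0
        for g in np.unique(groups):
            mask = groups == g
            h_cond += mask.mean() * _entropy(y[mask])
        scores[col] = h_y - h_cond
    return scores


def information_gain_filter(
    table: TreatmentTable,
    columns: list[str] | None = None,
    categorical: set[str] | None = None,
    n_bins: int = 10,
    tol: float = 1e-12,
) -> tuple[list[str], dict[str, float]]:
    """Keep only descriptors with strictly positive information gain."""
    scores = information_gain(table, columns, categorical, n_bins)
    kept = [c for c in (columns or table.descriptor_columns) if scores[c] > tol]
    return kept, scores


def dedupe(table: TreatmentTable, columns: list[str]) -> tuple[TreatmentTable, int]:
    """Collapse rows identical on (selected descriptors + endpoint).

    Rows sharing descriptors but disagreeing on the endpoint are all
    retained, with a warning — collapsing them would silently pick a
    label.
    """
    df = table.data
    key_cols = list(columns) + ["endpoint"]
    keep_mask = ~df.duplicated(subset=key_cols, keep="first")
    desc_dup = df.duplicated(subset=list(columns), keep=False)
    conflicting = df[desc_dup].groupby(list(columns))["endpoint"].nunique()
    if (conflicting > 1).any():
        warnings.warn(
            "duplicate descriptor rows with conflicting endpoints retained",
            stacklevel=2,
        )
    removed = int((~keep_mask).sum())
    return table.subset(keep_mask), removed


def preprocess(
    train: TreatmentTable,
    schema: DescriptorSchema,
    variance_threshold: float = 0.2,
    spearman_threshold: float = 0.95,
    ig_bins: int = 10,
    seed: int | None = None,  # accepted for interface symmetry; filters are deterministic
) -> PreprocessResult:
    """Run the full filtering cascade and z-score the survivors.

    Returns the normalised, deduplicated training table restricted to
    the selected descriptors, the filter trace, and the frozen
    normalisation parameters for downstream reuse.
    """
    categorical = set(schema.categorical_names)
    columns = [c for c in train.descriptor_columns if c in set(schema.names)]
    trace = FilterTrace()
    kept, trace.dropped_low_variance = variance_filter(
        train, variance_threshold, columns, categorical
    )
    kept, trace.dropped_correlated = spearman_filter(
        train, spearman_threshold, kept, categorical
    )
    kept, scores = information_gain_filter(train, kept, categorical, ig_bins)
    trace.ig_scores = {
        c: scores[c] for c in sorted(scores, key=lambda c: -scores[c])
    }
    trace.selected = kept
    deduped, trace.duplicates_removed = dedupe(train, kept)
    numeric_kept = [c for c in kept if c not in categorical]
    params = fit_normaliser(deduped, numeric_kept)
    keep_cols = [c for c in deduped.data.columns if c not in set(columns) - set(kept)]
    reduced = TreatmentTable(deduped.data[keep_cols].copy())
    normalised = transform(reduced, params, "forward")
    logger.info(
        "preprocess: %d -> %d descriptors, %d duplicate rows removed",
        len(columns), len(kept), trace.duplicates_removed,
    )
    return PreprocessResult(table=normalised, trace=trace, params=params)


def apply_preprocessing(
    table: TreatmentTable, selected: list[str], params: NormalisationParams
) -> TreatmentTable:
    """Replay a frozen column selection + normalisation on new data."""
    missing = [c for c in selected if c not in table.data.columns]
    if missing:
        raise ValueError(f"table is missing selected descriptors {missing}")
    meta = [c for c in table.data.columns if c not in table.descriptor_columns]
    reduced = TreatmentTable(table.data[meta + list(selected)].copy())
    return transform(reduced, params, "forward")
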
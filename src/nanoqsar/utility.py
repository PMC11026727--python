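"""Synthetic-data utility assessment.

The headline statistic is the propensity-score mean squared error
(pMSE): a logistic regression is trained to tell original rows (0) from
synthetic rows (1) under leave-one-out cross-validation — re-fitting the
variable filters and z-scoring inside every fold — and

    pMSE = (1/N) * sum_i (p_hat_i - c)^2,

with c the synthetic fraction.  pMSE = 0 means the classifier cannot do
better than the base rate: the synthetic rows are statistically
indistinguishable from the originals.  Per-descriptor KL divergence and
Wasserstein distance are reported as supporting diagnostics; the choice
between oversamplers is made on pMSE alone (lower wins, ties go to
ADASYN as the density-adaptive method).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .core_data import DescriptorSchema, TreatmentTable
from .preprocessing import spearman_filter, variance_filter

logger = logging.getLogger(__name__)


@dataclass
class UtilityReport:
    pmse: float
    c: float  # synthetic fraction
    n: int  # rows assessed
    method: str = ""
    kl_per_descriptor: dict[str, float] = field(default_factory=dict)
    wasserstein_per_descriptor: dict[str, float] = field(default_factory=dict)
    n_unconverged_folds: int = 0

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "pmse": self.pmse,
            "c": self.c,
            "n": self.n,
            "kl_per_descriptor": dict(self.kl_per_descriptor),
            "wasserstein_per_descriptor": dict(self.wasserstein_per_descriptor),
            "n_unconverged_folds": self.n_unconverged_folds,
        }


def pmse_from_probabilities(p_hat: np.ndarray, c: float) -> float:
    """Plain evaluation of the pMSE formula."""
    p_hat = np.asarray(p_hat, dtype=float)
    return float(np.mean((p_hat - c) ** 2))


def pmse(
    data: TreatmentTable,
    numeric_columns: list[str] | None = None,
    variance_threshold: float = 0.2,
    spearman_threshold: float = 0.9,
    population: str = "all",  # "all" | "minority"
    max_iter: int = 100,
    tol: float = 1e-6,
) -> UtilityReport:
    """LOO propensity-score MSE of an oversampled table.

    ``population="all"`` assesses every row of the oversampled table;
    ``"minority"`` restricts to the oversampled class (original minority
    rows + synthetic rows), where synthetic rows actually live.
    """
    if population not in ("all", "minority"):
        raise ValueError("population must be 'all' or 'minority'")
    prov = data.data["provenance"].to_numpy()
    if len(set(prov)) < 2:
        raise ValueError("table must contain both original and synthetic rows")
    if population == "minority":
        minority_label = data.data.loc[prov == "synthetic", "endpoint"].iloc[0]
        data = data.subset(data.endpoint.to_numpy() == minority_label)
        prov = data.data["provenance"].to_numpy()
    cols = numeric_columns if numeric_columns is not None else [
        c for c in data.descriptor_columns
        if pd.api.types.is_numeric_dtype(data.data[c])
    ]
    y = (prov == "synthetic").astype(int)
    n = len(data)
    c_frac = float(y.mean())
    X_raw = data.data[cols].to_numpy(float)
    p_hat = np.empty(n)
    unconverged = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold = data.subset(mask)
        kept, _ = variance_filter(fold, variance_threshold, cols)
        kept, _ = spearman_filter(fold, spearman_threshold, kept)
        if not kept:  # nothing survives filtering: no information
            p_hat[i] = fold_rate = float(y[mask].mean())
            continue
        idx = [cols.index(k) for k in kept]
        Xf = X_raw[mask][:, idx]
        mu = Xf.mean(axis=0)
        sd = Xf.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xf = (Xf - mu) / sd
        xq = (X_raw[i, idx] - mu) / sd
        model = LogisticRegression(penalty=None, max_iter=max_iter, tol=tol)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(Xf, y[mask])
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                unconverged += 1  # probability taken from the last iterate
        p_hat[i] = model.predict_proba(xq[None, :])[0, list(model.classes_).index(1)]
    return UtilityReport(
        pmse=pmse_from_probabilities(p_hat, c_frac),
        c=c_frac,
        n=n,
        n_unconverged_folds=unconverged,
    )


def kl_divergence(original: np.ndarray, oversampled: np.ndarray, bins: int = 10) -> float:
    """KL(original || oversampled) over shared equal-width histograms.

    Natural log; empty bins get additive smoothing eps = 1e-9.  A
    degenerate pooled range (all values identical) returns 0 with a
    warning.
    """
    original = np.asarray(original, dtype=float)
    oversampled = np.asarray(oversampled, dtype=float)
    if len(original) == 0 or len(oversampled) == 0:
        raise ValueError("both samples must be non-empty")
    pooled_min = min(original.min(), oversampled.min())
    pooled_max = max(original.max(), oversampled.max())
    if pooled_min == pooled_max:
        warnings.warn("degenerate pooled range; KL divergence set to 0", stacklevel=2)
        return 0.0
    edges = np.linspace(pooled_min, pooled_max, bins + 1)
    eps = 1e-9
    p = np.histogram(original, bins=edges)[0].astype(float)
    q = np.histogram(oversampled, bins=edges)[0].astype(float)
    p /= p.sum()
    q /= q.sum()
    p = np.where(p == 0, eps, p)
    q = np.where(q == 0, eps, q)
    return float(np.sum(p * np.log(p / q)))


def wasserstein(original: np.ndarray, oversampled: np.ndarray) -> float:
    """First-order 1-D Wasserstein (earth mover's) distance."""
    if len(np.asarray(original)) == 0 or len(np.asarray(oversampled)) == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.wasserstein_distance(original, oversampled))


def divergence_report(
    original: TreatmentTable,
    oversampled: TreatmentTable,
    columns: list[str] | None = None,
    bins: int = 10,
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-descriptor KL and Wasserstein between original and oversampled."""
    cols = columns if columns is not None else [
        c for c in original.descriptor_columns
        if pd.api.types.is_numeric_dtype(original.data[c])
        and c in oversampled.data.columns
    ]
    kl = {}
    wd = {}
    for c in cols:
        x = original.data[c].to_numpy(float)
        z = oversampled.data[c].to_numpy(float)
        kl[c] = kl_divergence(x, z, bins)
        wd[c] = wasserstein(x, z)
    return kl, wd


def assess_oversampling(
    original_train: TreatmentTable,
    oversampled: TreatmentTable,
    schema: DescriptorSchema,
    method: str,
    spearman_threshold: float = 0.9,
    variance_threshold: float = 0.2,
    population: str = "all",
    bins: int = 10,
) -> UtilityReport:
    """Full utility report (pMSE + divergences) for one oversampled table."""
    numeric = [
        c for c in schema.numeric_names
        if c in oversampled.data.columns
    ]
    report = pmse(
        oversampled,
        numeric_columns=numeric,
        variance_threshold=variance_threshold,
        spearman_threshold=spearman_threshold,
        population=population,
    )
    report.method = method
    report.kl_per_descriptor, report.wasserstein_per_descriptor = divergence_report(
        original_train, oversampled, columns=numeric, bins=bins
    )
    return report


def select_oversampler(report_smote: UtilityReport, report_adasyn: UtilityReport) -> str:
    """Pick the oversampler with the lower pMSE (tie -> adasyn)."""
    if report_smote.pmse < report_adasyn.pmse:
        return "smote"
    if report_smote.pmse == report_adasyn.pmse:
        logger.info("pMSE tie (%.6f); selecting adasyn by convention", report_smote.pmse)
    return "adasyn"
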
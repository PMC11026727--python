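"""Confusion-matrix metrics and the Y-randomisation robustness test.

The positive class is "high effect": TP counts high-effect treatments
correctly flagged as high.  Cohen's kappa uses the standard binary form

    kappa = 2(TP*TN - FP*FN) / [(TP+FP)(FP+TN) + (TP+FN)(FN+TN)]

and MCC its usual four-factor denominator; both are chance-corrected
summaries of a 2x2 table and are the headline numbers throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core_data import ENDPOINT_LABELS, POSITIVE_CLASS, TreatmentTable


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts; positive class = "high effect"."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """The six validation metrics; a ratio with zero denominator is None."""

    accuracy: float | None
    kappa: float | None
    recall: float | None
    precision: float | None
    specificity: float | None
    mcc: float | None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "recall": self.recall,
            "precision": self.precision,
            "specificity": self.specificity,
            "mcc": self.mcc,
        }

    def rounded(self, ndigits: int = 2) -> dict:
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in self.to_dict().items()
        }


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count TP/FP/FN/TN over paired label sequences."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred differ in length")
    for lab in set(y_true) | set(y_pred):
        if lab not in ENDPOINT_LABELS:
            raise ValueError(f"unknown endpoint label {lab!r}")
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == POSITIVE_CLASS:
            if p == POSITIVE_CLASS:
                tp += 1
            else:
                fn += 1
        else:
            if p == POSITIVE_CLASS:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return None
    return num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Compute accuracy, kappa, recall, precision, specificity and MCC."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    acc = (tp + tn) / c.total
    recall = _ratio(tp, tp + fn, "recall")
    precision = _ratio(tp, tp + fp, "precision")
    specificity = _ratio(tn, tn + fp, "specificity")
    kappa_den = (tp + fp) * (fp + tn) + (tp + fn) * (fn + tn)
    kappa = _ratio(2.0 * (tp * tn - fp * fn), kappa_den, "kappa")
    mcc_den2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = _ratio(tp * tn - fp * fn, math.sqrt(mcc_den2), "mcc") if mcc_den2 > 0 else _ratio(1, 0, "mcc")
    return MetricsReport(
        accuracy=acc, kappa=kappa, recall=recall,
        precision=precision, specificity=specificity, mcc=mcc,
    )


def evaluate(y_true, y_pred) -> MetricsReport:
    """Convenience: confusion + metrics in one call."""
    return metrics(confusion(y_true, y_pred))


def shuffle_endpoint(table: TreatmentTable, rng: np.random.Generator) -> TreatmentTable:
    """Permute the endpoint column between treatments (class counts kept)."""
    out = table.data.copy()
    vals = out["endpoint"].to_numpy().copy()
    out["endpoint"] = vals[rng.permutation(len(vals))]
    return TreatmentTable(out)


def y_randomisation(
    train: TreatmentTable,
    test: TreatmentTable,
    schema,
    family: str,
    n_rounds: int = 10,
    seed: int = 0,
    oversample_method: str = "adasyn",
    retune: bool = True,
    fixed_params: dict | None = None,
    automl_options: dict | None = None,
) -> list[MetricsReport]:
    """Refit the modelling pipeline on label-shuffled training data.

    Per round the training endpoints are permuted, the full chain
    (oversampling -> filtering -> normalisation -> tuning of *family*)
    is re-run, and the model is scored on the untouched test set.  A
    robust real model should beat every shuffled round.  With
    ``retune=False`` the hyperparameters in *fixed_params* are reused
    each round (faster; the default repeats all modelling steps).
    """
    # local imports: validation is a leaf for metric consumers, but the
    # randomisation test drives the whole pipeline
    from . import automl as _automl
    from ._rng import child_rng, child_seed
    from .oversampling import OversampleConfig, oversample_pipeline
    from .preprocessing import apply_preprocessing, preprocess

    rng = child_rng(seed, "y_randomisation")
    options = automl_options or {}
    reports: list[MetricsReport] = []
    for round_i in range(n_rounds):
        shuffled = shuffle_endpoint(train, rng)
        round_seed = child_seed(seed, f"y_randomisation_round_{round_i}")
        over = oversample_pipeline(
            shuffled,
            schema,
            OversampleConfig(method=oversample_method, seed=round_seed),
        )
        prep = preprocess(over, schema, seed=round_seed)
        X, y = _automl.design_matrix(prep.table, prep.trace.selected)
        if retune or fixed_params is None:
            tuned = _automl.cv_tune(
                family, X, y, seed=round_seed, **options
            )
        else:
            tuned = _automl.fit_fixed(family, X, y, fixed_params, seed=round_seed)
        test_sel = apply_preprocessing(test, prep.trace.selected, prep.params)
        Xt, yt = _automl.design_matrix(test_sel, prep.trace.selected)
        y_pred = tuned.predict_labels(Xt)
        reports.append(evaluate(list(test.endpoint), y_pred))
    return reports
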
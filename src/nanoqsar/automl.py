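"""Random-search autoML over seven classifier families.

Hyperparameters are tuned by uniform random search under stratified
5-fold cross-validation, maximising the mean Cohen's kappa across
folds; the search stops after a fixed number of candidate combinations
(10 by default) or after 5 consecutive combinations without
improvement.  The winning combination per family is refitted on the
full training set; the best family is then picked on the untouched test
set, ranked lexicographically by MCC, then kappa, then accuracy.

Family notes
------------
* "logistic_regression" exposes a literal *step size*, so it is fitted
  by SGD on the logistic loss with a constant learning rate.
* "naive_bayes" is a Gaussian naive Bayes with a *default probability*:
  a floor applied to each per-feature class-conditional density, which
  keeps a single outlying feature value from zeroing out a class.
* The XGBoost family tunes eta and max depth with the tree count fixed
  at 100.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import cohen_kappa_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from ._rng import child_rng, child_seed
from .core_data import POSITIVE_CLASS, NormalisationParams, TreatmentTable
from .validation import MetricsReport, evaluate

logger = logging.getLogger(__name__)

FAMILIES = (
    "gradient_boosting",
    "naive_bayes",
    "logistic_regression",
    "decision_tree",
    "random_forest",
    "neural_network",
    "xgboost",
)

#: Admissible values per tunable hyperparameter.  The study only fixed
#: which hyperparameters each family tunes; these ranges are chosen so
#: that typical small-tabular winners are interior points.
DEFAULT_SEARCH_SPACE: dict[str, dict[str, list]] = {
    "gradient_boosting": {"n_trees": [25, 50, 100, 200, 400]},
    "naive_bayes": {
        "default_probability": list(np.round(np.logspace(-4, -2, 5), 6)),
    },
    "logistic_regression": {"step_size": [0.001, 0.01, 0.1]},
    "decision_tree": {"min_records_per_node": [2, 4, 8, 16, 32]},
    "random_forest": {
        "max_depth": [2, 3, 4, 5, 6, 7, 8],
        "n_trees": [25, 50, 100, 200, 400],
        "min_child_size": [2, 4, 8, 16, 32],
    },
    "neural_network": {
        "hidden_layers": [1, 2],
        "hidden_neurons": [5, 10, 15, 20],
    },
    "xgboost": {
        "eta": [0.05, 0.1, 0.2, 0.3],
        "max_depth": [2, 3, 4, 5, 6, 7, 8],
    },
}


class _FlooredGaussianNB:
    """Gaussian naive Bayes with a per-feature density floor.

    Class-conditional densities are N(mu_jc, var_jc) evaluated
    per feature and clipped from below at ``default_probability`` before
    the naive product, so one extreme feature value cannot annihilate a
    class posterior.
    """

    def __init__(self, default_probability: float = 1e-3):
        self.default_probability = float(default_probability)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_FlooredGaussianNB":
        X = np.asarray(X, dtype=float)
        self.classes_ = np.unique(y)
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        self.mu_ = np.array([X[y == c].mean(axis=0) for c in self.classes_])
        var = np.array([X[y == c].var(axis=0, ddof=0) for c in self.classes_])
        self.var_ = np.maximum(var, 1e-9)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        log_post = np.empty((len(X), len(self.classes_)))
        for ci in range(len(self.classes_)):
            dens = np.exp(
                -0.5 * (X - self.mu_[ci]) ** 2 / self.var_[ci]
            ) / np.sqrt(2 * np.pi * self.var_[ci])
            dens = np.maximum(dens, self.default_probability)
            log_post[:, ci] = np.log(self.priors_[ci]) + np.log(dens).sum(axis=1)
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        return post / post.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def make_estimator(family: str, params: dict, seed: int):
    """Instantiate an unfitted classifier for a (family, hyperparams) pair."""
    if family == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=params["n_trees"], random_state=seed
        )
    if family == "naive_bayes":
        return _FlooredGaussianNB(default_probability=params["default_probability"])
    if family == "logistic_regression":
        return SGDClassifier(
            loss="log_loss", learning_rate="constant", eta0=params["step_size"],
            max_iter=1000, tol=1e-4, random_state=seed,
        )
    if family == "decision_tree":
        return DecisionTreeClassifier(
            min_samples_leaf=params["min_records_per_node"], random_state=seed
        )
    if family == "random_forest":
        return RandomForestClassifier(
            n_estimators=params["n_trees"], max_depth=params["max_depth"],
            min_samples_leaf=params["min_child_size"], random_state=seed,
        )
    if family == "neural_network":
        return MLPClassifier(
            hidden_layer_sizes=(params["hidden_neurons"],) * params["hidden_layers"],
            max_iter=500, random_state=seed,
        )
    if family == "xgboost":
        return XGBClassifier(
            learning_rate=params["eta"], max_depth=params["max_depth"],
            n_estimators=100, random_state=seed, eval_metric="logloss",
            verbosity=0,
        )
    raise ValueError(f"unknown model family {family!r}")


@dataclass
class TunedModel:
    """A tuned, fully fitted classifier plus everything prediction needs."""

    family: str
    params: dict
    cv_kappa: float
    estimator: object
    n_candidates_evaluated: int = 0
    fold_true: list = field(default_factory=list)  # per-fold held-out labels
    fold_pred: list = field(default_factory=list)  # per-fold held-out predictions
    selected: list[str] | None = None
    norm: NormalisationParams | None = None

    def predict_labels(self, X: np.ndarray) -> list[str]:
        """Predict endpoint labels; threshold 0.5 on P(high)."""
        proba = self.predict_proba_positive(X)
        return [POSITIVE_CLASS if p >= 0.5 else "low" for p in proba]

    def predict_proba_positive(self, X: np.ndarray) -> np.ndarray:
        est = self.estimator
        proba = est.predict_proba(np.asarray(X, dtype=float))
        pos_idx = int(np.flatnonzero(np.asarray(est.classes_) == 1)[0])
        return proba[:, pos_idx]


def design_matrix(table: TreatmentTable, selected: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) with y encoded 1 = "high effect", 0 = "low effect".

    Categorical selected descriptors are one-hot encoded (rare path; the
    usual selected set is all-numeric).
    """
    cols = table.data[selected]
    numeric = cols.select_dtypes(include=[np.number])
    non_numeric = [c for c in selected if c not in numeric.columns]
    if non_numeric:
        dummies = pd.get_dummies(cols[non_numeric], dtype=float)
        X = pd.concat([numeric, dummies], axis=1).to_numpy(float)
    else:
        X = numeric.to_numpy(float)
    y = (table.endpoint.to_numpy() == POSITIVE_CLASS).astype(int)
    return X, y


def _sample_params(space: dict[str, list], rng: np.random.Generator) -> dict:
    return {name: values[rng.integers(len(values))] for name, values in space.items()}


def _cv_kappa(family, params, X, y, folds, seed):
    """Mean Cohen's kappa over stratified CV folds; also returns fold records."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    kappas, trues, preds = [], [], []
    for tr, te in skf.split(X, y):
        est = make_estimator(family, params, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[tr], y[tr])
            yp = np.asarray(est.predict(X[te]))
        kappas.append(cohen_kappa_score(y[te], yp))
        trues.append(y[te].tolist())
        preds.append(yp.tolist())
    return float(np.mean(kappas)), trues, preds


def cv_tune(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    space: dict[str, list] | None = None,
    folds: int = 5,
    max_iter: int = 10,
    patience: int = 5,
    seed: int = 0,
) -> TunedModel:
    """Random-search one family under stratified k-fold CV on mean kappa.

    A combination whose fit fails in any fold scores kappa = −1 (worst).
    The winner is refitted on the full training set.
    """
    space = space if space is not None else DEFAULT_SEARCH_SPACE[family]
    if any(len(v) == 0 for v in space.values()):
        raise ValueError("empty hyperparameter range")
    rng = child_rng(seed, f"cv_tune_{family}")
    space_size = int(np.prod([len(v) for v in space.values()]))
    best: tuple[float, dict, list, list] | None = None
    seen: set = set()
    stale = 0
    n_eval = 0
    for _ in range(max_iter):
        if len(seen) >= space_size:
            break  # whole space evaluated; nothing left to draw
        params = _sample_params(space, rng)
        while tuple(sorted(params.items())) in seen:
            params = _sample_params(space, rng)
        seen.add(tuple(sorted(params.items())))
        try:
            kappa, trues, preds = _cv_kappa(family, params, X, y, folds, seed)
        except Exception as exc:  # noqa: BLE001 - scored as worst, search goes on
            warnings.warn(f"{family} failed for {params}: {exc}", stacklevel=2)
            kappa, trues, preds = -1.0, [], []
        n_eval += 1
        if best is None or kappa > best[0]:
            best = (kappa, params, trues, preds)
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    kappa, params, trues, preds = best
    est = make_estimator(family, params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    logger.info("%s tuned: %s (mean CV kappa %.3f, %d candidates)",
                family, params, kappa, n_eval)
    return TunedModel(
        family=family, params=params, cv_kappa=kappa, estimator=est,
        n_candidates_evaluated=n_eval, fold_true=trues, fold_pred=preds,
    )


def fit_fixed(family: str, X: np.ndarray, y: np.ndarray, params: dict, seed: int = 0) -> TunedModel:
    """Fit one family with frozen hyperparameters (no search)."""
    est = make_estimator(family, params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return TunedModel(family=family, params=params, cv_kappa=float("nan"),
                      estimator=est, n_candidates_evaluated=0)


def train_all(
    X: np.ndarray,
    y: np.ndarray,
    spaces: dict[str, dict] | None = None,
    folds: int = 5,
    max_iter: int = 10,
    patience: int = 5,
    seed: int = 0,
    families: tuple[str, ...] = FAMILIES,
) -> list[TunedModel]:
    """Tune every family with independent child seeds; skip hard failures."""
    models: list[TunedModel] = []
    for family in families:
        fam_space = (spaces or {}).get(family)
        try:
            models.append(
                cv_tune(family, X, y, fam_space, folds, max_iter, patience,
                        seed=child_seed(seed, f"family_{family}"))
            )
        except Exception as exc:  # noqa: BLE001
            logger.warning("family %s failed entirely: %s", family, exc)
    return models


def select_best(
    models: list[TunedModel], X_test: np.ndarray, y_test_labels: list[str]
) -> tuple[TunedModel, dict[str, MetricsReport]]:
    """Score every tuned model on the test set; rank by MCC, kappa, accuracy."""
    if not models:
        raise ValueError("no models to select from")
    table: dict[str, MetricsReport] = {}
    for m in models:
        table[m.family] = evaluate(y_test_labels, m.predict_labels(X_test))

    def key(m: TunedModel):
        r = table[m.family]
        return (
            r.mcc if r.mcc is not None else -2.0,
            r.kappa if r.kappa is not None else -2.0,
            r.accuracy if r.accuracy is not None else -1.0,
        )

    best = max(models, key=key)
    return best, table
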
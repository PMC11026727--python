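"""End-to-end workflow orchestration.

One config drives the whole chain: blind split -> train/test split ->
oversampling (both methods) -> utility assessment -> method selection ->
filtering + normalisation -> autoML over seven families -> model
selection on the test set -> blind evaluation -> applicability-domain
fit -> Y-randomisation.  Every stage writes its intermediate artifacts
into a run directory together with a machine-readable manifest, so any
stage can be audited or replayed in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import yaml

from . import automl as _automl
from ._rng import child_seed
from .adomain import ADModel, assess, fit_ad
from .core_data import (
    DescriptorSchema,
    NormalisationParams,
    TreatmentTable,
    load_dataset,
    stratified_split,
)
from .fixtures import FixtureConfig, generate_dataset
from .oversampling import OversampleConfig, oversample_pipeline
from .preprocessing import (
    FilterTrace,
    apply_preprocessing,
    dedupe,
    preprocess,
)
from .utility import assess_oversampling, select_oversampler
from .validation import evaluate, y_randomisation

logger = logging.getLogger(__name__)

STAGES = (
    "blind_split",
    "train_test_split",
    "oversampling",
    "utility",
    "method_selection",
    "preprocessing",
    "automl",
    "model_selection",
    "blind_evaluation",
    "applicability_domain",
    "y_randomisation",
)


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end run, with study defaults."""

    input_csv: str | None = None  # None -> generate the synthetic fixture
    schema_yaml: str | None = None
    seed: int = 0
    blind_fraction: float = 0.30
    test_fraction: float = 0.25
    k_neighbours: int = 5
    variance_threshold: float = 0.2
    spearman_threshold_model: float = 0.95
    spearman_threshold_pmse: float = 0.9
    pmse_population: str = "all"
    automl_folds: int = 5
    automl_max_iter: int = 10
    automl_patience: int = 5
    ad_k_neighbours: int = 5
    ad_sim_threshold: float = 0.8
    ad_weights: tuple[float, float, float] = (0.2, 0.3, 0.5)
    ad_on_oversampled: bool = True
    y_randomisation_rounds: int = 10
    y_randomisation_retune: bool = True
    families: tuple[str, ...] = _automl.FAMILIES

    def __post_init__(self) -> None:
        for frac in (self.blind_fraction, self.test_fraction):
            if not 0.0 < frac < 1.0:
                raise ValueError("fractions must lie in (0, 1)")
        if abs(sum(self.ad_weights) - 1.0) > 1e-9:
            raise ValueError("AD weights must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ad_weights" in raw:
            raw["ad_weights"] = tuple(raw["ad_weights"])
        if "families" in raw:
            raw["families"] = tuple(raw["families"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory view of a finished run (the run dir holds the same data)."""

    config: PipelineConfig
    chosen_method: str
    utility_reports: dict
    trace: FilterTrace
    params: NormalisationParams
    best_model: _automl.TunedModel
    test_metrics: dict
    blind_metrics: dict
    ad_model: ADModel
    blind_ad: "object"
    y_random_reports: list
    manifest: dict
    run_dir: Path | None = None


def schema_hash(schema: DescriptorSchema) -> str:
    blob = yaml.safe_dump(schema.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute all eleven stages; write artifacts if *out_dir* is given."""
    run_dir = Path(out_dir) if out_dir is not None else None
    if run_dir is not None:
        run_dir.mkdir(parents=True, exist_ok=True)

    if config.input_csv is not None:
        if config.schema_yaml is None:
            raise ValueError("schema_yaml required when input_csv is given")
        schema = DescriptorSchema.load(config.schema_yaml)
        table = load_dataset(config.input_csv, schema)
    else:
        table, schema = generate_dataset(FixtureConfig(seed=config.seed))

    manifest: dict = {
        "stages": list(STAGES),
        "seed": config.seed,
        "config": _jsonable(asdict(config)),
        "schema_hash": schema_hash(schema),
        "n_rows": len(table),
        "class_counts": table.class_counts(),
    }

    def _fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # 1-2: blind then train/test splits, stratified by endpoint
    try:
        blind_split = stratified_split(
            table, config.blind_fraction, child_seed(config.seed, "blind_split")
        )
        blind = blind_split.held_out
        rest = blind_split.train
    except Exception as exc:
        _fail("blind_split", exc)
    try:
        tt_split = stratified_split(
            rest, config.test_fraction, child_seed(config.seed, "train_test_split")
        )
        train, test = tt_split.train, tt_split.held_out
    except Exception as exc:
        _fail("train_test_split", exc)
    manifest["split_sizes"] = {
        "blind": len(blind), "test": len(test), "train": len(train)
    }

    # 3-5: oversample with both methods, compare utility, pick one
    oversampled = {}
    reports = {}
    try:
        for method in ("smote", "adasyn"):
            oversampled[method] = oversample_pipeline(
                train, schema,
                OversampleConfig(method=method, k_neighbours=config.k_neighbours,
                                 seed=child_seed(config.seed, f"oversample_{method}")),
            )
    except Exception as exc:
        _fail("oversampling", exc)
    try:
        for method, over in oversampled.items():
            reports[method] = assess_oversampling(
                train, over, schema, method,
                spearman_threshold=config.spearman_threshold_pmse,
                variance_threshold=config.variance_threshold,
                population=config.pmse_population,
            )
    except Exception as exc:
        _fail("utility", exc)
    chosen = select_oversampler(reports["smote"], reports["adasyn"])
    over_train = oversampled[chosen]
    manifest["utility"] = {m: {"pmse": r.pmse, "c": r.c, "n": r.n}
                           for m, r in reports.items()}
    manifest["chosen_oversampler"] = chosen
    manifest["oversampled_rows"] = len(over_train)

    # 6: filtering cascade + z-score, fitted on the oversampled training set
    try:
        prep = preprocess(
            over_train, schema,
            variance_threshold=config.variance_threshold,
            spearman_threshold=config.spearman_threshold_model,
        )
    except Exception as exc:
        _fail("preprocessing", exc)
    manifest["filter_trace"] = prep.trace.to_dict()

    # 7-8: tune all families, pick the best on the test set
    try:
        X, y = _automl.design_matrix(prep.table, prep.trace.selected)
        models = _automl.train_all(
            X, y, folds=config.automl_folds, max_iter=config.automl_max_iter,
            patience=config.automl_patience,
            seed=child_seed(config.seed, "automl"),
            families=config.families,
        )
    except Exception as exc:
        _fail("automl", exc)
    try:
        test_prep = apply_preprocessing(test, prep.trace.selected, prep.params)
        X_test, _ = _automl.design_matrix(test_prep, prep.trace.selected)
        best, test_table = _automl.select_best(models, X_test, list(test.endpoint))
    except Exception as exc:
        _fail("model_selection", exc)
    best.selected = prep.trace.selected
    best.norm = prep.params
    manifest["cv_kappa"] = {m.family: m.cv_kappa for m in models}
    manifest["hyperparameters"] = {m.family: _jsonable(m.params) for m in models}
    manifest["test_metrics"] = {f: r.to_dict() for f, r in test_table.items()}
    manifest["best_family"] = best.family

    # 9: blind evaluation — the blind set's only use
    try:
        blind_prep = apply_preprocessing(blind, prep.trace.selected, prep.params)
        X_blind, _ = _automl.design_matrix(blind_prep, prep.trace.selected)
        blind_report = evaluate(list(blind.endpoint), best.predict_labels(X_blind))
    except Exception as exc:
        _fail("blind_evaluation", exc)
    manifest["blind_metrics"] = blind_report.to_dict()

    # 10: applicability domain on the modelling training set
    try:
        ad_base = over_train if config.ad_on_oversampled else train
        ad_dedup, _ = dedupe(ad_base, prep.trace.selected)
        categorical = [c for c in prep.trace.selected
                       if c in set(schema.categorical_names)]
        ad_table = TreatmentTable(
            ad_dedup.data[[c for c in ad_dedup.data.columns
                           if c in set(prep.trace.selected)
                           or c not in set(ad_dedup.descriptor_columns)]].copy()
        )
        ad_model = fit_ad(
            ad_table, prep.params, categorical_columns=categorical,
            k_neighbours=config.ad_k_neighbours,
            sim_threshold=config.ad_sim_threshold,
            weights=config.ad_weights,
        )
        blind_ad = assess(blind, ad_model)
    except Exception as exc:
        _fail("applicability_domain", exc)
    manifest["ad"] = {
        "h_star": ad_model.h_star,
        "n_train": ad_model.n_train,
        "k_descriptors": ad_model.n_descriptors,
        "blind_inside_bb": int(blind_ad["ad_bb"].sum()),
        "blind_inside_lev": int(blind_ad["ad_lev"].sum()),
        "blind_inside_sim": int(blind_ad["ad_sim"].sum()),
    }

    # 11: Y-randomisation with the winning family
    try:
        y_reports = y_randomisation(
            train, test, schema, best.family,
            n_rounds=config.y_randomisation_rounds,
            seed=child_seed(config.seed, "y_randomisation"),
            oversample_method=chosen,
            retune=config.y_randomisation_retune,
            fixed_params=best.params,
            automl_options={
                "folds": config.automl_folds,
                "max_iter": config.automl_max_iter,
                "patience": config.automl_patience,
            },
        )
    except Exception as exc:
        _fail("y_randomisation", exc)
    manifest["y_randomisation"] = [
        {"accuracy": r.accuracy, "mcc": r.mcc} for r in y_reports
    ]

    result = PipelineResult(
        config=config, chosen_method=chosen, utility_reports=reports,
        trace=prep.trace, params=prep.params, best_model=best,
        test_metrics={f: r for f, r in test_table.items()},
        blind_metrics=blind_report.to_dict(), ad_model=ad_model,
        blind_ad=blind_ad, y_random_reports=y_reports, manifest=manifest,
        run_dir=run_dir,
    )
    if run_dir is not None:
        _write_artifacts(result, schema, train, test, blind, over_train)
    return result


def _write_artifacts(result: PipelineResult, schema, train, test, blind, over_train):
    d = result.run_dir
    for name, tab in (("train", train), ("test", test), ("blind", blind),
                      ("train_oversampled", over_train)):
        tab.save(d / f"{name}.csv")
    schema.save(d / "schema.yaml")
    with open(d / "manifest.json", "w") as fh:
        json.dump(_jsonable(result.manifest), fh, indent=2, sort_keys=True)
    save_model(d / "model", result.best_model, result.trace, result.params, schema,
               result.ad_model)
    result.blind_ad.to_csv(d / "blind_ad.csv", index=False)


def save_model(model_dir, tuned: _automl.TunedModel, trace: FilterTrace,
               params: NormalisationParams, schema: DescriptorSchema,
               ad_model: ADModel | None = None) -> None:
    """Serialize a tuned model + frozen preprocessing for later prediction."""
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "family": tuned.family,
        "hyperparameters": _jsonable(tuned.params),
        "cv_kappa": tuned.cv_kappa,
        "selected": trace.selected,
        "normalisation": params.to_dict(),
        "filter_trace": trace.to_dict(),
        "schema_hash": schema_hash(schema),
    }
    with open(model_dir / "model.json", "w") as fh:
        json.dump(_jsonable(meta), fh, indent=2, sort_keys=True)
    schema.save(model_dir / "schema.yaml")
    joblib.dump(tuned.estimator, model_dir / "estimator.joblib")
    if ad_model is not None:
        joblib.dump(ad_model, model_dir / "ad_model.joblib")


def load_model(model_dir):
    """Load a serialized model directory -> (TunedModel, trace-dict, schema, ADModel|None)."""
    model_dir = Path(model_dir)
    with open(model_dir / "model.json") as fh:
        meta = json.load(fh)
    schema = DescriptorSchema.load(model_dir / "schema.yaml")
    if meta["schema_hash"] != schema_hash(schema):
        raise ValueError("schema hash mismatch: model directory is inconsistent")
    tuned = _automl.TunedModel(
        family=meta["family"], params=meta["hyperparameters"],
        cv_kappa=meta["cv_kappa"],
        estimator=joblib.load(model_dir / "estimator.joblib"),
        selected=meta["selected"],
        norm=NormalisationParams.from_dict(meta["normalisation"]),
    )
    ad_path = model_dir / "ad_model.joblib"
    ad_model = joblib.load(ad_path) if ad_path.exists() else None
    return tuned, meta, schema, ad_model


def predict(model_dir, query: TreatmentTable) -> "object":
    """Predict endpoint class + AD reliability for each query treatment."""
    import pandas as pd

    tuned, meta, schema, ad_model = load_model(model_dir)
    prep = apply_preprocessing(query, tuned.selected, tuned.norm)
    X, _ = _automl.design_matrix(prep, tuned.selected)
    proba = tuned.predict_proba_positive(X)
    labels = tuned.predict_labels(X)
    out = pd.DataFrame({
        "treatment_id": query.data["treatment_id"],
        "predicted_class": labels,
        "probability": proba,
    })
    if ad_model is not None:
        ad = assess(query, ad_model).drop(columns=["treatment_id"])
        ad = ad.rename(columns={"score": "reliability_score",
                                "label": "reliability_label"})
        out = pd.concat([out, ad], axis=1)
    return out
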
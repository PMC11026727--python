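"""Synthetic treatment-table generator.

Emulates the statistical shape of a small nano-toxicity dose–response
study — a handful of nanoparticles, each exposed at a log-spaced grid of
concentrations, with correlated per-NP atomistic descriptors, a few
interdependent (difference) descriptors, a class imbalance of roughly
2:1 low:high, and a monotone dose-plus-descriptor signal driving the
endpoint.  Everything downstream is testable against these tables
without any external download.  No attempt is made to mimic real
descriptor physics; only the statistical structure matters here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .core_data import (
    ColumnSpec,
    DerivedRule,
    DescriptorSchema,
    TreatmentTable,
)
from .validation import ConfusionCounts, metrics as _metrics

CONCENTRATION_COLUMN = "concentration"


@dataclass
class FixtureConfig:
    """Knobs of the generator; defaults emulate the study-sized dataset.

    11 NPs x 10 concentrations = 110 treatments with ~34% "high effect"
    rows.  ``correlation_strength`` is the shared-factor variance
    fraction of the base descriptors; at exactly 1.0 two columns become
    exact duplicates of two others so duplicate/correlation filter paths
    can be exercised.
    """

    n_nps: int = 11
    n_concentrations: int = 10
    imbalance: float = 0.34
    n_descriptors: int = 10
    n_derived: int = 3
    correlation_strength: float = 0.6
    signal_descriptors: list[str] = field(default_factory=lambda: ["desc_01"])
    noise_sd: float = 0.5
    conc_weight: float = 1.8
    signal_weight: float = 1.2
    include_coating: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.imbalance < 1.0:
            raise ValueError("imbalance must lie in (0, 1)")
        if self.n_derived >= self.n_descriptors:
            raise ValueError("n_derived must be smaller than n_descriptors")
        if not 0.0 <= self.correlation_strength <= 1.0:
            raise ValueError("correlation_strength must lie in [0, 1]")
        n = self.n_nps * self.n_concentrations
        if round(self.imbalance * n) < 1 or round(self.imbalance * n) >= n:
            raise ValueError("imbalance infeasible for this table size")


def _build_schema(config: FixtureConfig) -> DescriptorSchema:
    n_base = config.n_descriptors - config.n_derived
    base = [f"desc_{i + 1:02d}" for i in range(n_base)]
    derived = [f"desc_diff_{i + 1:02d}" for i in range(config.n_derived)]
    columns = [ColumnSpec(CONCENTRATION_COLUMN, "numeric", "ug/mL")]
    columns += [ColumnSpec(name, "numeric") for name in base + derived]
    if config.include_coating:
        columns.append(ColumnSpec("coating", "categorical"))
    # difference rules pair consecutive base columns, cycling if short
    rules = [
        DerivedRule(
            target=derived[i],
            op="difference",
            a=base[(2 * i) % n_base],
            b=base[(2 * i + 1) % n_base],
        )
        for i in range(config.n_derived)
    ]
    return DescriptorSchema(columns=columns, derived_rules=rules)


def generate_dataset(config: FixtureConfig | None = None) -> tuple[TreatmentTable, DescriptorSchema]:
    """Generate a treatment table and its schema, fully seed-deterministic.

    Per-NP base descriptors follow a one-factor model with loading
    sqrt(correlation_strength); the endpoint is the top
    ``round(imbalance * n)`` rows of a latent score monotone in
    log-concentration and the signal descriptors, plus Gaussian noise.
    """
    config = config or FixtureConfig()
    schema = _build_schema(config)
    rng = child_rng(config.seed, "fixtures")
    n_base = config.n_descriptors - config.n_derived
    base_names = [f"desc_{i + 1:02d}" for i in range(n_base)]
    for name in config.signal_descriptors:
        if name not in base_names:
            raise ValueError(f"signal descriptor {name!r} is not a generated base column")

    rho = config.correlation_strength
    factor = rng.normal(size=config.n_nps)
    loadings = rng.uniform(0.5, 1.0, size=n_base) * rng.choice([-1.0, 1.0], size=n_base)
    noise = rng.normal(size=(config.n_nps, n_base))
    base = np.sqrt(rho) * factor[:, None] * loadings[None, :] + np.sqrt(1 - rho) * noise
    if rho == 1.0 and n_base >= 4:
        # exact duplicate columns to exercise dedup/correlation paths
        base[:, -1] = base[:, 0]
        base[:, -2] = base[:, 1]

    concs = np.logspace(-1, 2, config.n_concentrations)  # 0.1 .. 100 ug/mL
    rows = []
    for i in range(config.n_nps):
        for c in concs:
            row = {"treatment_id": f"NP{i + 1:03d}@{c:.4g}", "np_id": f"NP{i + 1:03d}",
                   CONCENTRATION_COLUMN: c}
            row.update({name: base[i, j] for j, name in enumerate(base_names)})
            if config.include_coating:
                row["coating"] = "coated" if i % 2 == 0 else "uncoated"
            rows.append(row)
    df = pd.DataFrame(rows)

    for rule in schema.derived_rules:
        df[rule.target] = rule.evaluate(
            df[rule.a].to_numpy(float), df[rule.b].to_numpy(float)
        )

    logc = np.log10(df[CONCENTRATION_COLUMN].to_numpy(float))
    score = config.conc_weight * (logc - logc.mean()) / logc.std()
    for name in config.signal_descriptors:
        x = df[name].to_numpy(float)
        sd = x.std() or 1.0
        score = score + config.signal_weight * (x - x.mean()) / sd
    score = score + config.noise_sd * rng.normal(size=len(df))

    n = len(df)
    n_high = int(round(config.imbalance * n))
    order = np.argsort(-score, kind="stable")
    labels = np.array(["low"] * n, dtype=object)
    labels[order[:n_high]] = "high"
    df["endpoint"] = labels
    df["provenance"] = "original"
    return TreatmentTable(df), schema


#: Printed two-decimal worked-example metrics used to reconstruct the
#: unique confusion matrices of the reference study's blind and test
#: evaluations (order: accuracy, kappa, recall, precision, specificity,
#: MCC), together with set size and positive count.
WORKED_EXAMPLES = {
    "blind": {"n": 33, "n_pos": 11,
              "printed": {"accuracy": 0.88, "kappa": 0.74, "recall": 0.91,
                          "precision": 0.77, "specificity": 0.86, "mcc": 0.75}},
    "test": {"n": 20, "n_pos": 7,
             "printed": {"accuracy": 0.95, "kappa": 0.89, "recall": 1.00,
                         "precision": 0.88, "specificity": 0.92, "mcc": 0.90}},
}


def worked_confusion(name: str) -> ConfusionCounts:
    """Reconstruct a worked-example confusion matrix by enumeration.

    Searches all integer (TP, FP) pairs consistent with the set size and
    positive count, and returns the unique matrix whose six metrics
    round to the printed two-decimal values.
    """
    if name not in WORKED_EXAMPLES:
        raise ValueError(f"unknown worked example {name!r}")
    spec = WORKED_EXAMPLES[name]
    n, n_pos = spec["n"], spec["n_pos"]
    n_neg = n - n_pos
    hits = []
    for tp in range(n_pos + 1):
        for fp in range(n_neg + 1):
            c = ConfusionCounts(tp=tp, fp=fp, fn=n_pos - tp, tn=n_neg - fp)
            with warnings.catch_warnings():
                # degenerate candidates legitimately have undefined ratios
                warnings.simplefilter("ignore")
                rep = _metrics(c)
            vals = {"accuracy": rep.accuracy, "kappa": rep.kappa, "recall": rep.recall,
                    "precision": rep.precision, "specificity": rep.specificity,
                    "mcc": rep.mcc}
            if any(v is None for v in vals.values()):
                continue
            # half-away-from-zero rounding admits |v - printed| == 0.005
            if all(abs(vals[k] - v) <= 0.005 + 1e-9 for k, v in spec["printed"].items()):
                hits.append(c)
    if len(hits) != 1:
        raise RuntimeError(
            f"expected a unique confusion matrix for {name!r}, found {len(hits)}"
        )
    return hits[0]
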
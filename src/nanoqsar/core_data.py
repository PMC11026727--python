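"""Data model for nanoparticle (NP) treatment tables.

A *treatment* is one (nanoparticle, exposure concentration) pair with a
vector of physicochemical/atomistic descriptors and a binary toxicity
endpoint (``low`` / ``high`` effect).  This module holds the tabular
container, CSV/schema I/O, stratified splitting, z-score normalisation
and the recalculation of interdependent (derived) descriptors — the
plumbing every downstream stage builds on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Columns that are metadata, never descriptors.
RESERVED_COLUMNS = ("treatment_id", "np_id", "endpoint", "provenance")

#: Admissible endpoint labels; "high" is the positive (toxic) class.
ENDPOINT_LABELS = ("low", "high")
POSITIVE_CLASS = "high"
NEGATIVE_CLASS = "low"


class SchemaError(ValueError):
    """Raised when a descriptor schema is internally inconsistent."""


class DataError(ValueError):
    """Raised when a treatment table violates its contract."""


@dataclass(frozen=True)
class ColumnSpec:
    """One descriptor column: name, kind and (free-text) units."""

    name: str
    kind: str  # "numeric" | "categorical"
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise SchemaError(f"unknown column kind {self.kind!r} for {self.name!r}")


@dataclass(frozen=True)
class DerivedRule:
    """A derived descriptor defined as difference(a, b) or ratio(a, b)."""

    target: str
    op: str  # "difference" | "ratio"
    a: str
    b: str

    def __post_init__(self) -> None:
        if self.op not in ("difference", "ratio"):
            raise SchemaError(f"unknown derived-rule op {self.op!r}")

    def evaluate(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        if self.op == "difference":
            return a - b
        with np.errstate(divide="ignore", invalid="ignore"):
            out = a / b
        return np.where(b == 0, np.nan, out)


@dataclass
class DescriptorSchema:
    """Ordered descriptor columns plus rules for interdependent columns.

    Derived descriptors (core–shell differences, ratios) never take part
    in interpolation-based oversampling; they are recomputed from their
    source columns afterwards, so the rules must be acyclic and refer
    only to existing columns.
    """

    columns: list[ColumnSpec]
    derived_rules: list[DerivedRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate column names in schema")
        known = set(names)
        targets = {r.target for r in self.derived_rules}
        if len(targets) != len(self.derived_rules):
            raise SchemaError("multiple rules for one target column")
        for r in self.derived_rules:
            for ref in (r.target, r.a, r.b):
                if ref not in known:
                    raise SchemaError(f"rule references unknown column {ref!r}")
            # a derived column may not feed another derived column: keeps
            # the dependency graph trivially acyclic
            if r.a in targets or r.b in targets:
                raise SchemaError(
                    f"rule for {r.target!r} depends on another derived column"
                )

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def numeric_names(self) -> list[str]:
        return [c.name for c in self.columns if c.kind == "numeric"]

    @property
    def categorical_names(self) -> list[str]:
        return [c.name for c in self.columns if c.kind == "categorical"]

    @property
    def derived_names(self) -> list[str]:
        return [r.target for r in self.derived_rules]

    def to_dict(self) -> dict:
        return {
            "columns": [
                {"name": c.name, "kind": c.kind, "units": c.units}
                for c in self.columns
            ],
            "derived_rules": [
                {"target": r.target, "op": r.op, "a": r.a, "b": r.b}
                for r in self.derived_rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorSchema":
        return cls(
            columns=[ColumnSpec(**c) for c in d.get("columns", [])],
            derived_rules=[DerivedRule(**r) for r in d.get("derived_rules", [])],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "DescriptorSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TreatmentTable:
    """Rectangular table of NP treatments.

    ``data`` holds one row per treatment with the reserved metadata
    columns (:data:`RESERVED_COLUMNS`) plus one column per descriptor.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("treatment_id", "endpoint"):
            if col not in self.data.columns:
                raise DataError(f"missing required column {col!r}")
        if "provenance" not in self.data.columns:
            self.data = self.data.assign(provenance="original")
        if "np_id" not in self.data.columns:
            self.data = self.data.assign(np_id=self.data["treatment_id"])
        bad = set(self.data["endpoint"]) - set(ENDPOINT_LABELS)
        if bad:
            raise DataError(f"unknown endpoint labels {sorted(bad)}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def descriptor_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in RESERVED_COLUMNS]

    @property
    def endpoint(self) -> pd.Series:
        return self.data["endpoint"]

    def class_counts(self) -> dict[str, int]:
        counts = self.data["endpoint"].value_counts()
        return {lab: int(counts.get(lab, 0)) for lab in ENDPOINT_LABELS}

    def descriptors(self, columns: list[str] | None = None) -> pd.DataFrame:
        return self.data[columns if columns is not None else self.descriptor_columns]

    def subset(self, mask) -> "TreatmentTable":
        return TreatmentTable(self.data.loc[mask].reset_index(drop=True).copy())

    def copy(self) -> "TreatmentTable":
        return TreatmentTable(self.data.copy())

    def save(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class NormalisationParams:
    """Per-column training mean/sd for z-score scaling.

    Columns with zero training spread are flagged and passed through
    unscaled in both directions.
    """

    mean: dict[str, float]
    sd: dict[str, float]

    @property
    def zero_sd_columns(self) -> list[str]:
        return [c for c, s in self.sd.items() if s == 0.0]

    @property
    def columns(self) -> list[str]:
        return list(self.mean)

    def to_dict(self) -> dict:
        return {"mean": dict(self.mean), "sd": dict(self.sd)}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalisationParams":
        return cls(mean=dict(d["mean"]), sd=dict(d["sd"]))


@dataclass
class SplitResult:
    """An exact stratified partition into train and held-out rows."""

    train: TreatmentTable
    held_out: TreatmentTable
    seed: int
    fraction: float


def load_dataset(path, schema: DescriptorSchema, endpoint_column: str = "endpoint") -> TreatmentTable:
    """Read a treatment table from CSV, validating it against *schema*.

    All loaded rows get ``provenance="original"``.  Non-numeric cells in
    numeric descriptor columns raise with the offending row and column.
    """
    df = pd.read_csv(path, dtype=str)
    if endpoint_column != "endpoint":
        if endpoint_column not in df.columns:
            raise DataError(f"missing endpoint column {endpoint_column!r}")
        df = df.rename(columns={endpoint_column: "endpoint"})
    if "endpoint" not in df.columns:
        raise DataError("missing endpoint column 'endpoint'")
    if len(df) == 0:
        raise DataError("no treatments in file")
    missing = [c for c in schema.names if c not in df.columns]
    if missing:
        raise DataError(f"file header missing schema columns {missing}")
    if df["treatment_id"].duplicated().any():
        dup = df.loc[df["treatment_id"].duplicated(), "treatment_id"].iloc[0]
        raise DataError(f"duplicate treatment_id {dup!r}")
    for col in schema.numeric_names:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise DataError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, row {row}"
            )
        df[col] = parsed
    df["provenance"] = "original"
    return TreatmentTable(df)


def _heldout_count(fraction: float, n: int) -> int:
    """round(fraction*n) with halves rounded away from zero."""
    x = fraction * n
    return int(np.floor(x + 0.5))


def stratified_split(table: TreatmentTable, fraction: float, seed: int) -> SplitResult:
    """Split off a held-out fraction, stratified by endpoint class.

    Per class the held-out count is ``round(fraction * class_count)``
    (ties away from zero), sampled without replacement; the result is an
    exact partition, deterministic for a fixed seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    held_idx: list[np.ndarray] = []
    for label in ENDPOINT_LABELS:
        idx = np.flatnonzero(table.data["endpoint"].to_numpy() == label)
        if len(idx) < 2:
            raise DataError(f"class {label!r} has fewer than 2 rows")
        k = _heldout_count(fraction, len(idx))
        if k >= len(idx):
            raise DataError(f"class {label!r} would be empty in the training set")
        held_idx.append(rng.choice(idx, size=k, replace=False))
    held = np.sort(np.concatenate(held_idx))
    mask = np.zeros(len(table), dtype=bool)
    mask[held] = True
    return SplitResult(
        train=table.subset(~mask),
        held_out=table.subset(mask),
        seed=seed,
        fraction=fraction,
    )


def fit_normaliser(train: TreatmentTable, columns: list[str] | None = None) -> NormalisationParams:
    """Learn per-column z-score parameters (sample sd, n−1) on training rows."""
    if len(train) == 0:
        raise DataError("cannot fit normaliser on an empty table")
    if columns is None:
        columns = [
            c
            for c in train.descriptor_columns
            if pd.api.types.is_numeric_dtype(train.data[c])
        ]
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for col in columns:
        x = train.data[col].to_numpy(dtype=float)
        mean[col] = float(np.nanmean(x))
        s = float(np.nanstd(x, ddof=1)) if len(x) > 1 else 0.0
        sd[col] = s
        if s == 0.0:
            logger.warning("column %r has zero training sd; passed through unscaled", col)
    return NormalisationParams(mean=mean, sd=sd)


def transform(
    table: TreatmentTable, params: NormalisationParams, direction: str = "forward"
) -> TreatmentTable:
    """Apply (or invert) the z-score transform columnwise.

    ``forward`` maps x to (x − mean)/sd, ``inverse`` maps back; columns
    flagged with sd = 0 pass through unchanged so the round trip is the
    identity for every column.
    """
    if direction not in ("forward", "inverse"):
        raise ValueError("direction must be 'forward' or 'inverse'")
    out = table.data.copy()
    for col in params.columns:
        if col not in out.columns:
            raise DataError(f"normaliser column {col!r} absent from table")
        m, s = params.mean[col], params.sd[col]
        if s == 0.0:
            continue
        x = out[col].to_numpy(dtype=float)
        out[col] = (x - m) / s if direction == "forward" else x * s + m
    return TreatmentTable(out)


def recalc_derived(table: TreatmentTable, schema: DescriptorSchema) -> TreatmentTable:
    """Overwrite derived descriptor columns from their source columns.

    Ratio rules with a zero denominator yield a missing value and a
    warning; non-derived columns are untouched.
    """
    out = table.data.copy()
    for rule in schema.derived_rules:
        for src in (rule.a, rule.b):
            if src not in out.columns:
                raise DataError(f"derived rule source column {src!r} missing")
        a = out[rule.a].to_numpy(dtype=float)
        b = out[rule.b].to_numpy(dtype=float)
        vals = rule.evaluate(a, b)
        if rule.op == "ratio" and np.any(b == 0):
            warnings.warn(
                f"zero denominator in ratio rule for {rule.target!r}; "
                "affected rows set to missing",
                stacklevel=2,
            )
        out[rule.target] = vals
    return TreatmentTable(out)
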
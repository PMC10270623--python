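"""Typed cohort data model: schema, CSV/YAML I/O, synthetic generation, train/test split.

A :class:`Cohort` is a rectangular table of fully observed, schema-conforming
feature values, one row per patient.  The synthetic generator draws numeric
features from truncated normals and categorical features from explicit level
probabilities, optionally planting latent cluster structure through per-cluster
mean shifts (in SD units) and level-probability offsets.  Hidden cluster labels
are kept alongside the table for parameter-recovery experiments but are never
written to disk and never visible to downstream pipelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ParameterizationError, SchemaError, ValidationError

VALID_DTYPES = ("numeric", "ordinal", "binary", "categorical")


@dataclass(frozen=True)
class Feature:
    """One column of the cohort schema.

    ``levels`` is required (ordered) for ordinal features, and the level list
    for binary/categorical features; it must be ``None`` for numeric features.
    """

    name: str
    dtype: str
    levels: tuple[str, ...] | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.dtype not in VALID_DTYPES:
            raise SchemaError(f"feature {self.name!r}: unknown dtype {self.dtype!r}")
        if self.dtype == "numeric":
            if self.levels is not None:
                raise SchemaError(f"numeric feature {self.name!r} must not define levels")
            return
        if self.levels is None or len(self.levels) < 2:
            raise SchemaError(f"feature {self.name!r}: needs >= 2 levels")
        if self.dtype == "binary" and len(self.levels) != 2:
            raise SchemaError(f"binary feature {self.name!r}: exactly 2 levels required")
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"feature {self.name!r}: duplicate levels")

    @property
    def is_categorical_like(self) -> bool:
        return self.dtype in ("ordinal", "binary", "categorical")


class FeatureSchema:
    """Ordered collection of :class:`Feature` definitions with unique names."""

    def __init__(self, features: list[Feature] | tuple[Feature, ...]):
        features = list(features)
        names = [f.name for f in features]
        if len(set(names)) != len(names):
            raise SchemaError("feature names must be unique")
        self._features = features
        self._by_name = {f.name: f for f in features}

    def __iter__(self):
        return iter(self._features)

    def __len__(self) -> int:
        return len(self._features)

    def __getitem__(self, name: str) -> Feature:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureSchema) and self._features == other._features

    @property
    def names(self) -> list[str]:
        return [f.name for f in self._features]

    def of_dtype(self, *dtypes: str) -> list[str]:
        return [f.name for f in self._features if f.dtype in dtypes]

    @property
    def numeric_names(self) -> list[str]:
        return self.of_dtype("numeric")

    @property
    def categorical_like_names(self) -> list[str]:
        """All non-numeric features (ordinal, binary, categorical) in schema order."""
        return [f.name for f in self._features if f.is_categorical_like]

    def to_yaml(self, path) -> None:
        entries = []
        for f in self:
            entry: dict = {"name": f.name, "dtype": f.dtype}
            if f.levels is not None:
                entry["levels"] = list(f.levels)
            if f.units:
                entry["units"] = f.units
            entries.append(entry)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"features": entries}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "features" not in raw:
            raise SchemaError(f"{path}: expected a mapping with a 'features' list")
        feats = []
        for entry in raw["features"]:
            levels = entry.get("levels")
            feats.append(
                Feature(
                    name=str(entry["name"]),
                    dtype=str(entry["dtype"]),
                    levels=tuple(str(x) for x in levels) if levels is not None else None,
                    units=str(entry.get("units", "")),
                )
            )
        return cls(feats)


class Cohort:
    """A fully observed patient table conforming to a :class:`FeatureSchema`.

    The table index holds unique patient identifiers.  ``hidden_labels`` (if
    present) are planted cluster assignments used only for evaluation; they are
    deliberately excluded from file output.
    """

    def __init__(self, table: pd.DataFrame, schema: FeatureSchema,
                 hidden_labels: np.ndarray | None = None):
        self.schema = schema
        self.table = table
        self.hidden_labels = hidden_labels
        self._validate()

    def _validate(self) -> None:
        if list(self.table.columns) != self.schema.names:
            raise ValidationError(
                f"columns {list(self.table.columns)} do not match schema {self.schema.names}")
        if self.table.index.has_duplicates:
            raise ValidationError("patient ids must be unique")
        for name in self.schema.names:
            col = self.table[name]
            feat = self.schema[name]
            if col.isna().any():
                row = col.index[col.isna()][0]
                raise ValidationError(f"missing value at row {row!r}, column {name!r}")
            if feat.dtype == "numeric":
                if not pd.api.types.is_numeric_dtype(col):
                    raise ValidationError(f"column {name!r} must be numeric")
            else:
                bad = ~col.isin(feat.levels)
                if bad.any():
                    row = col.index[bad][0]
                    raise ValidationError(
                        f"row {row!r}, column {name!r}: level {col[row]!r} not in schema "
                        f"levels {list(feat.levels)}")
        if self.hidden_labels is not None and len(self.hidden_labels) != len(self.table):
            raise ValidationError("hidden_labels length mismatch")

    @property
    def m(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list:
        return list(self.table.index)

    def subset(self, ids) -> "Cohort":
        positions = self.table.index.get_indexer(ids)
        labels = self.hidden_labels[positions] if self.hidden_labels is not None else None
        return Cohort(self.table.loc[ids].copy(), self.schema, labels)


@dataclass(frozen=True)
class NumericSpec:
    """Truncated-normal parameters for one numeric feature."""

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ParameterizationError(f"sd must be positive, got {self.sd}")
        if not self.lower < self.upper:
            raise ParameterizationError("lower bound must be below upper bound")


@dataclass
class CohortSpec:
    """Generative description of a synthetic cohort.

    ``level_probs`` maps each non-numeric feature to probabilities aligned with
    its schema levels.  With ``k_planted > 0``, ``numeric_shifts`` gives
    per-cluster mean shifts in SD units and ``prevalence_offsets`` per-cluster
    additive offsets on the probability of the *last* schema level (the
    remaining levels are rescaled proportionally).
    """

    schema: FeatureSchema
    m: int
    numeric: dict[str, NumericSpec] = field(default_factory=dict)
    level_probs: dict[str, tuple[float, ...]] = field(default_factory=dict)
    k_planted: int = 0
    numeric_shifts: dict[str, tuple[float, ...]] = field(default_factory=dict)
    prevalence_offsets: dict[str, tuple[float, ...]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.m < 2:
            raise ParameterizationError(f"m must be >= 2, got {self.m}")
        for name in self.schema.numeric_names:
            if name not in self.numeric:
                raise ParameterizationError(f"missing NumericSpec for {name!r}")
        for name in self.schema.categorical_like_names:
            probs = self.level_probs.get(name)
            feat = self.schema[name]
            if probs is None or len(probs) != len(feat.levels):
                raise ParameterizationError(f"level_probs for {name!r} must match level count")
            arr = np.asarray(probs, dtype=float)
            if (arr < 0).any() or (arr > 1).any():
                raise ParameterizationError(f"level_probs for {name!r} outside [0, 1]")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ParameterizationError(f"level_probs for {name!r} must sum to 1")
        for effects in (self.numeric_shifts, self.prevalence_offsets):
            for name, vals in effects.items():
                if name not in self.schema:
                    raise ParameterizationError(f"effect for unknown feature {name!r}")
                if self.k_planted and len(vals) != self.k_planted:
                    raise ParameterizationError(
                        f"effect for {name!r} must list one value per planted cluster")


@dataclass
class SplitCohort:
    """Disjoint train/test partition of a parent cohort."""

    train: Cohort
    test: Cohort
    fraction: float
    seed: int


def _shifted_probs(probs: np.ndarray, offset: float) -> np.ndarray:
    """Offset the last-level probability and rescale the rest proportionally."""
    p_last = probs[-1]
    p_new = float(np.clip(p_last + offset, 0.0, 1.0))
    out = probs.copy()
    if p_last < 1.0:
        out[:-1] = probs[:-1] * (1.0 - p_new) / (1.0 - p_last)
    else:
        out[:-1] = (1.0 - p_new) / (len(probs) - 1)
    out[-1] = p_new
    return out / out.sum()


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a synthetic cohort from ``spec`` (deterministic given ``spec.seed``)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    m = spec.m
    labels = rng.integers(0, spec.k_planted, size=m) if spec.k_planted > 0 else None

    data: dict[str, np.ndarray] = {}
    for feat in spec.schema:
        if feat.dtype == "numeric":
            ns = spec.numeric[feat.name]
            shifts = spec.numeric_shifts.get(feat.name)
            if labels is None or shifts is None:
                a = (ns.lower - ns.mean) / ns.sd
                b = (ns.upper - ns.mean) / ns.sd
                col = stats.truncnorm.rvs(a, b, loc=ns.mean, scale=ns.sd,
                                          size=m, random_state=rng)
            else:
                col = np.empty(m, dtype=float)
                for cl in range(spec.k_planted):
                    mask = labels == cl
                    loc = ns.mean + shifts[cl] * ns.sd
                    a = (ns.lower - loc) / ns.sd
                    b = (ns.upper - loc) / ns.sd
                    col[mask] = stats.truncnorm.rvs(a, b, loc=loc, scale=ns.sd,
                                                    size=int(mask.sum()), random_state=rng)
            data[feat.name] = col
        else:
            base = np.asarray(spec.level_probs[feat.name], dtype=float)
            offsets = spec.prevalence_offsets.get(feat.name)
            levels = np.asarray(feat.levels, dtype=object)
            if labels is None or offsets is None:
                col = rng.choice(levels, size=m, p=base / base.sum())
            else:
                col = np.empty(m, dtype=object)
                for cl in range(spec.k_planted):
                    mask = labels == cl
                    col[mask] = rng.choice(levels, size=int(mask.sum()),
                                           p=_shifted_probs(base, offsets[cl]))
            data[feat.name] = col

    ids = [f"P{i:06d}" for i in range(m)]
    table = pd.DataFrame(data, index=pd.Index(ids, name="patient_id"),
                         columns=spec.schema.names)
    return Cohort(table, spec.schema, hidden_labels=labels)


def split_train_test(cohort: Cohort, fraction: float = 0.7516, seed: int = 0) -> SplitCohort:
    """Seeded random partition; train size is ``round(fraction * m)``."""
    if not 0.0 < fraction < 1.0:
        raise ParameterizationError(f"fraction must be in (0, 1), got {fraction}")
    if cohort.m < 2:
        raise ParameterizationError("cohort must have at least 2 patients")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(cohort.m)
    n_train = int(math.floor(fraction * cohort.m + 0.5))
    n_train = min(max(n_train, 1), cohort.m - 1)
    train_pos = np.sort(perm[:n_train])
    test_pos = np.sort(perm[n_train:])
    ids = np.asarray(cohort.ids, dtype=object)
    return SplitCohort(
        train=cohort.subset(list(ids[train_pos])),
        test=cohort.subset(list(ids[test_pos])),
        fraction=fraction,
        seed=seed,
    )


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort table as UTF-8 CSV with ``patient_id`` as first column."""
    cohort.table.to_csv(path, index_label="patient_id", encoding="utf-8")


def read_cohort(path, schema: FeatureSchema) -> Cohort:
    """Read and validate a cohort CSV; any missing cell or unknown level is rejected."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if "patient_id" not in raw.columns:
        raise ValidationError(f"{path}: first column must be 'patient_id'")
    raw = raw.set_index("patient_id")
    if list(raw.columns) != schema.names:
        raise ValidationError(
            f"{path}: header {list(raw.columns)} does not match schema {schema.names}")
    cols: dict[str, pd.Series] = {}
    for name in schema.names:
        col = raw[name]
        empty = col.str.strip() == ""
        if empty.any():
            row = col.index[empty][0]
            raise ValidationError(f"{path}: missing value at row {row!r}, column {name!r}")
        if schema[name].dtype == "numeric":
            try:
                col = pd.to_numeric(col)
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"{path}: non-numeric value in column {name!r}") from exc
        cols[name] = col
    table = pd.DataFrame(cols, index=raw.index, columns=schema.names)
    return Cohort(table, schema)


# ---------------------------------------------------------------------------
# Presets


def planted_spec(m: int, seed: int = 0, k: int = 3, shift: float = 3.0,
                 offset: float = 0.3, n_numeric: int = 8, n_binary: int = 6) -> CohortSpec:
    """Mixed-type cohort with k planted clusters for parameter-recovery studies.

    Numeric features are unit-normal with per-cluster mean shifts of ``shift``
    SDs; binary features have base prevalence 0.5 offset by ``offset`` per
    cluster; one 4-level ordinal feature is offset on its top level.  Shift and
    offset patterns are rotated across features so every cluster pair is
    separated on several features.
    """
    feats = [Feature(f"n{i}", "numeric") for i in range(1, n_numeric + 1)]
    feats.append(Feature("ord1", "ordinal", ("l1", "l2", "l3", "l4")))
    feats += [Feature(f"b{i}", "binary", ("no", "yes")) for i in range(1, n_binary + 1)]
    base_shift = [0.0] * k
    num_patterns = []
    for i in range(max(k, 4)):
        pat = list(base_shift)
        pat[i % k] = shift
        pat[(i + 1) % k] = -shift
        num_patterns.append(tuple(pat))
    bin_patterns = []
    for i in range(k):
        pat = [0.0] * k
        pat[i % k] = offset
        pat[(i + 1) % k] = -offset
        bin_patterns.append(tuple(pat))
    return CohortSpec(
        schema=FeatureSchema(feats),
        m=m,
        numeric={f"n{i}": NumericSpec(0.0, 1.0) for i in range(1, n_numeric + 1)},
        level_probs={"ord1": (0.25, 0.25, 0.25, 0.25),
                     **{f"b{i}": (0.5, 0.5) for i in range(1, n_binary + 1)}},
        k_planted=k,
        numeric_shifts={f"n{i}": num_patterns[(i - 1) % len(num_patterns)]
                        for i in range(1, n_numeric + 1)},
        prevalence_offsets={**{f"b{i}": bin_patterns[(i - 1) % len(bin_patterns)]
                               for i in range(1, n_binary + 1)},
                            "ord1": bin_patterns[0]},
        seed=seed,
    )


def copd_schema() -> FeatureSchema:
    """The 16-feature COPD-like schema: 4 numeric, 1 ordinal therapy, 11 binary."""
    yn = ("no", "yes")
    return FeatureSchema([
        Feature("age", "numeric", units="years"),
        Feature("bmi", "numeric", units="kg/m^2"),
        Feature("fev1_pct_pred", "numeric", units="% predicted"),
        Feature("eosinophil_pct", "numeric", units="% WBC"),
        Feature("therapy", "ordinal", ("none", "mono", "dual", "triple")),
        Feature("sex", "binary", ("female", "male")),
        Feature("smoking", "binary", ("ex", "current")),
        Feature("anxiety", "binary", yn),
        Feature("depression", "binary", yn),
        Feature("atopy", "binary", yn),
        Feature("crs", "binary", yn),
        Feature("diabetes", "binary", yn),
        Feature("hypertension", "binary", yn),
        Feature("heart_failure", "binary", yn),
        Feature("ihd", "binary", yn),
        Feature("gerd", "binary", yn),
    ])


def copd_spec(m: int = 30467, seed: int = 0, k_planted: int = 0,
              numeric_shifts: dict | None = None,
              prevalence_offsets: dict | None = None) -> CohortSpec:
    """COPD-like marginals (means/SDs and prevalences of the motivating cohort).

    Numeric truncation bounds reflect eligibility (age >= 35) and physiological
    plausibility (BMI > 10, FEV1%pred in (5, 150), eosinophil % in (0, 20)).
    """
    def p2(p):  # binary: (negative, positive) level probabilities
        return (1.0 - p, p)

    return CohortSpec(
        schema=copd_schema(),
        m=m,
        numeric={
            "age": NumericSpec(67.0, 10.8, lower=35.0),
            "bmi": NumericSpec(27.5, 6.1, lower=10.0),
            "fev1_pct_pred": NumericSpec(66.1, 20.9, lower=5.0, upper=150.0),
            "eosinophil_pct": NumericSpec(3.0, 1.8, lower=0.0, upper=20.0),
        },
        level_probs={
            "therapy": (0.376, 0.132, 0.330, 0.162),
            "sex": p2(0.545),
            "smoking": p2(0.535),
            "anxiety": p2(0.101),
            "depression": p2(0.111),
            "atopy": p2(0.122),
            "crs": p2(0.019),
            "diabetes": p2(0.162),
            "hypertension": p2(0.340),
            "heart_failure": p2(0.151),
            "ihd": p2(0.230),
            "gerd": p2(0.089),
        },
        k_planted=k_planted,
        numeric_shifts=numeric_shifts or {},
        prevalence_offsets=prevalence_offsets or {},
        seed=seed,
    )
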
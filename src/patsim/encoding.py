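"""Deterministic feature transformations preceding embedding.

Clinical derivations (airflow-obstruction stage from FEV1% predicted, therapy
class from prescribed drug sets), numeric binning, one-hot encoding into an
indicator matrix, and train-fitted scaling.  Binning rules and scalers are
JSON-serializable so a fitted transform can be re-applied to unseen data
bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import DomainError, ParameterizationError, ValidationError

logger = logging.getLogger(__name__)

GOLD_EDGES = (30.0, 50.0, 80.0)
GOLD_LABELS = ("4", "3", "2", "1")  # ascending FEV1%pred -> descending stage
DRUG_CLASSES = frozenset({"ICS", "LABA", "LAMA"})


def derive_gold_stage(fev1_pct_pred):
    """Map FEV1% predicted to obstruction stage 1-4 (left-closed bands at 30/50/80)."""
    arr = np.asarray(fev1_pct_pred, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("FEV1% predicted must be positive")
    stage = np.where(arr >= 80, 1, np.where(arr >= 50, 2, np.where(arr >= 30, 3, 4)))
    return int(stage) if np.isscalar(fev1_pct_pred) or arr.ndim == 0 else stage


def derive_therapy_class(prescribed) -> str:
    """Classify a prescribed drug-class set into none/mono/dual/triple therapy.

    ICS alone counts as no therapy: the class is driven by the long-acting
    bronchodilators, with ICS upgrading mono to dual and dual to triple.
    """
    drugs = set(prescribed)
    unknown = drugs - DRUG_CLASSES
    if unknown:
        raise ValidationError(f"unknown drug token(s): {sorted(unknown)}")
    broncho = len(drugs & {"LABA", "LAMA"})
    ics = "ICS" in drugs
    if broncho == 0:
        return "none"
    if broncho == 1:
        return "dual" if ics else "mono"
    return "triple" if ics else "dual"


@dataclass(frozen=True)
class BinningRule:
    """Maps a numeric feature onto ordered bin labels.

    ``edges`` are the interior cut points (strictly increasing, one fewer than
    labels); intervals are left-closed right-open.  Optional ``lower``/``upper``
    declare the clinically meaningful range: values outside are clamped to the
    terminal bins with a logged warning.
    """

    feature: str
    edges: tuple[float, ...]
    labels: tuple[str, ...]
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.edges) + 1:
            raise ParameterizationError(
                f"rule for {self.feature!r}: need len(labels) == len(edges) + 1")
        if len(self.edges) and np.any(np.diff(self.edges) <= 0):
            raise ParameterizationError(f"rule for {self.feature!r}: edges must strictly increase")

    def to_json(self) -> str:
        return json.dumps({
            "feature": self.feature, "edges": list(self.edges),
            "labels": list(self.labels), "lower": self.lower, "upper": self.upper,
        })

    @classmethod
    def from_json(cls, payload: str) -> "BinningRule":
        d = json.loads(payload)
        return cls(d["feature"], tuple(d["edges"]), tuple(d["labels"]),
                   d.get("lower"), d.get("upper"))


def quantile_rule(feature: str, train_values, n_bins: int) -> BinningRule:
    """Build a quantile binning rule from training values only."""
    if n_bins < 2:
        raise ParameterizationError("n_bins must be >= 2")
    values = np.asarray(train_values, dtype=float)
    edges = np.quantile(values, np.arange(1, n_bins) / n_bins)
    if np.any(np.diff(edges) <= 0) or len(np.unique(values)) < n_bins:
        raise ParameterizationError(
            f"degenerate quantile edges for {feature!r}: too few distinct values")
    labels = tuple(f"q{i + 1}" for i in range(n_bins))
    return BinningRule(feature, tuple(float(e) for e in edges), labels)


def gold_rule(feature: str = "fev1_pct_pred") -> BinningRule:
    """Clinical binning rule for FEV1% predicted (stages 4..1 in ascending order)."""
    return BinningRule(feature, GOLD_EDGES, GOLD_LABELS, lower=0.0, upper=150.0)


def bin_numeric(values, rule: BinningRule) -> np.ndarray:
    """Assign each value to its (left-closed, right-open) bin label."""
    arr = np.asarray(values, dtype=float)
    if rule.lower is not None and np.any(arr < rule.lower):
        logger.warning("%s: %d value(s) below %s clamped to first bin",
                       rule.feature, int((arr < rule.lower).sum()), rule.lower)
    if rule.upper is not None and np.any(arr > rule.upper):
        logger.warning("%s: %d value(s) above %s clamped to last bin",
                       rule.feature, int((arr > rule.upper).sum()), rule.upper)
    idx = np.searchsorted(np.asarray(rule.edges), arr, side="right")
    return np.asarray(rule.labels, dtype=object)[idx]


@dataclass(frozen=True)
class ColumnMeta:
    """Provenance of one encoded column."""

    source: str
    level: str | None
    kind: str  # "numeric" or "indicator"


@dataclass
class EncodedMatrix:
    """m x p numeric matrix with per-column provenance metadata."""

    values: np.ndarray
    columns: list[ColumnMeta]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValidationError("values shape does not match column metadata")

    @property
    def sources(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.columns:
            seen.setdefault(c.source, None)
        return list(seen)

    def block_indices(self, source: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.columns) if c.source == source])

    def hstack(self, other: "EncodedMatrix") -> "EncodedMatrix":
        return EncodedMatrix(np.hstack([self.values, other.values]),
                             self.columns + other.columns)


def indicator_matrix(frame: pd.DataFrame, levels: dict[str, tuple[str, ...]]) -> EncodedMatrix:
    """One-hot encode ``frame`` columns with explicit level order; one block per feature."""
    blocks, meta = [], []
    for name, lv in levels.items():
        codes = pd.Categorical(frame[name], categories=list(lv)).codes
        if (codes < 0).any():
            bad = frame[name][codes < 0].iloc[0]
            raise ValidationError(f"column {name!r}: level {bad!r} not in {list(lv)}")
        block = np.zeros((len(frame), len(lv)))
        block[np.arange(len(frame)), codes] = 1.0
        blocks.append(block)
        meta.extend(ColumnMeta(name, l, "indicator") for l in lv)
    if not blocks:
        return EncodedMatrix(np.zeros((len(frame), 0)), [])
    return EncodedMatrix(np.hstack(blocks), meta)


def one_hot_encode(cohort: Cohort, features: list[str]) -> EncodedMatrix:
    """One-hot encode the listed (non-numeric) cohort features, schema level order."""
    levels: dict[str, tuple[str, ...]] = {}
    for name in features:
        feat = cohort.schema[name]
        if not feat.is_categorical_like:
            raise ValidationError(f"feature {name!r} is numeric; cannot one-hot encode")
        levels[name] = feat.levels
    return indicator_matrix(cohort.table, levels)


class Scaler:
    """Column-wise scaler fitted on training data, re-applicable to unseen rows.

    ``minmax`` maps train min to 0 and train max to 1 (test values may exceed
    [0, 1]); ``standardize`` maps to zero mean, unit SD on train.
    """

    def __init__(self, mode: str = "minmax"):
        if mode not in ("minmax", "standardize"):
            raise ParameterizationError(f"unknown scaling mode {mode!r}")
        self.mode = mode
        self.offset_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self.columns_: list[str] | None = None

    def fit(self, X) -> "Scaler":
        arr, names = _as_matrix(X)
        if self.mode == "minmax":
            lo, hi = arr.min(axis=0), arr.max(axis=0)
            span = hi - lo
            _check_nonzero(span, names, "range")
            self.offset_, self.scale_ = lo, span
        else:
            mean = arr.mean(axis=0)
            sd = arr.std(axis=0, ddof=1)
            _check_nonzero(sd, names, "standard deviation")
            self.offset_, self.scale_ = mean, sd
        self.columns_ = names
        return self

    def transform(self, X) -> np.ndarray:
        if self.offset_ is None:
            raise ValidationError("scaler not fitted")
        arr, _ = _as_matrix(X)
        if arr.shape[1] != len(self.offset_):
            raise ValidationError("column count does not match fitted scaler")
        return (arr - self.offset_) / self.scale_

    def fit_transform(self, X) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_json(self) -> str:
        return json.dumps({
            "mode": self.mode,
            "offset": [float(v) for v in self.offset_],
            "scale": [float(v) for v in self.scale_],
            "columns": self.columns_,
        })

    @classmethod
    def from_json(cls, payload: str) -> "Scaler":
        d = json.loads(payload)
        sc = cls(d["mode"])
        sc.offset_ = np.asarray(d["offset"], dtype=float)
        sc.scale_ = np.asarray(d["scale"], dtype=float)
        sc.columns_ = d["columns"]
        return sc


def scale_numeric(X, mode: str = "minmax") -> tuple[np.ndarray, Scaler]:
    """Fit a scaler on ``X`` and return (scaled values, fitted scaler)."""
    scaler = Scaler(mode)
    return scaler.fit_transform(X), scaler


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"col{i}" for i in range(arr.shape[1])]


def _check_nonzero(values: np.ndarray, names: list[str], what: str) -> None:
    bad = np.flatnonzero(values == 0)
    if bad.size:
        raise ValidationError(f"column {names[bad[0]]!r} has zero {what}")
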
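"""Relative-variability (RV) feature importance and its mean summaries (MRV).

RV compares per-feature variability within each patient's N nearest neighbors
(in a low-dimensional representation) to variability over all cohort pairs:
``RV = 100 * sample / cohort``.  Values near 0 mark features driving
similarity; values near 100 mark features the representation ignores.  The
cohort-level statistic is the median pairwise absolute difference for numeric
features, the mean pairwise absolute rank difference for ordinal features, and
the disagreeing-pair proportion for binary/categorical features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from .cohort import Cohort
from .errors import ParameterizationError
from .similarity import NeighborSet, nearest_neighbors, pairwise_distances

logger = logging.getLogger(__name__)

MAX_EXACT_PAIRS = 2_000_000
SUBSAMPLE_PAIRS = 1_000_000


@dataclass
class FeatureVariability:
    """Per-feature cohort-level variability; zero-variability features are flagged."""

    values: dict[str, float]
    flagged: set[str]


@dataclass
class MRVSummary:
    mrv_categorical: float | None
    mrv_numeric: float | None
    mrv_overall: float


def _ordinal_codes(col: pd.Series, levels) -> np.ndarray:
    return pd.Categorical(col, categories=list(levels), ordered=True).codes.astype(float)


def _mean_abs_rank_diff(codes: np.ndarray) -> float:
    """Mean pairwise |rank difference| via level counts (exact, O(levels^2))."""
    m = len(codes)
    uniq, counts = np.unique(codes, return_counts=True)
    total = 0.0
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            total += counts[i] * counts[j] * abs(uniq[i] - uniq[j])
    n_pairs = m * (m - 1) // 2
    return total / n_pairs


def _disagreement_proportion(col: np.ndarray) -> float:
    """Disagreeing pairs / total pairs via level counts (exact)."""
    m = len(col)
    _, counts = np.unique(col, return_counts=True)
    n_pairs = m * (m - 1) // 2
    agree = int(sum(c * (c - 1) // 2 for c in counts))
    return (n_pairs - agree) / n_pairs


def cohort_variability(cohort: Cohort, seed: int = 0,
                       max_exact_pairs: int = MAX_EXACT_PAIRS) -> FeatureVariability:
    """Cohort-level variability per feature; exact up to ``max_exact_pairs`` pairs.

    Ordinal and categorical statistics have exact closed forms from level
    counts at any m.  The numeric median falls back to a seeded uniform pair
    subsample of :data:`SUBSAMPLE_PAIRS` pairs above the threshold.
    """
    m = cohort.m
    if m < 2:
        raise ParameterizationError("need at least 2 patients")
    n_pairs = m * (m - 1) // 2
    rng = np.random.default_rng(seed)
    values: dict[str, float] = {}
    flagged: set[str] = set()
    for feat in cohort.schema:
        col = cohort.table[feat.name]
        if feat.dtype == "numeric":
            x = col.to_numpy(dtype=float)
            if n_pairs <= max_exact_pairs:
                diffs = pdist(x[:, None], metric="cityblock")
            else:
                i = rng.integers(0, m, size=SUBSAMPLE_PAIRS)
                j = rng.integers(0, m - 1, size=SUBSAMPLE_PAIRS)
                j = np.where(j >= i, j + 1, j)  # uniform over ordered pairs, i != j
                diffs = np.abs(x[i] - x[j])
            q = float(np.median(diffs))
        elif feat.dtype == "ordinal":
            q = float(_mean_abs_rank_diff(_ordinal_codes(col, feat.levels)))
        else:
            q = float(_disagreement_proportion(col.to_numpy()))
        values[feat.name] = q
        if q == 0.0:
            flagged.add(feat.name)
            logger.warning("feature %r has zero cohort variability; RV undefined", feat.name)
    return FeatureVariability(values, flagged)


def neighborhood_variability(cohort: Cohort, neighbors: NeighborSet,
                             numeric_stat: str = "median") -> dict[str, float]:
    """Per-feature variability over the (patient, neighbor) pair set.

    The cohort-level statistic is recomputed over the pooled set of all
    m x N (patient, neighbor) pairs: numeric -> median |difference|;
    ordinal -> mean |rank difference|; categorical -> disagreement proportion.
    For ordinal and categorical features this pooled value is identical to
    averaging per-patient statistics (every patient contributes N pairs); only
    the numeric median distinguishes the two readings, and pooling is the one
    under which uniformly random neighborhoods give RV = 100 with no structural
    bias.  ``numeric_stat`` may instead be ``"anchored_median"`` (per-patient
    median, then mean over patients; carries a ~+7% null bias) or ``"mean"``.
    """
    if numeric_stat not in ("median", "anchored_median", "mean"):
        raise ParameterizationError(f"unknown numeric_stat {numeric_stat!r}")
    idx = neighbors.indices
    out: dict[str, float] = {}
    for feat in cohort.schema:
        col = cohort.table[feat.name]
        if feat.dtype == "numeric":
            x = col.to_numpy(dtype=float)
            d = np.abs(x[:, None] - x[idx])
            if numeric_stat == "median":
                value = float(np.median(d))
            elif numeric_stat == "anchored_median":
                value = float(np.median(d, axis=1).mean())
            else:
                value = float(d.mean())
        elif feat.dtype == "ordinal":
            ranks = _ordinal_codes(col, feat.levels)
            value = float(np.abs(ranks[:, None] - ranks[idx]).mean())
        else:
            codes = pd.Categorical(col).codes
            value = float((codes[:, None] != codes[idx]).mean())
        out[feat.name] = value
    return out


def relative_variability_table(cohort_var: FeatureVariability,
                               neigh_var: dict[str, float],
                               schema) -> pd.DataFrame:
    """RV = 100 * neighborhood / cohort per feature, ranked ascending (rank 1 = most important).

    Features flagged for zero cohort variability are excluded with a warning.
    """
    rows = []
    for feat in schema:
        if feat.name in cohort_var.flagged:
            logger.warning("feature %r excluded from RV table (zero cohort variability)",
                           feat.name)
            continue
        rv = 100.0 * neigh_var[feat.name] / cohort_var.values[feat.name]
        rows.append({"feature": feat.name, "dtype": feat.dtype, "rv": rv})
    table = pd.DataFrame(rows)
    order = np.argsort(table["rv"].to_numpy(), kind="stable")
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    table["rank"] = ranks
    return table.sort_values("rank").reset_index(drop=True)


def mrv_summary(table: pd.DataFrame, ordinal_group: str = "categorical") -> MRVSummary:
    """Group means of RV.

    ``ordinal_group`` controls whether ordinal features are averaged with the
    categorical group (default, matching the published per-type summaries) or
    with the numeric group.
    """
    if ordinal_group not in ("categorical", "numeric"):
        raise ParameterizationError(f"unknown ordinal_group {ordinal_group!r}")
    if table.empty:
        raise ParameterizationError("empty RV table")
    numeric_dtypes = {"numeric"} | ({"ordinal"} if ordinal_group == "numeric" else set())
    is_num = table["dtype"].isin(numeric_dtypes)
    num = table.loc[is_num, "rv"]
    cat = table.loc[~is_num, "rv"]
    return MRVSummary(
        mrv_categorical=float(cat.mean()) if len(cat) else None,
        mrv_numeric=float(num.mean()) if len(num) else None,
        mrv_overall=float(table["rv"].mean()),
    )


def rv_robustness(cohort: Cohort, coords, n_list: list[int],
                  numeric_stat: str = "median",
                  seed: int = 0) -> tuple[dict[int, pd.DataFrame], pd.DataFrame]:
    """RV tables for several neighbor counts N, with consecutive rank correlations."""
    dist = pairwise_distances(coords, ids=cohort.ids)
    cvar = cohort_variability(cohort, seed=seed)
    tables: dict[int, pd.DataFrame] = {}
    for n in n_list:
        nbrs = nearest_neighbors(dist, n)
        nvar = neighborhood_variability(cohort, nbrs, numeric_stat=numeric_stat)
        tables[n] = relative_variability_table(cvar, nvar, cohort.schema)
    corr_rows = []
    ns = list(n_list)
    for a, b in zip(ns, ns[1:]):
        ta = tables[a].set_index("feature")["rank"]
        tb = tables[b].set_index("feature")["rank"].reindex(ta.index)
        rho = float(spearmanr(ta.to_numpy(), tb.to_numpy()).statistic)
        corr_rows.append({"n_a": a, "n_b": b, "spearman": rho})
    return tables, pd.DataFrame(corr_rows)
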
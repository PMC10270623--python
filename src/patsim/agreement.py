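"""Vignette export for blinded expert rating and rater-agreement statistics.

Two raters independently rank the best match proposed by each pipeline from 1
(best) to 4 (worst); ties are allowed as long as each case receives at least
one 1 and one 4.  Agreement is summarized as raw percentage agreement and
Cohen's kappa with large-sample (Fleiss-style) confidence intervals, both on
the raw ranks and on best/worst binarizations.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ParameterizationError, ValidationError

RANK_MIN, RANK_MAX = 1, 4


@dataclass
class RatingSet:
    """Rectangular ratings: one rank per (case, pipeline, rater)."""

    frame: pd.DataFrame  # columns: case_id, rater_id, pipeline, rank
    pipelines: list[str]
    raters: list[str]

    def ranks(self, pipeline: str) -> pd.DataFrame:
        """Cases x raters table of ranks for one pipeline."""
        sub = self.frame[self.frame["pipeline"] == pipeline]
        return sub.pivot(index="case_id", columns="rater_id", values="rank")


@dataclass
class KappaResult:
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    undefined: bool = False


def make_rating_set(frame: pd.DataFrame) -> RatingSet:
    """Validate a long-format rating table and wrap it as a :class:`RatingSet`.

    Enforces ranks in 1..4 and the rule that every (case, rater) assigns at
    least one rank 1 and one rank 4 across pipelines.
    """
    required = {"case_id", "rater_id", "pipeline", "rank"}
    if not required.issubset(frame.columns):
        raise ValidationError(f"rating table needs columns {sorted(required)}")
    frame = frame.copy()
    frame["rank"] = frame["rank"].astype(int)
    if ((frame["rank"] < RANK_MIN) | (frame["rank"] > RANK_MAX)).any():
        raise ValidationError(f"ranks must be in [{RANK_MIN}, {RANK_MAX}]")
    for (case, rater), grp in frame.groupby(["case_id", "rater_id"]):
        if RANK_MIN not in grp["rank"].values or RANK_MAX not in grp["rank"].values:
            raise ValidationError(
                f"case {case!r}, rater {rater!r}: needs at least one rank "
                f"{RANK_MIN} and one rank {RANK_MAX}")
    pipelines = sorted(frame["pipeline"].unique())
    raters = sorted(frame["rater_id"].unique())
    return RatingSet(frame, pipelines, raters)


def _binarize(ranks: np.ndarray, mode: str) -> np.ndarray:
    if mode == "overall":
        return ranks
    if mode == "is_best":
        return (ranks == RANK_MIN).astype(int)
    if mode == "is_worst":
        return (ranks == RANK_MAX).astype(int)
    raise ParameterizationError(f"unknown mode {mode!r}")


def _two_rater_labels(ratings: RatingSet, pipeline: str, mode: str):
    if len(ratings.raters) != 2:
        raise ValidationError("agreement statistics require exactly 2 raters")
    wide = ratings.ranks(pipeline)
    a = wide[ratings.raters[0]].to_numpy(dtype=int)
    b = wide[ratings.raters[1]].to_numpy(dtype=int)
    return _binarize(a, mode), _binarize(b, mode)


def percent_agreement(ratings: RatingSet, pipeline: str, mode: str = "overall") -> float:
    """Fraction of cases on which both raters assigned the same (possibly binarized) label."""
    a, b = _two_rater_labels(ratings, pipeline, mode)
    return float(np.mean(a == b))


def cohen_kappa(labels_a, labels_b, variance: str = "estimation") -> KappaResult:
    """Unweighted Cohen's kappa with a large-sample 95% confidence interval.

    ``variance="estimation"`` uses the asymptotic variance of the kappa
    estimate; ``variance="null"`` uses the hypothesis-testing (kappa = 0) form.
    Both raters constant in the same category makes kappa undefined, which is
    returned as a flagged NaN result rather than raised.
    """
    if variance not in ("estimation", "null"):
        raise ParameterizationError(f"unknown variance form {variance!r}")
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValidationError("label vectors must be equal-length and non-empty")
    n = len(a)
    cats = np.unique(np.concatenate([a, b]))
    k = len(cats)
    table = np.zeros((k, k))
    ai = np.searchsorted(cats, a)
    bi = np.searchsorted(cats, b)
    np.add.at(table, (ai, bi), 1)
    p = table / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(row @ col)
    if pe >= 1.0 - 1e-12:
        return KappaResult(float("nan"), float("nan"), float("nan"), float("nan"),
                           undefined=True)
    kappa = (po - pe) / (1.0 - pe)
    if variance == "estimation":
        term1 = sum(p[i, i] * ((1 - pe) - (row[i] + col[i]) * (1 - po)) ** 2
                    for i in range(k))
        term2 = (1 - po) ** 2 * sum(p[i, j] * (col[i] + row[j]) ** 2
                                    for i in range(k) for j in range(k) if i != j)
        term3 = (po * pe - 2 * pe + po) ** 2
        var = (term1 + term2 - term3) / (n * (1 - pe) ** 4)
    else:
        var = (pe + pe**2 - float(sum(row[i] * col[i] * (row[i] + col[i])
                                      for i in range(k)))) / (n * (1 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    return KappaResult(float(kappa), se, float(kappa - 1.96 * se),
                       float(kappa + 1.96 * se))


def kappa_for_pipeline(ratings: RatingSet, pipeline: str, mode: str = "overall",
                       variance: str = "estimation") -> KappaResult:
    a, b = _two_rater_labels(ratings, pipeline, mode)
    return cohen_kappa(a, b, variance=variance)


def agreement_report(ratings: RatingSet, variance: str = "estimation") -> pd.DataFrame:
    """Per-pipeline agreement table: % agreement and kappa (with CIs) for every mode."""
    rows = []
    for pipeline in ratings.pipelines:
        entry: dict = {"pipeline": pipeline}
        for mode in ("overall", "is_best", "is_worst"):
            entry[f"pct_{mode}"] = percent_agreement(ratings, pipeline, mode)
            kr = kappa_for_pipeline(ratings, pipeline, mode, variance=variance)
            entry[f"kappa_{mode}"] = kr.kappa
            entry[f"kappa_{mode}_ci_low"] = kr.ci_low
            entry[f"kappa_{mode}_ci_high"] = kr.ci_high
        a, b = _two_rater_labels(ratings, pipeline, "is_best")
        entry["pct_is_not_best"] = float(np.mean((1 - a) == (1 - b)))
        a, b = _two_rater_labels(ratings, pipeline, "is_worst")
        entry["pct_is_not_worst"] = float(np.mean((1 - a) == (1 - b)))
        rows.append(entry)
    return pd.DataFrame(rows)


def summarize_ratings(ratings: RatingSet) -> pd.DataFrame:
    """Per-pipeline best/worst assignment rates per rater, with the cross-rater average."""
    if ratings.frame.empty:
        raise ValidationError("empty rating set")
    rows = []
    for pipeline in ratings.pipelines:
        wide = ratings.ranks(pipeline)
        entry: dict = {"pipeline": pipeline}
        best_rates, worst_rates = [], []
        for rater in ratings.raters:
            ranks = wide[rater].to_numpy(dtype=int)
            best = float(np.mean(ranks == RANK_MIN))
            worst = float(np.mean(ranks == RANK_MAX))
            entry[f"best_{rater}"] = best
            entry[f"worst_{rater}"] = worst
            best_rates.append(best)
            worst_rates.append(worst)
        entry["best_avg"] = float(np.mean(best_rates))
        entry["worst_avg"] = float(np.mean(worst_rates))
        rows.append(entry)
    return pd.DataFrame(rows)


def export_vignettes(cohort: Cohort, representations: list, sample_size: int,
                     seed: int = 0) -> tuple[pd.DataFrame, dict[str, str]]:
    """Build a blinded vignette table of reference patients and best matches.

    Each row holds the reference's raw features plus, per pipeline, the best
    non-identical match's features under a shuffled letter code.  Returns the
    table and the letter -> pipeline blinding map (store it separately).
    """
    from .similarity import best_match_nonidentical, pairwise_distances

    if sample_size > cohort.m:
        raise ParameterizationError("sample_size exceeds cohort size")
    rng = np.random.default_rng(seed)
    refs = rng.choice(np.asarray(cohort.ids, dtype=object), size=sample_size, replace=False)
    letters = list(string.ascii_uppercase[:len(representations)])
    order = rng.permutation(len(representations))
    blinding = {letters[i]: representations[order[i]].name for i in range(len(order))}

    dists = {rep.name: pairwise_distances(rep.train_coords, ids=rep.train_ids)
             for rep in representations}
    rows = []
    for ref in refs:
        row: dict = {"case_id": ref}
        for fname in cohort.schema.names:
            row[f"reference_{fname}"] = cohort.table.at[ref, fname]
        for letter in letters:
            match = best_match_nonidentical(dists[blinding[letter]], cohort, ref)
            for fname in cohort.schema.names:
                row[f"match_{letter}_{fname}"] = cohort.table.at[match, fname]
        rows.append(row)
    return pd.DataFrame(rows), blinding
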
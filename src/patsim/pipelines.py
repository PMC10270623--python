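"""The four mixed-type data processing pipelines and the evaluation harness.

Pipelines (all fitted on the training split only; the test split is always
transformed with train-fitted state):

* ``MCA``          — bin numerics, one-hot everything, MCA, retain at threshold.
* ``MCA/PCA``      — MCA on categoricals in parallel with PCA on numerics, each
                     retained at the threshold, concatenated on native scales.
* ``MCA/PCA/PCA``  — as MCA/PCA, then a second PCA over the concatenation.
* ``AE``           — min-max-scaled numerics plus one-hot indicators through a
                     bottleneck autoencoder (fixed config or grid-searched).

``evaluate_all`` composes the representation step with RV/MRV feature
importance, Hopkins cluster tendency, cross-pipeline k-means congruity and
bootstrap pair-stability into one machine-readable report.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autoencoder as ae_mod
from .cluster import bootstrap_pair_stability, congruity, hopkins_index, kmeans_partition
from .cohort import Cohort, SplitCohort
from .encoding import (BinningRule, Scaler, bin_numeric, gold_rule, indicator_matrix,
                       one_hot_encode, quantile_rule)
from .errors import ParameterizationError, PatsimError
from .linear import fit_mca, fit_pca, retain_components
from .rv import (cohort_variability, mrv_summary, neighborhood_variability,
                 relative_variability_table)
from .similarity import nearest_neighbors, pairwise_distances

logger = logging.getLogger(__name__)

PIPELINE_NAMES = ("MCA", "MCA/PCA", "MCA/PCA/PCA", "AE")


def stage_seed(master_seed: int, label: str) -> int:
    """Deterministically derive a stage seed from the master seed and a label."""
    return int(np.random.SeedSequence(
        (int(master_seed), zlib.crc32(label.encode()))).generate_state(1)[0])


@dataclass
class PipelineConfig:
    name: str
    variance_threshold: float = 0.75
    n_bins: int = 4
    clinical_rules: dict[str, BinningRule] = field(
        default_factory=lambda: {"fev1_pct_pred": gold_rule()})
    scaling_mode: str = "minmax"
    mca_correction: str = "none"
    ae_config: ae_mod.AEConfig = field(default_factory=ae_mod.AEConfig)
    ae_grid: dict | None = None

    def __post_init__(self) -> None:
        if self.name not in PIPELINE_NAMES:
            raise ParameterizationError(
                f"unknown pipeline {self.name!r}; expected one of {PIPELINE_NAMES}")
        if not 0.0 < self.variance_threshold <= 1.0:
            raise ParameterizationError("variance_threshold must be in (0, 1]")


def default_configs(**overrides) -> list[PipelineConfig]:
    return [PipelineConfig(name, **overrides) for name in PIPELINE_NAMES]


@dataclass
class RepresentationResult:
    name: str
    train_coords: np.ndarray
    test_coords: np.ndarray
    train_ids: list
    test_ids: list
    state: dict

    @property
    def dimension(self) -> int:
        return self.train_coords.shape[1]


def _binned_frame(cohort: Cohort, rules: dict[str, BinningRule]) -> tuple[pd.DataFrame, dict]:
    frame = pd.DataFrame(index=cohort.table.index)
    levels: dict[str, tuple[str, ...]] = {}
    for name, rule in rules.items():
        frame[name] = bin_numeric(cohort.table[name].to_numpy(dtype=float), rule)
        levels[name] = rule.labels
    return frame, levels


def _fit_binning_rules(train: Cohort, config: PipelineConfig) -> dict[str, BinningRule]:
    rules: dict[str, BinningRule] = {}
    for name in train.schema.numeric_names:
        if name in config.clinical_rules:
            rules[name] = config.clinical_rules[name]
        else:
            rules[name] = quantile_rule(name, train.table[name].to_numpy(dtype=float),
                                        config.n_bins)
    return rules


def run_pipeline(split: SplitCohort, config: PipelineConfig,
                 master_seed: int = 0) -> RepresentationResult:
    """Fit one named pipeline on the training split and transform both splits."""
    try:
        return _run_pipeline(split, config, master_seed)
    except PatsimError as exc:
        raise type(exc)(f"[pipeline {config.name}] {exc}") from exc


def _run_pipeline(split: SplitCohort, config: PipelineConfig,
                  master_seed: int) -> RepresentationResult:
    train, test = split.train, split.test
    schema = train.schema
    numeric = schema.numeric_names
    categorical = schema.categorical_like_names
    state: dict = {}

    if config.name == "MCA":
        rules = _fit_binning_rules(train, config)
        bt_frame, bt_levels = _binned_frame(train, rules)
        bs_frame, _ = _binned_frame(test, rules)
        cat_levels = {n: schema[n].levels for n in categorical}
        z_train = indicator_matrix(pd.concat([bt_frame, train.table[categorical]], axis=1),
                                   {**bt_levels, **cat_levels})
        z_test = indicator_matrix(pd.concat([bs_frame, test.table[categorical]], axis=1),
                                  {**bt_levels, **cat_levels})
        emb = retain_components(
            fit_mca(z_train, correction=config.mca_correction, unobserved="drop"),
            config.variance_threshold)
        state["mca"] = emb
        state["binning"] = rules
        train_coords = emb.coordinates
        test_coords = emb.project(_restrict(z_test, emb))

    elif config.name in ("MCA/PCA", "MCA/PCA/PCA"):
        z_train = one_hot_encode(train, categorical)
        z_test = one_hot_encode(test, categorical)
        mca = retain_components(
            fit_mca(z_train, correction=config.mca_correction, unobserved="drop"),
            config.variance_threshold)
        pca = retain_components(
            fit_pca(train.table[numeric].to_numpy(dtype=float), standardize=True),
            config.variance_threshold)
        state["mca"], state["pca"] = mca, pca
        train_coords = np.hstack([mca.coordinates, pca.coordinates])
        test_coords = np.hstack([
            mca.project(_restrict(z_test, mca)),
            pca.project(test.table[numeric].to_numpy(dtype=float)),
        ])
        if config.name == "MCA/PCA/PCA":
            second = retain_components(fit_pca(train_coords, standardize=True),
                                       config.variance_threshold)
            state["pca2"] = second
            test_coords = second.project(test_coords)
            train_coords = second.coordinates

    else:  # AE
        num_train = train.table[numeric].to_numpy(dtype=float)
        num_test = test.table[numeric].to_numpy(dtype=float)
        scaler = Scaler(config.scaling_mode).fit(num_train)
        x_train = np.hstack([scaler.transform(num_train),
                             one_hot_encode(train, categorical).values])
        x_test = np.hstack([scaler.transform(num_test),
                            one_hot_encode(test, categorical).values])
        ae_seed = stage_seed(master_seed, f"ae:{config.name}")
        if config.ae_grid is not None:
            model, results = ae_mod.grid_search(x_train, x_test, grid=config.ae_grid,
                                               base_config=config.ae_config, seed=ae_seed)
            state["grid_results"] = results
        else:
            cfg = ae_mod.AEConfig(**{**config.ae_config.__dict__, "seed": ae_seed})
            model = ae_mod.fit_autoencoder(x_train, x_test, cfg)
            if model.diverged:
                raise ParameterizationError("autoencoder training diverged")
        state["scaler"] = scaler
        state["ae"] = model
        train_coords = ae_mod.encode(model, x_train)
        test_coords = ae_mod.encode(model, x_test)

    return RepresentationResult(config.name, train_coords, test_coords,
                                train.ids, test.ids, state)


def _restrict(encoded, emb):
    """Align an indicator matrix with the (possibly level-dropped) MCA columns."""
    fitted_cols = emb.state["columns"]
    if len(fitted_cols) == len(encoded.columns):
        return encoded
    fitted = {(c.source, c.level) for c in fitted_cols}
    keep = [i for i, c in enumerate(encoded.columns) if (c.source, c.level) in fitted]
    return encoded.values[:, keep]


def evaluate_all(split: SplitCohort, configs: list[PipelineConfig] | None = None,
                 n_neighbors: int = 20, ks: tuple[int, ...] = (2, 3, 4, 5),
                 master_seed: int = 0, hopkins_m_h: int = 100,
                 hopkins_repeats: int = 10, bootstrap_fraction: float = 0.1,
                 bootstrap_repeats: int = 20) -> dict:
    """Run every configured pipeline and assemble the full evaluation report."""
    configs = configs if configs is not None else default_configs()
    if not configs:
        raise ParameterizationError("need at least one pipeline config")
    report: dict = {
        "master_seed": int(master_seed),
        "n_neighbors": int(n_neighbors),
        "ks": [int(k) for k in ks],
        "m_train": split.train.m,
        "m_test": split.test.m,
        "pipelines": {},
        "congruity": {},
    }
    results: list[RepresentationResult] = []
    cvar = cohort_variability(split.train, seed=stage_seed(master_seed, "cohort_var"))
    for config in configs:
        t0 = time.perf_counter()
        rep = run_pipeline(split, config, master_seed)
        results.append(rep)
        dist = pairwise_distances(rep.train_coords, ids=rep.train_ids)
        nbrs = nearest_neighbors(dist, n_neighbors)
        nvar = neighborhood_variability(split.train, nbrs)
        rv_table = relative_variability_table(cvar, nvar, split.train.schema)
        mrv = mrv_summary(rv_table)
        hop = hopkins_index(rep.train_coords, m_h=min(hopkins_m_h, rep.train_coords.shape[0] - 1),
                            repeats=hopkins_repeats,
                            seed=stage_seed(master_seed, f"hopkins:{config.name}"))
        report["pipelines"][config.name] = {
            "dimension": rep.dimension,
            "rv": [{"feature": r.feature, "dtype": r.dtype, "rv": float(r.rv),
                    "rank": int(r.rank)} for r in rv_table.itertuples()],
            "mrv": {"categorical": mrv.mrv_categorical, "numeric": mrv.mrv_numeric,
                    "overall": mrv.mrv_overall},
            "hopkins": hop.statistic,
        }
        logger.info("pipeline %s: dim=%d, %.2fs", config.name, rep.dimension,
                    time.perf_counter() - t0)

    names = [r.name for r in results]
    for k in ks:
        t0 = time.perf_counter()
        seed_k = stage_seed(master_seed, f"kmeans:{k}")
        labelings = {r.name: kmeans_partition(r.train_coords, k, seed=seed_k).labels
                     for r in results}
        matrix = np.zeros((len(results), len(results)))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i == j:
                    matrix[i, j] = bootstrap_pair_stability(
                        results[i].train_coords, k, fraction=bootstrap_fraction,
                        repeats=bootstrap_repeats,
                        seed=stage_seed(master_seed, f"bootstrap:{k}:{a}"))
                elif i < j:
                    matrix[i, j] = congruity(labelings[a], labelings[b])
                    matrix[j, i] = matrix[i, j]
        report["congruity"][str(k)] = {"pipelines": names,
                                       "matrix": matrix.tolist()}
        logger.info("congruity k=%d: %.2fs", k, time.perf_counter() - t0)
    return report


def congruity_frame(report: dict, k: int) -> pd.DataFrame:
    """Table-shaped congruity matrix for one k (diagonal = bootstrap stability)."""
    block = report["congruity"][str(k)]
    return pd.DataFrame(block["matrix"], index=block["pipelines"],
                        columns=block["pipelines"])


def rv_frame(report: dict) -> pd.DataFrame:
    """Ranked RV per pipeline plus MRV summary rows, mirroring the published layout."""
    pieces = {}
    for name, block in report["pipelines"].items():
        col = {row["feature"]: row["rv"] for row in block["rv"]}
        col["MRV categorical"] = block["mrv"]["categorical"]
        col["MRV numeric"] = block["mrv"]["numeric"]
        col["MRV overall"] = block["mrv"]["overall"]
        pieces[name] = pd.Series(col)
    return pd.DataFrame(pieces)
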
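"""PCA/MCA embeddings against independent dense-eigendecomposition / CA-SVD oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import patsim as ps
from patsim.encoding import indicator_matrix
from patsim.errors import ParameterizationError, ValidationError
from patsim.linear import fit_mca, fit_pca, retain_components


def pca_oracle_eigvals(X, standardize=True):
    """Brute-force: eigendecomposition of the sample covariance matrix."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    if standardize:
        Xc = Xc / X.std(axis=0, ddof=1)
    vals = np.linalg.eigvalsh(np.cov(Xc, rowvar=False))
    return np.sort(vals)[::-1]


def ca_oracle(Z, q):
    """Brute-force CA of an indicator matrix: explicit standardized residual SVD."""
    Z = np.asarray(Z, dtype=float)
    n = Z.sum()
    P = Z / n
    r, c = P.sum(axis=1), P.sum(axis=0)
    S = np.diag(1 / np.sqrt(r)) @ (P - np.outer(r, c)) @ np.diag(1 / np.sqrt(c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    keep = s**2 > 1e-12
    coords = (U[:, keep] * s[keep]) / np.sqrt(r)[:, None]
    return s[keep] ** 2, coords


def random_indicator(rng, m, level_counts):
    frame = pd.DataFrame({
        f"f{i}": rng.choice([f"l{i}_{j}" for j in range(n_lv)], size=m)
        for i, n_lv in enumerate(level_counts)})
    levels = {f"f{i}": tuple(f"l{i}_{j}" for j in range(n_lv))
              for i, n_lv in enumerate(level_counts)}
    return indicator_matrix(frame, levels)


class TestPCA:
    def test_rank_one_line(self):
        x = np.linspace(0, 1, 20)
        emb = fit_pca(np.column_stack([x, 2 * x]), standardize=False)
        assert emb.explained[0] == pytest.approx(1.0)

    def test_eigvals_match_oracle(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0], [3.0, 1.0]])
        emb = fit_pca(X, standardize=False)
        np.testing.assert_allclose(emb.state["eigenvalues"],
                                   pca_oracle_eigvals(X, standardize=False), atol=1e-10)

    def test_scores_uncorrelated(self, rng):
        emb = fit_pca(rng.normal(size=(50, 5)))
        cov = np.cov(emb.coordinates, rowvar=False)
        np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0.0, atol=1e-8)

    def test_total_variance_preserved(self, rng):
        X = rng.normal(size=(40, 6))
        emb = fit_pca(X, standardize=True)
        assert emb.state["eigenvalues"].sum() == pytest.approx(6.0)

    def test_project_idempotent(self, rng):
        X = rng.normal(size=(30, 4))
        emb = fit_pca(X)
        np.testing.assert_allclose(emb.project(X), emb.coordinates, atol=1e-10)

    def test_duplicate_row_same_coords(self, rng):
        X = rng.normal(size=(20, 3))
        emb = fit_pca(X)
        np.testing.assert_allclose(emb.project(X[[4]]), emb.coordinates[[4]], atol=1e-10)

    def test_empty_projection(self, rng):
        emb = fit_pca(rng.normal(size=(10, 3)))
        assert emb.project(np.empty((0, 3))).shape == (0, emb.n_components)

    def test_constant_column_standardize_error(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValidationError):
            fit_pca(X, standardize=True)

    def test_oracle_equivalence_random(self, rng):
        for _ in range(10):
            X = rng.normal(size=(rng.integers(5, 21), rng.integers(2, 7)))
            emb = fit_pca(X, standardize=False)
            oracle = pca_oracle_eigvals(X, standardize=False)
            np.testing.assert_allclose(emb.state["eigenvalues"],
                                       oracle[:emb.n_components], atol=1e-8)


class TestMCA:
    def test_total_inertia_closed_form(self, rng):
        enc = random_indicator(rng, 30, [2, 3])
        emb = fit_mca(enc)
        assert emb.state["total_inertia"] == pytest.approx(5 / 2 - 1, abs=1e-10)

    @given(counts=st.lists(st.integers(2, 4), min_size=1, max_size=4))
    @settings(max_examples=25, deadline=None)
    def test_total_inertia_random_schemas(self, counts):
        rng = np.random.default_rng(sum(counts))
        enc = random_indicator(rng, 60, counts)
        try:
            emb = fit_mca(enc)
        except ValidationError:
            return  # some level unobserved in this draw
        j, q = sum(counts), len(counts)
        assert emb.state["total_inertia"] == pytest.approx(j / q - 1, abs=1e-8)

    def test_perfectly_associated_features_match_oracle(self):
        # two binary features that always co-occur, 6-row table
        frame = pd.DataFrame({"a": ["x", "x", "x", "y", "y", "y"],
                              "b": ["u", "u", "u", "v", "v", "v"]})
        enc = indicator_matrix(frame, {"a": ("x", "y"), "b": ("u", "v")})
        emb = fit_mca(enc)
        inertias, coords = ca_oracle(enc.values, 2)
        np.testing.assert_allclose(emb.state["inertias"], inertias, atol=1e-8)
        assert emb.state["inertias"][0] == pytest.approx(1.0)  # maximum for this design
        for k in range(coords.shape[1]):
            col = emb.coordinates[:, k]
            assert (np.allclose(col, coords[:, k], atol=1e-8)
                    or np.allclose(col, -coords[:, k], atol=1e-8))

    def test_single_feature_level_groups_identical(self):
        frame = pd.DataFrame({"a": ["x", "y", "z", "x", "y", "z"]})
        enc = indicator_matrix(frame, {"a": ("x", "y", "z")})
        emb = fit_mca(enc)
        np.testing.assert_allclose(emb.coordinates[0], emb.coordinates[3], atol=1e-10)
        np.testing.assert_allclose(emb.coordinates[1], emb.coordinates[4], atol=1e-10)

    def test_oracle_equivalence_random(self, rng):
        for _ in range(10):
            enc = random_indicator(rng, 20, [2, 3, 2])
            try:
                emb = fit_mca(enc)
            except ValidationError:
                continue
            inertias, coords = ca_oracle(enc.values, 3)
            np.testing.assert_allclose(emb.state["inertias"], inertias, atol=1e-8)
            for k in range(emb.n_components):
                col = emb.coordinates[:, k]
                assert (np.allclose(col, coords[:, k], atol=1e-7)
                        or np.allclose(col, -coords[:, k], atol=1e-7))

    def test_unobserved_level_error_and_drop(self):
        frame = pd.DataFrame({"a": ["x", "x", "x"], "b": ["u", "v", "u"]})
        enc = indicator_matrix(frame, {"a": ("x", "y"), "b": ("u", "v")})
        with pytest.raises(ValidationError):
            fit_mca(enc)
        emb = fit_mca(enc, unobserved="drop")
        assert len(emb.state["columns"]) == 3

    def test_project_reproduces_scores(self, rng):
        enc = random_indicator(rng, 40, [2, 3, 4])
        emb = fit_mca(enc)
        np.testing.assert_allclose(emb.project(enc), emb.coordinates, atol=1e-8)

    def test_benzecri_changes_only_explained(self, rng):
        enc = random_indicator(rng, 50, [2, 3])
        raw = fit_mca(enc, correction="none")
        adj = fit_mca(enc, correction="benzecri")
        np.testing.assert_allclose(raw.coordinates, adj.coordinates)
        assert not np.allclose(raw.explained, adj.explained)


class TestRetain:
    def test_cumulative_examples(self):
        emb = ps.Embedding("pca", np.zeros((4, 3)), np.array([0.5, 0.3, 0.2]),
                           {"mean": np.zeros(3), "scale": np.ones(3),
                            "components": np.eye(3), "eigenvalues": np.ones(3)})
        assert retain_components(emb, 0.75).n_components == 2
        emb2 = ps.Embedding("pca", np.zeros((4, 2)), np.array([0.8, 0.2]),
                            {"mean": np.zeros(2), "scale": np.ones(2),
                             "components": np.eye(2), "eigenvalues": np.ones(2)})
        assert retain_components(emb2, 0.75).n_components == 1
        assert retain_components(emb, 1.0).n_components == 3

    def test_never_zero_components(self, rng):
        emb = fit_pca(rng.normal(size=(20, 4)))
        assert retain_components(emb, 1e-9).n_components == 1

    def test_bad_threshold(self, rng):
        emb = fit_pca(rng.normal(size=(10, 2)))
        for t in (0.0, 1.2, -0.5):
            with pytest.raises(ParameterizationError):
                retain_components(emb, t)

    @given(a=st.floats(0.05, 1.0), b=st.floats(0.05, 1.0))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_threshold(self, a, b):
        rng = np.random.default_rng(7)
        emb = fit_pca(rng.normal(size=(25, 5)))
        lo, hi = min(a, b), max(a, b)
        assert (retain_components(emb, hi).n_components
                >= retain_components(emb, lo).n_components)

    def test_retained_state_still_projects(self, rng):
        X = rng.normal(size=(30, 5))
        emb = retain_components(fit_pca(X), 0.75)
        np.testing.assert_allclose(emb.project(X), emb.coordinates, atol=1e-10)

    def test_explained_fractions_valid(self, rng):
        for emb in (fit_pca(rng.normal(size=(30, 5))),
                    fit_mca(random_indicator(rng, 50, [2, 3, 4]))):
            assert np.all(np.diff(emb.explained) <= 1e-12)
            assert np.all(emb.explained >= 0) and np.all(emb.explained <= 1)
            assert emb.explained.sum() <= 1 + 1e-9
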
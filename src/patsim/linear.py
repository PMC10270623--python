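"""Linear embeddings: PCA on numeric blocks, MCA on indicator matrices.

Both return an :class:`Embedding` holding component scores, explained-variance
(or principal-inertia) fractions, and enough fitted state to project new rows.
Component signs are fixed by forcing the largest-magnitude loading of each
component positive, so results are reproducible across linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .encoding import EncodedMatrix
from .errors import ParameterizationError, ValidationError

_EIG_TOL = 1e-12


@dataclass
class Embedding:
    method: str  # "pca" or "mca"
    coordinates: np.ndarray  # m x c component scores
    explained: np.ndarray  # per-component explained fraction, non-increasing
    state: dict

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]

    def project(self, new_rows) -> np.ndarray:
        """Project new rows with the fitted state (training rows reproduce scores)."""
        if self.method == "pca":
            X = np.asarray(new_rows, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            if X.shape[1] != self.state["mean"].shape[0]:
                raise ValidationError(
                    f"expected {self.state['mean'].shape[0]} columns, got {X.shape[1]}")
            Xc = (X - self.state["mean"]) / self.state["scale"]
            return Xc @ self.state["components"].T
        Z = new_rows.values if isinstance(new_rows, EncodedMatrix) else np.asarray(
            new_rows, dtype=float)
        if Z.ndim == 1:
            Z = Z[None, :]
        col_coords = self.state["col_coords"]
        if Z.shape[1] != col_coords.shape[0]:
            raise ValidationError(
                f"expected {col_coords.shape[0]} indicator columns, got {Z.shape[1]}")
        return (Z / self.state["q"]) @ col_coords


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """In place: flip each component so its largest-|loading| entry is positive.

    ``loadings`` is c x p (one row per component), ``scores`` m x c.
    """
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0


def fit_pca(X, standardize: bool = True) -> Embedding:
    """PCA via SVD of the column-centered (optionally standardized) matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    m, p = X.shape
    if m < 2 or p < 1:
        raise ParameterizationError("PCA requires m >= 2 rows and p >= 1 columns")
    mean = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0, ddof=1)
        if np.any(scale == 0):
            j = int(np.flatnonzero(scale == 0)[0])
            raise ValidationError(f"column {j} is constant; cannot standardize")
    else:
        scale = np.ones(p)
    Xc = (X - mean) / scale
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (m - 1)
    keep = eigvals > _EIG_TOL * max(eigvals.max(), 1.0)
    eigvals, Vt = eigvals[keep], Vt[keep]
    scores = Xc @ Vt.T
    _fix_signs(Vt, scores)
    explained = eigvals / eigvals.sum()
    return Embedding("pca", scores, explained,
                     {"mean": mean, "scale": scale, "components": Vt,
                      "eigenvalues": eigvals})


def fit_mca(encoded: EncodedMatrix, correction: str = "none",
            unobserved: str = "error") -> Embedding:
    """Correspondence analysis of a one-hot indicator matrix.

    Scores are row principal coordinates; principal inertias are the squared
    singular values of the standardized residual matrix.  ``correction`` may be
    ``"none"`` (raw inertia fractions) or ``"benzecri"``.  ``unobserved``
    controls the handling of all-zero level columns: ``"error"`` or ``"drop"``.
    """
    if correction not in ("none", "benzecri"):
        raise ParameterizationError(f"unknown correction {correction!r}")
    Z = np.asarray(encoded.values, dtype=float)
    columns = list(encoded.columns)
    q = len({c.source for c in columns})
    if q < 1 or Z.shape[1] < 2:
        raise ParameterizationError("MCA requires at least one feature with >= 2 levels")
    col_sums = Z.sum(axis=0)
    if np.any(col_sums == 0):
        if unobserved == "drop":
            keep = col_sums > 0
            Z = Z[:, keep]
            columns = [c for c, k in zip(columns, keep) if k]
            col_sums = Z.sum(axis=0)
        else:
            j = int(np.flatnonzero(col_sums == 0)[0])
            raise ValidationError(
                f"level {columns[j].level!r} of {columns[j].source!r} is unobserved")
    for source in {c.source for c in columns}:
        idx = [i for i, c in enumerate(columns) if c.source == source]
        if not np.allclose(Z[:, idx].sum(axis=1), 1.0):
            raise ValidationError(f"indicator block for {source!r} does not sum to 1 per row")

    n = Z.sum()
    P = Z / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    inertias = s**2
    keep = inertias > _EIG_TOL
    inertias, U, s, Vt = inertias[keep], U[:, keep], s[keep], Vt[keep]

    col_coords = Vt.T / np.sqrt(c)[:, None]  # standard column coordinates, J x c
    scores = (U * s) / np.sqrt(r)[:, None]  # row principal coordinates
    _fix_signs(col_coords.T, scores)

    if correction == "benzecri":
        adj = np.where(inertias > 1.0 / q,
                       (q / (q - 1.0) * (inertias - 1.0 / q))**2, 0.0)
        explained = adj / adj.sum() if adj.sum() > 0 else np.full_like(adj, np.nan)
    else:
        explained = inertias / inertias.sum()

    return Embedding("mca", scores, explained,
                     {"col_coords": col_coords, "q": q, "inertias": inertias,
                      "columns": columns, "total_inertia": float(inertias.sum())})


def retain_components(embedding: Embedding, threshold: float) -> Embedding:
    """Keep the smallest leading c whose cumulative explained fraction meets ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ParameterizationError(f"threshold must be in (0, 1], got {threshold}")
    cum = np.cumsum(embedding.explained)
    reached = np.flatnonzero(cum >= threshold - 1e-12)
    c = int(reached[0]) + 1 if reached.size else len(cum)
    c = max(c, 1)
    state = dict(embedding.state)
    if embedding.method == "pca":
        state["components"] = state["components"][:c]
        state["eigenvalues"] = state["eigenvalues"][:c]
    else:
        state["col_coords"] = state["col_coords"][:, :c]
        state["inertias"] = state["inertias"][:c]
    return replace(embedding, coordinates=embedding.coordinates[:, :c],
                   explained=embedding.explained[:c], state=state)
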
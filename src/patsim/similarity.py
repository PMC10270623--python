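"""Pairwise Euclidean distances, neighbor retrieval, and best-match selection.

The best-match rule skips candidates whose raw feature vector is identical to
the reference on every schema feature, returning the closest genuinely
different patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .cohort import Cohort
from .errors import ParameterizationError, ValidationError

_CHUNK_ROWS = 4096


@dataclass
class DistanceMatrix:
    values: np.ndarray  # m x m, symmetric, zero diagonal
    ids: list

    @property
    def m(self) -> int:
        return self.values.shape[0]

    def index_of(self, patient_id) -> int:
        return self.ids.index(patient_id)

    def to_long(self) -> pd.DataFrame:
        """Long-format upper triangle (id_i, id_j, distance) for i < j."""
        iu, ju = np.triu_indices(self.m, k=1)
        ids = np.asarray(self.ids, dtype=object)
        return pd.DataFrame({"id_i": ids[iu], "id_j": ids[ju],
                             "distance": self.values[iu, ju]})


@dataclass
class NeighborSet:
    ids: list
    indices: np.ndarray  # m x N positions into ids
    distances: np.ndarray  # m x N, non-decreasing along each row

    @property
    def n_neighbors(self) -> int:
        return self.indices.shape[1]

    def to_frame(self) -> pd.DataFrame:
        ids = np.asarray(self.ids, dtype=object)
        rows = []
        for i in range(len(ids)):
            for rank in range(self.n_neighbors):
                rows.append((ids[i], rank + 1, ids[self.indices[i, rank]],
                             self.distances[i, rank]))
        return pd.DataFrame(rows, columns=["patient_id", "rank", "neighbor_id", "distance"])


def pairwise_distances(coords, ids=None) -> DistanceMatrix:
    """Dense Euclidean distance matrix, computed in row chunks for large m."""
    X = np.asarray(coords, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise ValidationError("coordinates contain non-finite values")
    m = X.shape[0]
    D = np.empty((m, m))
    for start in range(0, m, _CHUNK_ROWS):
        D[start:start + _CHUNK_ROWS] = cdist(X[start:start + _CHUNK_ROWS], X)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    if ids is None:
        ids = list(range(m))
    return DistanceMatrix(D, list(ids))


def nearest_neighbors(dist: DistanceMatrix, n_neighbors: int) -> NeighborSet:
    """Per patient, the N smallest off-diagonal distances; ties by ascending index."""
    m = dist.m
    if not 1 <= n_neighbors <= m - 1:
        raise ParameterizationError(f"n_neighbors must be in [1, {m - 1}]")
    D = dist.values.copy()
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")[:, :n_neighbors]
    rows = np.arange(m)[:, None]
    return NeighborSet(dist.ids, order, D[rows, order])


def best_match_nonidentical(dist: DistanceMatrix, cohort: Cohort, reference_id):
    """Closest patient differing from the reference on at least one raw feature."""
    ref_pos = dist.index_of(reference_id)
    values = cohort.table.to_numpy(dtype=object)
    ref_row = values[cohort.ids.index(reference_id)]
    D = dist.values[ref_pos].copy()
    D[ref_pos] = np.inf
    for pos in np.argsort(D, kind="stable"):
        if not np.isfinite(D[pos]):
            break
        candidate_id = dist.ids[pos]
        cand_row = values[cohort.ids.index(candidate_id)]
        if any(a != b for a, b in zip(ref_row, cand_row)):
            return candidate_id
    raise ValidationError(f"all patients are identical to reference {reference_id!r}")
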
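"""Cross-session neuron matching from centroid geometry.

Matches are mutual nearest neighbours within a maximal centroid distance
(default 10 μm, the standard co-registration ceiling), resolved greedily by
ascending distance, which guarantees a one-to-one table.  3D distance is used
when a depth coordinate is present, 2D otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger("wmcrys.registration")

DEFAULT_MAX_DIST_UM = 10.0


@dataclass
class MatchTable:
    """One-to-one matches between two sessions' neurons.

    ``pairs`` has columns (index_i, index_j, distance); ``id_i``/``id_j``
    carry the sessions' neuron identifiers for the same rows.
    """

    pairs: pd.DataFrame
    unmatched_i: np.ndarray
    unmatched_j: np.ndarray
    max_dist: float

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    def index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Positional index arrays (into centroids_i / centroids_j)."""
        return (self.pairs["index_i"].to_numpy(),
                self.pairs["index_j"].to_numpy())


def match_neurons(centroids_i: np.ndarray, centroids_j: np.ndarray,
                  max_dist: float = DEFAULT_MAX_DIST_UM,
                  ids_i: np.ndarray | None = None,
                  ids_j: np.ndarray | None = None) -> MatchTable:
    """Match neurons across two sessions by centroid proximity."""
    ci = np.asarray(centroids_i, dtype=float)
    cj = np.asarray(centroids_j, dtype=float)
    if ci.ndim != 2 or cj.ndim != 2:
        raise ValueError("centroid arrays must be 2-D [n_neurons, n_coords]")
    if ci.shape[0] == 0 or cj.shape[0] == 0:
        raise ValueError("centroid arrays must be non-empty")
    if ci.shape[1] != cj.shape[1]:
        raise ValueError(
            f"coordinate dimension mismatch: {ci.shape[1]} vs {cj.shape[1]}")

    tree_j = cKDTree(cj)
    tree_i = cKDTree(ci)
    d_ij, nn_ij = tree_j.query(ci, k=1)  # nearest j for each i
    d_ji, nn_ji = tree_i.query(cj, k=1)  # nearest i for each j

    cand = [(d_ij[i], i, int(nn_ij[i])) for i in range(len(ci))
            if d_ij[i] <= max_dist and nn_ji[int(nn_ij[i])] == i]
    cand.sort()
    used_i: set[int] = set()
    used_j: set[int] = set()
    rows = []
    for dist, i, j in cand:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        rows.append((i, j, float(dist)))

    pairs = pd.DataFrame(rows, columns=["index_i", "index_j", "distance"])
    if ids_i is not None:
        pairs["id_i"] = np.asarray(ids_i)[pairs["index_i"]] if len(pairs) \
            else np.array([], dtype=np.asarray(ids_i).dtype)
    if ids_j is not None:
        pairs["id_j"] = np.asarray(ids_j)[pairs["index_j"]] if len(pairs) \
            else np.array([], dtype=np.asarray(ids_j).dtype)
    unmatched_i = np.setdiff1d(np.arange(len(ci)), pairs["index_i"])
    unmatched_j = np.setdiff1d(np.arange(len(cj)), pairs["index_j"])
    return MatchTable(pairs=pairs, unmatched_i=unmatched_i,
                      unmatched_j=unmatched_j, max_dist=max_dist)


def match_sessions(session_i, session_j,
                   max_dist: float = DEFAULT_MAX_DIST_UM) -> MatchTable:
    """Match two :class:`~wmcrys.task_model.Session` objects by centroids."""
    return match_neurons(session_i.centroids, session_j.centroids,
                         max_dist=max_dist, ids_i=session_i.neuron_ids,
                         ids_j=session_j.neuron_ids)
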
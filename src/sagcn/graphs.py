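"""Construction of low-order and high-order functional graph networks.

From each time-series window two graph views are built over the same R ROIs:

* **Lo-FGN** (low order): adjacency is the Pearson functional-connectivity
  matrix with weak edges removed (|rho| < t zeroed); node features are the
  per-ROI mean and variance of the windowed BOLD signal.
* **Ho-FGN** (high order): "correlation of correlation" — the adjacency
  correlates pairs of connectivity *profiles* (rows of the FC matrix, with
  the two self/cross positions excluded to avoid unit-diagonal inflation);
  node features are the raw FC rows themselves.

Thresholding keeps edge magnitudes by default (weighted graph) so degrees
stay nonnegative for the symmetric normalisation used in the model; a binary
mode replaces survivors with 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .windowing import WindowSeries

logger = logging.getLogger("sagcn")


@dataclass
class FCMatrix:
    """Pearson functional connectivity for one window: symmetric, unit diagonal."""

    values: np.ndarray  # (R, R)
    subject_id: str = ""
    window_index: int = 0


@dataclass
class Adjacency:
    """Thresholded nonnegative adjacency with zero diagonal."""

    values: np.ndarray  # (R, R)
    threshold: float = 0.0


@dataclass
class GraphSample:
    adjacency: Adjacency
    node_features: np.ndarray  # (R, 2) for Lo, (R, R) for Ho
    label: int
    subject_id: str
    window_index: int
    view: str  # "lo" | "ho"

    @property
    def n_nodes(self) -> int:
        return self.adjacency.values.shape[0]


def pearson_fc(window: WindowSeries) -> FCMatrix:
    """Pearson correlation between every pair of ROI column series.

    ROIs with zero temporal variance get correlation 0 to all others (with a
    warning) rather than NaN; the diagonal stays 1.
    """
    x = window.series
    if x.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for a stable correlation")
    sd = x.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(x, rowvar=False)
    if flat.size:
        logger.warning(
            "window %s/%d: %d zero-variance ROI(s) %s, correlations set to 0",
            window.subject_id, window.window_index, flat.size, flat.tolist(),
        )
        fc[flat, :] = 0.0
        fc[:, flat] = 0.0
    np.fill_diagonal(fc, 1.0)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    return FCMatrix(fc, window.subject_id, window.window_index)


def threshold_adjacency(fc, t: float, binary: bool = False) -> Adjacency:
    """Sparsify a correlation-type matrix: zero |value| < t, drop the diagonal.

    Survivors keep their magnitude (weighted mode) or become 1 (binary mode).
    """
    if not (0.0 < t <= 1.0):
        raise ValueError(f"threshold must lie in (0, 1], got {t}")
    vals = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    mag = np.abs(vals)
    keep = mag >= t
    np.fill_diagonal(keep, False)
    adj = np.where(keep, 1.0 if binary else mag, 0.0)
    return Adjacency(adj, threshold=t)


def lo_node_features(window: WindowSeries, ddof: int = 1) -> np.ndarray:
    """Per-ROI (mean, variance) of the windowed BOLD signal, shape (R, 2).

    Variance uses the unbiased n-1 convention by default (``ddof=0`` for the
    population convention).
    """
    if window.series.shape[0] < 2:
        raise ValueError("need at least 2 timepoints for a variance")
    return np.column_stack(
        [window.series.mean(axis=0), window.series.var(axis=0, ddof=ddof)]
    )


def high_order_fc(fc: FCMatrix) -> np.ndarray:
    """Correlation between connectivity profiles ("correlation of correlation").

    Entry (i, j) is the Pearson correlation of rows i and j of the FC matrix
    with positions i and j removed from both vectors, so the unit diagonal and
    the shared rho_ij entry cannot inflate the similarity. Profiles with zero
    variance after exclusion yield 0 (with a warning). Diagonal is 1 by
    convention.
    """
    v = fc.values
    r = v.shape[0]
    if r < 4:
        raise ValueError("high-order FC needs at least 4 ROIs")
    n = r - 2  # profile length after excluding positions i and j
    # Pairwise sums with entries i and j excluded, all vectorised:
    #   S_u[i,j]  = sum_k v[i,k] - v[i,i] - v[i,j]
    #   S_uv[i,j] = sum_k v[i,k] v[j,k] - v[i,i] v[j,i] - v[i,j] v[j,j]
    row_sum = v.sum(axis=1)
    diag = np.diag(v)
    s_u = row_sum[:, None] - diag[:, None] - v
    s_v = s_u.T
    prod = v @ v.T
    s_uv = prod - v * diag[None, :] - diag[:, None] * v.T
    sq_sum = (v**2).sum(axis=1)
    s_uu = sq_sum[:, None] - diag[:, None] ** 2 - v**2
    s_vv = s_uu.T
    cov = n * s_uv - s_u * s_v
    var_u = n * s_uu - s_u**2
    var_v = n * s_vv - s_v**2
    denom = np.sqrt(np.maximum(var_u, 0.0) * np.maximum(var_v, 0.0))
    bad = denom <= n * n * 1e-24
    np.fill_diagonal(bad, False)  # diagonal is set to 1 by convention below
    if bad.any():
        logger.warning("high-order FC: zero-variance profile(s), entries set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(bad, 0.0, cov / np.where(denom == 0, 1.0, denom))
    np.fill_diagonal(ho, 1.0)
    return np.clip((ho + ho.T) / 2.0, -1.0, 1.0)


def build_lo_fgn(window: WindowSeries, t: float, binary: bool = False, ddof: int = 1) -> GraphSample:
    """Low-order graph: thresholded FC adjacency + (mean, variance) node features."""
    fc = pearson_fc(window)
    return GraphSample(
        adjacency=threshold_adjacency(fc, t, binary=binary),
        node_features=lo_node_features(window, ddof=ddof),
        label=window.label,
        subject_id=window.subject_id,
        window_index=window.window_index,
        view="lo",
    )


def build_ho_fgn(window: WindowSeries, t: float, binary: bool = False) -> GraphSample:
    """High-order graph: thresholded profile-correlation adjacency + FC rows as features."""
    fc = pearson_fc(window)
    return GraphSample(
        adjacency=threshold_adjacency(high_order_fc(fc), t, binary=binary),
        node_features=fc.values.copy(),
        label=window.label,
        subject_id=window.subject_id,
        window_index=window.window_index,
        view="ho",
    )


def build_graph_pairs(windows: list[WindowSeries], t: float, binary: bool = False,
                      ddof: int = 1) -> list[tuple[GraphSample, GraphSample]]:
    """Build the (Lo, Ho) pair for every window, sharing one FC computation."""
    out = []
    for w in windows:
        fc = pearson_fc(w)
        lo = GraphSample(threshold_adjacency(fc, t, binary=binary),
                         lo_node_features(w, ddof=ddof), w.label,
                         w.subject_id, w.window_index, "lo")
        ho = GraphSample(threshold_adjacency(high_order_fc(fc), t, binary=binary),
                         fc.values.copy(), w.label, w.subject_id, w.window_index, "ho")
        out.append((lo, ho))
    return out
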
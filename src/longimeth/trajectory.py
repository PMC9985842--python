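"""Clustering of longitudinal methylation trajectories.

Each developmental DMP's mean beta at birth, 6 and 12 months is z-scaled
across the three timepoints and probes are partitioned with PAM-style
k-medoids under the Spearman correlation distance d = 1 - rho (with
Euclidean tie-breaking, since three ranked values take few distinct
correlation levels). The number of clusters is picked from the
within-cluster sum-of-squares curve by the maximum-distance-to-chord
(elbow) rule.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "scale_trajectories",
    "spearman_distance_matrix",
    "cluster_trajectories",
    "select_k",
    "cluster_centroids",
    "wss_curve",
]


def scale_trajectories(means: pd.DataFrame) -> pd.DataFrame:
    """Z-scale each probe's (t0, t6, t12) means to mean 0, SD 1.

    Zero-variance (flat) trajectories carry no shape and are dropped with
    a warning.
    """
    if means.shape[1] != 3:
        raise ValueError("expected exactly 3 timepoint means per probe")
    arr = means.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] < 1e-12
    if flat.any():
        warnings.warn(f"dropping {int(flat.sum())} zero-variance trajectories")
    scaled = (arr[~flat] - mu[~flat]) / sd[~flat]
    return pd.DataFrame(scaled, index=means.index[~flat], columns=means.columns)


def spearman_distance_matrix(scaled: pd.DataFrame) -> np.ndarray:
    """d = 1 - Spearman rho between trajectories (rank-Pearson on rows)."""
    ranks = np.apply_along_axis(stats.rankdata, 1, scaled.to_numpy(dtype=float))
    ranks = (ranks - ranks.mean(axis=1, keepdims=True))
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    norms[norms < 1e-12] = 1.0
    ranks /= norms
    rho = np.clip(ranks @ ranks.T, -1.0, 1.0)
    return 1.0 - rho


def _maximin_init(d: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy farthest-point seeding from a random start."""
    n = d.shape[0]
    medoids = [int(rng.integers(n))]
    min_d = d[medoids[0]].copy()
    for _ in range(k - 1):
        nxt = int(min_d.argmax())
        medoids.append(nxt)
        min_d = np.minimum(min_d, d[nxt])
    return np.asarray(medoids)


def _pam_once(
    d: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray, float]:
    n = d.shape[0]
    medoids = _maximin_init(d, k, rng)
    labels = d[:, medoids].argmin(axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                # re-seed an empty cluster at the worst-served point
                new_medoids[c] = d[np.arange(n), medoids[labels]].argmax()
                continue
            sub = d[np.ix_(members, members)]
            new_medoids[c] = members[sub.sum(axis=1).argmin()]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
        labels = d[:, medoids].argmin(axis=1)
    cost = float(d[np.arange(n), medoids[labels]].sum())
    return labels, medoids, cost


def _combined_distance(scaled: pd.DataFrame) -> np.ndarray:
    """Spearman distance with squared-Euclidean as a strict tie-breaker.

    Three-timepoint trajectories admit few distinct Spearman values
    (steps of 0.5), so the Euclidean term is scaled to stay below the
    smallest Spearman gap and only discriminates within ties.
    """
    dist = spearman_distance_matrix(scaled)
    arr = scaled.to_numpy(dtype=float)
    sq = ((arr[:, None, :] - arr[None, :, :]) ** 2).sum(-1)
    eta = 0.25 / max(sq.max(), 1e-12)
    return dist + eta * sq


def cluster_trajectories(
    scaled: pd.DataFrame, k: int, seed: int = 0, n_restarts: int = 10
) -> pd.Series:
    """PAM-style k-medoids under Spearman distance with seeded restarts."""
    n = len(scaled)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of trajectories ({n})")
    if k == 1:
        return pd.Series(1, index=scaled.index, name="cluster")
    d = _combined_distance(scaled)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        labels, _, cost = _pam_once(d, k, rng)
        if best is None or cost < best[1]:
            best = (labels, cost)
    return pd.Series(best[0] + 1, index=scaled.index, name="cluster")


def wss_curve(scaled: pd.DataFrame, k_range, seed: int = 0) -> pd.Series:
    """Total within-cluster sum of squares (on scaled values) per k.

    Enforced non-increasing over k: each k's solution is the best of the
    seeded restarts, and any residual increase is clipped to the running
    minimum.
    """
    arr = scaled.to_numpy(dtype=float)
    wss = {}
    for k in k_range:
        labels = cluster_trajectories(scaled, k, seed=seed).to_numpy()
        total = 0.0
        for c in np.unique(labels):
            members = arr[labels == c]
            total += float(((members - members.mean(axis=0)) ** 2).sum())
        wss[k] = total
    s = pd.Series(wss).sort_index()
    return pd.Series(np.minimum.accumulate(s.to_numpy()), index=s.index)


def select_k(
    scaled: pd.DataFrame, k_range=range(2, 9), seed: int = 0
) -> tuple[int, pd.Series]:
    """Elbow of the WSS curve by maximum perpendicular distance to chord.

    Returns (k*, WSS curve). A flat curve (no elbow) returns the smallest
    k with a warning.
    """
    ks = list(k_range)
    if min(ks) < 2 or max(ks) > 12:
        raise ValueError("k_range must lie within [2, 12]")
    curve = wss_curve(scaled, ks, seed=seed)
    y = np.log(np.clip(curve.to_numpy(), 1e-12, None))
    x = np.asarray(ks, dtype=float)
    if y[0] - y[-1] < 1e-9:
        warnings.warn("flat WSS curve: no elbow; returning smallest k")
        return ks[0], curve
    # distance to the chord joining the endpoints, on the log-WSS curve
    # (WSS declines multiplicatively; the log linearises proportional drops)
    x_n = (x - x[0]) / (x[-1] - x[0])
    y_n = (y - y[0]) / (y[-1] - y[0])
    dists = np.abs(y_n - x_n) / np.sqrt(2)
    if dists.max() < 0.05:
        warnings.warn("weak elbow in the WSS curve; returning smallest k")
        return ks[0], curve
    return int(x[dists.argmax()]), curve


def cluster_centroids(scaled: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Mean scaled trajectory per cluster."""
    return scaled.groupby(labels).mean()


def shape_templates(center: float = 0.3, amplitude: float = 0.08) -> pd.DataFrame:
    """Six canonical longitudinal shapes as raw beta trajectories.

    Z-scaled three-point trajectories lie on a circle in the zero-mean
    plane; the six rank orderings occupy six 60-degree arcs. Placing one
    template at each arc centre yields maximally and equally separated
    shapes: gradual up/down, early (0-6 month) up/down, and the two
    non-monotone up-down / down-up patterns.
    """
    e1 = np.array([1.0, 0.0, -1.0]) / np.sqrt(2)
    e2 = np.array([-1.0, 2.0, -1.0]) / np.sqrt(6)
    names = {
        (1, 2, 3): "gradual_up",
        (3, 2, 1): "gradual_down",
        (1, 3, 2): "early_up",
        (3, 1, 2): "early_down",
        (2, 3, 1): "up_down",
        (2, 1, 3): "down_up",
    }
    rows = {}
    for j in range(6):
        theta = j * np.pi / 3  # arc centres (boundaries sit at 30 + 60 j degrees)
        v = np.sqrt(3) * (np.cos(theta) * e1 + np.sin(theta) * e2)
        raw = center + amplitude * v
        key = tuple(int(r) for r in stats.rankdata(raw))
        rows[names[key]] = raw
    out = pd.DataFrame(rows, index=["t0", "t6", "t12"]).T
    return out.loc[["gradual_up", "gradual_down", "early_up", "early_down", "up_down", "down_up"]]
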
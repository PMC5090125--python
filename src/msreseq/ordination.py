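"""Group discrimination by non-metric multidimensional scaling.

Implements Kruskal-style NMDS (isotonic regression of configuration
distances on dissimilarity ranks, Guttman majorization updates, random
restarts), confidence ellipses of group means, a label-permutation test of
group separation, and per-site discrimination ranking.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2
from sklearn.isotonic import IsotonicRegression

from msreseq.quantify import MethylationMatrix


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # samples x k, centered, PCA-aligned
    stress: float  # Kruskal stress-1
    converged: bool
    n_starts: int
    seed: int
    sample_ids: List[str]
    stress_trace: Optional[List[float]] = None  # best start's per-iteration stress


@dataclass
class GroupEllipse:
    group: str
    center: np.ndarray
    covariance: np.ndarray  # covariance of the group mean
    level: float
    semi_axes: Tuple[float, float]
    rotation: float  # radians of the major axis


# ---------------------------------------------------------------------------
# distances


def distance_matrix(matrix: MethylationMatrix,
                    metric: str = "bray-curtis") -> pd.DataFrame:
    """Symmetric sample-by-sample distances between matrix columns."""
    data = matrix.data.to_numpy().T  # samples x sites
    samples = matrix.samples
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    if np.any(data < 0):
        raise ValueError("distance input must be nonnegative")
    if metric in ("bray-curtis", "braycurtis"):
        if np.any(data.sum(axis=1) == 0):
            raise ValueError("all-zero sample column under Bray-Curtis")
        dist = squareform(pdist(data, metric="braycurtis"))
    elif metric == "euclidean":
        dist = squareform(pdist(data, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(dist, index=samples, columns=samples)


def _check_distances(d: np.ndarray) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")


# ---------------------------------------------------------------------------
# NMDS


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:k]
    vals = np.maximum(vals[idx], 0.0)
    return vecs[:, idx] * np.sqrt(vals)


def _stress_and_fit(config_d: np.ndarray, diss_order: np.ndarray,
                    iso: IsotonicRegression) -> Tuple[float, np.ndarray]:
    """Kruskal stress-1 and isotonic-fitted disparities (condensed form)."""
    fitted = np.empty_like(config_d)
    fitted[diss_order] = iso.fit_transform(
        np.arange(diss_order.size), config_d[diss_order]
    )
    denom = float(np.sum(config_d ** 2))
    if denom <= 0:
        return 1.0, fitted
    stress = math.sqrt(float(np.sum((config_d - fitted) ** 2)) / denom)
    return stress, fitted


def _nmds_single(d: np.ndarray, x0: np.ndarray, max_iter: int,
                 tol: float) -> Tuple[np.ndarray, float, bool, List[float]]:
    n = d.shape[0]
    diss = squareform(d, checks=False)
    diss_order = np.argsort(diss, kind="stable")
    iso = IsotonicRegression(increasing=True)
    x = x0 - x0.mean(axis=0)
    best_x = x
    trace: List[float] = []
    converged = False
    prev = np.inf
    for _ in range(max_iter):
        config_d = pdist(x)
        config_d = np.maximum(config_d, 1e-12)
        stress, fitted = _stress_and_fit(config_d, diss_order, iso)
        if stress > prev:  # keep the recorded trace non-increasing
            break
        best_x = x
        trace.append(stress)
        if prev - stress < tol:
            converged = True
            break
        prev = stress
        # Guttman transform toward the disparities
        ratio = squareform(fitted / config_d, checks=False)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = (b @ x) / n
        x -= x.mean(axis=0)
    final = trace[-1] if trace else 1.0
    return best_x, final, converged, trace


def nmds(distances: pd.DataFrame, k: int = 2, n_starts: int = 20,
         max_iter: int = 300, tol: float = 1e-6, seed: int = 0) -> OrdinationResult:
    """NMDS by stress majorization with random restarts plus a metric start.

    Returns the minimum-stress solution, centered and rotated to its
    principal axes (sign-fixed) for determinism.
    """
    d = distances.to_numpy(dtype=float)
    _check_distances(d)
    n = d.shape[0]
    if n <= k:
        raise ValueError("need more samples than embedding dimensions")
    rng = np.random.default_rng(seed)
    scale = max(float(d.max()), 1e-6)

    best: Optional[Tuple[np.ndarray, float, bool, List[float]]] = None
    starts = [_classical_mds(d, k)]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(rng.normal(scale=scale, size=(n, k)))
    for x0 in starts:
        result = _nmds_single(d, x0, max_iter, tol)
        if best is None or result[1] < best[1]:
            best = result
    assert best is not None
    x, stress, converged, trace = best

    # deterministic orientation: principal axes, positive leading signs
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for j in range(x.shape[1]):
        col = x[:, j]
        lead = col[np.argmax(np.abs(col))]
        if lead < 0:
            x[:, j] = -col
    return OrdinationResult(
        coordinates=x,
        stress=float(stress),
        converged=converged,
        n_starts=len(starts),
        seed=seed,
        sample_ids=list(distances.index),
        stress_trace=trace,
    )


# ---------------------------------------------------------------------------
# ellipses and tests


def confidence_ellipse(coordinates: np.ndarray, members: Sequence[int],
                       group: str = "", level: float = 0.95) -> GroupEllipse:
    """Confidence ellipse of the *group mean* (standard-error ellipse)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    pts = np.asarray(coordinates)[list(members)]
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points for an ellipse")
    center = pts.mean(axis=0)
    cov_mean = np.cov(pts, rowvar=False) / pts.shape[0]
    q = chi2.ppf(level, df=2)
    vals, vecs = np.linalg.eigh(cov_mean)
    vals = np.maximum(vals, 0.0)
    semi = np.sqrt(vals * q)
    major = vecs[:, np.argmax(vals)]
    return GroupEllipse(
        group=group,
        center=center,
        covariance=cov_mean,
        level=level,
        semi_axes=(float(semi.max()), float(semi.min())),
        rotation=float(math.atan2(major[1], major[0])),
    )


def _separation_statistic(d: np.ndarray, labels: np.ndarray) -> float:
    """Mean between-group distance minus mean within-group distance."""
    between = d[np.ix_(labels, ~labels)]
    w1 = d[np.ix_(labels, labels)][np.triu_indices(int(labels.sum()), 1)]
    w2 = d[np.ix_(~labels, ~labels)][np.triu_indices(int((~labels).sum()), 1)]
    within = np.concatenate([w1, w2])
    return float(between.mean() - within.mean())


def permutation_group_test(distances: pd.DataFrame, groups: Dict[str, str],
                           n_perm: int = 9999, seed: int = 0
                           ) -> Tuple[float, float, bool]:
    """Label-permutation test of group separation.

    Statistic: mean between-group minus mean within-group distance.
    Exhaustive enumeration when at most 10,000 distinct relabelings exist
    (p = fraction of relabelings with statistic >= observed); otherwise
    Monte Carlo with ``p = (1 + #{>= obs}) / (1 + n_perm)``.

    Returns ``(p_value, observed_statistic, exhaustive)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    d = distances.to_numpy(dtype=float)
    _check_distances(d)
    samples = list(distances.index)
    labels_sym = [groups[s] for s in samples]
    uniq = sorted(set(labels_sym))
    if len(uniq) != 2:
        raise ValueError("need exactly two groups")
    labels = np.array([lab == uniq[0] for lab in labels_sym])
    n, n1 = labels.size, int(labels.sum())
    if n1 < 2 or n - n1 < 2:
        raise ValueError("need at least 2 samples per group")
    observed = _separation_statistic(d, labels)

    n_combos = math.comb(n, n1)
    if n_combos <= 10_000:
        count = total = 0
        for combo in itertools.combinations(range(n), n1):
            perm = np.zeros(n, dtype=bool)
            perm[list(combo)] = True
            total += 1
            if _separation_statistic(d, perm) >= observed - 1e-12:
                count += 1
        return count / total, observed, True

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n1, replace=False)] = True
        if _separation_statistic(d, perm) >= observed - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm), observed, False


def site_discrimination_ranking(matrix: MethylationMatrix,
                                coordinates: np.ndarray) -> pd.DataFrame:
    """Rank sites by |correlation| with the group-centroid axis projection."""
    by_group = matrix.group_samples()
    if len(by_group) != 2:
        raise ValueError("need exactly two groups")
    samples = matrix.samples
    idx = {s: i for i, s in enumerate(samples)}
    (g1, s1), (g2, s2) = sorted(by_group.items())
    c1 = coordinates[[idx[s] for s in s1]].mean(axis=0)
    c2 = coordinates[[idx[s] for s in s2]].mean(axis=0)
    axis = c2 - c1
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("group centroids coincide")
    projection = coordinates @ (axis / norm)

    values = matrix.data.to_numpy()
    scores = np.zeros(values.shape[0])
    proj_c = projection - projection.mean()
    proj_ss = float(np.sum(proj_c ** 2))
    for i in range(values.shape[0]):
        row = values[i]
        row_c = row - row.mean()
        denom = math.sqrt(float(np.sum(row_c ** 2)) * proj_ss)
        scores[i] = abs(float(np.dot(row_c, proj_c)) / denom) if denom > 0 else 0.0
    out = pd.DataFrame({"site_id": matrix.data.index, "score": scores})
    out = out.sort_values(
        ["score", "site_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
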
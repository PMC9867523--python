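"""Heartbeat-template outlier detectors.

Three detectors flag noisy or mislabeled beats in a :class:`BeatMatrix`:

* DBSCAN over cosine distances (fixed epsilon / MinPts); every beat outside
  the largest density cluster is an outlier.
* DMEAN: distance to the mean beat template with adaptive thresholds, plus
  an R-amplitude rule.
* NCCC: greedy cluster admission ordered by each beat's average normalized
  cross-correlation; the first rejection flags itself and every beat after.

All three are scale-free (cosine / normalized correlation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from chairkit.ecg import BeatMatrix, RetainedPeaks

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DBSCANParams:
    epsilon: float = 0.45
    min_pts: int = 10
    metric: str = "cosine"

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


@dataclass
class OutlierMask:
    """Per-beat outlier flags (True = outlier) with provenance."""

    flags: np.ndarray
    method: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)

    def __len__(self) -> int:
        return len(self.flags)

    @property
    def fraction_flagged(self) -> float:
        return float(self.flags.mean()) if len(self.flags) else 0.0


def cosine_distance_matrix(beats: BeatMatrix) -> np.ndarray:
    """Pairwise cosine distances d(i,j) = 1 - <b_i,b_j>/(|b_i||b_j|)."""
    B = beats.beats
    if len(B) < 2:
        raise ValueError("need at least 2 beats")
    norms = np.linalg.norm(B, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"zero-norm beat at index {int(zero[0])}")
    sim = (B @ B.T) / np.outer(norms, norms)
    d = 1.0 - np.clip(sim, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def _dbscan_labels(dist: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Plain DBSCAN from a precomputed distance matrix.

    Neighborhoods include the point itself.  Returns -1 for noise, else a
    cluster id; deterministic given the input order (clusters are seeded in
    index order, expansion is breadth-first).
    """
    n = len(dist)
    neighbors = [np.flatnonzero(dist[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1, dtype=int)
    visited = np.zeros(n, dtype=bool)
    cluster = 0
    for i in range(n):
        if visited[i] or not core[i]:
            continue
        # breadth-first expansion of the density-reachable set
        labels[i] = cluster
        visited[i] = True
        queue = list(neighbors[i])
        while queue:
            j = queue.pop(0)
            if labels[j] == -1:
                labels[j] = cluster  # border or core point reached
            if visited[j]:
                continue
            visited[j] = True
            if core[j]:
                queue.extend(k for k in neighbors[j] if not visited[k] or labels[k] == -1)
        cluster += 1
    return labels


def dbscan_outliers(beats: BeatMatrix, p: DBSCANParams | None = None) -> OutlierMask:
    """Flag every beat outside the largest DBSCAN cluster.

    Noise points and members of all clusters except the largest are flagged:
    the normal morphology is taken to be a single dominant cluster.
    """
    p = p or DBSCANParams()
    n = len(beats)
    if n == 0:
        return OutlierMask(np.zeros(0, dtype=bool), "dbscan", vars(p).copy())
    if n == 1:
        flags = np.array([p.min_pts > 1])
        return OutlierMask(flags, "dbscan", vars(p).copy())
    if p.metric != "cosine":
        raise ValueError(f"unsupported metric {p.metric!r}")
    dist = cosine_distance_matrix(beats)
    labels = _dbscan_labels(dist, p.epsilon, p.min_pts)
    flags = labels < 0
    if labels.max() >= 0:
        sizes = np.bincount(labels[labels >= 0])
        keep = int(np.argmax(sizes))
        flags = labels != keep
    logger.info("dbscan_outliers: flagged %d/%d beats", int(flags.sum()), n)
    return OutlierMask(flags, "dbscan", vars(p).copy())


def dmean_outliers(
    beats: BeatMatrix, c1: float = 1.5, c2: float = 2.0, c3: float = 3.0
) -> OutlierMask:
    """Distance-to-mean-template outlier rule with adaptive thresholds.

    Beat i is flagged when its cosine distance to the mean template exceeds
    ``min(c1*median(d), mean(d) + c2*SD(d))``, or when its R amplitude
    deviates from the median amplitude by more than ``c3`` robust SDs
    (1.4826 * MAD).  The amplitude deviation comparison also uses a small
    absolute floor so exact replicas are never flagged.
    """
    if len(beats) < 3:
        raise ValueError("need at least 3 beats")
    B = beats.beats
    template = B.mean(axis=0)
    tnorm = np.linalg.norm(template)
    norms = np.linalg.norm(B, axis=1)
    if tnorm == 0 or (norms == 0).any():
        raise ValueError("zero-norm beat or template")
    d = 1.0 - (B @ template) / (norms * tnorm)
    thr = min(c1 * float(np.median(d)), float(np.mean(d) + c2 * np.std(d)))
    flags = d > max(thr, 1e-12)  # floor guards the all-identical case

    pre = int(round(beats.window[0] / 1000.0 * beats.fs))
    base_n = max(1, int(round(0.040 * beats.fs)))
    amps = B[:, pre] - np.median(B[:, :base_n], axis=1)
    med = np.median(amps)
    robust_sd = 1.4826 * np.median(np.abs(amps - med))
    flags |= np.abs(amps - med) > max(c3 * robust_sd, 1e-12)
    logger.info("dmean_outliers: flagged %d/%d beats", int(flags.sum()), len(B))
    return OutlierMask(flags, "dmean", {"c1": c1, "c2": c2, "c3": c3})


def _zero_lag_ncc(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def nccc_outliers(beats: BeatMatrix, init_size: int = 20, theta: float = 0.8) -> OutlierMask:
    """Greedy admission clustering by average normalized cross-correlation.

    ``A_i`` is beat i's mean zero-lag normalized cross-correlation against
    all other beats (beats are R-aligned, so zero lag suffices).  The initial
    cluster is the ``init_size`` beats with highest A; remaining beats are
    visited in descending A and admitted while their correlation with the
    current cluster's mean template stays >= ``theta``.  The first beat to
    fail — and every beat not yet visited — is flagged.
    """
    n = len(beats)
    if n <= init_size:
        warnings.warn(
            f"nccc_outliers: {n} beats <= init_size={init_size}; nothing removed",
            stacklevel=2,
        )
        return OutlierMask(np.zeros(n, dtype=bool), "nccc", {"init_size": init_size, "theta": theta})
    B = beats.beats
    norms = np.linalg.norm(B, axis=1)
    if (norms == 0).any():
        raise ValueError("zero-norm beat")
    sim = (B @ B.T) / np.outer(norms, norms)
    A = (sim.sum(axis=1) - 1.0) / (n - 1)  # exclude self-correlation
    order = np.argsort(-A, kind="stable")
    cluster = list(order[:init_size])
    flags = np.ones(n, dtype=bool)
    flags[cluster] = False
    remaining = list(order[init_size:])
    for i in remaining:
        template = B[cluster].mean(axis=0)
        if _zero_lag_ncc(B[i], template) >= theta:
            cluster.append(i)
            flags[i] = False
        else:
            break  # i and all unvisited beats stay flagged
    logger.info("nccc_outliers: flagged %d/%d beats", int(flags.sum()), n)
    return OutlierMask(flags, "nccc", {"init_size": init_size, "theta": theta})


def apply_mask(rpeaks: np.ndarray, mask: OutlierMask) -> RetainedPeaks:
    """Drop flagged beats, keeping consecutiveness bookkeeping for HR.

    Retained indices preserve order; runs of originally-adjacent retained
    peaks are recorded so heart-rate intervals never span a removed beat.
    """
    rpeaks = np.asarray(rpeaks, dtype=int)
    if len(rpeaks) != len(mask):
        raise ValueError(f"{len(rpeaks)} peaks but mask of length {len(mask)}")
    keep = ~mask.flags
    indices = rpeaks[keep]
    runs: list[np.ndarray] = []
    current: list[int] = []
    for r, k in zip(rpeaks, keep):
        if k:
            current.append(int(r))
        elif current:
            runs.append(np.array(current))
            current = []
    if current:
        runs.append(np.array(current))
    return RetainedPeaks(indices=indices, runs=runs)
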
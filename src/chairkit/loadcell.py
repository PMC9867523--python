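"""Load-cell stream cleaning, smoothing/downsampling, center-of-mass
features, and pushbutton bout splitting.

The center of mass (CM) is expressed in a frame with origin at the RB cell,
X toward LB and Y toward F:

    CMx = (dRL * LB + dRF * F) / (RB + LB + F)
    CMy = (dBF * F) / (RB + LB + F)

All sample intervals are 0-based and half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from chairkit.chairio import ChairGeometry, SessionStream

logger = logging.getLogger(__name__)


class UnoccupiedChairError(ValueError):
    """Zero total weight: no CM is defined for an empty chair."""


@dataclass(frozen=True)
class LoadTriple:
    """Weights (grams) at the front-middle, left-back and right-back cells."""

    F: float
    LB: float
    RB: float


@dataclass(frozen=True)
class CMPoint:
    """A center-of-mass feature point for one 1-s window."""

    CMx: float
    CMy: float
    window_index: int = 0
    label: str | None = None


def repair_extreme_outliers(series: np.ndarray, max_capacity_g: float) -> np.ndarray:
    """Replace over-capacity readings with the most recent valid reading.

    Readings above ``max_capacity_g`` (or non-finite) are invalid.  Invalid
    samples are replaced by the previous valid value; a run of invalid
    samples at the start is backfilled from the first valid value so output
    length always equals input length.

    Raises
    ------
    ValueError
        If the series is empty or contains no valid sample at all.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("cannot repair an empty series")
    invalid = ~np.isfinite(series) | (series > max_capacity_g)
    if invalid.all():
        raise ValueError("every sample exceeds capacity; no valid reference value exists")
    if not invalid.any():
        return series.copy()
    out = series.copy()
    # forward-fill: index of last valid sample at or before each position
    valid_idx = np.where(~invalid, np.arange(series.size), -1)
    np.maximum.accumulate(valid_idx, out=valid_idx)
    leading = valid_idx < 0
    filled = np.where(leading, 0, valid_idx)
    out = out[filled]
    if leading.any():  # backfill leading run from the first valid value
        first_valid = int(np.argmin(invalid))
        out[leading] = series[first_valid]
    n_bad = int(invalid.sum())
    logger.info("repair_extreme_outliers: replaced %d/%d samples (cap %g g)", n_bad, series.size, max_capacity_g)
    return out


def smooth_downsample(series: np.ndarray, fs: float) -> np.ndarray:
    """Moving average over non-overlapping 1-s windows (one value per second).

    ``output[i]`` is the mean of samples ``[i*w, (i+1)*w)`` with
    ``w = floor(fs)``; a trailing partial window is discarded.
    """
    series = np.asarray(series, dtype=float)
    if fs < 1:
        raise ValueError(f"fs must be >= 1, got {fs}")
    w = int(fs)
    if w != fs:
        logger.info("smooth_downsample: non-integer fs %g, window truncated to %d samples", fs, w)
    if series.size < w:
        raise ValueError(f"series of length {series.size} shorter than one window ({w})")
    n = series.size // w
    out = series[: n * w].reshape(n, w).mean(axis=1)
    logger.info("smooth_downsample: %d samples @ %g Hz -> %d windows", series.size, fs, n)
    return out


def compute_cm(t: LoadTriple, g: ChairGeometry) -> CMPoint:
    """Center of mass of a weight triple in the seat plane (cm)."""
    total = t.F + t.LB + t.RB
    if total <= 0:
        raise UnoccupiedChairError(f"total weight {total} g: unoccupied chair, CM undefined")
    cmx = (g.dRL * t.LB + g.dRF * t.F) / total
    cmy = (g.dBF * t.F) / total
    return CMPoint(CMx=cmx, CMy=cmy)


def compute_cm_series(
    F: np.ndarray, LB: np.ndarray, RB: np.ndarray, g: ChairGeometry
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized CM over aligned weight arrays.

    Returns ``(CMx, CMy, occupied)``; windows with zero total weight are
    flagged unoccupied and carry NaN coordinates (they must be excluded from
    feature extraction, never fed to a classifier).
    """
    F, LB, RB = (np.asarray(a, dtype=float) for a in (F, LB, RB))
    total = F + LB + RB
    occupied = total > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cmx = np.where(occupied, (g.dRL * LB + g.dRF * F) / total, np.nan)
        cmy = np.where(occupied, (g.dBF * F) / total, np.nan)
    n_empty = int((~occupied).sum())
    if n_empty:
        logger.info("compute_cm_series: %d unoccupied windows excluded", n_empty)
    return cmx, cmy, occupied


def split_static_bouts(
    button: np.ndarray, labels: list[str]
) -> list[tuple[int, int, str]]:
    """Pair pushbutton presses into labeled half-open bout intervals.

    Presses are rising edges of the binary button channel; the 1st and 2nd
    press delimit bout 1, the 3rd and 4th bout 2, and so on.  Samples between
    consecutive bouts form transition periods.
    """
    button = np.asarray(button, dtype=float)
    if button.size and not np.isin(button, (0.0, 1.0)).all():
        raise ValueError("button channel must be binary")
    edges = np.flatnonzero(np.diff(np.concatenate(([0.0], button))) == 1.0)
    if edges.size % 2:
        raise ValueError(f"odd number of button presses ({edges.size}); cannot pair bout boundaries")
    n_bouts = edges.size // 2
    if n_bouts == 0:
        return []
    if len(labels) < n_bouts:
        raise ValueError(f"{n_bouts} bouts but only {len(labels)} labels")
    bouts = [(int(edges[2 * i]), int(edges[2 * i + 1]), labels[i]) for i in range(n_bouts)]
    logger.info("split_static_bouts: %d bouts from %d presses", n_bouts, edges.size)
    return bouts


def extract_cm_dataset(
    stream: SessionStream,
    g: ChairGeometry,
    labels: list[str] | None = None,
    bouts: list[tuple[int, int, str]] | None = None,
) -> pd.DataFrame:
    """Run the full feature pipeline on a session.

    repair -> (bout-aligned) 1-s moving-average downsample -> CM.  When the
    session has a button channel (or explicit ``bouts``), windows are aligned
    to each bout start and labeled; otherwise the whole stream is one
    unlabeled block.

    Returns a frame with columns ``window_index, CMx, CMy, label``.
    """
    fs = stream.fs_loadcell
    chans = {c: repair_extreme_outliers(stream.channels[c], g.max_capacity_g) for c in ("F_g", "LB_g", "RB_g")}
    if bouts is None:
        if "button" in stream.channels and labels is not None:
            bouts = split_static_bouts(stream.channels["button"], labels)
        else:
            bouts = [(0, len(chans["F_g"]), None)]  # type: ignore[list-item]

    rows = []
    widx = 0
    for start, end, label in bouts:
        if end - start < int(fs):
            logger.info("bout [%d, %d) shorter than one window; skipped", start, end)
            continue
        means = {c: smooth_downsample(chans[c][start:end], fs) for c in chans}
        cmx, cmy, occ = compute_cm_series(means["F_g"], means["LB_g"], means["RB_g"], g)
        for x, y, ok in zip(cmx, cmy, occ):
            if ok:
                rows.append({"window_index": widx, "CMx": x, "CMy": y, "label": label})
            widx += 1
    return pd.DataFrame(rows, columns=["window_index", "CMx", "CMy", "label"])
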
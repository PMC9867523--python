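"""Synthetic posture sessions and ECG signals with ground truth.

The posture generator draws center-of-mass (CM) points from per-class 2-D
Gaussian clusters (a packaged statistics fixture provides the default
means/SDs/ranges), inverts the CM equations to per-cell weights that
conserve total body weight, and assembles full sessions with pushbutton
bout markers, sensor jitter and over-capacity spikes.  The ECG generator
builds beats from Gaussian bumps (P, Q, R, S, T) with known R-peak indices
and supports localized broadband artifact bursts.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chairkit.chairio import ChairGeometry, SessionStream
from chairkit.ecg import EcgSignal
from chairkit.loadcell import CMPoint, LoadTriple

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# posture cluster statistics

@dataclass
class PostureStats:
    """Per-class CM cluster statistics (mean/SD/max/min per axis, cm)."""

    table: pd.DataFrame  # indexed by class name

    REQUIRED = ("mean_x", "sd_x", "max_x", "min_x", "mean_y", "sd_y", "max_y", "min_y")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"stats table missing columns: {sorted(missing)}")
        t = self.table
        for ax in ("x", "y"):
            bad = ~((t[f"min_{ax}"] <= t[f"mean_{ax}"]) & (t[f"mean_{ax}"] <= t[f"max_{ax}"]))
            if bad.any():
                raise ValueError(f"min <= mean <= max violated for {list(t.index[bad])}")
            if (t[f"sd_{ax}"] <= 0).any():
                raise ValueError("sd must be positive")

    @property
    def classes(self) -> list[str]:
        return list(self.table.index)

    def row(self, cls: str) -> pd.Series:
        if cls not in self.table.index:
            raise KeyError(f"unknown posture class {cls!r}")
        return self.table.loc[cls]

    @classmethod
    def from_csv(cls, path) -> "PostureStats":
        frame = pd.read_csv(path).set_index("class")
        return cls(frame)

    @classmethod
    def default(cls) -> "PostureStats":
        ref = importlib.resources.files("chairkit") / "data" / "posture_stats.csv"
        with importlib.resources.as_file(ref) as p:
            return cls.from_csv(p)


def gen_cm_samples(
    stats: PostureStats,
    cls: str,
    n: int,
    seed: int,
    truncate: bool = False,
) -> np.ndarray:
    """Draw ``n`` (CMx, CMy) samples from a class's axis-aligned Gaussian.

    With ``truncate``, draws outside the class's [min, max] box are redrawn
    (rejection sampling).  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    row = stats.row(cls)
    rng = np.random.default_rng(seed)
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = n - filled
        draw = np.column_stack([
            rng.normal(row["mean_x"], row["sd_x"], m),
            rng.normal(row["mean_y"], row["sd_y"], m),
        ])
        if truncate:
            ok = (
                (draw[:, 0] >= row["min_x"]) & (draw[:, 0] <= row["max_x"])
                & (draw[:, 1] >= row["min_y"]) & (draw[:, 1] <= row["max_y"])
            )
            draw = draw[ok]
        out[filled : filled + len(draw)] = draw
        filled += len(draw)
    return out


def gen_cm_dataset(
    stats: PostureStats, classes, n_per_class: int, seed: int, truncate: bool = False
):
    """Stacked labeled CM samples for several classes (one sub-seed each)."""
    xs, ys = [], []
    for i, cls in enumerate(classes):
        xs.append(gen_cm_samples(stats, cls, n_per_class, seed + 10_000 * i, truncate))
        ys.extend([cls] * n_per_class)
    return np.vstack(xs), np.array(ys, dtype=object)


# ---------------------------------------------------------------------------
# CM -> weights inversion and session assembly

def invert_cm(cm: CMPoint, total_weight_g: float, g: ChairGeometry) -> LoadTriple:
    """Distribute a total weight over the three cells to realize a CM.

    Inverts the CM equations: F = W*CMy/dBF, LB = (W*CMx - dRF*F)/dRL,
    RB = W - LB - F.  The CM must lie inside the triangle with vertices
    (0, 0), (dRL, 0), (dRF, dBF), else a component would be negative.
    """
    W = total_weight_g
    F = W * cm.CMy / g.dBF
    LB = (W * cm.CMx - g.dRF * F) / g.dRL
    RB = W - LB - F
    if min(F, LB, RB) < 0:
        raise ValueError(
            f"CM ({cm.CMx:.3f}, {cm.CMy:.3f}) outside the support triangle: "
            f"weights F={F:.1f}, LB={LB:.1f}, RB={RB:.1f}"
        )
    return LoadTriple(F=F, LB=LB, RB=RB)


def _invert_cm_array(cmx, cmy, W: float, g: ChairGeometry):
    F = W * cmy / g.dBF
    LB = (W * cmx - g.dRF * F) / g.dRL
    RB = W - LB - F
    return F, LB, RB


def clip_to_triangle(cmx: float, cmy: float, g: ChairGeometry, margin: float = 1e-9) -> tuple[float, float]:
    """Project a CM point into the support triangle (component-wise clip)."""
    cmy = min(max(cmy, 0.0), g.dBF * (1 - margin))
    t = cmy / g.dBF
    lo = g.dRF * t
    hi = g.dRL + (g.dRF - g.dRL) * t
    return min(max(cmx, lo), hi), cmy


@dataclass
class SessionPlan:
    """Bout/transition structure and noise settings of a synthetic session."""

    bouts: list[tuple[str, float]]  # (class, duration s)
    transition_s: float = 5.0
    body_weight_g: float = 60_000.0
    noise_sd_g: float = 0.0
    spike_rate: float = 0.0
    seed: int = 0
    walk_step_sd: float = 0.005  # cm per sample, OU random walk
    walk_rho: float = 0.99

    def __post_init__(self) -> None:
        if self.body_weight_g <= 0:
            raise ValueError("body_weight_g must be positive")
        if any(d <= 0 for _, d in self.bouts):
            raise ValueError("bout durations must be positive")


@dataclass
class SessionTruth:
    """Generator-side ground truth accompanying a synthetic session."""

    bout_intervals: list[tuple[int, int, str]]
    per_sample_class: np.ndarray  # object array; None in transitions
    cm_trajectory: np.ndarray  # (n, 2) true per-sample CM
    window_cm: pd.DataFrame  # bout-aligned per-window mean CM with labels
    spike_samples: dict[str, np.ndarray] = field(default_factory=dict)


def gen_posture_session(
    plan: SessionPlan,
    stats: PostureStats | None = None,
    g: ChairGeometry | None = None,
    fs: float = 20.0,
) -> tuple[SessionStream, SessionTruth]:
    """Generate a full load-cell session with button markers and ground truth.

    Within a bout the CM performs a mean-reverting random walk (per-step SD
    ``walk_step_sd``) around one truncated draw from the class cluster,
    clipped to the class box; transitions interpolate the CM linearly between
    bout endpoints.  Weights come from :func:`invert_cm` plus optional
    Gaussian sensor noise and over-capacity spikes.  The button channel
    carries a one-sample pulse at each bout start and end.
    """
    stats = stats or PostureStats.default()
    g = g or ChairGeometry()
    rng = np.random.default_rng(plan.seed)
    w = int(fs)
    if len(plan.bouts) > 1 and int(round(plan.transition_s * fs)) < 1:
        raise ValueError("multi-bout sessions need at least one transition sample between bouts")

    seg_cm: list[np.ndarray] = []
    seg_cls: list[np.ndarray] = []
    bout_intervals: list[tuple[int, int, str]] = []
    window_rows = []
    cursor = 0
    n_trans = int(round(plan.transition_s * fs))
    prev_end_cm: np.ndarray | None = None
    widx = 0

    for cls, dur in plan.bouts:
        row = stats.row(cls)
        n = int(round(dur * fs))
        center = gen_cm_samples(stats, cls, 1, int(rng.integers(2**31)), truncate=True)[0]
        # OU walk around the bout center, contained in the class box
        steps = rng.normal(0.0, plan.walk_step_sd, size=(n, 2))
        walk = np.empty((n, 2))
        acc = np.zeros(2)
        for i in range(n):
            acc = plan.walk_rho * acc + steps[i]
            walk[i] = acc
        cm = center + walk
        cm[:, 0] = np.clip(cm[:, 0], row["min_x"], row["max_x"])
        cm[:, 1] = np.clip(cm[:, 1], row["min_y"], row["max_y"])
        cm = np.array([clip_to_triangle(x, y, g) for x, y in cm])

        if prev_end_cm is not None and n_trans > 0:
            t = (np.arange(n_trans) + 1.0) / (n_trans + 1.0)
            trans = prev_end_cm + t[:, None] * (cm[0] - prev_end_cm)
            seg_cm.append(trans)
            seg_cls.append(np.array([None] * n_trans, dtype=object))
            cursor += n_trans
        start = cursor
        seg_cm.append(cm)
        seg_cls.append(np.array([cls] * n, dtype=object))
        cursor += n
        bout_intervals.append((start, cursor, cls))
        prev_end_cm = cm[-1]
        for k in range(n // w):
            win = cm[k * w : (k + 1) * w]
            window_rows.append({
                "window_index": widx, "CMx": win[:, 0].mean(), "CMy": win[:, 1].mean(), "label": cls,
            })
            widx += 1

    # short unlabeled tail so the final bout's closing press has a sample
    n_tail = max(1, w // 2)
    seg_cm.append(np.tile(prev_end_cm, (n_tail, 1)))
    seg_cls.append(np.array([None] * n_tail, dtype=object))

    cm_all = np.vstack(seg_cm)
    cls_all = np.concatenate(seg_cls)
    n_total = len(cm_all)
    F, LB, RB = _invert_cm_array(cm_all[:, 0], cm_all[:, 1], plan.body_weight_g, g)

    channels = {"F_g": F, "LB_g": LB, "RB_g": RB}
    if plan.noise_sd_g > 0:
        for c in channels:
            channels[c] = channels[c] + rng.normal(0.0, plan.noise_sd_g, n_total)
    spike_log: dict[str, np.ndarray] = {}
    if plan.spike_rate > 0:
        for c in channels:
            hits = np.flatnonzero(rng.random(n_total) < plan.spike_rate)
            channels[c] = channels[c].copy()
            channels[c][hits] = g.max_capacity_g * rng.uniform(2.0, 20.0, hits.size)
            spike_log[c] = hits

    button = np.zeros(n_total)
    for start, end, _ in bout_intervals:
        button[start] = 1.0
        button[end] = 1.0

    stream = SessionStream(channels={**channels, "button": button}, fs_loadcell=fs)
    truth = SessionTruth(
        bout_intervals=bout_intervals,
        per_sample_class=cls_all,
        cm_trajectory=cm_all,
        window_cm=pd.DataFrame(window_rows, columns=["window_index", "CMx", "CMy", "label"]),
        spike_samples=spike_log,
    )
    logger.info("gen_posture_session: %d samples, %d bouts", n_total, len(bout_intervals))
    return stream, truth


# ---------------------------------------------------------------------------
# synthetic ECG

#: Gaussian bump parameters per wave: (offset s relative to R, amplitude
#: relative to R, width s).  Fixture conventions, configurable via gen_ecg.
BEAT_WAVES = {
    "P": (-0.12, 0.1875, 0.020),
    "Q": (-0.035, -0.125, 0.010),
    "R": (0.0, 1.0, 0.012),
    "S": (0.035, -0.1875, 0.012),
    "T": (0.22, 0.375, 0.040),
}

DEFAULT_R_AMPLITUDE = 0.8


def gen_ecg(
    fs: float,
    duration_s: float,
    hr_bpm: float = 60.0,
    hr_sd: float = 0.0,
    noise: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int = 0,
    r_amplitude: float = DEFAULT_R_AMPLITUDE,
) -> tuple[EcgSignal, np.ndarray, float]:
    """Synthesize an ECG trace with known R-peak ground truth.

    Each beat is a sum of Gaussian bumps (P, Q, R, S, T); RR intervals are
    Gaussian around ``60/hr_bpm`` with SD ``hr_sd``, truncated positive.
    ``noise`` is (baseline-wander amplitude, 50 Hz powerline amplitude,
    white-noise SD).  Returns (signal, true R sample indices, R amplitude).
    """
    if not (30.0 <= hr_bpm <= 220.0):
        raise ValueError(f"hr_bpm={hr_bpm} outside [30, 220]")
    if fs < 250:
        raise ValueError("fs must be >= 250 Hz")
    mean_rr = 60.0 / hr_bpm
    if duration_s < 2 * mean_rr:
        raise ValueError("duration must cover at least 2 beats")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    r_times = []
    tr = mean_rr / 2.0
    margin = 0.3  # keep full T wave inside the trace
    while tr < duration_s - margin:
        r_times.append(tr)
        rr = rng.normal(mean_rr, hr_sd) if hr_sd > 0 else mean_rr
        while rr <= 0.25:  # truncate positive (and above a refractory floor)
            rr = rng.normal(mean_rr, hr_sd)
        tr += rr
    r_times = np.asarray(r_times)
    r_idx = np.round(r_times * fs).astype(int)
    r_times = r_idx / fs  # snap ground truth to the sample grid

    sig = np.zeros(n)
    for rt in r_times:
        for off, rel_amp, width in BEAT_WAVES.values():
            center = rt + off
            lo = max(0, int((center - 5 * width) * fs))
            hi = min(n, int((center + 5 * width) * fs) + 1)
            if lo >= hi:
                continue
            tt = t[lo:hi] - center
            sig[lo:hi] += r_amplitude * rel_amp * np.exp(-0.5 * (tt / width) ** 2)

    base_amp, power_amp, white_sd = noise
    if base_amp > 0:
        sig += base_amp * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
    if power_amp > 0:
        sig += power_amp * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    if white_sd > 0:
        sig += rng.normal(0.0, white_sd, n)
    logger.info("gen_ecg: %d beats over %.0f s at %g Hz", len(r_idx), duration_s, fs)
    return EcgSignal(sig, fs), r_idx, r_amplitude


def inject_artifacts(
    sig: EcgSignal,
    burst_rate: float,
    burst_amp: float,
    seed: int = 0,
    r_amplitude: float = DEFAULT_R_AMPLITUDE,
) -> tuple[EcgSignal, list[tuple[int, int]]]:
    """Add localized high-amplitude broadband noise bursts.

    Burst onsets follow a Poisson process at ``burst_rate`` per minute;
    durations are uniform in 0.5–2 s; burst content is white noise of SD
    ``burst_amp * r_amplitude``, band-limited only by the downstream filter.
    Returns the contaminated signal and the half-open burst sample intervals.
    """
    if burst_amp <= 0:
        raise ValueError("burst_amp must be positive")
    rng = np.random.default_rng(seed)
    n = len(sig)
    out = sig.samples.copy()
    intervals: list[tuple[int, int]] = []
    if burst_rate > 0:
        t = 0.0
        duration_s = n / sig.fs
        while True:
            t += rng.exponential(60.0 / burst_rate)
            if t >= duration_s:
                break
            dur = rng.uniform(0.5, 2.0)
            lo = int(t * sig.fs)
            hi = min(n, int((t + dur) * sig.fs))
            out[lo:hi] += rng.normal(0.0, burst_amp * r_amplitude, hi - lo)
            intervals.append((lo, hi))
    logger.info("inject_artifacts: %d bursts", len(intervals))
    return EcgSignal(out, sig.fs, sig.role), intervals
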
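"""Single-lead ECG processing: FIR band-pass filtering, Hamilton-style
R-peak detection, beat segmentation, and signal/detection quality metrics.

Detection quality against a reference channel is summarized by

    performance (%) = 100 * TP / N_ref
    accuracy    (%) = 100 * TP / (TP + FP)

where TP/FP are true/false positive R-peak detections and N_ref the number
of reference R-peaks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

logger = logging.getLogger(__name__)

#: SNR cap (dB) reported for a zero residual.
SNR_CAP_DB = 100.0


@dataclass
class EcgSignal:
    """A single-lead ECG trace with its sampling rate."""

    samples: np.ndarray
    fs: float
    role: str = "experimental"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class BeatMatrix:
    """Fixed-length heartbeat windows aligned on their R-peaks."""

    beats: np.ndarray  # (n_beats, window_len)
    r_indices: np.ndarray
    window: tuple[float, float]  # (pre_ms, post_ms)
    fs: float

    def __post_init__(self) -> None:
        self.beats = np.atleast_2d(np.asarray(self.beats, dtype=float))
        self.r_indices = np.asarray(self.r_indices, dtype=int)
        if len(self.beats) != len(self.r_indices):
            raise ValueError("beats / r_indices length mismatch")
        if len(self.r_indices) > 1 and not (np.diff(self.r_indices) > 0).all():
            raise ValueError("r_indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.r_indices)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching detected R-peaks against a reference list."""

    TP: int
    FP: int
    FN: int
    N_ref: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.N_ref) < 0:
            raise ValueError("counts must be non-negative")
        if self.TP + self.FN != self.N_ref:
            raise ValueError("TP + FN must equal N_ref")


def bandpass_fir(sig: EcgSignal, order: int = 150, band: tuple[float, float] = (3.0, 45.0)) -> EcgSignal:
    """Linear-phase FIR band-pass (Hamming design), applied forward-backward.

    Offline zero-phase filtering: the filter of the stated order is run in
    both directions, so the effective magnitude response is squared and group
    delay cancels.  Output length equals input length.
    """
    if sig.fs <= 2 * band[1]:
        raise ValueError(f"fs={sig.fs} too low for upper band edge {band[1]} Hz")
    if len(sig) < 3 * (order + 1):
        raise ValueError(f"signal length {len(sig)} < 3*(order+1) = {3 * (order + 1)}")
    taps = sp_signal.firwin(order + 1, band, pass_zero=False, window="hamming", fs=sig.fs)
    taps -= taps.mean()  # pin H(0) to exactly zero (DC is deep in the stopband)
    filtered = sp_signal.filtfilt(taps, [1.0], sig.samples)
    return EcgSignal(filtered, sig.fs, sig.role)


@dataclass
class HamiltonParams:
    """Constants of the adaptive-threshold QRS detector."""

    buffer_len: int = 8
    refractory_ms: float = 200.0
    searchback_factor: float = 1.5
    threshold_coeff: float = 0.3125
    integration_ms: float = 80.0
    refine_ms: float = 40.0


def _detection_signal(x: np.ndarray, fs: float, p: HamiltonParams) -> np.ndarray:
    """band-limit -> differentiate -> rectify -> moving-window average."""
    nyq = fs / 2.0
    taps = sp_signal.firwin(int(fs * 0.1) | 1, [8.0, min(16.0, 0.9 * nyq)], pass_zero=False, fs=fs)
    band = sp_signal.filtfilt(taps, [1.0], x)
    rect = np.abs(np.diff(band, prepend=band[0]))
    w = max(1, int(round(p.integration_ms / 1000.0 * fs)))
    return np.convolve(rect, np.ones(w) / w, mode="same")


def detect_rpeaks(sig: EcgSignal, params: HamiltonParams | None = None) -> np.ndarray:
    """Hamilton-style adaptive-threshold QRS detection.

    Pipeline: band-limit, differentiate, rectify, ~80 ms moving-window
    average; candidate peaks are accepted against a detection threshold
    derived from running mean buffers (length ``buffer_len``) of QRS and
    noise peak heights, with a 200 ms refractory period and a search-back
    pass for RR intervals exceeding ``searchback_factor`` times the running
    average RR.  Accepted positions are refined to the local extremum of the
    band-passed signal within ±``refine_ms``.
    """
    p = params or HamiltonParams()
    fs = sig.fs
    if fs < 100:
        raise ValueError(f"fs={fs} Hz too low to resolve QRS complexes (< 100 Hz)")
    if len(sig) < 2 * fs:
        raise ValueError("signal shorter than 2 s")
    x = sig.samples
    det = _detection_signal(x, fs, p)
    if not np.any(det > 0):
        return np.array([], dtype=int)

    refractory = int(round(p.refractory_ms / 1000.0 * fs))
    cand, _ = sp_signal.find_peaks(det, distance=max(1, int(0.05 * fs)))
    if cand.size == 0:
        return np.array([], dtype=int)

    qrs_buf: list[float] = []
    noise_buf: list[float] = []
    rr_buf: list[float] = []
    # seed estimates from the first two seconds
    lead = det[: int(2 * fs)]
    qrs_est = float(np.max(lead))
    noise_est = float(np.mean(lead))
    accepted: list[int] = []

    def threshold() -> float:
        q = np.mean(qrs_buf) if qrs_buf else qrs_est
        n = np.mean(noise_buf) if noise_buf else noise_est
        return n + p.threshold_coeff * (q - n)

    def push(buf: list[float], v: float) -> None:
        buf.append(v)
        if len(buf) > p.buffer_len:
            buf.pop(0)

    def accept(idx: int) -> None:
        if accepted:
            push(rr_buf, float(idx - accepted[-1]))
        accepted.append(idx)
        push(qrs_buf, float(det[idx]))

    for idx in cand:
        if accepted and idx - accepted[-1] < refractory:
            continue
        if det[idx] > threshold():
            # search-back: long gap since the last beat -> revisit skipped candidates
            if accepted and rr_buf:
                mean_rr = float(np.mean(rr_buf))
                if idx - accepted[-1] > p.searchback_factor * mean_rr:
                    lo, hi = accepted[-1] + refractory, idx - refractory // 2
                    back = [c for c in cand if lo <= c < hi and det[c] > 0.5 * threshold()]
                    if back:
                        best = max(back, key=lambda c: det[c])
                        accept(int(best))
            accept(int(idx))
        else:
            push(noise_buf, float(det[idx]))

    if not accepted:
        return np.array([], dtype=int)

    # refine to the extremum of the band-passed waveform
    filtered = bandpass_fir(sig).samples if len(sig) >= 3 * 151 else x
    half = int(round(p.refine_ms / 1000.0 * fs))
    refined = []
    for idx in accepted:
        lo, hi = max(0, idx - half), min(len(x), idx + half + 1)
        refined.append(lo + int(np.argmax(np.abs(filtered[lo:hi]))))
    refined = np.unique(np.asarray(refined, dtype=int))
    # enforce refractory after refinement
    keep = [int(refined[0])]
    for r in refined[1:]:
        if r - keep[-1] >= refractory:
            keep.append(int(r))
    logger.info("detect_rpeaks: %d peaks in %.1f s", len(keep), len(x) / fs)
    return np.asarray(keep, dtype=int)


def segment_beats(
    sig: EcgSignal, rpeaks: np.ndarray, window: tuple[float, float] = (200.0, 400.0)
) -> BeatMatrix:
    """Cut fixed-length windows around each R-peak.

    ``window`` is (pre_ms, post_ms).  Beats whose window crosses a signal
    boundary are dropped (and logged); window length is
    ``round((pre+post)/1000*fs)`` samples.
    """
    rpeaks = np.asarray(rpeaks, dtype=int)
    if rpeaks.size > 1 and not (np.diff(rpeaks) > 0).all():
        raise ValueError("rpeaks must be strictly increasing")
    pre = int(round(window[0] / 1000.0 * sig.fs))
    total = int(round((window[0] + window[1]) / 1000.0 * sig.fs))
    beats, kept = [], []
    for r in rpeaks:
        lo = r - pre
        if lo < 0 or lo + total > len(sig):
            logger.info("segment_beats: beat at %d crosses boundary; dropped", r)
            continue
        beats.append(sig.samples[lo : lo + total])
        kept.append(r)
    arr = np.array(beats, dtype=float) if beats else np.empty((0, total))
    return BeatMatrix(arr, np.asarray(kept, dtype=int), window, sig.fs)


@dataclass
class RetainedPeaks:
    """R-peaks surviving outlier removal, with consecutiveness bookkeeping.

    ``runs`` lists maximal runs of originally-consecutive retained peaks;
    an interval spanning a removed beat belongs to no run.
    """

    indices: np.ndarray
    runs: list[np.ndarray] = field(default_factory=list)


def heart_rate(
    rpeaks: np.ndarray | RetainedPeaks,
    fs: float,
    plausible_bpm: tuple[float, float] = (40.0, 200.0),
) -> tuple[np.ndarray, float, float]:
    """Per-interval heart rate (bpm) and its mean ± SD.

    Only intervals between consecutive retained peaks contribute; intervals
    outside ``plausible_bpm`` are excluded and logged.  Fewer than two usable
    peaks yields an empty result (not an error).
    """
    if isinstance(rpeaks, RetainedPeaks):
        runs = rpeaks.runs
    else:
        runs = [np.asarray(rpeaks, dtype=int)]
    bpms = []
    for run in runs:
        if len(run) < 2:
            continue
        rr = np.diff(run) / fs
        bpms.append(60.0 / rr)
    if not bpms:
        return np.array([]), math.nan, math.nan
    bpm = np.concatenate(bpms)
    ok = (bpm >= plausible_bpm[0]) & (bpm <= plausible_bpm[1])
    if (~ok).any():
        logger.info("heart_rate: excluded %d implausible intervals", int((~ok).sum()))
    bpm = bpm[ok]
    if bpm.size == 0:
        return np.array([]), math.nan, math.nan
    return bpm, float(bpm.mean()), float(bpm.std())


def match_rpeaks(ref: np.ndarray, exp: np.ndarray, tol_ms: float, fs: float) -> MatchResult:
    """One-to-one matching of detected peaks to reference peaks.

    Greedy in-order matching within ``tol_ms`` (two-pointer over the sorted
    lists), which attains maximum-cardinality matching for interval
    compatibility on a line.  Unmatched experimental peaks count as FP,
    unmatched reference peaks as FN.
    """
    ref = np.asarray(ref, dtype=float)
    exp = np.asarray(exp, dtype=float)
    for name, arr in (("ref", ref), ("exp", exp)):
        if arr.size > 1 and not (np.diff(arr) > 0).all():
            raise ValueError(f"{name} indices must be strictly increasing")
    tol = tol_ms / 1000.0 * fs
    i = j = tp = 0
    while i < len(ref) and j < len(exp):
        if abs(ref[i] - exp[j]) <= tol:
            tp += 1
            i += 1
            j += 1
        elif ref[i] < exp[j]:
            i += 1
        else:
            j += 1
    return MatchResult(TP=tp, FP=len(exp) - tp, FN=len(ref) - tp, N_ref=len(ref))


def performance_accuracy(m: MatchResult) -> tuple[float, float | None]:
    """Detection performance and accuracy in percent.

    performance = 100*TP/N_ref; accuracy = 100*TP/(TP+FP), reported as
    ``None`` (absent, not zero) when no peak was detected at all.
    """
    if m.N_ref == 0:
        raise ValueError("N_ref must be positive")
    performance = 100.0 * m.TP / m.N_ref
    accuracy = 100.0 * m.TP / (m.TP + m.FP) if (m.TP + m.FP) > 0 else None
    return performance, accuracy


def compare_signals(exp: EcgSignal, ref: EcgSignal) -> tuple[float, float]:
    """SNR (dB) and cosine similarity of ``exp`` against the scaled reference.

    The reference is amplitude-scaled to the experimental signal by least
    squares (alpha = <exp, ref>/<ref, ref>); then
    SNR = 10*log10(sum((alpha*ref)^2) / sum((exp - alpha*ref)^2)), capped at
    +/-100 dB.  Cosine similarity is computed between ``exp`` and the scaled
    reference (invariant to the scaling magnitude, but carries its sign).
    """
    if len(exp) != len(ref):
        raise ValueError("signals must have equal length")
    if exp.fs != ref.fs:
        raise ValueError("signals must share a sampling rate")
    e, r = exp.samples, ref.samples
    rr = float(np.dot(r, r))
    ee = float(np.dot(e, e))
    if rr == 0 or ee == 0:
        raise ValueError("zero-norm input")
    alpha = float(np.dot(e, r)) / rr
    scaled = alpha * r
    resid = float(np.sum((e - scaled) ** 2))
    num = float(np.sum(scaled**2))
    if resid == 0:
        snr = SNR_CAP_DB
    elif num == 0:
        snr = -SNR_CAP_DB
    else:
        snr = float(np.clip(10.0 * np.log10(num / resid), -SNR_CAP_DB, SNR_CAP_DB))
    denom = math.sqrt(ee) * math.sqrt(float(np.sum(scaled**2)))
    cosine = float(np.dot(e, scaled) / denom) if denom > 0 else 0.0
    return snr, cosine


def r_amplitude(beats: BeatMatrix, unit_factor: float = 1.0) -> tuple[np.ndarray, float, float]:
    """Per-beat R amplitude (value at R minus baseline) and its mean ± SD.

    The baseline is the median of the first 40 ms of each beat window, so the
    measure is invariant to a constant offset.
    """
    if len(beats) == 0:
        raise ValueError("need at least one beat")
    pre = int(round(beats.window[0] / 1000.0 * beats.fs))
    base_n = max(1, int(round(0.040 * beats.fs)))
    baseline = np.median(beats.beats[:, :base_n], axis=1)
    amps = (beats.beats[:, pre] - baseline) * unit_factor
    return amps, float(amps.mean()), float(amps.std())
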
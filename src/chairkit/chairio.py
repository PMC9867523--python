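"""Session file I/O, chair geometry, and configuration.

A *session* is a time-aligned multichannel recording from the instrumented
chair: three load-cell channels (``F_g``, ``LB_g``, ``RB_g``, grams), an
optional pushbutton channel (``button``, binary) sampled at the load-cell
rate, and optional single-lead ECG channels (``ecg_exp``, ``ecg_ref``, raw
ADC units) sampled at their own rate.

Sessions are stored as plain CSV with one header row: the load-cell block is
keyed by ``lc_index`` and the ECG block by ``ecg_index``; the two blocks may
have different lengths, with the shorter block padded by empty cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

LOADCELL_CHANNELS = ("F_g", "LB_g", "RB_g", "button")
ECG_CHANNELS = ("ecg_exp", "ecg_ref")

#: Default geometry: seat-plane extents of 30.3 cm (X) by 26.1 cm (Y), front
#: cell on the midline, 50 kg rated capacity per cell.
DEFAULT_GEOMETRY = {"dRL": 30.3, "dRF": 15.15, "dBF": 26.1, "max_capacity_g": 50_000.0}


class SessionFormatError(ValueError):
    """Raised when a session file cannot be parsed against its schema."""


@dataclass(frozen=True)
class ChairGeometry:
    """Distances (cm) between the three seat load cells and the cell rating.

    The coordinate frame has its origin at the RB cell, X pointing toward LB
    and Y toward F.  ``dRL`` is the RB->LB distance along X, ``dRF`` the X
    offset of the F cell from RB, and ``dBF`` the Y offset of the F cell from
    the back cells.
    """

    dRL: float = DEFAULT_GEOMETRY["dRL"]
    dRF: float = DEFAULT_GEOMETRY["dRF"]
    dBF: float = DEFAULT_GEOMETRY["dBF"]
    max_capacity_g: float = DEFAULT_GEOMETRY["max_capacity_g"]

    def __post_init__(self) -> None:
        if not (0 < self.dRF < self.dRL):
            raise ValueError(f"require 0 < dRF < dRL, got dRF={self.dRF}, dRL={self.dRL}")
        if self.dBF <= 0:
            raise ValueError(f"dBF must be positive, got {self.dBF}")
        if self.max_capacity_g <= 0:
            raise ValueError(f"max_capacity_g must be positive, got {self.max_capacity_g}")


@dataclass
class SessionStream:
    """Named channel arrays plus sampling-rate metadata.

    ``channels`` maps channel names to 1-D float arrays.  All load-cell-rate
    channels must share one length and all ECG-rate channels another.
    """

    channels: dict[str, np.ndarray]
    fs_loadcell: float
    fs_ecg: float | None = None
    start_time: str | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lc_lens = {len(self.channels[c]) for c in LOADCELL_CHANNELS if c in self.channels}
        if len(lc_lens) > 1:
            raise ValueError(f"load-cell channels have unequal lengths: {sorted(lc_lens)}")
        ecg_lens = {len(self.channels[c]) for c in ECG_CHANNELS if c in self.channels}
        if len(ecg_lens) > 1:
            raise ValueError(f"ECG channels have unequal lengths: {sorted(ecg_lens)}")
        if self.fs_loadcell <= 0:
            raise ValueError("fs_loadcell must be positive")
        if ecg_lens and (self.fs_ecg is None or self.fs_ecg <= 0):
            raise ValueError("fs_ecg must be positive when ECG channels are present")
        if "button" in self.channels:
            btn = self.channels["button"]
            if not np.isin(btn, (0.0, 1.0)).all():
                raise ValueError("button channel must contain only 0 and 1")

    @property
    def n_loadcell(self) -> int:
        for c in LOADCELL_CHANNELS:
            if c in self.channels:
                return len(self.channels[c])
        return 0

    @property
    def n_ecg(self) -> int:
        for c in ECG_CHANNELS:
            if c in self.channels:
                return len(self.channels[c])
        return 0

    def loadcell_block(self) -> pd.DataFrame:
        cols = {c: self.channels[c] for c in LOADCELL_CHANNELS if c in self.channels}
        return pd.DataFrame(cols)


def read_session(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    fs_loadcell: float = 20.0,
    fs_ecg: float | None = None,
    require_loadcell: bool = True,
) -> SessionStream:
    """Read a session CSV into a :class:`SessionStream`.

    Parameters
    ----------
    path:
        CSV file with one header row.
    schema:
        Mapping from canonical channel names (``F_g``, ``LB_g``, ``RB_g``,
        ``button``, ``ecg_exp``, ``ecg_ref``) to column names in the file.
        Must name at least the three load-cell channels.  Channels whose
        column is optional (button/ECG) and absent from the header are simply
        omitted; a *named* load-cell column missing from the header is an
        error.
    fs_loadcell, fs_ecg:
        Sampling rates in Hz for the two channel blocks.

    Raises
    ------
    SessionFormatError
        Empty file, missing required column, or a non-numeric cell (the error
        message names the 1-based line number).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema is None:
        schema = {c: c for c in LOADCELL_CHANNELS + ECG_CHANNELS}
    for req in ("F_g", "LB_g", "RB_g"):
        if req not in schema:
            raise SessionFormatError(f"schema must name the {req!r} load-cell column")

    try:
        frame = pd.read_csv(path, dtype=str, skip_blank_lines=False)
    except pd.errors.EmptyDataError:
        raise SessionFormatError(f"{path}: empty session file") from None
    header = list(frame.columns)

    if require_loadcell:
        for canonical in ("F_g", "LB_g", "RB_g"):
            if schema[canonical] not in header:
                raise SessionFormatError(
                    f"{path}: required column {schema[canonical]!r} (for {canonical}) not in header {header}"
                )

    channels: dict[str, np.ndarray] = {}
    for canonical, column in schema.items():
        if column not in header:
            continue  # absent optional channel
        raw = frame[column]
        values = pd.to_numeric(raw, errors="coerce")
        bad = values.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise SessionFormatError(
                f"{path}: unparseable value {raw[bad.idxmax()]!r} in column {column!r} at line {line}"
            )
        arr = values.to_numpy(dtype=float)
        arr = arr[~np.isnan(arr)]  # strip block padding
        channels[canonical] = arr

    stream = SessionStream(channels=channels, fs_loadcell=fs_loadcell, fs_ecg=fs_ecg)
    logger.info(
        "read %s: %d load-cell samples @ %g Hz, %d ECG samples",
        path, stream.n_loadcell, fs_loadcell, stream.n_ecg,
    )
    return stream


def write_session(stream: SessionStream, path: str | Path) -> Path:
    """Write a session to CSV (inverse of :func:`read_session`).

    Load-cell and ECG blocks are written side by side, each keyed by its own
    sample-index column; the shorter block is padded with empty cells.
    Numeric fidelity is full ``repr`` precision, so a round trip is exact to
    well within 1e-9 relative.
    """
    path = Path(path)
    n_lc, n_ecg = stream.n_loadcell, stream.n_ecg
    n = max(n_lc, n_ecg)
    cols: dict[str, np.ndarray] = {}

    def padded(arr: np.ndarray) -> np.ndarray:
        out = np.full(n, np.nan)
        out[: len(arr)] = arr
        return out

    if n_lc:
        cols["lc_index"] = padded(np.arange(n_lc, dtype=float))
        for c in LOADCELL_CHANNELS:
            if c in stream.channels:
                cols[c] = padded(stream.channels[c])
    if n_ecg:
        cols["ecg_index"] = padded(np.arange(n_ecg, dtype=float))
        for c in ECG_CHANNELS:
            if c in stream.channels:
                cols[c] = padded(stream.channels[c])

    if not cols:  # empty-channel stream -> header-only file
        header = ",".join(LOADCELL_CHANNELS[:3])
        path.write_text(header + "\n")
        return path

    frame = pd.DataFrame(cols)
    frame.to_csv(path, index=False, float_format="%.17g")
    logger.info("wrote %s: %d load-cell samples, %d ECG samples", path, n_lc, n_ecg)
    return path


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict[str, Any] = {
    "geometry": dict(DEFAULT_GEOMETRY),
    "processing": {
        "fs_loadcell": 20.0,
        "fs_ecg": 500.0,
        "fir_order": 150,
        "fir_band": [3.0, 45.0],
        "beat_window_ms": [200.0, 400.0],
        "match_tol_ms": 100.0,
        "hamilton": {
            "buffer_len": 8,
            "refractory_ms": 200.0,
            "searchback_factor": 1.5,
            "threshold_coeff": 0.3125,
        },
        "outliers": {
            "dbscan": {"epsilon": 0.45, "min_pts": 10, "metric": "cosine"},
            "dmean": {"c1": 1.5, "c2": 2.0, "c3": 3.0},
            "nccc": {"init_size": 20, "theta": 0.8},
        },
    },
    "grids": {
        "knn_k": [250, 500, 750, 1000, 2000, 3000],
        "nc": {"metric": ["euclidean", "cityblock"]},
        "svm": {"kernel": ["linear", "rbf"], "C": [1e-3, 1e-2, 1e-1, 1.0, 10.0], "gamma": [0.05, 0.1, 0.5, 1.0]},
        "gmm": {"covariance": ["tied", "full", "diagonal", "spherical"]},
    },
}


@dataclass
class ChairConfig:
    geometry: ChairGeometry
    processing: dict[str, Any]
    grids: dict[str, Any]


def _deep_update(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> ChairConfig:
    """Load a YAML config, applying defaults for every absent key.

    ``None`` (or an empty file) returns the full default set.  Geometry
    invariants are validated; an override with ``dRF >= dRL`` raises.
    """
    merged = DEFAULT_CONFIG
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        merged = _deep_update(DEFAULT_CONFIG, raw)
    geometry = ChairGeometry(**merged["geometry"])
    return ChairConfig(geometry=geometry, processing=merged["processing"], grids=merged["grids"])
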
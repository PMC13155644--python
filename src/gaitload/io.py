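"""Trial time-series I/O.

Reads and writes uniformly sampled multi-channel trial data in two
plain-text dialects:

* ``csv`` — comma-separated with a ``# rate=<Hz>`` comment line followed by a
  header row whose first column is ``time``.
* ``sto_mot`` — tab-separated motion/storage dialect: free-form header lines
  (``nRows=``, ``nColumns=``, ``rate=`` recognised) terminated by an
  ``endheader`` sentinel, then a header row and the data table.

Both dialects round-trip losslessly to better than 1e-9 relative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TimeSeries",
    "TrialMeta",
    "read_timeseries",
    "write_timeseries",
    "load_trial",
    "TrialBundle",
]

_TIME_TOL = 1e-9  # allowed deviation from uniform spacing, seconds

# canonical channel names required per trial kind
BASE_REQUIRED = ("emg_medial_gastrocnemius", "vertical_grf")
MODEL_REQUIRED = (
    "angle_hip",
    "angle_knee",
    "angle_ankle",
    "moment_hip",
    "moment_knee",
    "moment_ankle",
    "knee_axial_force",
)


@dataclass
class TimeSeries:
    """Named channels on a shared uniform time grid.

    Attributes
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing with constant spacing.
    channels : dict of str -> ndarray
        Channel name to value array; every array has the same length as
        ``time``.
    rate : float
        Sampling rate in Hz.
    """

    time: np.ndarray
    channels: dict[str, np.ndarray]
    rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        n = self.time.size
        for name, vals in self.channels.items():
            vals = np.asarray(vals, dtype=float)
            self.channels[name] = vals
            if vals.size != n:
                raise ValueError(
                    f"channel {name!r} has {vals.size} samples, expected {n}"
                )
        _check_uniform(self.time, self.rate)

    @property
    def n_samples(self) -> int:
        return self.time.size

    def copy(self) -> "TimeSeries":
        return TimeSeries(
            self.time.copy(),
            {k: v.copy() for k, v in self.channels.items()},
            self.rate,
        )


def _check_uniform(time: np.ndarray, rate: float) -> None:
    if time.size < 2:
        return
    dt = 1.0 / rate
    diffs = np.diff(time)
    bad = np.nonzero(np.abs(diffs - dt) > _TIME_TOL + 1e-9 * abs(dt))[0]
    if bad.size:
        i = int(bad[0]) + 1
        raise ValueError(
            f"non-uniform sampling: time[{i}]={time[i]!r} deviates from "
            f"expected spacing {dt!r}"
        )
    if np.any(diffs <= 0):
        raise ValueError("time must be strictly increasing")


@dataclass
class TrialMeta:
    """Per-trial participant metadata and normalization constants."""

    participant_id: str
    session: int = 1
    trial_kind: str = "baseline"  # baseline | feedback
    body_mass: float | None = None  # kg
    height: float | None = None  # m
    treadmill_speed: float | None = None  # m/s
    mvc_values: dict[str, float] = field(default_factory=dict)
    emg_is_envelope: bool = False  # True when EMG channels are pre-conditioned

    def __post_init__(self) -> None:
        if self.session not in (1, 2):
            raise ValueError(f"session must be 1 or 2, got {self.session}")
        if self.trial_kind not in ("baseline", "feedback"):
            raise ValueError(f"unknown trial_kind {self.trial_kind!r}")
        if self.body_mass is not None and self.body_mass <= 0:
            raise ValueError("body_mass must be > 0")
        if self.height is not None and self.height <= 0:
            raise ValueError("height must be > 0")
        for m, v in self.mvc_values.items():
            if v < 0:
                raise ValueError(f"mvc value for {m!r} must be >= 0")


@dataclass
class TrialBundle:
    """A loaded, validated trial: merged time series plus metadata."""

    ts: TimeSeries
    meta: TrialMeta


def _infer_rate(time: np.ndarray, declared: float | None) -> float:
    if declared is not None:
        return float(declared)
    if time.size < 2:
        raise ValueError(
            "cannot infer sampling rate from a single sample; "
            "declare rate in the file header"
        )
    # the first interval sets the expected spacing, so a later break is
    # reported at the first sample that deviates from it
    dt = time[1] - time[0]
    if dt <= 0:
        raise ValueError("time must be strictly increasing")
    return 1.0 / dt


def _parse_table(header_line: str, data_lines: list[str], sep: str):
    names = header_line.rstrip("\n").split(sep)
    names = [n.strip() for n in names]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate column names: {dupes}")
    if not names or names[0] != "time":
        raise ValueError(f"first column must be 'time', got {names[0]!r}")
    rows = [ln.rstrip("\n").split(sep) for ln in data_lines if ln.strip()]
    data = np.array(rows, dtype=float)
    if data.ndim == 1:
        data = data.reshape(0, len(names))
    if data.shape[1] != len(names):
        raise ValueError("row width does not match header")
    return names, data


def read_timeseries(path: str | Path, dialect: str = "csv") -> TimeSeries:
    """Read a trial time-series file.

    Parameters
    ----------
    path : path
        Existing text file in the given dialect.
    dialect : {"csv", "sto_mot"}

    Raises
    ------
    ValueError
        On non-uniform time (naming the first offending index), duplicate
        column names, or a malformed header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    lines = path.read_text().splitlines()
    declared_rate: float | None = None

    if dialect in ("sto_mot", "sto", "mot"):
        try:
            end = next(i for i, ln in enumerate(lines) if ln.strip() == "endheader")
        except StopIteration:
            raise ValueError(f"{path}: missing 'endheader' sentinel")
        for ln in lines[:end]:
            if "=" in ln:
                key, _, val = ln.partition("=")
                if key.strip().lower() == "rate":
                    declared_rate = float(val)
        names, data = _parse_table(lines[end + 1], lines[end + 2 :], "\t")
    elif dialect == "csv":
        body = []
        for ln in lines:
            if ln.startswith("#"):
                stripped = ln.lstrip("#").strip()
                if stripped.lower().startswith("rate="):
                    declared_rate = float(stripped.split("=", 1)[1])
            elif ln.strip():
                body.append(ln)
        if not body:
            raise ValueError(f"{path}: empty file")
        names, data = _parse_table(body[0], body[1:], ",")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    time = data[:, 0]
    rate = _infer_rate(time, declared_rate)
    channels = {name: data[:, j] for j, name in enumerate(names) if j > 0}
    return TimeSeries(time=time, channels=channels, rate=rate)


def write_timeseries(ts: TimeSeries, path: str | Path, dialect: str = "csv") -> Path:
    """Write a TimeSeries; ``read_timeseries`` of the result reproduces the
    channels to 1e-9 relative."""
    if not ts.channels:
        raise ValueError("cannot write a TimeSeries with no channels")
    path = Path(path)
    names = ["time"] + list(ts.channels)
    cols = [ts.time] + [ts.channels[n] for n in names[1:]]
    mat = np.column_stack(cols)

    def fmt_row(row, sep):
        return sep.join(f"{v:.17g}" for v in row)

    if dialect in ("sto_mot", "sto", "mot"):
        header = [
            "gaitload",
            "version=1",
            f"nRows={mat.shape[0]}",
            f"nColumns={mat.shape[1]}",
            f"rate={ts.rate:.17g}",
            "endheader",
            "\t".join(names),
        ]
        body = [fmt_row(r, "\t") for r in mat]
    elif dialect == "csv":
        header = [f"# rate={ts.rate:.17g}", ",".join(names)]
        body = [fmt_row(r, ",") for r in mat]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(header + body) + "\n")
    return path


_UNIT_FACTORS = {
    # angles canonical: degrees
    ("angles", "deg"): 1.0,
    ("angles", "rad"): 180.0 / math.pi,
    # forces canonical: N
    ("forces", "N"): 1.0,
    ("forces", "kN"): 1e3,
    # moments canonical: N*m
    ("moments", "Nm"): 1.0,
    ("moments", "N*m"): 1.0,
}


def load_trial(config_entry: dict) -> TrialBundle:
    """Load and merge the files of one trial into a validated bundle.

    ``config_entry`` keys::

        files:       list of {path, dialect} (or a single mapping)
        channel_map: optional {file-column -> canonical name}
        units:       optional {angles: deg|rad, forces: N|kN, moments: Nm}
        modeling:    bool — require model channels and mass/height
        meta:        TrialMeta fields (participant_id, trial_kind, ...)

    Raises
    ------
    ValueError
        Missing required channel (named in the message), or missing
        mass/height for a modeling trial.
    """
    files = config_entry.get("files", [])
    if isinstance(files, dict):
        files = [files]
    if not files:
        raise ValueError("config entry lists no files")

    cmap = config_entry.get("channel_map", {})
    units = config_entry.get("units", {})
    merged: dict[str, np.ndarray] = {}
    ref: TimeSeries | None = None
    for f in files:
        ts = read_timeseries(f["path"], f.get("dialect", "csv"))
        if ref is None:
            ref = ts
        else:
            if abs(ts.rate - ref.rate) > 1e-9 or ts.n_samples != ref.n_samples:
                raise ValueError(
                    f"{f['path']}: rate/length mismatch with first file"
                )
        for name, vals in ts.channels.items():
            canon = cmap.get(name, name)
            if canon in merged:
                raise ValueError(f"channel {canon!r} provided twice")
            merged[canon] = _convert_units(canon, vals, units)
    assert ref is not None

    meta = TrialMeta(**config_entry.get("meta", {}))

    required = list(BASE_REQUIRED)
    if config_entry.get("modeling", False):
        required += list(MODEL_REQUIRED)
        if meta.body_mass is None or meta.height is None:
            raise ValueError(
                "modeling trial requires body_mass and height in meta"
            )
    missing = [ch for ch in required if ch not in merged]
    if missing:
        raise ValueError(f"missing required channel(s): {missing}")

    return TrialBundle(ts=TimeSeries(ref.time, merged, ref.rate), meta=meta)


def _convert_units(name: str, vals: np.ndarray, units: dict) -> np.ndarray:
    if name.startswith("angle_"):
        kind = "angles"
    elif name.startswith("moment_"):
        kind = "moments"
    elif name.endswith("_grf") or name.endswith("_force"):
        kind = "forces"
    else:
        return vals
    unit = units.get(kind)
    if unit is None:
        return vals
    try:
        factor = _UNIT_FACTORS[(kind, unit)]
    except KeyError:
        raise ValueError(f"unknown unit {unit!r} for {kind}")
    return vals * factor
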
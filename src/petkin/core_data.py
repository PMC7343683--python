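"""Core data containers, tabular I/O and numerical utilities.

Canonical internal units throughout the package: time in minutes, activity
concentration in kBq/mL, rate constants in min^-1.  Files may declare other
time units (notably seconds, as in BIDS-style blood files) and are converted
on read.

The fundamental objects are the regional :class:`TimeActivityCurve` (TAC) —
frame timing plus decay-corrected activity — and the :class:`BloodSet`
holding arterial whole-blood activity, plasma activity and the parent
(unmetabolised) fraction, from which the metabolite-corrected arterial input
function (AIF) is derived.  Continuous-time model evaluation happens on a
uniform :class:`FineGrid` (default 1-s step).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

SEC_PER_MIN = 60.0
#: default fine-grid step in minutes (1 second)
DEFAULT_GRID_STEP = 1.0 / 60.0
#: physical half-life of carbon-11 in minutes
C11_HALFLIFE_MIN = 20.4

_PF_TOL = 1e-9  # slack on parent fraction before declaring a file invalid


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class KineticsError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(KineticsError):
    """A file could not be parsed in the declared dialect."""


class ValidationError(KineticsError):
    """Input data violate a structural invariant (timing, ranges, keys)."""


class ConfigurationError(KineticsError):
    """An option value is outside its closed vocabulary or inconsistent."""


class DegenerateInputError(KineticsError):
    """Input is structurally valid but carries no usable signal."""


class ConvergenceError(KineticsError):
    """Nonlinear fitting failed to converge.

    ``best`` carries the best fit found so far (may be ``None``).
    """

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _as_float_vec(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be a 1-D vector")
    return arr


@dataclass
class TimeActivityCurve:
    """Framewise regional activity with frame timing.

    Parameters
    ----------
    region_name : str
        Region-of-interest label.
    frame_start, frame_end : array-like, minutes
        Frame boundaries; ``frame_end[i] > frame_start[i]`` and starts
        non-decreasing.
    activity : array-like, kBq/mL
        Decay-corrected activity concentration per frame.
    """

    region_name: str
    frame_start: np.ndarray
    frame_end: np.ndarray
    activity: np.ndarray

    def __post_init__(self):
        self.frame_start = _as_float_vec(self.frame_start, "frame_start")
        self.frame_end = _as_float_vec(self.frame_end, "frame_end")
        self.activity = _as_float_vec(self.activity, "activity")
        n = self.frame_start.size
        if not (self.frame_end.size == n and self.activity.size == n):
            raise ValidationError(
                f"TAC '{self.region_name}': vector lengths differ "
                f"({n}, {self.frame_end.size}, {self.activity.size})"
            )
        if n < 3:
            raise ValidationError(
                f"TAC '{self.region_name}': need >= 3 frames, got {n}"
            )
        if np.isnan(self.frame_start).any() or np.isnan(self.frame_end).any():
            raise ValidationError(f"TAC '{self.region_name}': NaN in frame timing")
        bad = np.nonzero(self.frame_end <= self.frame_start)[0]
        if bad.size:
            raise ValidationError(
                f"TAC '{self.region_name}': frame_end <= frame_start at row {bad[0] + 1}"
            )
        if np.any(np.diff(self.frame_start) < 0):
            raise ValidationError(
                f"TAC '{self.region_name}': frame_start must be non-decreasing"
            )

    @property
    def frame_mid(self) -> np.ndarray:
        """Frame midtimes, minutes."""
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def frame_dur(self) -> np.ndarray:
        """Frame durations, minutes."""
        return self.frame_end - self.frame_start

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    def with_activity(self, activity, region_name: str | None = None) -> "TimeActivityCurve":
        return TimeActivityCurve(
            region_name if region_name is not None else self.region_name,
            self.frame_start.copy(), self.frame_end.copy(), np.asarray(activity, float),
        )


@dataclass
class BloodSet:
    """Arterial blood time courses yielding the metabolite-corrected AIF.

    ``delay`` (minutes, default 0) shifts all blood curves later in time when
    positive; it is normally set once per measurement by delay fitting on the
    whole-brain TAC and reused for every region.
    """

    time: np.ndarray
    whole_blood: np.ndarray
    plasma: np.ndarray
    parent_fraction: np.ndarray
    delay: float = 0.0

    def __post_init__(self):
        self.time = _as_float_vec(self.time, "time")
        self.whole_blood = _as_float_vec(self.whole_blood, "whole_blood")
        self.plasma = _as_float_vec(self.plasma, "plasma")
        self.parent_fraction = _as_float_vec(self.parent_fraction, "parent_fraction")
        n = self.time.size
        if not (self.whole_blood.size == n and self.plasma.size == n
                and self.parent_fraction.size == n):
            raise ValidationError("BloodSet: vector lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("BloodSet: sample times must be strictly increasing")
        pf = self.parent_fraction
        if np.any(pf < -_PF_TOL) or np.any(pf > 1.0 + _PF_TOL):
            bad = np.nonzero((pf < -_PF_TOL) | (pf > 1.0 + _PF_TOL))[0][0]
            raise ValidationError(
                f"BloodSet: parent_fraction outside [0, 1] at row {bad} (value {pf[bad]})"
            )
        self.parent_fraction = np.clip(pf, 0.0, 1.0)

    def with_delay(self, delay: float) -> "BloodSet":
        return replace(self, time=self.time.copy(), whole_blood=self.whole_blood.copy(),
                       plasma=self.plasma.copy(),
                       parent_fraction=self.parent_fraction.copy(), delay=float(delay))


@dataclass
class FineGrid:
    """Uniform time grid with named curves, the substrate for convolution."""

    t: np.ndarray
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.t = _as_float_vec(self.t, "t")
        steps = np.diff(self.t)
        if steps.size and not np.allclose(steps, steps[0], rtol=0, atol=1e-12):
            raise ValidationError("FineGrid: spacing must be uniform")

    @classmethod
    def make(cls, t_end: float, step: float = DEFAULT_GRID_STEP) -> "FineGrid":
        n = int(np.ceil(t_end / step)) + 1
        return cls(t=np.arange(n) * step)

    @property
    def step(self) -> float:
        return float(self.t[1] - self.t[0])

    def __getitem__(self, key: str) -> np.ndarray:
        return self.values[key]

    def __setitem__(self, key: str, val) -> None:
        arr = np.asarray(val, dtype=float)
        if arr.shape != self.t.shape:
            raise ValidationError("FineGrid: curve length must match grid")
        self.values[key] = arr


# ---------------------------------------------------------------------------
# numerical utilities
# ---------------------------------------------------------------------------

def cumint(t, y) -> np.ndarray:
    """Cumulative trapezoidal integral of a sampled curve (kBq*min/mL).

    An implicit (t=0, y=0) anchor is prepended when the first sample time is
    positive — TACs start at injection with zero activity.  The result has
    the same sample times as the input.
    """
    t = _as_float_vec(t, "t")
    y = _as_float_vec(y, "y")
    if t.size != y.size:
        raise ValidationError("cumint: t and y must have equal length")
    if np.any(np.diff(t) < 0):
        raise ValidationError("cumint: times must be ascending")
    if t.size and t[0] > 0:
        t = np.concatenate([[0.0], t])
        y = np.concatenate([[0.0], y])
        return cumulative_trapezoid(y, t, initial=0.0)[1:]
    return cumulative_trapezoid(y, t, initial=0.0)


def conv_trapz(grid_t: np.ndarray, f: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Trapezoidal convolution (f * g)(t) = int_0^t f(s) g(t-s) ds on a uniform grid.

    Uses FFT convolution with end-point correction; both inputs must be
    sampled on ``grid_t``.
    """
    from scipy.signal import fftconvolve

    dt = grid_t[1] - grid_t[0]
    full = fftconvolve(f, g)[: f.size]
    return dt * (full - 0.5 * (f[0] * g + f * g[0]))


def interp_with_anchor(t, y, t_new) -> np.ndarray:
    """Linear interpolation with a (0, 0) anchor before the first sample.

    Beyond the last sample the last value is held (callers needing a decaying
    tail use :func:`_exp_tail` via :func:`sample_blood_curve`).
    """
    t = _as_float_vec(t, "t")
    y = _as_float_vec(y, "y")
    if t.size and t[0] > 0:
        t = np.concatenate([[0.0], t])
        y = np.concatenate([[0.0], y])
    return np.interp(t_new, t, y)


def _exp_tail(t, y):
    """Mono-exponential fitted to the final third of (t, y) samples.

    Returns a callable f(s).  Falls back to holding the last value when the
    tail has fewer than two positive samples or is not decaying.
    """
    n_tail = max(3, int(np.ceil(t.size / 3)))
    tt, yy = t[-n_tail:], y[-n_tail:]
    pos = yy > 0
    if pos.sum() < 2:
        return lambda s: np.full_like(np.asarray(s, float), y[-1])
    c1, c0 = np.polyfit(tt[pos], np.log(yy[pos]), 1)
    if c1 >= 0:  # non-decaying tail: refuse to extrapolate growth
        return lambda s: np.full_like(np.asarray(s, float), y[-1])
    return lambda s: np.exp(c0 + c1 * np.asarray(s, float))


def sample_blood_curve(t, y, grid_t, delay: float = 0.0) -> np.ndarray:
    """Sample a blood-domain curve onto a grid with the package conventions.

    The curve is shifted later by ``delay`` (output(tau) = input(tau - delay)),
    linearly interpolated, anchored at (0, 0) before the first sample, and
    extrapolated beyond the last sample with a mono-exponential fitted to the
    final third of samples.
    """
    t = _as_float_vec(t, "t")
    y = _as_float_vec(y, "y")
    s = np.asarray(grid_t, float) - delay
    out = interp_with_anchor(t, y, np.clip(s, 0.0, None))
    # before time zero (after shift) there is no tracer
    out = np.where(s < 0, 0.0, out)
    beyond = s > t[-1]
    if beyond.any():
        out[beyond] = _exp_tail(t, y)(s[beyond])
    return out


def aif_curve(blood: BloodSet, t_end: float | None = None,
              step: float = DEFAULT_GRID_STEP) -> FineGrid:
    """Metabolite-corrected arterial input function on a fine grid.

    The AIF is plasma activity times parent fraction, shifted by
    ``blood.delay``, interpolated with a (0, 0) anchor and a mono-exponential
    tail.  The grid also carries the (delay-shifted) whole-blood curve under
    the key ``"whole_blood"`` for blood-volume mixing.
    """
    corrected = blood.plasma * blood.parent_fraction
    if not np.any(corrected > 0):
        raise DegenerateInputError("aif_curve: metabolite-corrected plasma is all zero")
    if t_end is None:
        t_end = float(blood.time[-1])
    grid = FineGrid.make(t_end, step)
    grid["aif"] = sample_blood_curve(blood.time, corrected, grid.t, blood.delay)
    grid["whole_blood"] = sample_blood_curve(blood.time, blood.whole_blood,
                                             grid.t, blood.delay)
    return grid


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # lossless float round-trip in text

_BIDS_BLOOD_COLS = ["time", "whole_blood_radioactivity",
                    "plasma_radioactivity", "metabolite_parent_fraction"]


def _read_table(path, sep):
    try:
        # round_trip parsing: written tables must re-read bit-identically
        return pd.read_csv(path, sep=sep, comment="#",
                           float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"{path}: cannot parse table ({exc})") from exc


def _time_unit_from_comments(path, default=None):
    unit = default
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "time_unit:" in line:
                unit = line.split("time_unit:")[1].strip()
    return unit


def _to_minutes(values, unit, path):
    if unit in ("min", "minutes"):
        return np.asarray(values, float)
    if unit in ("sec", "s", "seconds"):
        return np.asarray(values, float) / SEC_PER_MIN
    raise FormatError(f"{path}: unknown time unit '{unit}'")


def read_tacs(path, dialect: str = "tacfile") -> list[TimeActivityCurve]:
    """Read regional TACs from a tabular text file.

    ``tacfile`` is the native dialect: tab-separated, a ``# time_unit: min|sec``
    comment line, then columns ``frame_start  frame_end  <region> ...``.
    ``pmod-like`` is whitespace-separated with bracketed units in the header,
    e.g. ``start[seconds] end[seconds] striatum[kBq/cc]``.
    """
    if dialect == "tacfile":
        unit = _time_unit_from_comments(path, default="min")
        df = _read_table(path, sep="\t")
        cols = list(df.columns)
        if cols[:2] != ["frame_start", "frame_end"]:
            raise FormatError(
                f"{path}: expected leading columns frame_start, frame_end, got {cols[:2]}"
            )
        start = _to_minutes(df["frame_start"], unit, path)
        end = _to_minutes(df["frame_end"], unit, path)
        regions = cols[2:]
    elif dialect == "pmod-like":
        df = _read_table(path, sep=r"\s+")
        cols = list(df.columns)
        if len(cols) < 3:
            raise FormatError(f"{path}: need start, end and at least one region column")

        def _unit_of(col):
            if "[" in col and col.endswith("]"):
                return col[col.index("[") + 1:-1]
            return "min"

        start = _to_minutes(df[cols[0]], _unit_of(cols[0]), path)
        end = _to_minutes(df[cols[1]], _unit_of(cols[1]), path)
        regions = cols[2:]
        df = df.rename(columns={c: c.split("[")[0] for c in regions})
        regions = [c.split("[")[0] for c in regions]
    else:
        raise ConfigurationError(f"unknown TAC dialect '{dialect}'")
    if not regions:
        raise FormatError(f"{path}: no region columns found")
    return [TimeActivityCurve(r, start, end, df[r].to_numpy(float)) for r in regions]


def write_tacs(tacs: list[TimeActivityCurve], path, dialect: str = "tacfile") -> None:
    """Write TACs sharing one frame schedule; inverse of :func:`read_tacs`."""
    ref = tacs[0]
    for t in tacs[1:]:
        if not (np.array_equal(t.frame_start, ref.frame_start)
                and np.array_equal(t.frame_end, ref.frame_end)):
            raise ValidationError("write_tacs: all TACs must share frame timing")
    if dialect == "tacfile":
        df = pd.DataFrame({"frame_start": ref.frame_start, "frame_end": ref.frame_end})
        for t in tacs:
            df[t.region_name] = t.activity
        buf = io.StringIO()
        buf.write("# time_unit: min\n")
        df.to_csv(buf, sep="\t", index=False, float_format=_FLOAT_FMT)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
    elif dialect == "pmod-like":
        df = pd.DataFrame({
            "start[seconds]": ref.frame_start * SEC_PER_MIN,
            "end[seconds]": ref.frame_end * SEC_PER_MIN,
        })
        for t in tacs:
            df[f"{t.region_name}[kBq/cc]"] = t.activity
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    else:
        raise ConfigurationError(f"unknown TAC dialect '{dialect}'")


def read_blood(path, dialect: str = "plain") -> BloodSet:
    """Read arterial blood data.

    ``plain`` is the native dialect (tab-separated, ``# time_unit`` comment,
    columns ``time whole_blood plasma parent_fraction``).  ``bids-blood`` is a
    minimal BIDS-PET-style ``*_blood.tsv``: columns ``time,
    whole_blood_radioactivity, plasma_radioactivity,
    metabolite_parent_fraction`` with time in seconds.
    """
    if dialect == "plain":
        unit = _time_unit_from_comments(path, default="min")
        df = _read_table(path, sep="\t")
        needed = ["time", "whole_blood", "plasma", "parent_fraction"]
        if list(df.columns)[:4] != needed:
            raise FormatError(f"{path}: expected columns {needed}")
        return BloodSet(
            time=_to_minutes(df["time"], unit, path),
            whole_blood=df["whole_blood"].to_numpy(float),
            plasma=df["plasma"].to_numpy(float),
            parent_fraction=df["parent_fraction"].to_numpy(float),
        )
    if dialect == "bids-blood":
        df = _read_table(path, sep="\t")
        missing = [c for c in _BIDS_BLOOD_COLS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing bids-blood columns {missing}")
        return BloodSet(
            time=df["time"].to_numpy(float) / SEC_PER_MIN,
            whole_blood=df["whole_blood_radioactivity"].to_numpy(float),
            plasma=df["plasma_radioactivity"].to_numpy(float),
            parent_fraction=df["metabolite_parent_fraction"].to_numpy(float),
        )
    raise ConfigurationError(f"unknown blood dialect '{dialect}'")


def write_blood(blood: BloodSet, path, dialect: str = "plain") -> None:
    """Write blood data; inverse of :func:`read_blood`."""
    if dialect == "plain":
        df = pd.DataFrame({
            "time": blood.time, "whole_blood": blood.whole_blood,
            "plasma": blood.plasma, "parent_fraction": blood.parent_fraction,
        })
        buf = io.StringIO()
        buf.write("# time_unit: min\n")
        df.to_csv(buf, sep="\t", index=False, float_format=_FLOAT_FMT)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
    elif dialect == "bids-blood":
        df = pd.DataFrame({
            "time": blood.time * SEC_PER_MIN,
            "whole_blood_radioactivity": blood.whole_blood,
            "plasma_radioactivity": blood.plasma,
            "metabolite_parent_fraction": blood.parent_fraction,
        })
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    else:
        raise ConfigurationError(f"unknown blood dialect '{dialect}'")
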
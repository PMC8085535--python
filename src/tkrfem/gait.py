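"""Gait boundary conditions: motion-table ingestion, filtering and synthesis.

The solver is driven by three stance-phase time series: knee flexion angle
(deg, prescribed), axial joint force Fz (N, compression positive, pushing
the femur onto the insert) and a varus-valgus drive moment My (N*mm, about
the anterior-posterior axis). Real trials arrive as OpenSim storage/motion
tables (IK angles, joint-reaction loads); synthetic trials emulate the
canonical two-peak stance loading with axial-force maxima at 20% (loading
response) and 80% (pre-swing) of stance.

Unit canonicalization: forces N, moments N*mm, angles deg, time s.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "GaitBC",
    "LoadCurve",
    "MotionFormatError",
    "read_motion_table",
    "lowpass_filter",
    "synth_gait",
    "build_load_curves",
    "GAIT_PATTERNS",
]


class MotionFormatError(ValueError):
    """Malformed OpenSim storage/motion file."""


@dataclass
class GaitBC:
    """Time-aligned stance-phase boundary conditions."""

    t: np.ndarray        # s, strictly increasing
    flexion: np.ndarray  # deg
    Fz: np.ndarray       # N, compression positive
    My: np.ndarray       # N*mm
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.flexion = np.asarray(self.flexion, dtype=float)
        self.Fz = np.asarray(self.Fz, dtype=float)
        self.My = np.asarray(self.My, dtype=float)
        n = len(self.t)
        if not (len(self.flexion) == len(self.Fz) == len(self.My) == n):
            raise ValueError("GaitBC series must have equal lengths")
        if n and np.any(np.diff(self.t) <= 0):
            raise ValueError("GaitBC time grid must be strictly increasing")
        if np.any(self.Fz < 0):
            raise ValueError("axial force must be >= 0 within stance")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def stance_fraction(self) -> np.ndarray:
        """Normalized stance time t/t_end in [0, 1]."""
        return self.t / self.t[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.t, "flexion_deg": self.flexion, "Fz_N": self.Fz, "My_Nmm": self.My}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "GaitBC":
        df = pd.read_csv(path)
        required = {"time", "flexion_deg", "Fz_N", "My_Nmm"}
        missing = required - set(df.columns)
        if missing:
            raise MotionFormatError(f"gait CSV missing columns: {sorted(missing)}")
        return cls(df["time"], df["flexion_deg"], df["Fz_N"], df["My_Nmm"], label)


@dataclass
class LoadCurve:
    """Piecewise-linear load curve with constant extrapolation."""

    points: np.ndarray  # (n, 2) of (time, value)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) < 2:
            raise ValueError("a load curve needs at least 2 points")
        if np.any(np.diff(self.points[:, 0]) <= 0):
            raise ValueError("load-curve times must be strictly increasing")

    interpolation = "linear"
    extend = "constant"

    def __call__(self, t):
        return np.interp(t, self.points[:, 0], self.points[:, 1])

    @property
    def t_end(self) -> float:
        return float(self.points[-1, 0])


def read_motion_table(path) -> pd.DataFrame:
    """Read an OpenSim storage/motion (.sto/.mot) table.

    Header key-value lines (``nRows``, ``nColumns``, ``inDegrees``) run up to
    an ``endheader`` line; the body is a tab/space-delimited table whose first
    column is ``time``. Returned with ``df.attrs['in_degrees']`` set from the
    header and the declared row count enforced.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    header: dict[str, str] = {}
    body_start = None
    for i, line in enumerate(lines):
        if line.strip().lower() == "endheader":
            body_start = i + 1
            break
        if "=" in line:
            key, _, val = line.partition("=")
            header[key.strip().lower()] = val.strip()
    if body_start is None:
        raise MotionFormatError(f"{path}: no 'endheader' line found")
    body = [ln for ln in lines[body_start:] if ln.strip()]
    if not body:
        raise MotionFormatError(f"{path}: empty table body")
    df = pd.read_csv(io.StringIO("\n".join(body)), sep=r"\s+")
    if "nrows" in header:
        declared = int(header["nrows"])
        if declared != len(df):
            raise MotionFormatError(
                f"{path}: header declares nRows={declared} but table has {len(df)} rows"
            )
    if "ncolumns" in header:
        declared = int(header["ncolumns"])
        if declared != df.shape[1]:
            raise MotionFormatError(
                f"{path}: header declares nColumns={declared} but table has {df.shape[1]}"
            )
    if df.columns[0].lower() != "time":
        raise MotionFormatError(f"{path}: first column must be 'time'")
    df.attrs["in_degrees"] = header.get("indegrees", "yes").lower() == "yes"
    return df


def lowpass_filter(series, cutoff: float = 6.0, order: int = 4, fs: float | None = None):
    """Zero-phase (forward-backward) Butterworth low-pass.

    ``series`` is a 1-D array sampled uniformly at ``fs`` Hz (default 120 Hz,
    the common motion-capture rate). 6 Hz / 4th order is the conventional
    gait-data choice. DC passes unchanged; tones well above cutoff are
    strongly attenuated.
    """
    x = np.asarray(series, dtype=float)
    fs = 120.0 if fs is None else float(fs)
    nyq = fs / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, Nyquist={nyq} Hz), got {cutoff}")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


#: Pattern shape constants. ``sigma`` is the Gaussian bump width (fraction of
#: stance), ``base`` the mid-stance plateau level relative to the peaks,
#: ``amp2`` the second-peak amplitude relative to the first. Bouncy gait has
#: sharper force bumps (abrupt loading), crouch a raised valley and flexed
#: baseline, smooth wide gentle bumps.
GAIT_PATTERNS = {
    "normal": dict(sigma=0.07, base=0.25, amp2=1.05, flex_base=0.0, flex_amp=20.0, my_scale=1.0),
    "bouncy": dict(sigma=0.045, base=0.20, amp2=1.08, flex_base=0.0, flex_amp=25.0, my_scale=1.2),
    "crouch": dict(sigma=0.08, base=0.50, amp2=1.02, flex_base=20.0, flex_amp=15.0, my_scale=1.0),
    "smooth": dict(sigma=0.115, base=0.30, amp2=1.03, flex_base=0.0, flex_amp=15.0, my_scale=0.8),
}

#: Stance fractions of the two vertical-force peaks (loading response,
#: pre-swing).
PEAK_FRACTIONS = (0.20, 0.80)

#: Default peak axial force, N (~2.9 x body weight for a 70 kg subject).
DEFAULT_PEAK_FORCE = 2000.0

#: Default varus-valgus drive moment amplitude, N*mm.
DEFAULT_MY_AMPLITUDE = 3000.0


def _trapezoid(s: np.ndarray, ramp: float = 0.15) -> np.ndarray:
    """Unit plateau with linear ramps at both stance ends (zero at s=0,1)."""
    return np.clip(np.minimum(s, 1.0 - s) / ramp, 0.0, 1.0)


def synth_gait(
    pattern: str,
    peak_force: float = DEFAULT_PEAK_FORCE,
    n_points: int = 101,
    seed: int = 0,
    duration: float = 1.0,
    my_amplitude: float = DEFAULT_MY_AMPLITUDE,
) -> GaitBC:
    """Synthesize stance-phase boundary conditions for one gait pattern.

    Fz is an M-shaped curve: a trapezoidal base plus two Gaussian bumps
    centered at 20% and 80% of stance (the two-peak loading of level walking),
    rescaled so the global maximum equals ``peak_force``. The seed applies a
    small smooth jitter (bump centers +-0.4% stance, amplitudes +-2%) so
    repeated trials differ slightly; the same seed reproduces the trial
    bitwise. Flexion is ``flex_base + flex_amp*sin(pi s)``; My is a smooth
    low-amplitude full-cycle sine.
    """
    if n_points < 21:
        raise ValueError("n_points must be >= 21")
    if peak_force <= 0:
        raise ValueError("peak_force must be positive")
    try:
        cfg = GAIT_PATTERNS[pattern]
    except KeyError:
        raise ValueError(
            f"unknown gait pattern {pattern!r}; expected one of {sorted(GAIT_PATTERNS)}"
        ) from None
    rng = np.random.default_rng(seed)
    c1 = PEAK_FRACTIONS[0] + rng.uniform(-0.004, 0.004)
    c2 = PEAK_FRACTIONS[1] + rng.uniform(-0.004, 0.004)
    a1 = 1.0 * (1.0 + rng.uniform(-0.02, 0.02))
    a2 = cfg["amp2"] * (1.0 + rng.uniform(-0.02, 0.02))
    s = np.linspace(0.0, 1.0, n_points)
    sig = cfg["sigma"]
    shape = cfg["base"] * _trapezoid(s)
    shape = shape + a1 * np.exp(-0.5 * ((s - c1) / sig) ** 2)
    shape = shape + a2 * np.exp(-0.5 * ((s - c2) / sig) ** 2)
    Fz = peak_force * shape / shape.max()
    flexion = cfg["flex_base"] + cfg["flex_amp"] * np.sin(np.pi * s)
    My = my_amplitude * cfg["my_scale"] * np.sin(2.0 * np.pi * s)
    return GaitBC(duration * s, flexion, Fz, My, label=pattern)


def build_load_curves(bc: GaitBC, settle_duration: float) -> dict[str, LoadCurve]:
    """Two-step load curves: a contact-settling ramp then the gait record.

    Step 1 occupies ``[0, settle_duration]``: flexion and My are held at their
    initial gait values while Fz ramps linearly from 0 (the femur descends
    until first contact and load builds up). Step 2 appends the gait curves
    shifted by ``settle_duration``.
    """
    if settle_duration <= 0:
        raise ValueError("settle_duration must be positive")
    if len(bc) == 0:
        raise ValueError("empty GaitBC")
    t2 = bc.t + settle_duration

    def shifted(values, start_value):
        pts = [(0.0, start_value)]
        if abs(values[0] - start_value) > 0 or t2[0] > settle_duration:
            pts.append((settle_duration, values[0]))
        pts += list(zip(t2, values))
        # drop duplicate time at the step boundary
        out = [pts[0]]
        for tt, vv in pts[1:]:
            if tt > out[-1][0]:
                out.append((tt, vv))
        return LoadCurve(np.asarray(out))

    return {
        "flexion": shifted(bc.flexion, bc.flexion[0]),
        "Fz": shifted(bc.Fz, 0.0),
        "My": shifted(bc.My, bc.My[0]),
    }
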
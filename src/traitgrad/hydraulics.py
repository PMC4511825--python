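"""Stem hydraulic conductivity from gravimetric flow measurements.

A cut stem segment is fed a KCl solution from a reservoir raised ~1 m
above it (hydrostatic head ~9.8 kPa) while a balance logs cumulative
outflow mass every few seconds.  From the stable part of that log:

    flow  F   [kg/s]              least-squares slope of mass vs time
    K_h   = F * L / dP            conductivity of the segment
    K_s   = K_h / A_sapwood       sapwood-specific conductivity
    PLC   = (K_max - K_s) / K_max fraction of capacity lost to embolism

where L is segment length (m), dP the pressure difference (MPa) and
A_sapwood the conductive xylem cross-section (m^2).  K_max is K_s
re-measured after flushing out embolisms; it enters only as an input.

Note K_h = F*L/dP is flux divided by the pressure *gradient* dP/L, units
kg m s^-1 MPa^-1.  Published unit strings for K_h sometimes repeat the
K_s units (kg m^-1 s^-1 MPa^-1), which is dimensionally inconsistent
with that definition; this module follows the definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STANDARD_GRAVITY = 9.8  # m/s^2; gives the conventional 9.8 kPa per metre of water
WATER_DENSITY = 1000.0  # kg/m^3


class FlowLogError(ValueError):
    """A balance log violates its invariants or is too short to analyse."""


@dataclass(frozen=True)
class FlowLog:
    """Balance time series: cumulative mass (kg) at strictly increasing times (s)."""

    time_s: np.ndarray = field(repr=False)
    mass_kg: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        m = np.asarray(self.mass_kg, dtype=float)
        if t.ndim != 1 or t.shape != m.shape:
            raise FlowLogError("time and mass must be 1-D arrays of equal length")
        if t.size < 2:
            raise FlowLogError("flow log needs at least 2 points")
        if not np.all(np.diff(t) > 0):
            raise FlowLogError("timestamps must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "mass_kg", m)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    @classmethod
    def read_csv(cls, path) -> "FlowLog":
        df = pd.read_csv(path)
        for col in ("time_s", "mass_kg"):
            if col not in df.columns:
                raise FlowLogError(f"missing column {col!r} in flow-log CSV")
        return cls(df["time_s"].to_numpy(float), df["mass_kg"].to_numpy(float))

    def write_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time_s, "mass_kg": self.mass_kg}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class StemSegment:
    """Geometry and head of one measured stem segment."""

    length_m: float
    sapwood_area_m2: float
    pressure_head_MPa: float
    segment_id: str = ""

    def __post_init__(self) -> None:
        for name in ("length_m", "sapwood_area_m2", "pressure_head_MPa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class FlowEstimate:
    """Fitted steady flow with the window it came from."""

    flow_kg_s: float
    window_start_s: float
    window_end_s: float
    r_squared: float
    negative_flow: bool
    unstable: bool  # no window reached the R^2 threshold


@dataclass(frozen=True)
class ConductivityRecord:
    """Derived conductivities for one stem segment.

    PLC is stored as a dimensionless fraction in (-inf, 1]; a negative
    value (native exceeding flushed conductivity, i.e. measurement noise)
    is kept and flagged, never clamped.
    """

    segment_id: str
    K_h: float
    K_s_native: float
    K_max: float | None = None
    PLC: float | None = None
    negative_plc: bool = False

    def __post_init__(self) -> None:
        if (self.K_max is None) != (self.PLC is None):
            raise ValueError("PLC must be present exactly when K_max is present")
        if self.K_h < 0 or self.K_s_native < 0:
            raise ValueError("conductivities must be non-negative")
        if self.PLC is not None and self.PLC > 1:
            raise ValueError("PLC cannot exceed 1")


def hydrostatic_pressure(
    height_m: float, density: float = WATER_DENSITY, g: float = STANDARD_GRAVITY
) -> float:
    """Pressure (kPa) of a fluid column: rho * g * h / 1000.

    Defaults give the conventional 9.8 kPa for a 1 m water column.
    """
    if height_m < 0:
        raise ValueError(f"column height must be >= 0, got {height_m}")
    return density * g * height_m / 1000.0


def _linear_fit(t: np.ndarray, m: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R^2; R^2 defined as 1 for a perfect fit."""
    slope, intercept = np.polyfit(t, m, 1)
    predicted = slope * t + intercept
    ss_res = float(np.sum((m - predicted) ** 2))
    ss_tot = float(np.sum((m - np.mean(m)) ** 2))
    if ss_tot == 0 or ss_res <= 1e-20 * max(ss_tot, 1.0):
        return float(slope), 1.0
    return float(slope), 1.0 - ss_res / ss_tot


def estimate_flow(
    log: FlowLog, window_s: float = 180.0, r2_threshold: float = 0.99
) -> FlowEstimate:
    """Steady flow rate (kg/s) from the stable window of a balance log.

    Slides a window of at least ``window_s`` across the log and fits a
    line to mass vs time in each.  Among windows whose fit reaches
    ``r2_threshold``, picks the one whose first-difference coefficient of
    variation is smallest (ties resolved toward the latest window, where
    flow has settled).  If no window reaches the threshold the globally
    most stable window is returned with ``unstable=True``.
    """
    if log.duration_s < window_s:
        raise FlowLogError(
            f"log spans {log.duration_s:.0f} s, shorter than the {window_s:.0f} s window"
        )
    t, m = log.time_s, log.mass_kg
    n = t.size
    candidates = []  # (diff_cv, -start_index) minimised; r2 carried along
    for start in range(n - 1):
        if t[-1] - t[start] < window_s:
            break  # no later start can span a full window either
        # first index whose time closes a window of >= window_s
        end = int(np.searchsorted(t, t[start] + window_s - 1e-9))
        end = min(max(end, start + 1), n - 1)
        sl = slice(start, end + 1)
        diffs = np.diff(m[sl])
        mean_diff = float(np.mean(diffs))
        sd_diff = float(np.std(diffs, ddof=1)) if diffs.size > 1 else 0.0
        diff_cv = 0.0 if sd_diff == 0 else np.inf if mean_diff == 0 else abs(sd_diff / mean_diff)
        slope, r2 = _linear_fit(t[sl], m[sl])
        candidates.append((diff_cv, -start, r2, slope, float(t[start]), float(t[end])))
    if not candidates:
        raise FlowLogError("no window of the requested span fits inside the log")
    stable = [c for c in candidates if c[2] >= r2_threshold]
    unstable = not stable
    pool = stable if stable else candidates
    diff_cv, neg_start, r2, slope, w0, w1 = min(pool, key=lambda c: (c[0], c[1]))
    if slope < 0:
        warnings.warn(
            f"fitted flow is negative ({slope:.3g} kg/s); check the balance log",
            stacklevel=2,
        )
    return FlowEstimate(
        flow_kg_s=slope,
        window_start_s=w0,
        window_end_s=w1,
        r_squared=r2,
        negative_flow=slope < 0,
        unstable=unstable,
    )


def compute_kh(flow_kg_s: float, length_m: float, delta_p_MPa: float) -> float:
    """Hydraulic conductivity K_h = F * L / dP (kg m s^-1 MPa^-1)."""
    if flow_kg_s < 0:
        raise ValueError(f"flow must be >= 0, got {flow_kg_s}")
    if length_m <= 0:
        raise ValueError(f"segment length must be positive, got {length_m}")
    if delta_p_MPa <= 0:
        raise ValueError(f"pressure difference must be positive, got {delta_p_MPa}")
    return flow_kg_s * length_m / delta_p_MPa


def compute_ks(kh: float, sapwood_area_m2: float) -> float:
    """Sapwood-specific conductivity K_s = K_h / A (kg m^-1 s^-1 MPa^-1)."""
    if sapwood_area_m2 <= 0:
        raise ValueError(f"sapwood area must be positive, got {sapwood_area_m2}")
    if kh < 0:
        raise ValueError(f"K_h must be >= 0, got {kh}")
    return kh / sapwood_area_m2


def compute_plc(ks_native: float, k_max: float) -> float:
    """Percent loss of conductivity as a fraction: (K_max - K_s) / K_max.

    A negative result (native above flushed maximum) is returned as-is
    with a warning — it signals measurement noise, not a valid embolism
    level, and clamping it would hide that.
    """
    if k_max <= 0:
        raise ValueError(f"K_max must be positive, got {k_max}")
    plc = (k_max - ks_native) / k_max
    if plc < 0:
        warnings.warn(
            f"PLC = {plc:.3g} < 0 (native K_s exceeds K_max); measurement noise?",
            stacklevel=2,
        )
    return plc


def conductivity_record(
    log: FlowLog,
    segment: StemSegment,
    k_max: float | None = None,
    window_s: float = 180.0,
) -> ConductivityRecord:
    """Full per-segment pipeline: flow fit -> K_h -> K_s (-> PLC if K_max given)."""
    est = estimate_flow(log, window_s=window_s)
    flow = max(est.flow_kg_s, 0.0)
    kh = compute_kh(flow, segment.length_m, segment.pressure_head_MPa)
    ks = compute_ks(kh, segment.sapwood_area_m2)
    plc = None
    negative = False
    if k_max is not None:
        plc = compute_plc(ks, k_max)
        negative = plc < 0
    return ConductivityRecord(
        segment_id=segment.segment_id,
        K_h=kh,
        K_s_native=ks,
        K_max=k_max,
        PLC=plc,
        negative_plc=negative,
    )
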
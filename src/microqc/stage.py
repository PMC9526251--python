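"""Stage drift and positioning-repeatability metrics from bead tracks.

Drift: a single bead imaged as a z-stack time-lapse is tracked by its 3D
intensity centre of mass.  Three metrics follow: the stabilisation time
τ_stab (earliest anchor frame after which the per-axis displacement from
the anchor stays below the lateral/axial resolution for every later
frame), and the mean 3D velocities V_b and V_a before and after it, in
nm/min.  Each quantity is classified standard / acceptable / critical
and the overall class is the worst of the three.

Repeatability: the bead position at repeated visits to a reference stage
position; the sample standard deviations σ_x and σ_y of those
coordinates are the repeatability values, flagged against 0.2 µm.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from microqc.core import AcquisitionMeta, DriftClassBounds, DEFAULT_TOLERANCES, ToleranceRegistry
from microqc.resolution import ResolutionSpec

NM_PER_UM = 1000.0


class DriftClass(str, enum.Enum):
    STANDARD = "standard"
    ACCEPTABLE = "acceptable"
    CRITICAL = "critical"


_CLASS_ORDER = {DriftClass.STANDARD: 0, DriftClass.ACCEPTABLE: 1, DriftClass.CRITICAL: 2}


@dataclass(frozen=True)
class TrackSeries:
    """Time-indexed bead positions: times in minutes, positions in µm.

    ``positions`` is (n, 2) or (n, 3); ``valid`` marks frames where the
    bead was actually found (lost frames are never interpolated).
    """

    times: np.ndarray
    positions: np.ndarray
    valid: Optional[np.ndarray] = None
    source: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        if p.ndim != 2 or p.shape[1] not in (2, 3):
            raise ValueError("positions must be (n, 2) or (n, 3)")
        if t.shape[0] != p.shape[0]:
            raise ValueError("one position per time point required")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        v = self.valid
        v = np.ones(t.size, dtype=bool) if v is None else np.asarray(v, dtype=bool)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "valid", v)

    @classmethod
    def from_csv(cls, path: str) -> "TrackSeries":
        """Read a track table: columns t_min, x_um, y_um[, z_um]."""
        df = pd.read_csv(path)
        cols = [c for c in ("x_um", "y_um", "z_um") if c in df.columns]
        if "t_min" not in df.columns or len(cols) < 2:
            raise ValueError(f"{path}: expected columns t_min, x_um, y_um[, z_um]")
        return cls(times=df["t_min"].to_numpy(), positions=df[cols].to_numpy(), source=path)


@dataclass
class DriftMetrics:
    """τ_stab (min, None = never stabilised), V_b/V_a (nm/min), classes."""

    tau_stab: Optional[float]
    v_before: float
    v_after: float
    tau_class: DriftClass
    vb_class: DriftClass
    va_class: DriftClass

    @property
    def overall(self) -> DriftClass:
        return max(
            (self.tau_class, self.vb_class, self.va_class), key=_CLASS_ORDER.__getitem__
        )

    @property
    def stabilized(self) -> bool:
        return self.tau_stab is not None


def track_single_bead(
    timelapse: np.ndarray,
    meta: AcquisitionMeta,
    threshold: Optional[float] = None,
) -> TrackSeries:
    """Per-frame 3D centre of mass of the dominant bead in a T×Z×Y×X stack.

    Each frame is background-subtracted (median of the frame) and
    thresholded at half its maximum; frames whose maximum does not rise
    above the threshold are flagged invalid, never interpolated.
    """
    stack = np.asarray(timelapse, dtype=float)
    if stack.ndim != 4:
        raise ValueError(f"expected (T, Z, Y, X), got shape {stack.shape}")
    if meta.time_interval is None:
        raise ValueError("meta.time_interval (s) is required to build the time base")
    z_step = meta.z_step if meta.z_step is not None else meta.pixel_size_xy
    n_t = stack.shape[0]
    times = np.arange(n_t) * meta.time_interval / 60.0
    positions = np.zeros((n_t, 3))
    valid = np.ones(n_t, dtype=bool)
    for ti in range(n_t):
        frame = stack[ti] - np.median(stack[ti])
        level = threshold if threshold is not None else 0.5 * frame.max()
        if frame.max() <= 0 or level <= 0:
            valid[ti] = False
            continue
        mask = frame >= level
        w = np.where(mask, frame, 0.0)
        total = w.sum()
        if total <= 0:
            valid[ti] = False
            continue
        zz, yy, xx = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1], 0 : frame.shape[2]]
        positions[ti] = (
            (xx * w).sum() / total * meta.pixel_size_xy,
            (yy * w).sum() / total * meta.pixel_size_xy,
            (zz * w).sum() / total * z_step,
        )
    return TrackSeries(times=times, positions=positions, valid=valid, source="tracked stack")


def _mean_step_velocity(times: np.ndarray, pos: np.ndarray) -> float:
    """Mean over steps of ‖Δp‖/Δt, nm/min (0 for fewer than 2 frames)."""
    if times.size < 2:
        return 0.0
    dp = np.linalg.norm(np.diff(pos, axis=0), axis=1) * NM_PER_UM
    dt = np.diff(times)
    return float(np.mean(dp / dt))


def _classify_tau(tau: Optional[float], b: DriftClassBounds) -> DriftClass:
    if tau is None or tau > b.tau_acceptable_max:
        return DriftClass.CRITICAL
    if tau < b.tau_standard_max:
        return DriftClass.STANDARD
    return DriftClass.ACCEPTABLE


def _classify_v(v: float, acceptable_max: float, b: DriftClassBounds) -> DriftClass:
    if v < b.v_standard_max:
        return DriftClass.STANDARD
    if v <= acceptable_max:
        return DriftClass.ACCEPTABLE
    return DriftClass.CRITICAL


def classify_drift(
    tau: Optional[float],
    v_before: float,
    v_after: float,
    bounds: DriftClassBounds = DriftClassBounds(),
) -> DriftMetrics:
    """Classify pre-computed drift quantities against the class bounds."""
    return DriftMetrics(
        tau_stab=tau,
        v_before=v_before,
        v_after=v_after,
        tau_class=_classify_tau(tau, bounds),
        vb_class=_classify_v(v_before, bounds.vb_acceptable_max, bounds),
        va_class=_classify_v(v_after, bounds.va_acceptable_max, bounds),
    )


def drift_metrics(
    track: TrackSeries,
    spec: ResolutionSpec,
    bounds: DriftClassBounds = DriftClassBounds(),
) -> DriftMetrics:
    """Stabilisation time and before/after velocities of one bead track.

    τ_stab is the time of the earliest anchor frame k such that every
    later frame stays within the lateral resolution of the anchor in x
    and y and within the axial resolution in z, simultaneously.
    Velocities are the mean step speed (3D norm over step interval)
    before and after that frame.
    """
    t = track.times[track.valid]
    p = track.positions[track.valid]
    if t.size < 3:
        raise ValueError("need at least 3 valid frames")
    n_axes = p.shape[1]
    limits = np.array([spec.lateral, spec.lateral, spec.axial][:n_axes])

    tau: Optional[float] = None
    anchor = None
    # the final frame cannot anchor: stabilisation needs at least one
    # later frame confirming the criterion
    for k in range(t.size - 1):
        dev = np.abs(p[k + 1 :] - p[k])
        if np.all(dev < limits):
            tau = float(t[k] - t[0])
            anchor = k
            break
    if anchor is None:
        v_before = _mean_step_velocity(t, p)
        return classify_drift(None, v_before, v_before, bounds)
    v_before = _mean_step_velocity(t[: anchor + 1], p[: anchor + 1])
    v_after = _mean_step_velocity(t[anchor:], p[anchor:])
    return classify_drift(tau, v_before, v_after, bounds)


def repeatability(
    visits: TrackSeries,
    registry: ToleranceRegistry = DEFAULT_TOLERANCES,
) -> dict[str, float | bool]:
    """σ_x, σ_y (µm) of the bead position across reference visits.

    ``visits`` must already be restricted to the reference-position
    frames (e.g. every other frame of the nine-position cycle
    Pref-P1-Pref-P2-Pref-P3-Pref-P4-Pref).
    """
    p = visits.positions[visits.valid]
    if p.shape[0] < 2:
        raise ValueError("need at least 2 reference visits")
    sigma_x = float(np.std(p[:, 0], ddof=1))
    sigma_y = float(np.std(p[:, 1], ddof=1))
    from microqc.core import flag_metric

    return {
        "sigma_x": sigma_x,
        "sigma_y": sigma_y,
        "sigma_x_pass": flag_metric(sigma_x, "repeatability", registry),
        "sigma_y_pass": flag_metric(sigma_y, "repeatability", registry),
        "n_visits": int(p.shape[0]),
    }


def reference_visits(track: TrackSeries, cycle: int = 9, ref_indices: Sequence[int] = (0, 2, 4, 6, 8)) -> TrackSeries:
    """Select the reference-position frames from a multi-position cycle.

    The default nine-position protocol visits the reference at every
    even index of each cycle.
    """
    idx = np.array(
        [i for i in range(track.times.size) if (i % cycle) in set(ref_indices)], dtype=int
    )
    if idx.size < 2:
        raise ValueError("fewer than 2 reference visits in the schedule")
    return TrackSeries(
        times=track.times[idx],
        positions=track.positions[idx],
        valid=track.valid[idx],
        source=track.source,
    )
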
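"""Illumination-power stability metrics from power-meter time series.

Two metrics summarise a trace: the min–max stability factor
STAB = 100·[1 − (P_max − P_min)/(P_max + P_min)] and the standard
deviation of the max-normalised power.  Both are scale invariant.
Typical acquisition cadences are 5 min at 1 Hz (short term) and 2 h at
one sample per 30 s (mid term); any strictly increasing time base is
accepted.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from microqc.core import DEFAULT_TOLERANCES, ToleranceRegistry, flag_metric


class Regime(str, enum.Enum):
    SHORT = "short"  # 5 min @ 1 s
    MID = "mid"      # 2 h @ 30 s
    LONG = "long"    # monthly sessions


@dataclass(frozen=True)
class PowerTrace:
    """Time-stamped power readings: times in seconds, power in watts
    (or any fixed proportional unit — the metrics are scale invariant)."""

    times: np.ndarray
    power: np.ndarray
    label: str = ""
    regime: Regime = Regime.MID

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if t.shape != p.shape or t.ndim != 1:
            raise ValueError("times and power must be 1D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("power values must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "power", p)

    @classmethod
    def from_csv(cls, path: str, label: str = "", regime: Regime = Regime.MID) -> "PowerTrace":
        """Read a two-column CSV (time_s, power_W); header optional."""
        df = pd.read_csv(path, header=None, comment="#")
        # drop a header row if the first row is non-numeric
        try:
            float(df.iloc[0, 0])
        except (TypeError, ValueError):
            df = df.iloc[1:]
        df = df.astype(float)
        return cls(times=df.iloc[:, 0].to_numpy(), power=df.iloc[:, 1].to_numpy(),
                   label=label or path, regime=regime)


def stability_metrics(
    trace: PowerTrace, registry: ToleranceRegistry = DEFAULT_TOLERANCES
) -> dict[str, float | bool]:
    """STAB factor (%) and SD of the max-normalised power, with flags."""
    p = trace.power
    if p.size < 2:
        raise ValueError("need at least 2 samples")
    p_max, p_min = float(p.max()), float(p.min())
    if p_max <= 0:
        raise ValueError("all-zero power trace")
    stab = 100.0 * (1.0 - (p_max - p_min) / (p_max + p_min))
    sd_norm = float(np.std(p / p_max, ddof=1))
    return {
        "stab_power": stab,
        "sd_norm_power": sd_norm,
        "stab_pass": flag_metric(stab, "stab_power", registry),
        "sd_norm_pass": flag_metric(sd_norm, "sd_norm_power", registry),
    }


def warmup_summary(
    trace: PowerTrace, window: float, band: float = 0.01
) -> Optional[float]:
    """Warm-up time: when the trace settles into a band around its end value.

    The settled reference is the mean over the final ``window`` seconds.
    The warm-up time is the earliest t such that every sample from t to
    the end lies within ±``band`` (fractional) of that reference.
    Returns the time in seconds, 0.0 for an already-settled trace, or
    ``None`` if the trace never stabilises.
    """
    t, p = trace.times, trace.power
    if t[-1] - t[0] < 2 * window:
        raise ValueError("trace must span at least twice the window")
    ref = float(p[t >= t[-1] - window].mean())
    if ref <= 0:
        raise ValueError("non-positive settled reference power")
    within = np.abs(p - ref) <= band * ref
    if not within[-1]:
        return None
    # last index where the trace is outside the band
    outside = np.nonzero(~within)[0]
    if outside.size == 0:
        return 0.0
    first_settled = outside[-1] + 1
    if first_settled >= t.size:
        return None
    return float(t[first_settled] - t[0])


def session_table(traces: Sequence[PowerTrace]) -> pd.DataFrame:
    """Long-term descriptive summary: per-session STAB and mean power."""
    rows = []
    for tr in traces:
        m = stability_metrics(tr)
        rows.append(
            {
                "label": tr.label,
                "mean_power": float(tr.power.mean()),
                "stab_power": m["stab_power"],
                "sd_norm_power": m["sd_norm_power"],
            }
        )
    return pd.DataFrame(rows)
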
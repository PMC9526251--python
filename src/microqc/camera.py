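"""Dark-frame characterisation of camera sensors.

From a T×Y×X stack of dark frames (shutter closed, short exposure so
dark current is negligible):

* offset  — global mean of the temporal-mean image, in ADU;
* DSNU    — spatial SD of the temporal-mean image × gain, in electrons;
* read-noise map — per-pixel temporal SD × gain, in electrons,
  summarised by its RMS and median (vendors publish either).

Two comparison metrics: VAR = 100·N_theor/N_exp against the datasheet
read noise, and STAB_noise = 100·[1 − (N_max − N_min)/(N_max + N_min)]
over repeated sessions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from microqc.core import DEFAULT_TOLERANCES, ToleranceRegistry, flag_metric


@dataclass
class CameraNoiseResult:
    """Dark-series analysis output; energies in electrons unless noted."""

    offset: float            # ADU
    offset_e: float          # electrons
    dsnu: float
    noise_map: np.ndarray
    rms_noise: float
    median_noise: float
    n_frames: int
    gain: float
    hot_pixel_count: int
    var_vs_spec: Optional[float] = None
    var_pass: Optional[bool] = None


def dark_series_analysis(
    frames: np.ndarray,
    gain: float,
    spec_noise: Optional[float] = None,
    spec_kind: str = "rms",
    hot_pixel_threshold: Optional[float] = None,
    registry: ToleranceRegistry = DEFAULT_TOLERANCES,
) -> CameraNoiseResult:
    """Analyse a stack of dark frames.

    Parameters
    ----------
    frames
        (T, Y, X) dark stack in ADU; T ≥ 2 (100 frames recommended —
        fewer inflates the DSNU through residual temporal noise).
    gain
        Conversion factor in e⁻/ADU.
    spec_noise
        Datasheet read noise in electrons; enables the VAR metric
        against the RMS or median summary per ``spec_kind``.
    hot_pixel_threshold
        Electron level above which a pixel's read noise counts it as
        hot; defaults to 5× the median noise.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError(f"expected (T, Y, X), got shape {frames.shape}")
    n_frames = frames.shape[0]
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if not np.all(np.isfinite(frames)):
        raise ValueError("non-finite pixel values in dark stack")
    if gain <= 0:
        raise ValueError("gain must be positive")
    if n_frames < 100:
        warnings.warn(
            f"{n_frames} frames; 100 recommended for DSNU evaluation", stacklevel=2
        )

    mean_img = frames.mean(axis=0)
    offset = float(mean_img.mean())
    dsnu = float(mean_img.std(ddof=1)) * gain
    noise_map = frames.std(axis=0, ddof=1) * gain
    rms_noise = float(np.sqrt(np.mean(noise_map**2)))
    median_noise = float(np.median(noise_map))

    if hot_pixel_threshold is None:
        hot_pixel_threshold = 5.0 * median_noise
    hot = int(np.count_nonzero(noise_map > hot_pixel_threshold)) if hot_pixel_threshold > 0 else 0

    result = CameraNoiseResult(
        offset=offset,
        offset_e=offset * gain,
        dsnu=dsnu,
        noise_map=noise_map,
        rms_noise=rms_noise,
        median_noise=median_noise,
        n_frames=n_frames,
        gain=gain,
        hot_pixel_count=hot,
    )
    if spec_noise is not None:
        measured = rms_noise if spec_kind == "rms" else median_noise
        result.var_vs_spec = var_metric(spec_noise, measured)
        result.var_pass = flag_metric(result.var_vs_spec, "var_noise", registry)
    return result


def var_metric(n_theor: float, n_exp: float) -> float:
    """VAR = 100 · N_theor / N_exp (%): above 100 means better than spec."""
    if n_theor <= 0 or n_exp <= 0:
        raise ValueError("read-noise values must be positive")
    return 100.0 * n_theor / n_exp


def stab_noise(
    history: Sequence[float], registry: ToleranceRegistry = DEFAULT_TOLERANCES
) -> dict[str, float | bool]:
    """Long-term read-noise stability over sessions, min–max factor (%)."""
    values = np.asarray(history, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 sessions")
    if np.any(values <= 0):
        raise ValueError("read-noise history must be strictly positive")
    n_max, n_min = float(values.max()), float(values.min())
    stab = 100.0 * (1.0 - (n_max - n_min) / (n_max + n_min))
    return {"stab_noise": stab, "stab_pass": flag_metric(stab, "stab_noise", registry)}
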
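"""Ground-truth fixture generators for every QC analysis.

Each generator is deterministic under a fixed seed and returns both the
dataset (in the format its consuming module reads) and a truth dict that
suffices to compute the expected metric values without rerunning the
generator.  The noise model is Poisson shot noise on the signal plus
Gaussian read noise, then quantisation to the sensor bit depth — the
minimal model that reproduces SBR/SNR-dependent fitting behaviour.

Default geometries follow the acquisition protocols the analyses are
designed for: sub-resolution (175 nm class) beads for PSF work, 1 µm
multicolour beads for coregistration, 100 dark frames for camera noise,
a 5 min @ 1 Hz power trace, a 15 h / 10 min-interval drift series and a
20-cycle nine-position repeatability schedule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from microqc.resolution import FWHM_PER_SIGMA


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _quantize(image: np.ndarray, bit_depth: int) -> np.ndarray:
    max_val = 2**bit_depth - 1
    return np.clip(np.round(image), 0, max_val).astype(np.uint16 if bit_depth > 8 else np.uint8)


def _apply_noise(
    signal: np.ndarray,
    rng: np.random.Generator,
    shot_noise: bool,
    read_sigma: float,
) -> np.ndarray:
    out = rng.poisson(np.clip(signal, 0, None)).astype(float) if shot_noise else signal.astype(float)
    if read_sigma > 0:
        out = out + rng.normal(0.0, read_sigma, size=out.shape)
    return out


def _sphere_kernel_1d(diameter_px: float) -> np.ndarray:
    """Line profile of a uniform sphere (for finite bead-size broadening)."""
    r = diameter_px / 2.0
    n = int(math.ceil(r))
    x = np.arange(-n, n + 1, dtype=float)
    prof = np.clip(r**2 - x**2, 0, None)
    s = prof.sum()
    return prof / s if s > 0 else np.array([1.0])


def make_bead_stack(
    seed: int = 0,
    shape: tuple[int, int, int] = (41, 192, 192),
    pixel_size_xy: float = 0.05,
    z_step: float = 0.1,
    fwhm_xy: float = 0.19125,
    fwhm_z: float = 0.71827,
    n_beads: int = 5,
    positions: Optional[Sequence[tuple[float, float, float]]] = None,
    amplitude: float = 10000.0,
    background: float = 100.0,
    bead_diameter: float = 0.0,
    shot_noise: bool = False,
    read_sigma: float = 0.0,
    bit_depth: int = 16,
    min_spacing_px: float = 24.0,
) -> tuple[np.ndarray, dict]:
    """Synthesise a z-stack of anisotropic Gaussian beads with ground truth.

    Bead FWHMs are given in µm; positions (z, y, x) in pixels/planes.  If
    ``positions`` is None, ``n_beads`` positions are placed on a jittered
    grid away from the borders.  ``bead_diameter`` > 0 (µm) convolves
    each axis profile with a uniform-sphere projection, broadening the
    apparent FWHM the way a finite bead does.
    """
    rng = _rng(seed)
    nz, ny, nx = shape
    sigma_xy_px = fwhm_xy / FWHM_PER_SIGMA / pixel_size_xy
    sigma_z_px = fwhm_z / FWHM_PER_SIGMA / z_step
    if fwhm_xy / pixel_size_xy < 2 or fwhm_z / z_step < 2:
        import warnings

        warnings.warn("bead FWHM below 2 sampling intervals; fits will be unreliable", stacklevel=2)

    if positions is None:
        margin = 24
        n_side = int(math.ceil(math.sqrt(n_beads)))
        xs = np.linspace(margin, nx - 1 - margin, n_side)
        ys = np.linspace(margin, ny - 1 - margin, n_side)
        grid = [(nz // 2, y, x) for y in ys for x in xs][:n_beads]
        positions = [
            (
                z + rng.uniform(-0.4, 0.4),
                y + rng.uniform(-0.4, 0.4),
                x + rng.uniform(-0.4, 0.4),
            )
            for z, y, x in grid
        ]
    positions = [tuple(map(float, p)) for p in positions]

    overlap = False
    arr = np.array([(p[1], p[2]) for p in positions])
    if len(arr) > 1:
        from scipy.spatial.distance import pdist

        overlap = bool(pdist(arr).min() < min_spacing_px)

    zz = np.arange(nz, dtype=float)
    yy = np.arange(ny, dtype=float)
    xx = np.arange(nx, dtype=float)
    signal = np.zeros(shape, dtype=float)
    for zc, yc, xc in positions:
        gz = np.exp(-((zz - zc) ** 2) / (2 * sigma_z_px**2))
        gy = np.exp(-((yy - yc) ** 2) / (2 * sigma_xy_px**2))
        gx = np.exp(-((xx - xc) ** 2) / (2 * sigma_xy_px**2))
        if bead_diameter > 0:
            kx = _sphere_kernel_1d(bead_diameter / pixel_size_xy)
            kz = _sphere_kernel_1d(bead_diameter / z_step)
            gy = np.convolve(gy, kx, mode="same")
            gx = np.convolve(gx, kx, mode="same")
            gz = np.convolve(gz, kz, mode="same")
        bead = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        # amplitude is the rendered peak, whatever the bead size
        peak = bead.max()
        if peak > 0:
            bead = bead / peak
        signal += amplitude * bead
    signal += background

    noisy = _apply_noise(signal, rng, shot_noise, read_sigma)
    stack = _quantize(noisy, bit_depth)
    truth = {
        "seed": seed,
        "positions_zyx_px": positions,
        "fwhm_xy_um": fwhm_xy,
        "fwhm_z_um": fwhm_z,
        "pixel_size_xy": pixel_size_xy,
        "z_step": z_step,
        "amplitude": amplitude,
        "background": background,
        "bead_diameter_um": bead_diameter,
        "overlap_warning": overlap,
        "bit_depth": bit_depth,
    }
    return stack, truth


def make_flat_field(
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    center: Optional[tuple[float, float]] = None,
    edge_peak_ratio: float = 1.0,
    peak: float = 30000.0,
    read_sigma: float = 0.0,
    shot_noise: bool = False,
    bit_depth: int = 16,
) -> tuple[np.ndarray, dict]:
    """Vignetted (Gaussian-profile) illumination field.

    ``edge_peak_ratio`` is the intensity at the farthest corner relative
    to the peak — the ground truth for the uniformity metric (×100) when
    the peak is centred.  1.0 gives a perfectly flat field.
    """
    if not 0 < edge_peak_ratio <= 1:
        raise ValueError("edge_peak_ratio must be in (0, 1]")
    rng = _rng(seed)
    ny, nx = shape
    if center is None:
        center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    r2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
    if edge_peak_ratio < 1.0:
        corners = [
            (0, 0), (0, nx - 1), (ny - 1, 0), (ny - 1, nx - 1)
        ]
        r2_max = max((cx - center[0]) ** 2 + (cy - center[1]) ** 2 for cy, cx in corners)
        sigma2 = -r2_max / (2.0 * math.log(edge_peak_ratio))
        signal = peak * np.exp(-r2 / (2.0 * sigma2))
    else:
        signal = np.full(shape, peak)
    noisy = _apply_noise(signal, rng, shot_noise, read_sigma)
    image = _quantize(noisy, bit_depth)
    truth = {
        "seed": seed,
        "center_xy_px": (center[0], center[1]),
        "edge_peak_ratio": edge_peak_ratio,
        "expected_uniformity": 100.0 * edge_peak_ratio,
        "peak": peak,
        "bit_depth": bit_depth,
    }
    return image, truth


def make_shifted_channels(
    seed: int = 0,
    shape: tuple[int, int, int] = (41, 192, 192),
    pixel_size_xy: float = 0.05,
    z_step: float = 0.1,
    shifts_um: Sequence[tuple[float, float, float]] = ((0.0, 0.0, 0.0), (0.1, 0.0, 0.0)),
    n_beads: int = 5,
    fwhm_xy: float = 0.19125,
    fwhm_z: float = 0.71827,
    bead_diameter: float = 1.0,
    amplitude: float = 10000.0,
    background: float = 100.0,
    shot_noise: bool = False,
    read_sigma: float = 0.0,
    bit_depth: int = 16,
) -> tuple[np.ndarray, dict]:
    """Multichannel bead stack with per-channel (x, y, z) µm offsets.

    Channel 0's shift is normally (0,0,0); the injected inter-channel
    shifts are the coregistration ground truth.  Default bead diameter is
    1 µm, the recommended size for coregistration work.
    """
    rng = _rng(seed)
    nz, ny, nx = shape
    margin = 28
    n_side = int(math.ceil(math.sqrt(n_beads)))
    xs = np.linspace(margin, nx - 1 - margin, n_side)
    ys = np.linspace(margin, ny - 1 - margin, n_side)
    base = [(nz // 2, y, x) for y in ys for x in xs][:n_beads]
    base = [
        (z + rng.uniform(-0.3, 0.3), y + rng.uniform(-0.3, 0.3), x + rng.uniform(-0.3, 0.3))
        for z, y, x in base
    ]
    channels = []
    for ci, (dx, dy, dz) in enumerate(shifts_um):
        pos = [
            (z + dz / z_step, y + dy / pixel_size_xy, x + dx / pixel_size_xy)
            for z, y, x in base
        ]
        ch, _ = make_bead_stack(
            seed=seed + 1000 * (ci + 1),
            shape=shape,
            pixel_size_xy=pixel_size_xy,
            z_step=z_step,
            fwhm_xy=fwhm_xy,
            fwhm_z=fwhm_z,
            positions=pos,
            amplitude=amplitude,
            background=background,
            bead_diameter=bead_diameter,
            shot_noise=shot_noise,
            read_sigma=read_sigma,
            bit_depth=bit_depth,
        )
        channels.append(ch)
    stack = np.stack(channels, axis=0)
    truth = {
        "seed": seed,
        "base_positions_zyx_px": base,
        "shifts_um": [tuple(s) for s in shifts_um],
        "pixel_size_xy": pixel_size_xy,
        "z_step": z_step,
        "bead_diameter_um": bead_diameter,
    }
    return stack, truth


def make_power_trace(
    seed: int = 0,
    duration_s: float = 300.0,
    interval_s: float = 1.0,
    mean_power: float = 1e-3,
    rel_noise: float = 0.0,
    step_time_s: Optional[float] = None,
    step_fraction: float = 0.9,
    drift_per_s: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Power-meter trace: optional warm-up step, linear drift and noise.

    Before ``step_time_s`` the power sits at ``step_fraction`` of its
    settled value — a square warm-up profile with a known warm-up time.
    """
    rng = _rng(seed)
    t = np.arange(0.0, duration_s + interval_s / 2, interval_s)
    p = np.full(t.size, mean_power)
    if step_time_s is not None:
        p[t < step_time_s] *= step_fraction
    p = p * (1.0 + drift_per_s * t)
    if rel_noise > 0:
        p = p * (1.0 + rng.normal(0.0, rel_noise, size=t.size))
    p = np.clip(p, 0, None)
    df = pd.DataFrame({"time_s": t, "power_W": p})
    truth = {
        "seed": seed,
        "mean_power": mean_power,
        "rel_noise": rel_noise,
        "step_time_s": step_time_s,
        "step_fraction": step_fraction,
        "drift_per_s": drift_per_s,
    }
    return df, truth


def make_drift_track(
    seed: int = 0,
    duration_min: float = 900.0,
    interval_min: float = 10.0,
    drift_amplitude_um: tuple[float, float, float] = (1.0, 1.0, 3.0),
    relaxation_min: float = 30.0,
    plateau_noise_um: float = 0.005,
) -> tuple[pd.DataFrame, dict]:
    """Exponential-relaxation drift trajectory (x, y, z in µm vs minutes).

    The position relaxes from an initial offset toward the origin with
    the given time constant, plus small Gaussian jitter on the plateau.
    The default span models an overnight 15 h acquisition at 10 min
    intervals with the axial drift dominating, as typical stages show.
    """
    rng = _rng(seed)
    t = np.arange(0.0, duration_min + interval_min / 2, interval_min)
    amp = np.asarray(drift_amplitude_um, dtype=float)
    pos = amp[None, :] * np.exp(-t / relaxation_min)[:, None]
    pos += rng.normal(0.0, plateau_noise_um, size=pos.shape)
    df = pd.DataFrame({"t_min": t, "x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2]})
    truth = {
        "seed": seed,
        "drift_amplitude_um": tuple(amp),
        "relaxation_min": relaxation_min,
        "plateau_noise_um": plateau_noise_um,
        "interval_min": interval_min,
    }
    return df, truth


def make_drift_stack(
    seed: int = 0,
    track: Optional[pd.DataFrame] = None,
    shape: tuple[int, int, int] = (15, 48, 48),
    pixel_size_xy: float = 0.1,
    z_step: float = 1.0,
    fwhm_xy: float = 0.4,
    fwhm_z: float = 1.2,
    amplitude: float = 8000.0,
    background: float = 100.0,
    n_frames: int = 20,
    interval_min: float = 10.0,
    bit_depth: int = 16,
) -> tuple[np.ndarray, dict]:
    """Render a drifting bead as a T×Z×Y×X time-lapse for the tracker."""
    if track is None:
        track, _ = make_drift_track(
            seed=seed, duration_min=(n_frames - 1) * interval_min, interval_min=interval_min
        )
    nz, ny, nx = shape
    frames = []
    origin = np.array([(nx - 1) / 2 * pixel_size_xy, (ny - 1) / 2 * pixel_size_xy, (nz - 1) / 2 * z_step])
    sigma_xy = fwhm_xy / FWHM_PER_SIGMA
    sigma_z = fwhm_z / FWHM_PER_SIGMA
    zz = np.arange(nz) * z_step
    yy = np.arange(ny) * pixel_size_xy
    xx = np.arange(nx) * pixel_size_xy
    for _, row in track.iterrows():
        cx, cy, cz = origin[0] + row["x_um"], origin[1] + row["y_um"], origin[2] + row["z_um"]
        g = (
            np.exp(-((zz - cz) ** 2) / (2 * sigma_z**2))[:, None, None]
            * np.exp(-((yy - cy) ** 2) / (2 * sigma_xy**2))[None, :, None]
            * np.exp(-((xx - cx) ** 2) / (2 * sigma_xy**2))[None, None, :]
        )
        frames.append(_quantize(amplitude * g + background, bit_depth))
    stack = np.stack(frames, axis=0)
    truth = {
        "seed": seed,
        "origin_um": tuple(origin),
        "track": track.to_dict(orient="list"),
        "pixel_size_xy": pixel_size_xy,
        "z_step": z_step,
    }
    return stack, truth


def make_repeatability_visits(
    seed: int = 0,
    n_cycles: int = 20,
    sigma_um: tuple[float, float] = (0.05, 0.05),
    center_um: tuple[float, float] = (50.0, 50.0),
    interval_min: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Reference-position visit table with Gaussian repositioning error.

    Emulates the nine-position cycle protocol restricted to its
    reference visits: 5 reference returns per cycle over ``n_cycles``.
    """
    rng = _rng(seed)
    n_visits = 5 * n_cycles
    t = np.arange(n_visits) * interval_min
    x = center_um[0] + rng.normal(0.0, sigma_um[0], n_visits)
    y = center_um[1] + rng.normal(0.0, sigma_um[1], n_visits)
    df = pd.DataFrame({"t_min": t, "x_um": x, "y_um": y})
    truth = {"seed": seed, "sigma_um": tuple(sigma_um), "n_visits": n_visits}
    return df, truth


def make_dark_stack(
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    n_frames: int = 100,
    offset: float = 100.0,
    offset_spread: float = 1.0,
    column_amplitude: float = 0.0,
    temporal_sigma: float = 2.0,
    gain: float = 0.5,
    bit_depth: int = 16,
    quantize: bool = False,
) -> tuple[np.ndarray, dict]:
    """Dark-frame series with a fixed offset pattern and temporal noise.

    The per-pixel offset map is Normal(offset, offset_spread) plus an
    optional sinusoidal column pattern (sCMOS-style fixed pattern
    noise); each frame adds independent Normal(0, temporal_sigma) read
    noise.  Expected DSNU at large T is offset-map SD × gain; expected
    RMS read noise is temporal_sigma × gain.  Quantisation is off by
    default so analytic expectations hold exactly.
    """
    rng = _rng(seed)
    ny, nx = shape
    offset_map = offset + rng.normal(0.0, offset_spread, size=shape)
    if column_amplitude > 0:
        offset_map = offset_map + column_amplitude * np.sin(
            2 * np.pi * np.arange(nx) / max(nx / 8, 1)
        )[None, :]
    frames = offset_map[None, :, :] + rng.normal(0.0, temporal_sigma, size=(n_frames, ny, nx))
    if quantize:
        frames = _quantize(frames, bit_depth).astype(float)
    truth = {
        "seed": seed,
        "offset": offset,
        "offset_map_sd": float(offset_map.std(ddof=1)),
        "temporal_sigma": temporal_sigma,
        "gain": gain,
        "expected_dsnu_large_t": float(offset_map.std(ddof=1)) * gain,
        "expected_rms_noise": temporal_sigma * gain,
        "n_frames": n_frames,
    }
    return frames, truth


def write_truth(truth: dict, path: str) -> None:
    """Serialise a truth sidecar as JSON next to a generated dataset."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=float)
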
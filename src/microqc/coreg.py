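"""Chromatic coregistration from multicolour bead stacks.

For each bead the intensity centre of mass is computed per channel after
local background subtraction; the inter-channel distance r_exp is
compared with a direction-dependent reference distance r_ref, the radius
of the resolution ellipsoid (semi-axes = lateral, lateral, axial
theoretical resolution) along the displacement direction.  The reference
resolution is taken from the shorter-wavelength channel of each pair —
the more stringent value.  A ratio r_exp/r_ref above 1 flags a channel
pair whose chromatic shift exceeds the resolution of the system.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import center_of_mass

from microqc.core import AcquisitionMeta, ChannelMeta
from microqc.psf import BeadRecord, detect_beads
from microqc.resolution import ResolutionSpec, theoretical_resolution


@dataclass
class CoregPairResult:
    """One bead, one channel pair: displacement, r_exp, r_ref, ratio."""

    channel_a: str
    channel_b: str
    shift_um: tuple[float, float, float]
    shift_px: tuple[float, float, float]
    r_exp: float
    r_ref: float

    @property
    def ratio(self) -> float:
        return self.r_exp / self.r_ref


def bead_center_of_mass(
    stack: np.ndarray,
    meta: AcquisitionMeta,
    roi: Optional[tuple[slice, slice, slice]] = None,
) -> tuple[float, float, float]:
    """Intensity-weighted bead centroid in µm, background-subtracted.

    The background estimate is the median of the ROI border voxels; it
    is subtracted (clipping at zero) before the centroid so that the
    estimate is not pulled toward the ROI centre by a constant offset.
    Returns (x, y, z) in physical units.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError(f"expected (Z, Y, X), got shape {stack.shape}")
    sub = stack[roi] if roi is not None else stack

    border = np.concatenate(
        [
            sub[0].ravel(), sub[-1].ravel(),
            sub[:, 0].ravel(), sub[:, -1].ravel(),
            sub[:, :, 0].ravel(), sub[:, :, -1].ravel(),
        ]
    )
    signal = np.clip(sub - np.median(border), 0, None)
    if signal.sum() == 0:
        raise ValueError("ROI is empty after background subtraction")
    zc, yc, xc = center_of_mass(signal)
    z0 = roi[0].start or 0 if roi is not None else 0
    y0 = roi[1].start or 0 if roi is not None else 0
    x0 = roi[2].start or 0 if roi is not None else 0
    z_step = meta.z_step if meta.z_step is not None else meta.pixel_size_xy
    return (
        (xc + x0) * meta.pixel_size_xy,
        (yc + y0) * meta.pixel_size_xy,
        (zc + z0) * z_step,
    )


def reference_distance(direction: Sequence[float], spec: ResolutionSpec) -> float:
    """Radius of the resolution ellipsoid along a unit displacement.

    The ellipsoid has semi-axes (R_lat, R_lat, R_ax); for a unit vector
    u the radius is 1/sqrt((ux²+uy²)/R_lat² + uz²/R_ax²), so a purely
    lateral displacement equal to the lateral resolution gives a ratio
    of exactly 1.
    """
    u = np.asarray(direction, dtype=float)
    norm = float(np.linalg.norm(u))
    if norm == 0:
        raise ValueError("direction must be a non-zero vector")
    u = u / norm
    lat2 = u[0] ** 2 + u[1] ** 2
    ax2 = u[2] ** 2 if u.size > 2 else 0.0
    return 1.0 / math.sqrt(lat2 / spec.lateral**2 + ax2 / spec.axial**2)


def _pair_spec(meta: AcquisitionMeta, a: ChannelMeta, b: ChannelMeta) -> ResolutionSpec:
    # the shortest wavelength of the pair sets the (most stringent) reference
    shorter = a if a.lambda_ex <= b.lambda_ex else b
    return theoretical_resolution(meta, shorter)


@dataclass
class CoregSummary:
    """Mean ± SD coregistration ratio per channel pair across beads."""

    pair: tuple[str, str]
    mean_ratio: float
    sd_ratio: float
    n_beads: int
    flagged: bool


def coreg_analysis(
    stack: np.ndarray,
    meta: AcquisitionMeta,
    beads: Optional[Sequence[BeadRecord]] = None,
    prominence: Optional[float] = None,
    coreg_ratio_max: float = 1.0,
    bead_diameter: float = 1.0,
) -> tuple[list[dict], list[CoregSummary]]:
    """Coregistration ratios for every bead and channel pair.

    Parameters
    ----------
    stack
        (C, Z, Y, X) multichannel bead stack.
    beads
        Pre-detected bead records; if omitted, beads are detected on the
        per-pixel maximum across channels with ``prominence``.
    bead_diameter
        Physical bead diameter in µm (default 1 µm, the recommended
        size); the centre-of-mass ROI is enlarged by the bead radius so
        the full bead is contained and the centroid is unbiased.

    Returns per-bead rows and per-pair mean ± SD summaries.  With C
    channels there are C·(C−1)/2 pairs.  Beads whose ROI is empty in one
    channel are skipped for the affected pairs and counted.
    """
    stack = np.asarray(stack)
    if stack.ndim != 4:
        raise ValueError(f"expected (C, Z, Y, X), got shape {stack.shape}")
    n_ch = stack.shape[0]
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    if len(meta.channels) < n_ch:
        raise ValueError("meta must declare one ChannelMeta per stack channel")

    if beads is None:
        if prominence is None:
            raise ValueError("either beads or prominence must be given")
        combined = stack.max(axis=0)
        beads = detect_beads(combined, meta, prominence)
    kept = [b for b in beads if b.kept]
    # widen the ROI by the bead radius: a PSF-sized ROI would clip a
    # micron-sized bead and pull both centroids toward the ROI centre
    extra_xy = int(math.ceil(bead_diameter / 2.0 / meta.pixel_size_xy))
    extra_z = int(math.ceil(bead_diameter / 2.0 / (meta.z_step or meta.pixel_size_xy)))
    for b in kept:
        b.roi_xy += extra_xy
        b.roi_z += extra_z
    if len(kept) < 5:
        warnings.warn(
            f"only {len(kept)} beads; protocol recommends acquiring at least 5",
            stacklevel=2,
        )

    rows: list[dict] = []
    per_pair: dict[tuple[str, str], list[float]] = {}
    px = meta.pixel_size_xy
    z_step = meta.z_step if meta.z_step is not None else px
    for bi, bead in enumerate(kept):
        nz = stack.shape[1]
        roi = (
            slice(max(0, bead.z_max - bead.roi_z), min(nz, bead.z_max + bead.roi_z + 1)),
            slice(bead.y - bead.roi_xy, bead.y + bead.roi_xy + 1),
            slice(bead.x - bead.roi_xy, bead.x + bead.roi_xy + 1),
        )
        centers: dict[int, tuple[float, float, float]] = {}
        for c in range(n_ch):
            try:
                centers[c] = bead_center_of_mass(stack[c], meta, roi)
            except ValueError:
                continue
        for ca, cb in itertools.combinations(range(n_ch), 2):
            name_a, name_b = meta.channels[ca].name, meta.channels[cb].name
            key = (name_a, name_b)
            per_pair.setdefault(key, [])
            if ca not in centers or cb not in centers:
                rows.append({"bead": bi, "pair": key, "skipped": True})
                continue
            a, b = np.array(centers[ca]), np.array(centers[cb])
            shift = b - a
            r_exp = float(np.linalg.norm(shift))
            spec = _pair_spec(meta, meta.channels[ca], meta.channels[cb])
            direction = shift if r_exp > 0 else np.array([1.0, 0.0, 0.0])
            r_ref = reference_distance(direction, spec)
            result = CoregPairResult(
                channel_a=name_a,
                channel_b=name_b,
                shift_um=tuple(shift),
                shift_px=(shift[0] / px, shift[1] / px, shift[2] / z_step),
                r_exp=r_exp,
                r_ref=r_ref,
            )
            per_pair[key].append(result.ratio)
            rows.append(
                {
                    "bead": bi,
                    "pair": key,
                    "r_exp": r_exp,
                    "r_ref": r_ref,
                    "ratio": result.ratio,
                    "shift_um": result.shift_um,
                    "skipped": False,
                }
            )

    summaries = []
    for key, ratios in per_pair.items():
        if not ratios:
            continue
        arr = np.array(ratios)
        mean = float(arr.mean())
        summaries.append(
            CoregSummary(
                pair=key,
                mean_ratio=mean,
                sd_ratio=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                n_beads=int(arr.size),
                flagged=mean > coreg_ratio_max,
            )
        )
    return rows, summaries
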
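"""Point-spread-function characterisation from sub-resolution bead stacks.

Beads are located on a maximum-intensity z-projection, filtered by the
edge/spacing/saturation exclusion rules, and each kept bead is measured
by fitting one-dimensional Gaussian-plus-offset profiles through the
brightest voxel of its ROI along x, y and z.  The per-bead outputs are
the three FWHMs, their goodness of fit R², the lateral asymmetry ratio
LAR = min(FWHMx, FWHMy)/max(FWHMx, FWHMy), the signal-to-background
ratio (segmented bead mean over a 1-µm annulus mean) and a square-root
signal-to-noise proxy at 12-bit normalisation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max
from scipy.ndimage import binary_dilation
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from microqc.core import AcquisitionMeta
from microqc.resolution import FWHM_PER_SIGMA, ResolutionSpec, theoretical_resolution


class Exclusion(str, enum.Enum):
    KEPT = "kept"
    EDGE = "edge"
    TOO_CLOSE = "too_close"
    SATURATED = "saturated"
    CENTRAL_ZONE_OUT = "central_zone_out"


@dataclass
class BeadRecord:
    """A candidate bead from the maximum-intensity projection.

    Coordinates are 0-based pixel indices; a voxel's centre is its
    coordinate.  ``roi_xy``/``roi_z`` give the half-extent of the cubic
    analysis neighbourhood in pixels/planes.
    """

    x: int
    y: int
    z_max: int
    roi_xy: int
    roi_z: int
    exclusion: Exclusion = Exclusion.KEPT

    @property
    def kept(self) -> bool:
        return self.exclusion is Exclusion.KEPT


@dataclass
class PsfResult:
    """Per-bead PSF measurement. FWHMs in µm; invalid fits carry a reason."""

    fwhm_x: float = math.nan
    fwhm_y: float = math.nan
    fwhm_z: float = math.nan
    r2_x: float = math.nan
    r2_y: float = math.nan
    r2_z: float = math.nan
    sbr: float = math.nan
    snr: float = math.nan
    ratio_xy: float = math.nan
    ratio_z: float = math.nan
    valid: bool = True
    invalid_reason: str = ""
    bead: Optional[BeadRecord] = None

    @property
    def lar(self) -> float:
        """Lateral asymmetry ratio min/max of the two lateral FWHMs."""
        lo, hi = sorted((self.fwhm_x, self.fwhm_y))
        return lo / hi


def default_roi_half_extents(meta: AcquisitionMeta, spec: ResolutionSpec) -> tuple[int, int]:
    """ROI half-extent in pixels (xy) and planes (z).

    The full ROI side is six expected FWHMs, wide enough to contain
    essentially all of a Gaussian bead plus local background.
    """
    half_xy = max(3, int(math.ceil(3.0 * spec.lateral / meta.pixel_size_xy)))
    z_step = meta.z_step if meta.z_step is not None else meta.pixel_size_xy
    half_z = max(3, int(math.ceil(3.0 * spec.axial / z_step)))
    return half_xy, half_z


def detect_beads(
    stack: np.ndarray,
    meta: AcquisitionMeta,
    prominence: float,
    min_spacing: Optional[float] = None,
    edge_margin: Optional[float] = None,
    discard_saturated: bool = True,
    spec: Optional[ResolutionSpec] = None,
) -> list[BeadRecord]:
    """Locate bead candidates and apply the exclusion rules.

    Candidates are local maxima of the maximum-intensity z-projection
    exceeding ``prominence``.  Candidates within ``min_spacing`` (µm) of
    another candidate, within ``edge_margin`` (µm) of a lateral border,
    or containing a saturated voxel in their ROI are *marked* excluded,
    never silently dropped.

    Defaults: ``min_spacing`` is twice the ROI side, ``edge_margin`` the
    ROI half-side.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError(f"expected a 3D (Z,Y,X) stack, got shape {stack.shape}")
    if stack.shape[0] < 3:
        raise ValueError("need at least 3 z-planes")
    if stack.size == 0:
        raise ValueError("empty stack")
    if prominence <= 0:
        raise ValueError("prominence must be positive")

    if spec is None:
        if not meta.channels:
            raise ValueError("need a channel in meta (or an explicit ResolutionSpec)")
        spec = theoretical_resolution(meta, meta.channels[0])
    half_xy, half_z = default_roi_half_extents(meta, spec)
    px = meta.pixel_size_xy
    if min_spacing is None:
        min_spacing = 2.0 * (2 * half_xy + 1) * px
    if edge_margin is None:
        edge_margin = half_xy * px

    mip = stack.max(axis=0)
    # min_distance of one ROI half-extent merges plateau maxima within a
    # single (possibly flat-topped) bead; distinct beads closer than that
    # are far inside min_spacing anyway and would be excluded regardless
    coords = peak_local_max(
        mip.astype(float),
        min_distance=max(1, half_xy),
        threshold_abs=float(prominence),
        exclude_border=False,  # the edge rule marks, never silently drops
    )
    # deterministic candidate order: ascending (y, x)
    coords = coords[np.lexsort((coords[:, 1], coords[:, 0]))]

    records: list[BeadRecord] = []
    margin_px = edge_margin / px
    ny, nx = mip.shape
    for yy, xx in coords:
        z_max = int(np.argmax(stack[:, yy, xx]))
        records.append(BeadRecord(x=int(xx), y=int(yy), z_max=z_max, roi_xy=half_xy, roi_z=half_z))

    pos = np.array([[r.x, r.y] for r in records], dtype=float)
    for i, rec in enumerate(records):
        if (
            rec.x < margin_px
            or rec.y < margin_px
            or rec.x > nx - 1 - margin_px
            or rec.y > ny - 1 - margin_px
        ):
            rec.exclusion = Exclusion.EDGE
            continue
        if len(records) > 1:
            d = np.hypot(*(pos - pos[i]).T) * px
            d[i] = np.inf
            if d.min() < min_spacing:
                rec.exclusion = Exclusion.TOO_CLOSE
                continue
        if discard_saturated and _roi_view(stack, rec).max() >= meta.max_value:
            rec.exclusion = Exclusion.SATURATED

    if not any(r.kept for r in records):
        import warnings

        warnings.warn("no beads kept after exclusion rules", stacklevel=2)
    return records


def central_zone_filter(
    beads: Sequence[BeadRecord], image_shape: tuple[int, int], fraction: float = 0.30
) -> list[BeadRecord]:
    """Flag beads outside the centred window of side fraction·min(w, h).

    Restricting the analysis to the central zone of the field of view
    avoids off-axis aberrations biasing the FWHM statistics.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ny, nx = image_shape[-2], image_shape[-1]
    half = fraction * min(nx, ny) / 2.0
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    for rec in beads:
        if rec.kept and (abs(rec.x - cx) > half or abs(rec.y - cy) > half):
            rec.exclusion = Exclusion.CENTRAL_ZONE_OUT
    return list(beads)


def _roi_view(stack: np.ndarray, bead: BeadRecord) -> np.ndarray:
    nz, ny, nx = stack.shape
    z0, z1 = max(0, bead.z_max - bead.roi_z), min(nz, bead.z_max + bead.roi_z + 1)
    y0, y1 = max(0, bead.y - bead.roi_xy), min(ny, bead.y + bead.roi_xy + 1)
    x0, x1 = max(0, bead.x - bead.roi_xy), min(nx, bead.x + bead.roi_xy + 1)
    return stack[z0:z1, y0:y1, x0:x1]


def _gaussian(x: np.ndarray, amp: float, mu: float, sigma: float, offset: float) -> np.ndarray:
    return offset + amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _fit_profile(profile: np.ndarray) -> tuple[float, float, str]:
    """Fit Gaussian+constant to a 1D profile; return (sigma, r2, reason).

    Initialisation from the profile maximum, intensity centroid and
    second moment.  A failed or degenerate fit returns NaNs with the
    reason string set.
    """
    y = np.asarray(profile, dtype=float)
    x = np.arange(y.size, dtype=float)
    offset0 = float(y.min())
    amp0 = float(y.max() - offset0)
    if amp0 <= 0:
        return math.nan, math.nan, "flat profile"
    w = np.clip(y - offset0, 0, None)
    mu0 = float((x * w).sum() / w.sum())
    var0 = float(((x - mu0) ** 2 * w).sum() / w.sum())
    sigma0 = max(math.sqrt(var0), 0.5)
    try:
        popt, _ = curve_fit(
            _gaussian, x, y, p0=[amp0, mu0, sigma0, offset0], maxfev=5000
        )
    except RuntimeError:
        return math.nan, math.nan, "fit did not converge"
    amp, mu, sigma, offset = popt
    sigma = abs(float(sigma))
    if amp <= 0 or sigma <= 0 or not math.isfinite(sigma):
        return math.nan, math.nan, "degenerate fit"
    resid = y - _gaussian(x, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else math.nan
    return sigma, r2, ""


def _sbr(stack: np.ndarray, bead: BeadRecord, meta: AcquisitionMeta, z_peak: int) -> float:
    """Signal-to-background: segmented bead mean over a 1-µm annulus mean.

    The bead is segmented by Otsu threshold on the ROI's brightest plane;
    the background annulus extends 1 µm outward from the segmentation.
    """
    ny, nx = stack.shape[1:]
    y0, y1 = max(0, bead.y - bead.roi_xy), min(ny, bead.y + bead.roi_xy + 1)
    x0, x1 = max(0, bead.x - bead.roi_xy), min(nx, bead.x + bead.roi_xy + 1)
    plane = stack[z_peak, y0:y1, x0:x1].astype(float)
    if plane.max() == plane.min():
        return math.nan
    mask = plane > threshold_otsu(plane)
    if not mask.any():
        return math.nan
    annulus_px = max(1, int(round(1.0 / meta.pixel_size_xy)))
    dilated = binary_dilation(mask, structure=disk(annulus_px))
    annulus = dilated & ~mask
    if not annulus.any():
        return math.nan
    background = float(plane[annulus].mean())
    if background <= 0:
        return math.inf
    return float(plane[mask].mean()) / background


def fit_psf(stack: np.ndarray, bead: BeadRecord, meta: AcquisitionMeta) -> PsfResult:
    """Measure one bead: per-axis Gaussian fits, SBR and SNR.

    Profiles are single-voxel-wide lines through the brightest voxel of
    the bead's ROI; ties on the maximum are broken toward the lowest
    (z, y, x) index.  FWHM = 2√(2 ln 2)·σ, converted to µm with the
    pixel size (xy) or z-step (z).
    """
    stack = np.asarray(stack)
    if not bead.kept:
        raise ValueError(f"bead at ({bead.x},{bead.y}) is excluded: {bead.exclusion.value}")
    roi = _roi_view(stack, bead)
    # global maximum inside the ROI; np.argmax takes the first (lowest index) tie
    zc, yc, xc = np.unravel_index(int(np.argmax(roi)), roi.shape)

    sig_x, r2_x, why_x = _fit_profile(roi[zc, yc, :])
    sig_y, r2_y, why_y = _fit_profile(roi[zc, :, xc])
    sig_z, r2_z, why_z = _fit_profile(roi[:, yc, xc])

    z_step = meta.z_step if meta.z_step is not None else meta.pixel_size_xy
    res = PsfResult(
        fwhm_x=FWHM_PER_SIGMA * sig_x * meta.pixel_size_xy,
        fwhm_y=FWHM_PER_SIGMA * sig_y * meta.pixel_size_xy,
        fwhm_z=FWHM_PER_SIGMA * sig_z * z_step,
        r2_x=r2_x,
        r2_y=r2_y,
        r2_z=r2_z,
        bead=bead,
    )
    reasons = "; ".join(w for w in (why_x, why_y, why_z) if w)
    if reasons:
        res.valid = False
        res.invalid_reason = reasons

    z_abs = max(0, bead.z_max - bead.roi_z) + zc
    res.sbr = _sbr(stack, bead, meta, z_abs)
    # SNR proxy: sqrt of the max voxel rescaled to a 12-bit range
    max_val = float(roi.max())
    res.snr = math.sqrt(max_val / 2 ** (meta.bit_depth - 12))
    return res


def attach_ratios(result: PsfResult, spec: ResolutionSpec) -> PsfResult:
    """Fill in measured/theoretical FWHM ratios for one bead."""
    lateral = (result.fwhm_x + result.fwhm_y) / 2.0
    result.ratio_xy = lateral / spec.lateral
    result.ratio_z = result.fwhm_z / spec.axial
    return result


@dataclass
class PsfSummary:
    """Aggregate over beads passing the per-axis R² filter."""

    n_beads: int
    mean_fwhm: dict[str, float]
    sd_fwhm: dict[str, float]
    n_used: dict[str, int]
    mean_ratio_xy: float
    mean_ratio_z: float
    mean_sbr: float
    mean_lar: float
    ratio_xy_pass: bool
    ratio_z_pass: bool
    warnings: list[str] = field(default_factory=list)


def summarize_psf(
    results: Sequence[PsfResult],
    spec: ResolutionSpec,
    r2_min: float = 0.95,
    fwhm_ratio_max: float = 1.5,
) -> PsfSummary:
    """Per-axis mean ± SD FWHM over beads whose fit passes ``r2_min``.

    The R² filter is applied independently per axis, so a bead with a
    poor axial fit still contributes to the lateral statistics.  Mean
    measured/theoretical ratios are flagged against the FWHM tolerance.
    """
    valid = [r for r in results if r.valid]
    if not valid:
        raise ValueError("no valid PSF results to summarise")
    warnings: list[str] = []
    if len(valid) < 5:
        warnings.append(f"only {len(valid)} beads analysed; protocol recommends at least 5")

    axes = {"x": "fwhm_x", "y": "fwhm_y", "z": "fwhm_z"}
    mean_fwhm: dict[str, float] = {}
    sd_fwhm: dict[str, float] = {}
    n_used: dict[str, int] = {}
    for axis, attr in axes.items():
        passing = [getattr(r, attr) for r in valid if getattr(r, f"r2_{axis}") >= r2_min]
        if not passing:
            raise ValueError(f"all beads filtered out on axis {axis} by R² >= {r2_min}")
        arr = np.array(passing)
        mean_fwhm[axis] = float(arr.mean())
        sd_fwhm[axis] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        n_used[axis] = int(arr.size)

    lateral = (mean_fwhm["x"] + mean_fwhm["y"]) / 2.0
    mean_ratio_xy = lateral / spec.lateral
    mean_ratio_z = mean_fwhm["z"] / spec.axial
    sbrs = [r.sbr for r in valid if math.isfinite(r.sbr)]
    lars = [r.lar for r in valid if math.isfinite(r.lar)]
    return PsfSummary(
        n_beads=len(valid),
        mean_fwhm=mean_fwhm,
        sd_fwhm=sd_fwhm,
        n_used=n_used,
        mean_ratio_xy=mean_ratio_xy,
        mean_ratio_z=mean_ratio_z,
        mean_sbr=float(np.mean(sbrs)) if sbrs else math.nan,
        mean_lar=float(np.mean(lars)) if lars else math.nan,
        ratio_xy_pass=mean_ratio_xy <= fwhm_ratio_max,
        ratio_z_pass=mean_ratio_z <= fwhm_ratio_max,
        warnings=warnings,
    )


def analyze_psf_stack(
    stack: np.ndarray,
    meta: AcquisitionMeta,
    prominence: float,
    channel_index: int = 0,
    r2_min: float = 0.95,
    central_fraction: Optional[float] = None,
    discard_saturated: bool = True,
) -> tuple[list[PsfResult], PsfSummary]:
    """End-to-end PSF analysis of one single-channel z-stack."""
    spec = theoretical_resolution(meta, meta.channels[channel_index])
    beads = detect_beads(stack, meta, prominence, discard_saturated=discard_saturated, spec=spec)
    if central_fraction is not None:
        central_zone_filter(beads, stack.shape[-2:], central_fraction)
    results = [attach_ratios(fit_psf(stack, b, meta), spec) for b in beads if b.kept]
    summary = summarize_psf(results, spec, r2_min=r2_min)
    return results, summary
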
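"""Field-illumination flatness analysis.

The image is smoothed with a Gaussian blur (sigma = 2 pixels) to
de-weight hot pixels and dust, normalised by its maximum, and binned
into isointensity steps.  Two metrics are computed:

* Uniformity  U = 100 · I_min / I_max  over the smoothed field of view.
* Centering   C = 100 − 100 · 2·d / diag, where d is the distance of the
  reference-zone centre (the geometric centre of the top isointensity
  band, 90–100% by default) from the image centre and diag the image
  diagonal.

Both are percentages; 100 is the ideal flat, centred field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from microqc.core import (
    AcquisitionMeta,
    DEFAULT_TOLERANCES,
    QCReport,
    ToleranceRegistry,
    make_provenance,
)

BLUR_SIGMA = 2.0


@dataclass
class FieldIllumResult:
    """Per-channel uniformity/centering metrics and diagnostic maps.

    Centre coordinates are (x, y) in 0-based pixels.  ``centering_max_pixel``
    is the variant computed from the single brightest pixel instead of the
    reference-zone centre.
    """

    uniformity: float
    centering: float
    centering_max_pixel: float
    geometric_center: tuple[float, float]
    intensity_centroid: tuple[float, float]
    max_pixel: tuple[int, int]
    reference_center: tuple[float, float]
    normalized_map: np.ndarray
    iso_map: np.ndarray
    saturated: bool
    bins: int

    def passes(self, registry: ToleranceRegistry = DEFAULT_TOLERANCES) -> dict[str, bool]:
        from microqc.core import flag_metric

        return {
            "uniformity": flag_metric(self.uniformity, "uniformity", registry),
            "centering": flag_metric(self.centering, "centering", registry),
        }


def _centering(center: tuple[float, float], width: int, height: int) -> float:
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    d = math.hypot(center[0] - cx, center[1] - cy)
    return 100.0 - 100.0 * 2.0 * d / math.hypot(width, height)


def analyze_field(
    image: np.ndarray,
    bins: int = 10,
    reference_band: float = 0.9,
    discard_saturated: bool = False,
    bit_depth: int = 16,
) -> FieldIllumResult:
    """Analyse one single-channel field-illumination image.

    Parameters
    ----------
    image
        2D image, at least 16×16 pixels.
    bins
        Number of equal-width isointensity bins (10 gives 10% steps).
    reference_band
        Lower edge of the reference zone on the normalised scale;
        0.9 selects the 90–100% band.
    discard_saturated
        If True, a saturated image raises instead of being analysed.
        Saturation is evaluated on the blurred image, so an isolated hot
        pixel does not trigger it.
    bit_depth
        Sensor bit depth used for the saturation value.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {image.shape}")
    if min(image.shape) < 16:
        raise ValueError("image must be at least 16x16")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if image.max() <= 0:
        raise ValueError("constant-zero image: normalization undefined")

    blurred = gaussian_filter(image, sigma=BLUR_SIGMA)
    max_val = float(2**bit_depth - 1)
    # the blur is exact on a uniform saturated region up to float error
    saturated = bool(blurred.max() >= max_val - 0.5)
    if saturated and discard_saturated:
        raise ValueError("image saturated after blur; analysis skipped")

    i_max = float(blurred.max())
    i_min = float(blurred.min())
    uniformity = 100.0 * i_min / i_max

    normalized = blurred / i_max
    # bin index b covers (b/bins, (b+1)/bins]; the top bin includes 1.0
    iso_map = np.minimum((normalized * bins).astype(int), bins - 1)

    ny, nx = image.shape
    yy, xx = np.nonzero(normalized >= reference_band)
    ref_center = (float(xx.mean()), float(yy.mean()))
    flat_idx = int(np.argmax(blurred))
    my, mx = np.unravel_index(flat_idx, blurred.shape)

    total = blurred.sum()
    gy, gx = np.mgrid[0:ny, 0:nx]
    centroid = (float((gx * blurred).sum() / total), float((gy * blurred).sum() / total))

    return FieldIllumResult(
        uniformity=uniformity,
        centering=_centering(ref_center, nx, ny),
        centering_max_pixel=_centering((float(mx), float(my)), nx, ny),
        geometric_center=((nx - 1) / 2.0, (ny - 1) / 2.0),
        intensity_centroid=centroid,
        max_pixel=(int(mx), int(my)),
        reference_center=ref_center,
        normalized_map=normalized,
        iso_map=iso_map,
        saturated=saturated,
        bins=bins,
    )


def analyze_field_multichannel(
    stack: np.ndarray,
    meta: Optional[AcquisitionMeta] = None,
    bins: int = 10,
    reference_band: float = 0.9,
    discard_saturated: bool = False,
    registry: ToleranceRegistry = DEFAULT_TOLERANCES,
) -> tuple[list[Optional[FieldIllumResult]], QCReport]:
    """Per-channel field-illumination analysis of a (C, Y, X) stack.

    A failure on one channel (e.g. saturation with discard enabled) is
    recorded in the report and does not stop the other channels.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected (C, Y, X), got shape {stack.shape}")
    bit_depth = meta.bit_depth if meta is not None else 16

    report = QCReport(analysis="field_illumination", provenance=make_provenance(meta=meta))
    results: list[Optional[FieldIllumResult]] = []
    rows = []
    for c in range(stack.shape[0]):
        name = (
            meta.channels[c].name
            if meta is not None and c < len(meta.channels)
            else f"ch{c}"
        )
        try:
            res = analyze_field(
                stack[c],
                bins=bins,
                reference_band=reference_band,
                discard_saturated=discard_saturated,
                bit_depth=bit_depth,
            )
        except ValueError as exc:
            results.append(None)
            rows.append({"channel": name, "error": str(exc)})
            continue
        results.append(res)
        flags = res.passes(registry)
        rows.append(
            {
                "channel": name,
                "uniformity": res.uniformity,
                "centering": res.centering,
                "uniformity_pass": flags["uniformity"],
                "centering_pass": flags["centering"],
                "saturated": res.saturated,
            }
        )
        report.add_metric(f"uniformity[{name}]", res.uniformity, registry=None, units="%")
        report.metrics[-1].threshold, _ = registry.threshold("uniformity")
        report.metrics[-1].passed = flags["uniformity"]
        report.add_metric(f"centering[{name}]", res.centering, registry=None, units="%")
        report.metrics[-1].threshold, _ = registry.threshold("centering")
        report.metrics[-1].passed = flags["centering"]
    report.tables["channels"] = rows
    return results, report
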
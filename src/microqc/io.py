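"""TIFF/OME-TIFF reading with axis canonicalisation.

Arrays are returned in T,Z,C,Y,X order regardless of on-disk layout,
with singleton axes inserted for missing dimensions.  Metadata
precedence is CLI/config overrides > OME metadata > TIFF tags; callers
supply overrides explicitly.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import tifffile

CANONICAL_AXES = "TZCYX"


def read_stack(path: str, axes: Optional[str] = None) -> np.ndarray:
    """Read a TIFF and canonicalise to (T, Z, C, Y, X).

    ``axes`` overrides the axis string when the file does not declare
    one; otherwise the tifffile series metadata is used.  A plain 2D
    image comes back as (1, 1, 1, Y, X).
    """
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        file_axes = axes or series.axes
    file_axes = file_axes.upper().replace("S", "C").replace("Q", "T")
    if len(file_axes) != data.ndim:
        raise ValueError(
            f"{path}: axis string {file_axes!r} does not match array with {data.ndim} dims"
        )
    unknown = set(file_axes) - set(CANONICAL_AXES)
    if unknown:
        raise ValueError(f"{path}: unsupported axes {sorted(unknown)}")
    for ax in CANONICAL_AXES:
        if ax not in file_axes:
            data = np.expand_dims(data, 0)
            file_axes = ax + file_axes
    order = [file_axes.index(ax) for ax in CANONICAL_AXES]
    return np.transpose(data, order)


def write_stack(path: str, data: np.ndarray, axes: str = "ZYX") -> None:
    """Write an array as TIFF with an explicit axis declaration."""
    tifffile.imwrite(path, data, metadata={"axes": axes})


def read_pixel_size(path: str) -> Optional[float]:
    """Best-effort pixel size (µm) from TIFF resolution tags, else None."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is None:
            return None
        num, den = res.value
        if num == 0:
            return None
        per_unit = num / den
        # ResolutionUnit: 2 = inch, 3 = centimetre
        if unit is not None and unit.value == 2:
            return 25400.0 / per_unit
        if unit is not None and unit.value == 3:
            return 10000.0 / per_unit
    return None
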
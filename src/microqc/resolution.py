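"""Theoretical resolution and sampling-density formulas.

The diffraction-limited full width at half maximum (FWHM) of the point
spread function, per modality:

* Wide-field:            lateral 0.51·λem/NA,  axial 1.77·n·λem/NA²
* Laser-scanning confocal (pinhole ≥ 1 A.U., NA > 0.5):
                         lateral 0.51·λex/NA,  axial 0.88·λex/(n−√(n²−NA²))
* Spinning-disk confocal (pinhole below 1 A.U.):
                         lateral 0.51·λem/NA,  axial λem/(n−√(n²−NA²))

Wavelengths are taken in nm at the API and converted to µm internally;
all returned lengths are in µm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from microqc.core import AcquisitionMeta, ChannelMeta, Modality

#: FWHM of a Gaussian in units of its standard deviation, 2*sqrt(2*ln 2).
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

NM_PER_UM = 1000.0


@dataclass(frozen=True)
class ResolutionSpec:
    """Theoretical lateral and axial resolution (µm) for one channel."""

    lateral: float
    axial: float
    modality: Modality
    channel: ChannelMeta

    def __post_init__(self) -> None:
        if self.lateral <= 0 or self.axial <= 0:
            raise ValueError("resolutions must be positive")


def theoretical_resolution(meta: AcquisitionMeta, channel: ChannelMeta) -> ResolutionSpec:
    """Diffraction-limited FWHM resolution for one channel, in µm.

    Raises
    ------
    ValueError
        If NA exceeds the refractive index (the confocal axial term
        would take the square root of a negative number).
    """
    na, n = meta.na, meta.refractive_index
    if na > n:
        raise ValueError(f"NA ({na}) > refractive index ({n}): axial formula undefined")
    lam_em = channel.lambda_em / NM_PER_UM
    lam_ex = channel.lambda_ex / NM_PER_UM
    modality = Modality(meta.modality)
    if modality is Modality.WF:
        lateral = 0.51 * lam_em / na
        axial = 1.77 * n * lam_em / na**2
    elif modality is Modality.LSCM:
        lateral = 0.51 * lam_ex / na
        axial = 0.88 * lam_ex / (n - math.sqrt(n**2 - na**2))
    else:  # SDCM
        lateral = 0.51 * lam_em / na
        axial = lam_em / (n - math.sqrt(n**2 - na**2))
    return ResolutionSpec(lateral=lateral, axial=axial, modality=modality, channel=channel)


def nyquist_pixel(lambda_ex: float, na: float, pinhole_factor: float = 1.0) -> float:
    """Shannon–Nyquist pixel-size criterion λex/(8·NA), in nm.

    Parameters
    ----------
    lambda_ex
        Excitation wavelength in nm.
    na
        Numerical aperture.
    pinhole_factor
        1.0 for a closed pinhole; 1.6 for a 1-A.U. pinhole, which relaxes
        the criterion by allowing a 1.6× larger pixel.
    """
    if na <= 0:
        raise ValueError("NA must be positive")
    if pinhole_factor < 1:
        raise ValueError("pinhole_factor must be >= 1")
    return pinhole_factor * lambda_ex / (8.0 * na)


def nyquist_pixel_nm(lambda_ex: float, na: float, pinhole_factor: float = 1.0) -> int:
    """Nyquist criterion reported as an integer number of nanometres.

    The criterion is an upper bound on the pixel size, so the integer
    report truncates: the largest whole-nm pixel that still satisfies it.
    """
    return int(math.floor(nyquist_pixel(lambda_ex, na, pinhole_factor)))


def sampling_check(meta: AcquisitionMeta, channel: ChannelMeta) -> dict[str, bool | None]:
    """Check lateral and axial sampling against half the resolution.

    An axis passes when its sampling interval is at most half the
    theoretical resolution on that axis.  If no z-step is declared the
    axial entry is ``None`` and the result is flagged incomplete.
    """
    spec = theoretical_resolution(meta, channel)
    lateral_ok = meta.pixel_size_xy <= spec.lateral / 2.0
    axial_ok = None if meta.z_step is None else meta.z_step <= spec.axial / 2.0
    return {
        "lateral": bool(lateral_ok),
        "axial": axial_ok,
        "complete": meta.z_step is not None,
    }
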
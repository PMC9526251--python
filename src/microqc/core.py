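"""Shared domain types for microscope quality control.

Acquisition metadata, the tolerance registry with pass/fail flagging, and
the QC report container used by every analysis module.

Unit conventions: lengths are stored in micrometres, velocities in
nanometres per minute, times in minutes.  Wavelengths enter the API in
nanometres (the unit vendors print) and are converted at the boundary.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import enum
import json
import logging
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import yaml

logger = logging.getLogger("microqc")

VALID_BIT_DEPTHS = (8, 10, 12, 14, 16)


class Modality(str, enum.Enum):
    """Imaging modality: wide-field, laser-scanning or spinning-disk confocal."""

    WF = "WF"
    LSCM = "LSCM"
    SDCM = "SDCM"


@dataclass(frozen=True)
class ChannelMeta:
    """One fluorescence channel: excitation and emission wavelengths in nm."""

    name: str
    lambda_ex: float
    lambda_em: float

    def __post_init__(self) -> None:
        if not (0 < self.lambda_ex <= self.lambda_em):
            raise ValueError(
                f"channel {self.name!r}: need 0 < lambda_ex <= lambda_em, "
                f"got ex={self.lambda_ex}, em={self.lambda_em}"
            )


@dataclass(frozen=True)
class AcquisitionMeta:
    """Optical and sensor context consumed by every metric.

    Parameters
    ----------
    modality
        Wide-field (``WF``), laser-scanning confocal (``LSCM``) or
        spinning-disk confocal (``SDCM``).
    na
        Numerical aperture of the objective.  Must not exceed the
        refractive index (the confocal axial formulas take
        ``sqrt(n**2 - NA**2)``).
    refractive_index
        Refractive index of the immersion medium.
    pixel_size_xy
        Sample-plane pixel size in µm/pixel.
    z_step
        Axial plane spacing in µm, if a z-stack was acquired.
    time_interval
        Frame interval in seconds for time series.
    channels
        Per-channel excitation/emission wavelengths.
    bit_depth
        Sensor digitisation depth; one of 8, 10, 12, 14, 16.
    conversion_gain
        e⁻/ADU conversion factor, needed only by the camera analyses.
    """

    modality: Modality
    na: float
    refractive_index: float
    pixel_size_xy: float
    channels: tuple[ChannelMeta, ...] = ()
    z_step: Optional[float] = None
    time_interval: Optional[float] = None
    bit_depth: int = 16
    conversion_gain: Optional[float] = None

    def __post_init__(self) -> None:
        if self.na <= 0:
            raise ValueError("numerical aperture must be positive")
        if self.refractive_index < 1:
            raise ValueError("refractive index must be >= 1")
        if self.na > self.refractive_index:
            raise ValueError(
                f"NA ({self.na}) must not exceed the refractive index "
                f"({self.refractive_index})"
            )
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be positive")
        if self.z_step is not None and self.z_step <= 0:
            raise ValueError("z_step must be positive")
        if self.bit_depth not in VALID_BIT_DEPTHS:
            raise ValueError(f"bit_depth must be one of {VALID_BIT_DEPTHS}")
        if self.conversion_gain is not None and self.conversion_gain <= 0:
            raise ValueError("conversion_gain must be positive")
        object.__setattr__(self, "modality", Modality(self.modality))
        object.__setattr__(self, "channels", tuple(self.channels))

    @property
    def max_value(self) -> int:
        """Saturation value for the declared bit depth."""
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class DriftClassBounds:
    """Class boundaries for the three-way drift classification.

    Stabilisation time in minutes, velocities in nm/min.  A quantity is
    *standard* below the standard bound, *acceptable* up to the acceptable
    bound, *critical* beyond it.
    """

    tau_standard_max: float = 45.0
    tau_acceptable_max: float = 120.0
    v_standard_max: float = 15.0
    vb_acceptable_max: float = 100.0
    va_acceptable_max: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.tau_standard_max < self.tau_acceptable_max:
            raise ValueError("tau bounds must satisfy 0 < standard < acceptable")
        if not 0 < self.v_standard_max <= min(self.vb_acceptable_max, self.va_acceptable_max):
            raise ValueError("velocity bounds must satisfy 0 < standard <= acceptable")


# direction of each tolerance: "min" means value >= threshold passes,
# "max" means value <= threshold passes.  Boundary equality passes.
_METRIC_DIRECTIONS: dict[str, tuple[str, str]] = {
    "fwhm_ratio": ("fwhm_ratio_max", "max"),
    "uniformity": ("uniformity_min", "min"),
    "centering": ("centering_min", "min"),
    "coreg_ratio": ("coreg_ratio_max", "max"),
    "stab_power": ("stab_power_min", "min"),
    "sd_norm_power": ("sd_norm_power_max", "max"),
    "repeatability": ("repeatability_max", "max"),
    "var_noise": ("var_noise_min", "min"),
    "stab_noise": ("stab_noise_min", "min"),
}
# the registry field names double as metric ids
_METRIC_ALIASES = {attr: (attr, d) for attr, d in _METRIC_DIRECTIONS.values()}


@dataclass(frozen=True)
class ToleranceRegistry:
    """Default tolerance thresholds for every QC metric.

    Thresholds are inclusive on the passing side: uniformity of exactly
    50% passes.  The normalised-power SD limit defaults to 0.02, matching
    the scale of typical normalised laser-power traces.  All values can
    be overridden from a YAML config via :func:`load_tolerances`.
    """

    fwhm_ratio_max: float = 1.5
    uniformity_min: float = 50.0
    centering_min: float = 20.0
    coreg_ratio_max: float = 1.0
    stab_power_min: float = 97.0
    sd_norm_power_max: float = 0.02
    repeatability_max: float = 0.2
    var_noise_min: float = 90.0
    stab_noise_min: float = 97.0
    drift_bounds: DriftClassBounds = field(default_factory=DriftClassBounds)

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name == "drift_bounds":
                continue
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be strictly positive")

    def threshold(self, metric_id: str) -> tuple[float, str]:
        """Return (threshold, direction) for a metric id.

        Both short ids (``"uniformity"``) and registry field names
        (``"uniformity_min"``) are accepted.
        """
        entry = _METRIC_DIRECTIONS.get(metric_id) or _METRIC_ALIASES.get(metric_id)
        if entry is None:
            raise KeyError(f"unknown metric id {metric_id!r}")
        attr, direction = entry
        return getattr(self, attr), direction

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


DEFAULT_TOLERANCES = ToleranceRegistry()


def flag_metric(value: float, metric_id: str, registry: ToleranceRegistry = DEFAULT_TOLERANCES) -> bool:
    """Return True if ``value`` satisfies the tolerance for ``metric_id``.

    Min-type metrics pass when value >= threshold, max-type when
    value <= threshold; equality passes in both cases.
    """
    import math

    if not math.isfinite(value):
        raise ValueError(f"metric value for {metric_id!r} is not finite: {value}")
    threshold, direction = registry.threshold(metric_id)
    return value >= threshold if direction == "min" else value <= threshold


def load_tolerances(path: str) -> ToleranceRegistry:
    """Build a tolerance registry from a YAML file of overrides.

    Keys mirror the registry field names; ``drift_bounds`` may be a nested
    mapping.  Missing keys keep their defaults.
    """
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    if not isinstance(overrides, dict):
        raise ValueError(f"tolerance config {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(ToleranceRegistry)}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown tolerance keys in {path}: {sorted(unknown)}")
    if "drift_bounds" in overrides:
        overrides["drift_bounds"] = DriftClassBounds(**overrides["drift_bounds"])
    return ToleranceRegistry(**overrides)


@dataclass
class MetricEntry:
    """One reported metric with its threshold and pass/fail flag."""

    metric_id: str
    value: float
    threshold: Optional[float]
    passed: Optional[bool]
    units: str = ""

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class QCReport:
    """Serializable result container shared by all analyses.

    Every metric entry carries its threshold and boolean flag;
    round-trips losslessly through JSON.
    """

    analysis: str
    metrics: list[MetricEntry] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)
    tables: dict[str, list[dict[str, Any]]] = field(default_factory=dict)

    def add_metric(
        self,
        metric_id: str,
        value: float,
        registry: Optional[ToleranceRegistry] = DEFAULT_TOLERANCES,
        units: str = "",
    ) -> MetricEntry:
        """Append a metric, flagging it against the registry when known there."""
        threshold = passed = None
        if registry is not None:
            try:
                threshold, _ = registry.threshold(metric_id)
                passed = flag_metric(value, metric_id, registry)
            except KeyError:
                pass
        entry = MetricEntry(metric_id, float(value), threshold, passed, units)
        self.metrics.append(entry)
        return entry

    @property
    def all_passed(self) -> bool:
        return all(m.passed for m in self.metrics if m.passed is not None)

    def to_dict(self) -> dict[str, Any]:
        return {
            "analysis": self.analysis,
            "metrics": [m.to_dict() for m in self.metrics],
            "provenance": self.provenance,
            "tables": self.tables,
        }

    def to_json(self, path: Optional[str] = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "QCReport":
        return cls(
            analysis=d["analysis"],
            metrics=[MetricEntry(**m) for m in d["metrics"]],
            provenance=d.get("provenance", {}),
            tables=d.get("tables", {}),
        )

    @classmethod
    def from_json(cls, text: str) -> "QCReport":
        return cls.from_dict(json.loads(text))

    def to_csv(self, path: str) -> None:
        """Write the metric table as CSV (one row per metric)."""
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["analysis", "metric_id", "value", "threshold", "passed", "units"]
            )
            writer.writeheader()
            for m in self.metrics:
                row = m.to_dict()
                row["analysis"] = self.analysis
                writer.writerow(row)


def make_provenance(input_file: Optional[str] = None, meta: Optional[AcquisitionMeta] = None) -> dict[str, Any]:
    """Standard provenance block: input path, metadata, version, timestamp."""
    from microqc import __version__

    prov: dict[str, Any] = {
        "software": "microqc",
        "version": __version__,
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
    }
    if input_file is not None:
        prov["input_file"] = str(input_file)
    if meta is not None:
        d = dataclasses.asdict(meta)
        d["modality"] = meta.modality.value
        prov["acquisition_meta"] = d
    return prov
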
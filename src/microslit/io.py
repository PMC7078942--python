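"""File formats, run configuration and the reproducible pipeline.

Images travel as 16-bit TIFF or PNG (integer counts, bit-exact round trip)
or 32-bit float TIFF (dose maps), always accompanied by a JSON sidecar
``<image>.json`` carrying the sample pitch, units and acquisition metadata —
an image without its sidecar has unknown units and is refused.  Profiles are
CSV at full float precision.  A :class:`RunConfig` (validated, unknown keys
rejected) drives :func:`run_pipeline`: simulate → average → dark-subtract →
calibrate → analyze, fully determined by its seed.

Coordinates: 0-based array indices; physical positions at sample centres,
``(i + 0.5) * pitch`` µm.  Rows cross the peak pattern; columns run along
the slits.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, Field

from . import frames as fr
from . import profiles as pr
from . import simulator as sim
from .geometry import BeamlineGeometry, CollimatorSpec

logger = logging.getLogger("microslit")

__all__ = [
    "UnitsUnknownError",
    "read_image",
    "write_image",
    "write_profile_csv",
    "read_profile_csv",
    "RunConfig",
    "load_config",
    "run_pipeline",
]


class UnitsUnknownError(IOError):
    """Raised when an image has no JSON sidecar describing pitch and units."""


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_image(path, obj) -> Path:
    """Write a SensorFrame, DoseImage or FieldImage with its JSON sidecar.

    Integer-valued counts go to uint16 (bit-exact); float data to float32
    TIFF.  PNG is supported for uint16 only.  Returns the sidecar path.
    """
    path = Path(path)
    if isinstance(obj, fr.SensorFrame):
        data, kind, units, pitch = obj.counts, "sensor_frame", "counts", obj.pixel_pitch_um
        extra = {
            "integration_time_ms": obj.integration_time_ms,
            "saturated_fraction": float(obj.saturated_mask.mean()),
        }
    elif isinstance(obj, fr.DoseImage):
        data, kind, units, pitch = obj.dose_rate, "dose_image", "mGy/min", obj.sample_pitch_um
        extra = {"calibration_gain": obj.calibration_gain}
    elif isinstance(obj, sim.FieldImage):
        data, kind, units, pitch = obj.values, "field_image", obj.units, obj.sample_pitch_um
        extra = {}
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")

    integral = np.all(data == np.rint(data)) and data.min() >= 0 and data.max() <= 65535
    if integral:
        arr = data.astype(np.uint16)
        dtype = "uint16"
    else:
        arr = data.astype(np.float32)
        dtype = "float32"
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif suffix == ".png":
        if dtype != "uint16":
            raise ValueError("PNG output requires integer counts in [0, 65535]")
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    else:
        raise ValueError(f"unsupported image suffix {suffix!r} (use .tif/.tiff/.png)")

    meta = getattr(obj, "meta", {})
    sidecar = {
        "kind": kind,
        "units": units,
        "sample_pitch_um": pitch,
        "dtype": dtype,
        "meta": _jsonable(meta),
        **extra,
    }
    sc_path = _sidecar_path(path)
    sc_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return sc_path


def read_image(path):
    """Read an image written by :func:`write_image`; sidecar is mandatory."""
    path = Path(path)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise UnitsUnknownError(
            f"no sidecar {sc_path.name}: sample pitch and units are unknown"
        )
    sidecar = json.loads(sc_path.read_text())
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image suffix {suffix!r}")
    arr = np.asarray(arr, dtype=float)
    kind = sidecar["kind"]
    if kind == "sensor_frame":
        return fr.SensorFrame(
            counts=arr,
            integration_time_ms=sidecar["integration_time_ms"],
            pixel_pitch_um=sidecar["sample_pitch_um"],
            meta=sidecar.get("meta", {}),
        )
    if kind == "dose_image":
        return fr.DoseImage(
            dose_rate=arr,
            sample_pitch_um=sidecar["sample_pitch_um"],
            calibration_gain=sidecar["calibration_gain"],
            meta=sidecar.get("meta", {}),
        )
    if kind == "field_image":
        return sim.FieldImage(
            values=arr,
            sample_pitch_um=sidecar["sample_pitch_um"],
            units=sidecar["units"],
            meta=sidecar.get("meta", {}),
        )
    raise ValueError(f"unknown image kind {kind!r} in sidecar")


def write_profile_csv(path, profile: pr.Profile) -> None:
    """Write a profile as CSV at full float precision."""
    df = pd.DataFrame({"position_um": profile.positions_um, "value": profile.values})
    df.to_csv(path, index=False, float_format="%.17g")


def read_profile_csv(path, band: str = "") -> pr.Profile:
    df = pd.read_csv(path, float_precision="round_trip")
    return pr.Profile(df["position_um"].to_numpy(), df["value"].to_numpy(), band=band)


# ---------------------------------------------------------------------------
# run configuration


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    source_collimator_distance_mm: float = 212.0
    collimator_plane_distance_mm: float = 68.0
    source_size_mm: float = 0.4
    slit_width_um: float = 100.0
    detector_ssd_mm: float | None = None
    ssd_slack_mm: float = 15.0

    def build(self) -> BeamlineGeometry:
        return BeamlineGeometry(**self.model_dump())


class CollimatorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_slits: int = 51
    slit_separation_um: float = 400.0
    slit_length_mm: float = 20.0
    leakage_fraction: float = 0.01
    hole_diameter_mm: float = 0.3
    heel_gradient_per_mm: float = 0.0
    closed_transmission_fraction: float = 0.05

    def build(self) -> CollimatorSpec:
        return CollimatorSpec(**self.model_dump())


class DetectorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pixel_pitch_um: float = 50.0
    n_rows: int = 620
    n_cols: int = 256
    dark_mean: float = 100.0
    dark_sigma: float = 2.0
    read_noise_sigma: float = 5.0
    gain_counts_per_mGy: float = 1.0e5
    integration_time_ms: float = 28.0
    saturation_level: float = 65535.0

    def build(self) -> sim.DetectorModel:
        return sim.DetectorModel(**self.model_dump())


class ScannerConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sample_pitch_um: float = 18.1
    blur_fwhm_um: float = 200.0
    noise_sigma: float = 0.01

    def build(self) -> sim.ScannerModel:
        return sim.ScannerModel(**self.model_dump())


class AnalysisConfigModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    expected_separation_um: float = 512.0
    axis: str = "rows"
    band: tuple[int, int] | None = None
    min_prominence_fraction: float = 0.1
    fit_window_fraction: float = 0.45
    valley_fraction: float = 0.2

    def build(self) -> pr.AnalysisConfig:
        return pr.AnalysisConfig(**self.model_dump())


class RunConfig(BaseModel):
    """Validated end-to-end run description; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    collimator: CollimatorConfig = Field(default_factory=CollimatorConfig)
    detector: DetectorConfig = Field(default_factory=DetectorConfig)
    scanner: ScannerConfig | None = None
    analysis: AnalysisConfigModel = Field(default_factory=AnalysisConfigModel)
    peak_dose_rate_mGy_min: float = 60.0
    projected_separation_um: float | None = 512.0
    exposure_s: float = 240.0
    n_frames: int = 8
    n_dark_frames: int = 8
    seed: int = 0
    supersample: int = 8


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    return RunConfig.model_validate_json(Path(path).read_text())


def run_pipeline(config: RunConfig) -> dict:
    """Simulate → average → dark-subtract → calibrate → analyze.

    Returns a JSON-serialisable report with every analysis field plus the
    parameters and seed; identical config and seed give an identical report.
    """
    geom = config.geometry.build()
    coll = config.collimator.build()
    det = config.detector.build()
    logger.info(
        "pipeline: seed=%d n_frames=%d fit_window_fraction=%.3g valley_fraction=%.3g "
        "supersample=%d",
        config.seed, config.n_frames, config.analysis.fit_window_fraction,
        config.analysis.valley_fraction, config.supersample,
    )
    field = sim.build_field(
        geom,
        coll,
        peak_dose_rate=config.peak_dose_rate_mGy_min,
        projected_separation_um=config.projected_separation_um,
    )
    raw = sim.render_detector_frames(
        field, det, config.n_frames, seed=config.seed, supersample=config.supersample
    )
    darks = sim.render_dark_frames(det, config.n_dark_frames, seed=config.seed + 1)
    corrected = fr.subtract_dark(fr.average_frames(raw), fr.average_frames(darks))
    # counts -> dose rate from the simulated signal chain (counts per frame
    # per unit dose rate); a measured gain can be substituted via derive_gain
    gain = 1.0 / det.counts_per_frame_per_mGy_min
    dose = fr.calibrate(corrected, gain)
    analysis = pr.analyze_field(dose, coll, config.analysis.build())

    leakage_only = geom.slit_width_um == 0.0
    report = {
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "leakage_only_regime": leakage_only,
        "n_peaks": len(analysis.peaks),
        "separation_mean_um": analysis.separation_mean_um,
        "separation_sd_um": analysis.separation_sd_um,
        "pvdr_mean": analysis.pvdr_mean,
        "pvdr_per_peak": analysis.pvdr_per_peak.tolist(),
        "valley_levels": analysis.valleys.tolist(),
        "fwhm_trend_slope_um_per_mm": analysis.fwhm_trend_slope_um_per_mm,
        "fwhm_trend_intercept_um": analysis.fwhm_trend_intercept_um,
        "fwhm_trend_r2": analysis.fwhm_trend_r2,
        "peaks": [
            {
                "index": p.peak_index,
                "center_um": p.center_um,
                "aligned_center_um": float(c),
                "fwhm_um": p.fwhm_um,
                "fwhm_crossing_um": p.fwhm_crossing_um,
                "amplitude": p.amplitude,
                "baseline": p.baseline,
                "converged": p.converged,
            }
            for p, c in zip(analysis.peaks, analysis.aligned_centers_um)
        ],
    }
    return _jsonable(report)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj
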
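import numpy as np
import pytest

import microslit as ms
from microslit import frames as fr
from microslit import profiles as pr
from microslit import simulator as sim


def make_geometry(slit_width_um: float) -> ms.BeamlineGeometry:
    """The reference beamline: A=212 mm, B=68 mm, S=0.4 mm, SSD 290 mm."""
    with pytest.warns(UserWarning, match="SSD"):
        return ms.BeamlineGeometry(
            source_collimator_distance_mm=212.0,
            collimator_plane_distance_mm=68.0,
            source_size_mm=0.4,
            slit_width_um=slit_width_um,
            detector_ssd_mm=290.0,
        )


@pytest.fixture(scope="session")
def geom_w0() -> ms.BeamlineGeometry:
    return make_geometry(0.0)


@pytest.fixture(scope="session")
def geom_w100() -> ms.BeamlineGeometry:
    return make_geometry(100.0)


@pytest.fixture(scope="session")
def collimator() -> ms.CollimatorSpec:
    return ms.CollimatorSpec()


@pytest.fixture(scope="session")
def small_detector() -> sim.DetectorModel:
    """620 x 160 pixels at 50 µm: tall enough for all 51 peaks at 512 µm."""
    return sim.DetectorModel(n_rows=620, n_cols=160)


@pytest.fixture(scope="session")
def analysis_config() -> pr.AnalysisConfig:
    return pr.AnalysisConfig(expected_separation_um=512.0, band=(30, 130))


def render_dose_image(
    geom: ms.BeamlineGeometry,
    coll: ms.CollimatorSpec,
    det: sim.DetectorModel,
    seed: int,
    n_frames: int = 4,
    peak_dose_rate: float = 60.0,
) -> fr.DoseImage:
    """Full simulate -> average -> dark-subtract -> calibrate chain."""
    field = sim.build_field(geom, coll, peak_dose_rate, projected_separation_um=512.0)
    raw = sim.render_detector_frames(field, det, n_frames, seed=seed)
    darks = sim.render_dark_frames(det, n_frames, seed=seed + 10_000)
    corrected = fr.subtract_dark(fr.average_frames(raw), fr.average_frames(darks))
    return fr.calibrate(corrected, 1.0 / det.counts_per_frame_per_mGy_min)


@pytest.fixture(scope="session")
def dose_image_w50(collimator, small_detector) -> fr.DoseImage:
    """Shared round-trip image at 50 µm nominal slit width with noise."""
    return render_dose_image(make_geometry(50.0), collimator, small_detector, seed=2024)


@pytest.fixture(scope="session")
def analysis_w50(dose_image_w50, collimator, analysis_config) -> pr.FieldAnalysis:
    return pr.analyze_field(dose_image_w50, collimator, analysis_config)


def constant_field(value: float):
    """A spatially uniform dose-rate field callable."""

    def field(y, x):
        return np.broadcast_to(
            float(value), np.broadcast(np.asarray(y), np.asarray(x)).shape
        ).copy()

    return field
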
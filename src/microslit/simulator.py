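"""Synthetic microbeam-field and detector-image generation.

Axis convention (used throughout the package): the multi-slit peak pattern
varies along **rows** (the y axis, µm) — a "vertical profile" across the
peaks is taken down the rows; the slits extend along **columns** (the x axis,
µm).  The physical origin (0, 0) is the centre of the central slit's
projection, and pixel (i, j) of a rendered image is centred at
``((i + 0.5 - n_rows/2) * pitch, (j + 0.5 - n_cols/2) * pitch)``.

The continuous field model is

    f(y, x) = leak · I0  +  Σ_slits  amp_i · P_i(y) · M(x)     (+ drill holes)

with ``P_i`` the exact rect⊗rect penumbra profile of slit *i* (optionally
width-scaled by a linear heel gradient), ``M`` the projected slit extent
along x, and drill-hole disks at both slit ends rendered at the open-field
intensity ``I0``.  The whole field is scaled so the central slit's peak
equals the requested peak dose rate.  The per-slit peak amplitude relative to
the open field is ``min(a, b)/b`` (partial source occlusion by a narrow
slit), floored at the closed-slit-line transmission so the 51-line pattern
remains detectable even with the collimator fully shut.

Detector frames follow a counts = gain · dose + dark + noise model with
Poisson shot noise, Gaussian dark/read noise and saturation clipping;
film scans are a linear dose map with Gaussian optical blur and
multiplicative noise.  All randomness flows from one explicit seed through
``numpy.random.SeedSequence`` spawning, so frame *k* is reproducible
independently of how many frames are requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import (
    GAUSSIAN_FWHM_FACTOR,
    BeamlineGeometry,
    CollimatorSpec,
    exact_penumbra_profile,
    trapezoid_widths,
)

__all__ = [
    "DetectorModel",
    "ScannerModel",
    "FieldImage",
    "ContinuousField",
    "build_field",
    "render_expected_dose_rate",
    "render_detector_frames",
    "render_dark_frames",
    "render_film_scan",
    "make_slanted_edge",
    "make_bar_pattern",
]


@dataclass(frozen=True)
class DetectorModel:
    """Pixelated CMOS detector signal-chain parameters.

    ``gain_counts_per_mGy`` converts absorbed dose per frame (mGy) to mean
    signal counts; dark current enters as an additive offset ``dark_mean``
    with Gaussian frame-to-frame scatter ``dark_sigma``; read noise is a
    zero-mean Gaussian in counts.  Counts are quantised to integers and
    clipped at ``saturation_level``.
    """

    pixel_pitch_um: float = 50.0
    n_rows: int = 1204
    n_cols: int = 1248
    dark_mean: float = 100.0
    dark_sigma: float = 2.0
    read_noise_sigma: float = 5.0
    gain_counts_per_mGy: float = 1.0e5
    integration_time_ms: float = 28.0
    saturation_level: float = 65535.0

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if not 0 <= self.dark_mean < self.saturation_level:
            raise ValueError("dark_mean must lie in [0, saturation)")
        if self.dark_sigma < 0 or self.read_noise_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("detector must have at least one pixel")
        if self.gain_counts_per_mGy <= 0 or self.integration_time_ms <= 0:
            raise ValueError("gain and integration time must be positive")

    @property
    def counts_per_frame_per_mGy_min(self) -> float:
        """Mean counts per frame for a 1 mGy/min dose rate."""
        return self.gain_counts_per_mGy * self.integration_time_ms / 60000.0


@dataclass(frozen=True)
class ScannerModel:
    """Film-scan sampling model: pitch, optical blur, multiplicative noise.

    ``blur_fwhm_um`` is a Gaussian blur standing in for the scanning device's
    optical transfer; ``noise_sigma`` is the fractional (multiplicative)
    noise per sample.
    """

    sample_pitch_um: float = 18.1
    blur_fwhm_um: float = 200.0
    noise_sigma: float = 0.01

    def __post_init__(self) -> None:
        if self.sample_pitch_um <= 0:
            raise ValueError("sample pitch must be positive")
        if self.blur_fwhm_um < 0 or self.noise_sigma < 0:
            raise ValueError("blur and noise must be >= 0")


@dataclass
class FieldImage:
    """A sampled 2D field (dose map or abstract intensity).

    Rows cross the slit pattern; columns run along the slits.
    """

    values: np.ndarray
    sample_pitch_um: float
    units: str = "mGy"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D array")
        if self.sample_pitch_um <= 0:
            raise ValueError("sample pitch must be positive")
        if np.any(self.values < 0):
            raise ValueError("field values must be non-negative")


class ContinuousField:
    """Callable continuous dose-rate field f(y_um, x_um) in mGy/min.

    Built by :func:`build_field`; vectorised over broadcastable ``y``/``x``
    arrays.  Exposes the projected slit-centre positions and per-slit
    trapezoid parameters for use as ground truth in tests.
    """

    def __init__(
        self,
        geom: BeamlineGeometry,
        coll: CollimatorSpec,
        peak_dose_rate: float,
        projected_separation_um: float,
        magnification: float,
    ) -> None:
        self.geom = geom
        self.coll = coll
        self.peak_dose_rate = peak_dose_rate
        self.separation_um = projected_separation_um
        self.magnification = magnification

        n = coll.n_slits
        self.peak_positions_um = (np.arange(n) - (n - 1) / 2.0) * projected_separation_um
        self.half_length_um = 500.0 * coll.slit_length_mm * magnification
        self.hole_radius_um = 500.0 * coll.hole_diameter_mm * magnification

        a, b = trapezoid_widths(geom)
        if b > 0:
            open_frac = min(a, b) / b
        else:
            open_frac = 1.0 if a > 0 else 0.0
        self.amplitude_fraction = float(np.clip(open_frac, coll.closed_transmission_fraction, 1.0))
        # heel effect: per-slit width scale, floored at 0.1x nominal
        scales = 1.0 + coll.heel_gradient_per_mm * self.peak_positions_um / 1000.0
        self.width_scales = np.clip(scales, 0.1, None)
        central = coll.leakage_fraction + self.amplitude_fraction
        self.scale = peak_dose_rate / central

    @property
    def fwhm_per_slit_um(self) -> np.ndarray:
        """Ground-truth FWHM (µm) of each slit's profile, heel included."""
        a, b = trapezoid_widths(self.geom)
        return max(a, b) * self.width_scales

    def peak_profile(self, offsets_um: np.ndarray, slit_index: int) -> np.ndarray:
        """Normalised profile of one slit versus offset from its centre."""
        s = self.width_scales[slit_index]
        return exact_penumbra_profile(self.geom, np.asarray(offsets_um) / s)

    def __call__(self, y_um, x_um):
        y = np.asarray(y_um, dtype=float)
        x = np.asarray(x_um, dtype=float)
        peaks = self._peak_sum(y)
        in_slit = (np.abs(x) <= self.half_length_um).astype(float)
        base = self.coll.leakage_fraction + peaks * in_slit
        base = self._apply_holes(base, y, x)
        return self.scale * base

    def _peak_sum(self, y: np.ndarray) -> np.ndarray:
        """Σ_i amp·P_i(y); only the nearest slits can contribute."""
        c = self.peak_positions_um
        sep = self.separation_um
        idx0 = np.rint((y - c[0]) / sep).astype(int)
        out = np.zeros_like(y, dtype=float)
        for di in (-1, 0, 1):
            idx = idx0 + di
            valid = (idx >= 0) & (idx < len(c))
            idxc = np.clip(idx, 0, len(c) - 1)
            off = y - c[idxc]
            prof = exact_penumbra_profile(self.geom, off / self.width_scales[idxc])
            out += np.where(valid, prof, 0.0)
        # overlapping penumbrae cannot transmit more than the open field
        np.clip(out, 0.0, 1.0, out=out)
        return self.amplitude_fraction * out

    def _apply_holes(self, base: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
        if self.hole_radius_um <= 0:
            return base
        r2 = self.hole_radius_um**2
        c = self.peak_positions_um
        idx = np.clip(np.rint((y - c[0]) / self.separation_um).astype(int), 0, len(c) - 1)
        dy2 = (y - c[idx]) ** 2
        for xc in (-self.half_length_um, self.half_length_um):
            mask = dy2 + (x - xc) ** 2 <= r2
            base = np.where(mask, np.maximum(base, 1.0), base)
        return base


def build_field(
    geom: BeamlineGeometry,
    coll: CollimatorSpec,
    peak_dose_rate: float = 60.0,
    projected_separation_um: float | None = None,
    pattern_distance_mm: float | None = None,
) -> ContinuousField:
    """Construct the continuous multi-slit field at the image plane.

    The projected centre-to-centre separation is, in order of precedence:
    ``projected_separation_um`` explicitly; else the slit pitch magnified
    from ``pattern_distance_mm`` to the detector SSD; else magnified from the
    collimator plane (distance A).  The effective pattern plane inside a
    thick collimator is not knowable from first principles, so measured
    separations may be supplied directly.
    """
    coll.validate_against(geom)
    if peak_dose_rate <= 0:
        raise ValueError("peak dose rate must be positive")
    ssd = geom.detector_ssd_mm
    if projected_separation_um is not None:
        sep = projected_separation_um
    else:
        d_pat = pattern_distance_mm if pattern_distance_mm is not None else (
            geom.source_collimator_distance_mm
        )
        sep = coll.slit_separation_um * ssd / d_pat
    magnification = sep / coll.slit_separation_um
    return ContinuousField(geom, coll, peak_dose_rate, sep, magnification)


def _pixel_centers(n: int, pitch: float, center: float = 0.0) -> np.ndarray:
    return (np.arange(n) - (n - 1) / 2.0) * pitch + center


def render_expected_dose_rate(
    field,
    n_rows: int,
    n_cols: int,
    pitch_um: float,
    supersample: int = 8,
    center_um: tuple[float, float] = (0.0, 0.0),
    chunk_rows: int = 64,
) -> np.ndarray:
    """Noise-free pixel-aperture-averaged dose rate (mGy/min) on a pixel grid.

    Each pixel integrates the continuous field over its pitch×pitch aperture
    using ``supersample``² sample points (>= 4 per side enforced).
    """
    if supersample < 4:
        raise ValueError("supersample must be >= 4 per pixel side")
    yc = _pixel_centers(n_rows, pitch_um, center_um[0])
    xc = _pixel_centers(n_cols, pitch_um, center_um[1])
    sub = ((np.arange(supersample) + 0.5) / supersample - 0.5) * pitch_um
    xs = (xc[:, None] + sub[None, :]).ravel()
    out = np.empty((n_rows, n_cols), dtype=float)
    for start in range(0, n_rows, chunk_rows):
        stop = min(start + chunk_rows, n_rows)
        ys = (yc[start:stop, None] + sub[None, :]).ravel()
        vals = field(ys[:, None], xs[None, :])
        vals = vals.reshape(stop - start, supersample, n_cols, supersample)
        out[start:stop] = vals.mean(axis=(1, 3))
    return out


def _make_frame(counts, det: DetectorModel, saturated, meta):
    # local import avoids a frames <-> simulator import cycle
    from .frames import SensorFrame

    return SensorFrame(
        counts=counts,
        integration_time_ms=det.integration_time_ms,
        pixel_pitch_um=det.pixel_pitch_um,
        saturated_mask=saturated,
        meta=meta,
    )


def render_detector_frames(
    field,
    det: DetectorModel,
    n_frames: int,
    seed: int,
    supersample: int = 8,
    exposure_s: float | None = None,
    center_um: tuple[float, float] = (0.0, 0.0),
):
    """Render ``n_frames`` independent noisy detector frames of a field.

    Signal counts are Poisson draws around gain·dose-per-frame; dark offset
    and read noise are Gaussian; counts are rounded to integers and clipped
    to ``[0, saturation_level]``.  Identical seed ⇒ identical frames, and
    frame *k* does not depend on ``n_frames``.
    Returns a list of ``SensorFrame``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if exposure_s is not None and n_frames * det.integration_time_ms / 1000.0 > exposure_s:
        warnings.warn("requested frames exceed the stated exposure time", stacklevel=2)
    rate = render_expected_dose_rate(
        field, det.n_rows, det.n_cols, det.pixel_pitch_um, supersample, center_um
    )
    expected = rate * det.counts_per_frame_per_mGy_min
    if np.any(expected + det.dark_mean > det.saturation_level):
        warnings.warn("mean signal exceeds the saturation level", stacklevel=2)
    return _draw_frames(expected, det, n_frames, seed, field_meta={"center_um": center_um})


def render_dark_frames(det: DetectorModel, n_frames: int, seed: int):
    """Render dark frames (no irradiation): offset + noise only."""
    expected = np.zeros((det.n_rows, det.n_cols))
    return _draw_frames(expected, det, n_frames, seed, field_meta={"dark": True})


def _draw_frames(expected: np.ndarray, det: DetectorModel, n_frames: int, seed: int, field_meta):
    children = np.random.SeedSequence([int(seed)]).spawn(n_frames)
    frames = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        counts = rng.poisson(expected).astype(float)
        counts += rng.normal(det.dark_mean, det.dark_sigma, expected.shape)
        if det.read_noise_sigma > 0:
            counts += rng.normal(0.0, det.read_noise_sigma, expected.shape)
        counts = np.rint(counts)
        saturated = counts >= det.saturation_level
        counts = np.clip(counts, 0.0, det.saturation_level)
        meta = {"seed": int(seed), "frame": k, **field_meta}
        if saturated.any():
            meta["saturation_warning"] = True
        frames.append(_make_frame(counts, det, saturated, meta))
    return frames


def render_film_scan(
    field,
    sc: ScannerModel,
    exposure_s: float,
    n_rows: int,
    n_cols: int,
    seed: int | None = None,
    supersample: int = 4,
    center_um: tuple[float, float] = (0.0, 0.0),
) -> FieldImage:
    """Render a film scan: linear dose map, Gaussian blur, multiplicative noise.

    Dose (mGy) = dose rate × exposure; blur of FWHM ``sc.blur_fwhm_um``
    emulates the scanning optics; ``seed=None`` disables noise.
    """
    if exposure_s <= 0:
        raise ValueError("exposure must be positive")
    dose = render_expected_dose_rate(
        field, n_rows, n_cols, sc.sample_pitch_um, supersample, center_um
    ) * (exposure_s / 60.0)
    if sc.blur_fwhm_um > 0:
        sigma_px = sc.blur_fwhm_um / GAUSSIAN_FWHM_FACTOR / sc.sample_pitch_um
        dose = gaussian_filter(dose, sigma_px, mode="nearest")
    if seed is not None and sc.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
        dose = dose * (1.0 + rng.normal(0.0, sc.noise_sigma, dose.shape))
        dose = np.clip(dose, 0.0, None)
    meta = {"exposure_s": exposure_s, "seed": seed, "kind": "film_scan"}
    return FieldImage(dose, sc.sample_pitch_um, units="mGy", meta=meta)


def make_slanted_edge(
    det: DetectorModel,
    angle_deg: float = 4.0,
    seed: int | None = None,
    low_counts: float = 500.0,
    high_counts: float = 3000.0,
    n_rows: int | None = None,
    n_cols: int | None = None,
    n_sub: int = 64,
):
    """Render a slanted sharp-edge image for edge-spread-function analysis.

    The edge is a half-plane boundary through the image centre, tilted
    ``angle_deg`` from the column (vertical) direction; the right side is
    bright.  Pixel coverage is exact along x and sub-sampled ``n_sub`` times
    along y, so at zero noise the image is the pixel-aperture-integrated
    ideal step.  ``seed=None`` gives a noise-free frame; otherwise Poisson +
    read noise are applied.  Returns a ``SensorFrame``.
    """
    nr = n_rows or min(det.n_rows, 256)
    nc = n_cols or min(det.n_cols, 256)
    p = det.pixel_pitch_um
    tan = np.tan(np.deg2rad(angle_deg))
    yc = _pixel_centers(nr, p)
    xc = _pixel_centers(nc, p)
    sub = ((np.arange(n_sub) + 0.5) / n_sub - 0.5) * p
    ys = yc[:, None] + sub[None, :]          # (nr, n_sub)
    edge_x = tan * ys                        # edge position per row subsample
    # coverage of the bright half-plane x > edge_x over pixel [xc-p/2, xc+p/2]
    frac = np.clip((xc[None, None, :] + p / 2.0 - edge_x[:, :, None]) / p, 0.0, 1.0)
    coverage = frac.mean(axis=1)
    counts = low_counts + (high_counts - low_counts) * coverage
    if seed is not None:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
        counts = rng.poisson(counts).astype(float)
        if det.read_noise_sigma > 0:
            counts += rng.normal(0.0, det.read_noise_sigma, counts.shape)
        counts = np.clip(np.rint(counts), 0.0, det.saturation_level)
    saturated = counts >= det.saturation_level
    meta = {"kind": "slanted_edge", "angle_deg": angle_deg, "seed": seed}
    return _make_frame(counts, det, saturated, meta)


def make_bar_pattern(
    model,
    line_widths_um,
    n_periods: int = 8,
    n_rows: int = 64,
    supersample: int = 8,
) -> FieldImage:
    """Render a bar (square-wave) resolution pattern.

    ``model`` may be a :class:`DetectorModel` (pixel-aperture averaging only)
    or a :class:`ScannerModel` (aperture averaging plus Gaussian blur).  Each
    requested line width occupies one block of ``n_periods`` periods
    (period = 2 × line width) along the column axis, separated by flat dark
    guard bands; block pixel ranges are recorded in ``meta['block_slices']``.
    Intensity alternates between 0 and 1.
    """
    if isinstance(model, DetectorModel):
        pitch, blur = model.pixel_pitch_um, 0.0
    elif isinstance(model, ScannerModel):
        pitch, blur = model.sample_pitch_um, model.blur_fwhm_um
    else:
        raise TypeError("model must be a DetectorModel or ScannerModel")
    widths = [float(w) for w in line_widths_um]
    if not widths or any(w <= 0 for w in widths):
        raise ValueError("line widths must be positive")

    segments = []  # (x_start_um, x_end_um, line_width)
    cursor = 0.0
    for w in widths:
        guard = max(4.0 * w, 4.0 * pitch)
        cursor += guard
        segments.append((cursor, cursor + n_periods * 2.0 * w, w))
        cursor += n_periods * 2.0 * w
    cursor += max(4.0 * widths[-1], 4.0 * pitch)

    n_cols = int(np.ceil(cursor / pitch))
    sub = ((np.arange(supersample) + 0.5) / supersample) * pitch
    xs = (np.arange(n_cols)[:, None] * pitch + sub[None, :]).ravel()
    profile_ss = np.zeros_like(xs)
    for x0, x1, w in segments:
        inside = (xs >= x0) & (xs < x1)
        phase = np.floor((xs[inside] - x0) / w).astype(int)
        profile_ss[inside] = (phase % 2 == 0).astype(float)  # start on a bright bar
    if blur > 0:
        sigma_samples = blur / GAUSSIAN_FWHM_FACTOR / (pitch / supersample)
        profile_ss = gaussian_filter(profile_ss, sigma_samples, mode="nearest")
    profile = profile_ss.reshape(n_cols, supersample).mean(axis=1)
    values = np.tile(profile, (n_rows, 1))
    block_slices = [
        (int(np.floor(x0 / pitch)), int(np.ceil(x1 / pitch))) for x0, x1, _ in segments
    ]
    meta = {"block_slices": block_slices, "line_widths_um": widths, "kind": "bar_pattern"}
    return FieldImage(values, pitch, units="relative", meta=meta)
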
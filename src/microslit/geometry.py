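"""Geometric model of slit projection for a multi-slit microbeam collimator.

A finite x-ray source of size ``S`` (mm) sits a distance ``A`` (mm) upstream of
a thin collimator slit of width ``w`` (µm); the image plane lies a further
``B`` (mm) downstream.  The projected beam at the image plane is the
convolution of the magnified slit aperture, a uniform window of width

    a = (1 + B/A) * w          [µm]

with the projected source, a uniform window of width

    b = B * S / A              [µm]

The widely used first-order approximation to the projected beam width is the
sum of the two,

    L = (B/A + 1) * w + B * S / A,

which is linear in both the slit width and the source size.  The exact
rect⊗rect profile is a trapezoid with flat top ``|a - b|``, base ``a + b`` and
FWHM ``max(a, b)``; ``L`` is its base-to-top mean and always bounds the FWHM
from above.

Units: distances ``A``, ``B``, ``S`` and SSDs in mm; slit widths, beam widths
and separations in µm.  All public functions state their units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

__all__ = [
    "BeamlineGeometry",
    "CollimatorSpec",
    "InvalidGeometryError",
    "DegenerateApertureError",
    "projected_beam_width",
    "width_uncertainty",
    "trapezoid_widths",
    "trapezoid_fwhm",
    "exact_penumbra_profile",
    "projected_separation",
    "infer_distance_offset",
    "distance_offset_statistics",
    "round_to_sig_figs",
]

#: FWHM of a unit-σ Gaussian.
GAUSSIAN_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


class InvalidGeometryError(ValueError):
    """Raised when beamline parameters are non-finite or unphysical."""


class DegenerateApertureError(ValueError):
    """Raised when both the magnified slit and projected source have zero width."""


@dataclass(frozen=True)
class BeamlineGeometry:
    """Source–collimator–image-plane geometry of one slit.

    Parameters
    ----------
    source_collimator_distance_mm
        A, distance from the source to the collimator plane (mm), > 0.
    collimator_plane_distance_mm
        B, distance from the collimator plane to the image plane (mm), >= 0.
    source_size_mm
        S, effective source size (mm), >= 0.
    slit_width_um
        w, collimator slit opening (µm), >= 0.
    detector_ssd_mm
        D, source-to-surface distance of the image plane (mm).  Stored
        independently of A + B because mechanical mounting constraints mean
        the quoted distances need not sum exactly; a mismatch up to
        ``ssd_slack_mm`` raises a warning, beyond it an error.
    """

    source_collimator_distance_mm: float
    collimator_plane_distance_mm: float
    source_size_mm: float = 0.0
    slit_width_um: float = 0.0
    detector_ssd_mm: float | None = None
    ssd_slack_mm: float = field(default=15.0, compare=False)

    def __post_init__(self) -> None:
        a = self.source_collimator_distance_mm
        b = self.collimator_plane_distance_mm
        s = self.source_size_mm
        w = self.slit_width_um
        for name, v in (("A", a), ("B", b), ("S", s), ("w", w)):
            if not np.isfinite(v):
                raise InvalidGeometryError(f"{name} must be finite, got {v!r}")
        if a <= 0:
            raise InvalidGeometryError(f"source-collimator distance A must be > 0, got {a}")
        if b < 0 or s < 0 or w < 0:
            raise InvalidGeometryError("B, S and w must be non-negative")
        if self.detector_ssd_mm is None:
            object.__setattr__(self, "detector_ssd_mm", a + b)
        else:
            gap = abs(self.detector_ssd_mm - (a + b))
            if gap > self.ssd_slack_mm:
                raise InvalidGeometryError(
                    f"detector SSD {self.detector_ssd_mm} mm differs from A+B={a + b} mm "
                    f"by {gap:.3g} mm (> slack {self.ssd_slack_mm} mm)"
                )
            if gap > 1e-9:
                warnings.warn(
                    f"detector SSD {self.detector_ssd_mm} mm != A+B = {a + b} mm "
                    f"(difference {gap:.3g} mm); SSD kept as stated",
                    stacklevel=3,
                )

    @property
    def magnification(self) -> float:
        """Geometric magnification (A+B)/A of the collimator plane."""
        return (self.source_collimator_distance_mm + self.collimator_plane_distance_mm) / (
            self.source_collimator_distance_mm
        )

    def with_slit_width(self, slit_width_um: float) -> "BeamlineGeometry":
        """Copy of this geometry with a different slit opening (µm)."""
        return replace(self, slit_width_um=slit_width_um)


@dataclass(frozen=True)
class CollimatorSpec:
    """Multi-slit collimator layout and imperfections.

    ``heel_gradient_per_mm`` is the fractional change of per-slit FWHM per mm
    of position across the slit pattern (anode heel effect); 0 disables it.
    ``leakage_fraction`` is the transmission of the closed bulk collimator
    relative to the open field; ``closed_transmission_fraction`` is the
    (higher) residual transmission along a slit line when the slit is driven
    fully shut — the machined slit channel is thinner than the bulk, so the
    slit pattern remains visible even at zero nominal width.
    """

    n_slits: int = 51
    slit_separation_um: float = 400.0
    slit_length_mm: float = 20.0
    leakage_fraction: float = 0.01
    hole_diameter_mm: float = 0.3
    heel_gradient_per_mm: float = 0.0
    closed_transmission_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_slits < 1:
            raise ValueError("n_slits must be >= 1")
        if self.slit_separation_um <= 0:
            raise ValueError("slit separation must be positive")
        if not 0.0 <= self.leakage_fraction < 1.0:
            raise ValueError("leakage_fraction must lie in [0, 1)")
        if not 0.0 <= self.closed_transmission_fraction <= 1.0:
            raise ValueError("closed_transmission_fraction must lie in [0, 1]")
        if self.slit_length_mm <= 0 or self.hole_diameter_mm < 0:
            raise ValueError("slit_length_mm must be > 0 and hole_diameter_mm >= 0")

    def validate_against(self, geom: BeamlineGeometry) -> None:
        """Check the slit pitch exceeds the slit opening of ``geom``."""
        if self.slit_separation_um <= geom.slit_width_um:
            raise ValueError(
                f"slit separation {self.slit_separation_um} µm must exceed "
                f"slit width {geom.slit_width_um} µm"
            )


def projected_beam_width(geom: BeamlineGeometry) -> float:
    """First-order projected beam width L = (B/A + 1)·w + B·S/A, in µm.

    Linear in both the slit width and the source size; equals the base-to-top
    mean of the exact trapezoidal profile and bounds its FWHM from above.
    """
    a_mm = geom.source_collimator_distance_mm
    b_mm = geom.collimator_plane_distance_mm
    return (b_mm / a_mm + 1.0) * geom.slit_width_um + 1000.0 * b_mm * geom.source_size_mm / a_mm


def width_uncertainty(geom: BeamlineGeometry, rel_source_uncertainty: float) -> float:
    """Uncertainty on L (µm) from a relative uncertainty on the source size.

    L is linear in S, so first-order propagation ΔL = B·(rel·S)/A is exact.
    """
    if rel_source_uncertainty < 0:
        raise ValueError("relative uncertainty must be >= 0")
    a_mm = geom.source_collimator_distance_mm
    b_mm = geom.collimator_plane_distance_mm
    return 1000.0 * b_mm * rel_source_uncertainty * geom.source_size_mm / a_mm


def trapezoid_widths(geom: BeamlineGeometry) -> tuple[float, float]:
    """(a, b) in µm: magnified slit width and projected source width."""
    a_mm = geom.source_collimator_distance_mm
    b_mm = geom.collimator_plane_distance_mm
    a = (1.0 + b_mm / a_mm) * geom.slit_width_um
    b = 1000.0 * b_mm * geom.source_size_mm / a_mm
    return a, b


def trapezoid_fwhm(geom: BeamlineGeometry) -> float:
    """FWHM of the exact rect⊗rect profile: max(a, b), in µm."""
    a, b = trapezoid_widths(geom)
    return max(a, b)


def exact_penumbra_profile(
    geom: BeamlineGeometry,
    positions_um: np.ndarray,
    source_model: str = "rect",
) -> np.ndarray:
    """Exact single-slit beam profile at the image plane, peak-normalised to 1.

    With ``source_model="rect"`` (default) both the magnified aperture
    (width ``a``) and the projected source (width ``b``) are uniform windows
    and the profile is their convolution: a symmetric trapezoid with flat top
    ``|a-b|``, base ``a+b`` and FWHM ``max(a, b)``.

    ``source_model="gaussian"`` replaces the projected source by a Gaussian of
    the same FWHM ``b`` (measured microbeam peaks are close to Gaussian); the
    profile is then a difference of error functions.

    Parameters
    ----------
    positions_um
        Positions across the beam, µm, measured from the slit-projection axis.
    """
    x = np.asarray(positions_um, dtype=float)
    a, b = trapezoid_widths(geom)
    if a == 0.0 and b == 0.0:
        raise DegenerateApertureError("both the magnified slit and projected source have zero width")
    if source_model == "rect":
        return _trapezoid(x, a, b)
    if source_model == "gaussian":
        if b == 0.0:
            return _trapezoid(x, a, b)
        sigma = b / GAUSSIAN_FWHM_FACTOR
        if a == 0.0:
            return np.exp(-0.5 * (x / sigma) ** 2)
        s2 = sigma * math.sqrt(2.0)
        prof = 0.5 * (erf((x + a / 2.0) / s2) - erf((x - a / 2.0) / s2))
        return prof / (erf(a / (2.0 * s2)))  # peak value at x = 0
    raise ValueError(f"unknown source_model {source_model!r}")


def _trapezoid(x: np.ndarray, a: float, b: float) -> np.ndarray:
    """rect(a) ⊗ rect(b), peak-normalised; ``a`` or ``b`` may be zero."""
    hi = (a + b) / 2.0
    ramp = min(a, b)
    if ramp == 0.0:
        return (np.abs(x) < hi).astype(float)
    return np.clip((hi - np.abs(x)) / ramp, 0.0, 1.0)


def projected_separation(sep_um: float, d_pattern_mm: float, d_plane_mm: float) -> float:
    """Magnify a centre-to-centre separation from one plane to another (µm).

    Similar triangles from a point projection: a pattern with pitch ``sep_um``
    at distance ``d_pattern_mm`` from the source appears with pitch
    ``sep_um * d_plane_mm / d_pattern_mm`` at distance ``d_plane_mm``.
    """
    if d_pattern_mm <= 0 or d_plane_mm <= 0:
        raise ValueError("plane distances must be positive")
    if d_plane_mm < d_pattern_mm:
        raise ValueError("projection plane must not be upstream of the pattern plane")
    return sep_um * d_plane_mm / d_pattern_mm


def infer_distance_offset(sep_ref_um: float, sep_other_um: float, ssd_ref_mm: float) -> float:
    """Distance offset (mm) of a second measurement plane from separation ratios.

    If the same slit pattern is measured with pitch ``sep_ref_um`` at a
    reference SSD and pitch ``sep_other_um`` elsewhere, the inverse-square /
    similar-triangles first-order estimate of how much *closer to the source*
    the second plane sat is

        Δ = ssd_ref · (sep_ref − sep_other) / sep_ref .

    Positive means closer to the source (smaller magnification).
    """
    if sep_ref_um <= 0 or sep_other_um <= 0:
        raise ValueError("separations must be positive")
    if ssd_ref_mm <= 0:
        raise ValueError("reference SSD must be positive")
    return ssd_ref_mm * (sep_ref_um - sep_other_um) / sep_ref_um


def distance_offset_statistics(
    seps_ref_um: np.ndarray,
    seps_other_um: np.ndarray,
    ssd_ref_mm: float,
) -> tuple[float, float]:
    """Mean and sample standard deviation (ddof=1) of per-row distance offsets.

    Applies :func:`infer_distance_offset` row-wise (e.g. one row per nominal
    slit width) and summarises.  Returns ``(mean_mm, sd_mm)``; the sd is nan
    for a single row.
    """
    ref = np.asarray(seps_ref_um, dtype=float)
    oth = np.asarray(seps_other_um, dtype=float)
    if ref.shape != oth.shape:
        raise ValueError("separation arrays must have matching shapes")
    offsets = np.array(
        [infer_distance_offset(r, o, ssd_ref_mm) for r, o in zip(ref.ravel(), oth.ravel())]
    )
    sd = float(np.std(offsets, ddof=1)) if offsets.size > 1 else float("nan")
    return float(np.mean(offsets)), sd


def round_to_sig_figs(value: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (uncertainty-quoting convention)."""
    if value == 0 or not np.isfinite(value):
        return value
    ndigits = sig - 1 - int(math.floor(math.log10(abs(value))))
    return round(value, ndigits)
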
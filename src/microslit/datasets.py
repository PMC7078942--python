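"""Bundled reference measurements.

``SLIT_SEPARATION_TABLE`` holds published peak-to-peak separations of a
51-slit tungsten microbeam collimator (400 µm nominal pitch) measured at a
source-to-surface distance of 29 cm with three readout systems: a CMOS pixel
detector (50 µm pitch), radiochromic film read on a flatbed scanner
(1400 dpi), and radiochromic film read on an optical microscope (1.29 µm
pixels).  One row per nominal slit width; uncertainties are one sample
standard deviation over the fitted peak spacings.

These values serve as in-package inputs for the distance-offset worked
example: small differences in measured pitch between readout systems reveal
sub-millimetre differences in their distance from the source.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["SLIT_SEPARATION_TABLE", "REFERENCE_SSD_MM", "slit_separation_table"]

#: SSD of the CMOS detector measurement, mm.
REFERENCE_SSD_MM = 290.0

_ROWS = [
    # nominal width, CMOS mean/sd, flatbed mean/sd, microscope mean/sd (µm)
    (25, 513.4, 13.9, 512.0, 11.3, 508.3, 9.9),
    (50, 512.9, 10.1, 511.7, 9.7, 508.9, 9.1),
    (75, 512.6, 9.2, 511.9, 10.1, 508.3, 8.6),
    (100, 512.4, 9.5, 511.8, 9.6, 508.5, 9.8),
]

SLIT_SEPARATION_TABLE = pd.DataFrame(
    _ROWS,
    columns=[
        "nominal_width_um",
        "cmos_um",
        "cmos_sd_um",
        "flatbed_um",
        "flatbed_sd_um",
        "microscope_um",
        "microscope_sd_um",
    ],
)


def slit_separation_table() -> pd.DataFrame:
    """Return a copy of the bundled peak-separation table."""
    return SLIT_SEPARATION_TABLE.copy()
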
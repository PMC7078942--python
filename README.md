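# microslit

Simulation and analysis of multi-slit collimated x-ray **microbeam** fields,
for medical-physics dosimetry work on spatially fractionated radiotherapy
(MRT).  The package targets people characterising microbeam collimators with
pixelated detectors or radiochromic film: it provides a geometric model of
slit projection, a synthetic-data generator with a realistic detector signal
chain, and the full measurement pipeline — profiles, peak fitting, FWHM,
peak separations, peak-to-valley dose ratio (PVDR), heel-effect trends and
modulation-transfer-function (MTF) estimation.

## The model

A finite x-ray source of size *S* sits a distance *A* upstream of a
collimator slit of width *w*; the image plane lies *B* further downstream.
The projected beam width is approximated by

    L = (B/A + 1)·w + B·S/A

which is linear in both *w* and *S*.  The exact profile is the convolution
of the magnified aperture, a uniform window of width *a* = (1 + B/A)·w,
with the projected source, width *b* = B·S/A: a trapezoid with flat top
|a − b|, base a + b and FWHM max(a, b).  At *A* = 212 mm, *B* = 68 mm,
*S* = 0.4 mm the *w* → 0 limit — the smallest resolvable beam FWHM — is
B·S/A = **128.3 µm**, with a ±13 µm uncertainty for a 10% source-size
uncertainty.

A 51-slit collimator (400 µm pitch, slit widths adjustable 0–100 µm)
projected to a 29 cm SSD yields ≈512 µm peak-to-peak separations; comparing
separations measured at nominally identical SSDs inverts, through similar
triangles, into sub-millimetre distance offsets between measurement planes.
The simulator renders such fields onto a 50 µm-pitch CMOS detector (frame
averaging, dark subtraction, Poisson + read noise, saturation) or onto
film-scan samplings with optical blur, including collimator leakage,
drill-hole hotspots at the slit ends and a linear heel-effect FWHM gradient.

## Worked example

```python
import numpy as np
import microslit as ms
from microslit import simulator as sim, frames as fr, profiles as pr

geom = ms.BeamlineGeometry(212, 68, 0.4, slit_width_um=50, detector_ssd_mm=290)
coll = ms.CollimatorSpec()                      # 51 slits, 400 µm pitch
det = sim.DetectorModel(n_rows=620, n_cols=160)  # 50 µm pixels

field = sim.build_field(geom, coll, peak_dose_rate=60.0, projected_separation_um=512.0)
frames = sim.render_detector_frames(field, det, n_frames=5, seed=1)
darks = sim.render_dark_frames(det, n_frames=5, seed=2)
corrected = fr.subtract_dark(fr.average_frames(frames), fr.average_frames(darks))
dose = fr.calibrate(corrected, 1.0 / det.counts_per_frame_per_mGy_min)

an = pr.analyze_field(dose, coll, pr.AnalysisConfig(expected_separation_um=512.0,
                                                    band=(30, 130)))
print(f"peaks found:        {len(an.peaks)}")
print(f"separation:         {an.separation_mean_um:.1f} +/- {an.separation_sd_um:.1f} um")
print(f"FWHM (crossing):    {np.nanmean(an.fwhm_crossing_um):.1f} um")
print(f"mean PVDR:          {an.pvdr_mean:.1f}")
```

prints

```
peaks found:        51
separation:         512.0 +/- 0.4 um
FWHM (crossing):    129.4 um
mean PVDR:          56.1
```

All 51 microbeams are recovered at the constructed 512 µm pitch; the
measured FWHM at *w* = 50 µm is the geometric penumbra width 128.3 µm
(plus ~1% sampling broadening) because here the source penumbra, not the
slit opening, limits the beam width; the PVDR reflects the 50%-open slit
over the 1% collimator leakage floor.

A `microslit` CLI wraps the same chain: `simulate`, `process`, `analyze`,
`mtf`, `geometry` and `pipeline` subcommands take a validated JSON
configuration (see `microslit.io.RunConfig`) and produce TIFF frames,
per-peak CSV tables, summary JSON and MTF curves.

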
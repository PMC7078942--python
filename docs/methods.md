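# Methods

## Geometric model

The slit projection model treats the collimator as a single infinitely thin
layer.  With source–collimator distance *A* (mm), collimator–image-plane
distance *B* (mm), source size *S* (mm) and slit width *w* (µm), the image
of one slit is the convolution of two uniform windows: the magnified
aperture, width *a* = (1 + B/A)·w, and the projected source,
width *b* = B·S/A (both in µm).  The exact profile is therefore a trapezoid
(flat top |a − b|, base a + b, FWHM max(a, b)); the first-order width
L = a + b bounds the FWHM from above, with equality when either window
vanishes.  Because L is linear in *S*, the uncertainty from a relative
source-size uncertainty r is exactly B·(r·S)/A; quoted values round it to
two significant figures per the usual uncertainty-quoting convention.
A Gaussian-source variant (same FWHM *b*) is available because measured
microbeam peaks are close to Gaussian; the uniform model remains the
default since it is the one the trapezoid algebra is built on.

The stated distances of the reference beamline do not close exactly
(A + B = 280 mm against a stated SSD of 290 mm; the collimator is 7 mm
thick and the plane within it that defines *A* and *B* is not knowable).
`BeamlineGeometry` therefore stores the SSD independently of A + B and
warns — rather than errors — when they disagree by up to a configurable
slack (default 15 mm).  For the same reason the projected slit-pattern
pitch is a free parameter of `build_field`: the bundled reference
measurements give ≈512 µm at 290 mm SSD, which back-solves to an effective
pattern plane of ≈226.6 mm, between the collimator entrance and the
detector; naive projection from the entrance plane would give ≈528 µm.

Distance offsets between measurement planes are inferred from pitch ratios
by the first-order similar-triangles relation
Δ = SSD·(sep_ref − sep_other)/sep_ref, applied per nominal slit width and
summarised as mean ± sample standard deviation (n − 1).

## Synthetic fields and images

`build_field` composes: a uniform leakage floor (`leakage_fraction`, default
0.01 — no published transmission value exists for the closed collimator, so
this is a free parameter); 51 trapezoid peaks at the projected pitch with
per-slit amplitude min(a, b)/b (partial source occlusion), floored at
`closed_transmission_fraction` (default 0.05) so the slit-line pattern stays
detectable with the collimator driven fully shut, as observed in leakage
fields; drill-hole disks (0.3 mm diameter) at both slit ends rendered at
open-field intensity — their exact positions along the slits are not
documented, so they sit symmetrically at the ends; and a linear heel-effect
gradient that scales each slit's profile width by (1 + g·y_mm), truncated
below at 0.1× nominal.  This multiplicative width gradient matches the
monotone FWHM-versus-position trend seen across such fields without
asserting its physical cause.  The field is normalised so the central
slit's peak equals the requested peak dose rate (default 60 mGy/min, the
order of magnitude of the reference irradiator after collimation).

Detector frames integrate the field over each 50 µm pixel aperture with
8× per-side supersampling (configurable, minimum 4), convert dose to counts
(gain 10⁵ counts/mGy, 28 ms integration), then add Poisson shot noise on
the signal, a Gaussian dark offset (mean 100, σ 2 counts), Gaussian read
noise (σ 5 counts), integer quantisation and saturation clipping at 65535.
All randomness derives from one explicit seed via `SeedSequence` spawning,
so frame *k* is bit-reproducible regardless of how many frames are
requested.  Film scans are modelled as a linear dose map with a Gaussian
optical blur standing in for the scanner MTF plus multiplicative noise;
real radiochromic-film saturation and triple-channel behaviour are out of
scope, so simulated "film" differs from the simulated detector only in
pitch, blur and noise model.  Axis convention everywhere: the peak pattern
varies along rows; slits run along columns.

What the generator does *not* emulate — scatter, spectral/beam-hardening
effects, rolling-shutter readout, film-scan lateral artefacts, the
three-layer collimator — bounds what passing tests show: they validate the
measurement chain against known geometric ground truth, not against the
full physics of a real beamline.

## Measurement chain

Profiles are band means across a stated lane range, positions at sample
centres (i + 0.5)·pitch.  Peaks are local maxima with prominence ≥ 10% of
the profile range, thinned greedily so no two survive within half the
expected separation.  Each peak is fitted with baseline + Gaussian by
bounded least squares on a window of half-width 0.45× the expected
separation (keeps neighbours out); initialisation is baseline = window
minimum, amplitude = range, centre = baseline-subtracted centroid,
σ = RMS width; non-convergence or a σ pinned at its bounds returns a
flagged fit.

Two FWHM estimators are reported per peak.  The Gaussian 2√(2 ln 2)·σ is
best for centres and amplitudes but biased on trapezoids: fitted to the
near-triangular w = 100 µm profile it overshoots the true FWHM by ~4.6%
(pinned as a regression value), and fitted to the w → 0 rectangle it
*undershoots* by ~13%.  The direct half-maximum crossing (linear
interpolation, floor = mean of the lowest quartile of window samples) is
model-free and tracks the trapezoid truth to ~1–2% whenever the flat top
exceeds the sample pitch; it is therefore the estimator used for the
FWHM-versus-position (heel) trend and the slit-width sweep, while the
Gaussian form remains the fitted peak model.

Valleys are the mean of the centred 20% of samples in each gap (no
published definition of the valley region exists; 20% keeps clear of both
penumbrae).  PVDR uses the fitted peak dose (amplitude + baseline) over the
mean of the adjacent valley levels — peak dose rather than amplitude-only
because PVDR is conventionally compared against absolute peak/valley dose
plots; amplitude-only is one field away for users who prefer it.  Boundary
peaks use their single adjacent valley; a non-positive valley flags the
ratio as undefined (nan).

The slit-width sweep fits FWHM(w) by ordinary least squares for
w ≥ 20 µm — below that the shrinking aperture is dominated by the source
penumbra and the points leave the line — and reports the intercept ± its
standard error as the minimum resolvable FWHM, alongside the geometric
overlay line (slope 1 + B/A, intercept B·S/A).  The packaged sweep
scenario runs 0–100 µm in 5 µm steps at film-scan sampling (18.1 µm pitch,
20 µm blur, 0.5% noise, seed-pinned): at 50 µm detector pitch the
aperture clips the near-triangular tips of the widest slits and drags the
extrapolated intercept several percent low, an estimator artefact the
finer sampling avoids.

Peak indices are 1-based by rank when all slits are found (the central
slit of 51 is index 26, and indexing is invariant under profile reversal);
otherwise by rounding offsets from the median-position peak to the nearest
multiple of the expected separation.  Reported centres are re-expressed
relative to the central peak.  Separations are consecutive differences of
fitted centres, summarised as mean ± sample sd (n − 1).

## MTF estimation

Slanted edge: per-row 50% crossings are fitted with a line to refine the
edge angle (rejected if axis-aligned — no sub-pixel phase diversity — if
more than 15° from the estimate, or if it drifts > 1° across the ROI); all
pixels are projected onto the edge normal, binned at 0.1 pixel, tails
monotonised toward the flat-field asymptotes.  The LSF is the centred
finite difference of the ESF, Hann-windowed; the MTF is the normalised
|DFT|, reported to the pixel Nyquist frequency in lp/mm from the physical
pitch.  The known transfer functions of the 0.1-pixel binning (rect
average) and of the centred-difference operator are divided out by default;
without this correction the curve reads ~1.6% low at Nyquist for purely
numerical reasons.  So configured, the estimate matches the closed-form
|sinc| of a square pixel aperture to better than 0.1% and a Gaussian-blur
Fourier pair to ~0.5%.

Bar patterns report the square-wave modulation (max − min)/(max + min) of
the band-averaged profile per block, at frequency 500/line-width lp/mm,
normalised by the lowest-frequency block.  No Coltman conversion to
sine-wave MTF is applied; consequently bar modulation bounds the
sine-wave MTF from above (by up to 4/π where harmonics vanish), which the
tests check directionally and, on a mild-blur system, within 0.1 absolute.

## Numerical and scope choices

* Sample sd everywhere uses ddof = 1; fit convergence tolerance 1e-8
  relative on parameters.
* Dark subtraction clips negative residuals to zero (flagged) to keep dose
  maps physical; calibration is single-point linear (operation in the
  pixels' linear response region is assumed, no per-pixel flat field).
* Problem sizes in the packaged scenarios (620×160-pixel detector region,
  70-lane film scans, 5 frames per acquisition, 1000 frames for the noise
  model check) are chosen so every scenario runs in seconds while leaving
  estimator noise well inside the tolerances being tested.
* Degenerate inputs: zero-width aperture *and* source is an error; a flat
  profile yields an empty peak list, not an error; fewer than two peaks is
  an analysis error; images without unit/pitch sidecars are refused.

## Known limitations

No scatter or spectral modelling means simulated PVDRs are substantially
higher than measured ones for the same leakage (real valleys fill in with
scattered dose); the heel gradient is phenomenological; bar-pattern
modulation is aliased for line widths below the sample pitch; the Gaussian
peak model's FWHM bias on trapezoids is quantified rather than corrected.
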
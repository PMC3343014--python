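# Methods

## Scope and model

`sptpalmsim` simulates the measurement chain of single-molecule tracking
PALM in two dimensions: generative localization scatter → per-step random
walks (free or confined) → photon emission and pixel accumulation →
elliptical Gaussian fitting with a calculated precision → multi-frame
tracks and D_eff estimation → density maps and FWHM morphology readouts.
It contains no microscope-hardware, photophysics (blinking/bleaching), or
3D components, and it analyses no real image data; optionally it ingests
externally produced localization tables (CSV with `x_nm, y_nm[, detected]`)
for the morphology readouts.

## Localization scatter convention

Localizations (and emitted photons) scatter around their true position with
radial magnitude |Normal(0, σ)| and uniform angle — a **half-normal radial**
law, *not* an isotropic bivariate normal. Consequences used throughout:

- mean radial distance = σ·√(2/π) ≈ 0.798 σ, with sd ≈ 0.60 σ;
- mean squared radial distance = σ² (so per-axis variance is σ²/2);
- two independent draws are ⟨d⟩ ≈ 1.20 σ apart (RMS √2 σ);
- the 2D density carries an integrable 1/r cusp at the center.

The cusp matters downstream: the pixelated image of a *fixed* molecule is
sharper than a 250 nm Gaussian, so the least-squares Gaussian fit converges
to a fitted width of ~60–70 nm and a calculated precision of ~3.8 nm at
1000 photons — below the 7.96 nm the closed-form precision formula gives
when evaluated at the nominal PSF width. Both numbers are self-consistent
readouts of the same generator; the closed form at (s=250, a=100, N=1000)
remains the nominal-PSF reference value.

## Random walks

N_steps = round(4Dt/r²) with D in µm²/s (1 µm²/s = 1000 nm²/ms), t in ms,
r = 1 nm. Two step conventions:

- **as-stated** (default): each axis displaces Uniform(−√2 r, +√2 r) per
  step. Per-step E[dx²+dy²] = 4r²/3, so the free-walk MSD is (4/3)·4Dt.
  Mean step length is ≈1.08 r, not exactly r; we keep the literal rule and
  document the discrepancy rather than reinterpreting it.
- **calibrated**: the uniform bound is scaled by √3/2 so E[step²] = r²
  exactly and MSD = 4Dt; used when quantitative D recovery matters.

Confinement redraws the entire step until the proposed position is inside
the region (no reflection), with a 10⁴-proposal cap per step that raises on
pathological geometry. Regions are unions of axis-aligned rectangles: a
`width × length` rectangle with origin at its lower-left corner, and a
spine composite (500 nm square head; 100 × 1000 nm neck; 500 × 1500 nm
dendrite; neck centred on both midlines). Uniform region sampling is
rejection from the bounding box. The sequential confined loop is a numba
kernel (~40 ns/step), seeded from the injected Generator so every walk
remains reproducible.

## Image formation

Each of the N_steps+1 trajectory positions emits a photon with probability
p = n_photons/n_positions (capped at 1), realized as a Binomial draw plus a
uniform subset of step indices — distributionally identical to per-step
Bernoulli thinning, vectorized. A single-position (fixed) molecule emits
exactly n_photons. Photon landing positions add half-normal radial PSF
scatter with s = 250 nm. Photons are binned on a = 100 nm pixels
(`floor((pos − origin)/a)`), default grid 15 × 15 pixels centred on the
trajectory start (1.5 µm, = 6s across); photons off-grid are dropped but
tallied so counts + overflow always equals the emitted number. Background
noise (default 0, as localization failures under noise are not the object
of study) is additive Gaussian per pixel, clipped at zero.

## Fitting and precision

Peaks are 8-neighborhood local maxima at or above a low threshold (default
1 count); only the brightest peak is fit, since fast molecules over long
exposures frequently fragment into several peaks. The fit is unweighted
least squares of A·exp(−(x−x0)²/2sx² − (y−y0)²/2sy²) + offset over a 9 × 9
pixel window (clipped to the grid, ≥6 non-zero pixels required),
Levenberg–Marquardt with an analytic Jacobian, tolerances 1e-8, max 200
function evaluations; non-convergence or a center escaping the window is
reported (`converged=False`), never retried. N_fit is the window sum minus
offset·area, floored at 1. The calculated precision applies the pixelated
detector formula at the fitted geometric-mean width √(sx·sy), so blur that
widens the apparent spot degrades the calculated precision — the coupling
under study. The empirical error of a moving molecule is measured against
the mean true emission position of its photons (the centroid an unbiased
fitter estimates). Rare (<1%) gross mislocalizations — the misspecified
Gaussian latching a pixel off — give the error distribution heavy tails;
tests that compare empirical spread with the calculated precision use a
MAD-based robust sd (which agrees within a few percent) and bound the
outlier fraction separately.

## Tracks and D_eff

Frames are continuous in time: diffuse and emit for t_e, localize, then
diffuse dark for frame_interval − t_e. D_eff = ⟨R²⟩/(4Δt) over consecutive
detected pairs, Δt being the frame interval (time between localized
positions, not the exposure); ⟨R⟩²/(4Δt) is available as a literal
"mean distance" alternative. The immobile-molecule limit has the closed
form D_eff = σ_loc²/(2Δt) (E[R²] = 2σ_loc² for independent scatter draws),
exposed via `scatter_track` as an analytic oracle that bypasses imaging.
Full per-step trajectories are retained only on request
(`keep_trajectories=True`); long-exposure 1000-frame tracks would otherwise
hold ~10⁸ positions. Per-frame end positions and emission centroids are
always kept.

## Morphology readouts

Transverse density profiles use 10 nm bins by default (5–25 nm is a tested
insensitivity range), aligned to the region bounding box and extended
outward in whole bins so no localization is dropped. FWHM takes the raw
peak bin as the maximum (optional 3-bin moving average for sparse
profiles), halves it, and interpolates the outermost crossings linearly
between bin centers; a profile that never falls below half clamps at its
edge. For a symmetric localization-error kernel the convolved profile of a
uniform strip crosses half-maximum exactly at the true edges, so the
asymptotic FWHM equals the strip width exactly; the raw-peak half-level is
biased slightly high by sampling noise on the peak bin, which pulls the
finite-sample FWHM ~0.5–1.5 nm *below* the true width at t_e = 0 (measured
99.5 nm for a 100 nm strip at 4000 molecules). Width comparisons should
therefore be made against the convolution oracle (same estimator applied
to uniform positions plus the error kernel), as the tests do, rather than
against the bare geometric width.

## Campaigns and reproducibility

Every stochastic operation takes an explicit `numpy.random.Generator`.
Campaign runners spawn one independent substream per grid cell from a
single `SeedSequence`, so any cell can be regenerated alone; outputs are
tidy CSVs whose `#` header lines record all parameters and the seed, plus
a JSON manifest and a text log. Same config + seed ⇒ byte-identical CSVs.

Default campaign sizes are scaled for interactive use (10⁴ scatter pairs,
10³ molecules, 100-frame tracks); the deeper end-to-end checks in the test
suite use 10⁵ pairs, 1000–4000 molecules, and 7 × 1000-frame tracks —
sizes at which every asserted trend clears three standard errors.

## What the generator does and does not emulate

The synthetic data reproduce radially half-normal localization scatter,
uniform per-step walks with rejection confinement, binomially thinned
photon emission, Gaussian PSF scatter, and noiseless pixel accumulation.
They do **not** emulate EM-CCD gain or readout noise, Poisson backgrounds,
fluorophore blinking/bleaching, anisotropic or astigmatic PSFs, drift, or
3D motion projected to 2D. Passing tests therefore validate the artifact
mechanisms (distance/angle bias, blur-degraded precision, inward bias,
D_eff inversion) — not the absolute precision attainable on any particular
microscope.

## Known limitations

- The Gaussian fit is misspecified for the cusped fixed-molecule image;
  fitted widths are convention-dependent and should be compared within
  this generator, not across packages.
- Rejection confinement slightly distorts the step distribution near
  boundaries (as any non-reflecting rule does); this is the stated rule,
  not an approximation error.
- The as-stated step mode overshoots the nominal MSD by 4/3; use the
  calibrated mode for quantitative free-diffusion recovery.
- D_eff estimation uses consecutive-frame jumps only; no MSD-vs-lag
  fitting or confinement-model fitting is provided.
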
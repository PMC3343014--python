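# sptpalmsim

Monte Carlo simulation of single-molecule tracking PALM (photoactivated
localization microscopy): how finite localization precision and molecular
motion during camera exposure distort measured distances, angles, diffusion
coefficients, and the apparent morphology of small cellular structures such
as dendritic spines and filopodia.

## Who this is for

Single-molecule microscopists designing sptPALM experiments — choosing
integration (excitation) times, photon budgets, and frame rates — and anyone
interpreting localization-based reconstructions of bounded structures at the
50–500 nm scale, where motion artifacts rival or exceed the localization
precision itself.

## The model

**Localization scatter.** A molecule localized with precision σ_loc appears
at radial distance |Normal(0, σ_loc)| from its true position, at a uniform
angle — a half-normal radial law with mean 0.80 σ_loc. Two localizations of
the same *fixed* molecule are therefore ~1.2 σ_loc apart on average: the
floor of apparent motion in any tracking experiment.

**Diffusion.** Random walks take N_steps = 4Dt/r² per-step displacements
(r = 1 nm), each axis Uniform(−√2 r, √2 r); walks confined to a bounded
region redraw any step that would exit. An exactly calibrated step mode
(MSD = 4Dt) is available alongside this literal convention.

**Image formation.** During one exposure the molecule emits ~N photons at
evenly distributed times along its path; each lands with half-normal radial
PSF scatter (s = 250 nm) and is accumulated on 100 nm pixels. Motion smears
the photon cloud, dimming the brightest pixel and widening the apparent spot.

**Localization and precision.** The brightest peak is fit with an elliptical
2D Gaussian (least squares); the calculated precision follows the
pixelated-detector formula

σ² = (s² + a²/12)/N + 8π s⁴ b²/(a² N²)

evaluated at the *fitted* width s = √(sx·sy), which couples motion blur into
the precision estimate.

**Tracking.** D_eff = ⟨R²⟩/4Δt over consecutive localizations. In bounded
regions each localization is the centroid of the path covered during the
exposure, so localizations collapse inward: structures appear thinner
(smaller FWHM of the transverse density profile) and — counterintuitively —
*faster* molecules can measure *slower* than slow ones.

## Worked example

Distance and angle accuracy as a function of true separation (in units of
σ_loc), 100,000 pairs:

```bash
$ sptpalmsim loc-error --sigma 1.0 --separations 0:3:1 --n-pairs 100000 --seed 7 --out stats.csv
$ cat stats.csv
# tool=loc-error
# sigma=1.0
# n_pairs=100000
# seed=7
separation,mean_dist,sd_dist,frac_pi4,angle_sd
0.0,1.197840438027667,0.7426933398091138,0.2524,1.8100409595453355
1.0,1.5299128783472569,0.8077630324130722,0.62016,1.0690497969752055
2.0,2.2696199712016782,0.9117166799264667,0.85692,0.6031076461038772
3.0,3.1742489837453025,0.9570933142901336,0.95822,0.37209059130119254
```

A fixed molecule (separation 0) shows 1.20 σ of pure-error apparent motion
and isotropic directions (25% of vectors within π/4 of any reference). At a
true displacement of 1 σ the measured distance is still biased high
(1.53 σ) but 62% of vectors already point within π/4 of the true direction;
at 2 σ, 86%.

The confined-diffusion inversion, in a 100 nm box with 50 ms continuous
exposure (5 molecules × 200 frames each):

```python
import numpy as np
from sptpalmsim import Rectangle, make_track, estimate_deff

for D in (0.1, 1.0):
    rng = np.random.default_rng(42)
    deffs = [estimate_deff(make_track(D, Rectangle(100, 100), 50.0, 50.0, 200, rng=rng))
             for _ in range(5)]
    print(f"D={D}: measured D_eff = {np.mean(deffs):.4f} um^2/s")
```

```
D=0.1: measured D_eff = 0.0044 um^2/s
D=1.0: measured D_eff = 0.0011 um^2/s
```

Both are far below truth, and the 10× faster molecule measures 4× *slower*:
over 50 ms it explores the whole box, so every localization lands near the
box center. Short excitation pulses (t_e ~ 1 ms) remove the inversion.

Figure-level campaigns (parameter sweeps with tidy CSV output, per-cell
reproducible seeding) run via `sptpalmsim run --campaign fig3 --seed 42
--out results/`.

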
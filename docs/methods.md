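# Methods

`rifdyn` simulates and analyses live-cell time-lapse recordings of
radiation-induced DNA-repair foci (RIF) — GFP-tagged NBS1 accumulations at
DNA double-strand breaks — in interphase nuclei exposed to densely ionising
alpha particles and/or sparsely ionising gamma rays, applied alone or
sequentially in either order. This note documents the generative model, the
measurement conventions, the numerical choices, and the limits of what the
synthetic data can demonstrate.

## Timeline conventions

Time zero is the start of irradiation. Recording begins after the exposure
itself plus ~4 min of live-cell chamber assembly, so the first recorded
frame of condition *c* lies at `t = offset(c) + 1` min with 1-based frame
indices and 1 frame/min:

| condition | offset (min) | first frame (min) |
|---|---|---|
| control | 4.0 | 5 |
| gamma (2.0 Gy) | 9.6 | ~11 |
| alpha (1.7 Gy) | 11.5 | ~13 |
| mixed, both orders (0.83 Gy α + 1.02 Gy γ) | 15.0 | 16 |

The mixed offset uses the rounded ~11-min total exposure so the first mixed
frame lands on minute 16. Recordings run 300 frames at 60 s.

## Generative model (module `simulate`)

**Focus counts and placement.** Per-nucleus focus counts at the first
recorded frame are Poisson with condition means 1.0 (control), 17.1 (α),
30.9 (γ), 28.3 (α→γ) and 25.2 (γ→α). Gamma-like foci are uniform inside the
elliptical nucleus (default semi-axes 6×4 µm, ±8% jitter, random
orientation). Alpha-like foci lie along straight traversal chords: a
Poisson number of chords, each carrying a Poisson(3) number of collinear
foci at 1.2 µm mean along-chord spacing (evenly compressed when a chord is
shorter than the run). For the sequential exposures the two components are
superposed with weights equal to the dose fractions (0.449 α / 0.551 γ) and
keep their subpopulation labels. Foci are born exactly at the first
recorded frame; for exponential lifetimes this is equivalent, by
memorylessness, to earlier birth conditioned on survival to recording.

**Decay.** Lifetimes are exponential per subpopulation, a fast "simple
damage" and a slow "complex damage" class. The decay constants are not
reported quantities; they were calibrated once so the expected count
`M·Σ wᵢ·exp(−λᵢ t)` after ~300 min of recording matches the observed
end-of-observation means (γ 9.1, α 1.1, α→γ 11.9, γ→α 6.4 foci/nucleus):

| condition | subpopulations (weight, λ per min) |
|---|---|
| control | background (1.0, 0.02) |
| gamma | simple (0.8, 0.006), complex (0.2, 0.0005) |
| alpha | simple (0.5, 0.03), complex (0.5, 0.007) |
| α→γ | γ-simple (0.551, 0.01), α-complex (0.449, 0.0006) |
| γ→α | γ-simple (0.551, 0.012), α-complex (0.449, 0.002) |

A per-nucleus `birth_rate_per_min` for late background foci exists but the
presets keep it at 0: within the 5-h window decay dominates, and a clean
start-of-recording mean gives an exact oracle for count-recovery tests.

**Motion.** Each focus performs an independent stationary per-axis
Ornstein–Uhlenbeck (OU) walk with relaxation rate `θ = 2·d·D_c/r_c²`
(d = 2) and stationary per-axis standard deviation `r_c/2`, advanced with
the exact discrete-time transition (no Euler error). This is the unique
Gaussian Markov process whose ensemble MSD (reference = first frame, d = 2)
equals the confined-subdiffusion model

    MSD(Δt) = r_c² · (1 − exp(−2·d·D_c·Δt / r_c²)),

so fitting that model to simulated data is a true inverse problem. Motion
presets per condition are the live-cell fit values: γ→α (349.0 nm²/s,
1014 nm), α (242.1, 980.5), α→γ (240.8, 897.0), γ (206.0, 961.4); control
foci use the γ values. The whole nucleus additionally performs a
random-walk drift (20 nm rms/frame) that carries the foci with it.

**Imaging.** Frames are 256×256 px at 100 nm/px, 16-bit: a soft-edged
elliptical nucleus (interior 400 counts on a 100-count camera floor) plus
one 2-D Gaussian per live focus, then Poisson shot noise and Gaussian read
noise (sd 10). Spot presets are near the diffraction limit of widefield GFP
imaging: amplitude 350±50 counts and σ 78±6 nm for dispersed foci, 550±80
and 105±10 nm for clustered foci. Rendered spot size is deliberately *not*
derived from the measured focus-area scale (~0.2–0.5 µm² half-max area):
at ~31 foci per 75 µm² nucleus, spots that large would merge several foci
per nucleus and no detector could recover the counts. Ground-truth tables
therefore carry a separate per-focus `area_um2` drawn from the
per-subpopulation normal presets (early window: α 0.513±0.045, γ
0.219±0.035, α→γ 0.348±0.052, γ→α 0.220±0.025 µm²; late-window parameters
on the complex subpopulations), which is what the area-kinetics machinery
consumes.

## Detection (module `detect`)

Nucleus segmentation: Otsu threshold on a Gaussian-smoothed frame (σ 2 px),
largest connected component, holes filled; the centre of mass (COM) is the
intensity-weighted centroid and the off-focus background is the in-mask
median. Focus detection: scale-normalised Laplacian-of-Gaussian maxima over
scales (0.6, 0.9, 1.3, 1.9) px, thresholded at `median + k·MAD` of the
in-mask response with the MAD scaled by 1.4826 so `k` (default 5) reads as
robust sigma units; an unscaled MAD at k=5 (~3.4σ) would contribute false
positives comparable to the entire control-condition focus count. Peaks in
a 2-px rim outside the mask are kept only if the raw pixel outshines the
nuclear background (a focus sitting on the envelope). Overlapping peaks
within one spot sigma keep the stronger. Each focus region is the connected
set of pixels above half the peak's background-subtracted height — the
package's operational definition of focus area — and focus intensity is the
background-subtracted sum over that region (the raw sum is also emitted,
since it is not recorded whether the original analysis subtracted
background before forming intensity ratios). The relative intensity of the
foci in a nucleus is `I = I_focus / (I_nucleus − I_focus)`, i.e. total
focus intensity over off-focus nuclear intensity.

Detector scales, spot presets and threshold were fixed once against the
simulator's ground truth: ≥95% frame-1 recall at ≤0.05 false positives per
nucleus across conditions and seeds. The residual misses are pairs of foci
within ~250 nm, which are optically one spot for any detector at this pixel
size; consequently the detected mean count per nucleus runs ~2–5% below the
generative mean (largest for the chord-clustered alpha geometry).

## Tracking (module `track`)

Positions are drift-corrected by subtracting the per-frame nucleus COM.
Linking is greedy nearest-neighbour, accepting links in order of increasing
displacement with a hard bound of 1200 nm per link (≳3× the rms frame
displacement of the most mobile condition, with headroom for localisation
error). A track may bridge up to 5 missing frames: dim foci near the
detection threshold and transiently blended neighbours produce serially
correlated outages of several frames, while the OU position decorrelation
time `r_c²/(4·D_c)` (~19 frames at the measured mobility) keeps the last
observed position a valid association reference over such gaps. Tracks
shorter than 3 observations are excluded from mobility analysis. A
detection continues at most one track; identity through sub-resolution
encounters is ill-posed for any linker, so track-recovery guarantees are
stated for foci that never approach a co-live neighbour within 400 nm
(~96% of such tracks are recovered with ≥80% of their observed frames in
one track under the gamma preset).

## Kinetics (module `kinetics`)

Focus frequency is the total number of registered foci divided by the
number of imaged nuclei per time point, with the SEM taken across nuclei
(nuclei with zero foci included). The additivity prediction for the mixed
exposures is not uniquely determined by the source material; it is
implemented as control plus dose-fraction-weighted excesses,

    predicted(t) = c(t) + (0.83/1.7)·[α(t) − c(t)] + (1.02/2.0)·[γ(t) − c(t)],

with SEMs propagated in quadrature under the same weights. With the printed
start-of-recording means this yields 24.1 foci/nucleus, close to but not
exactly the published predicted value (23.9), whose derivation is unstated;
the dose pairs are arguments, not constants.

Decay/rise rates come from OLS lines `y = a·t + b` over stated windows
(e.g. the first 90 min of decay). Long-horizon shape is captured by
polynomial fits — order 8 for mean area, order 6 for total intensity — on a
time axis affinely mapped to [−1, 1] (a pure reparameterisation; raw
minutes at these orders are numerically hostile). Windowed focus-area
distributions (0–99 and 100–300 min) are summarised by maximum-likelihood
normal fits on the raw per-focus areas, i.e. sample mean and sd, avoiding
any histogram-binning choice.

## Mobility (module `mobility`)

The ensemble MSD uses each track's first observed, drift-corrected position
as its reference; squared displacements are averaged across tracks per lag
(ensemble, not time, averaging — the literal reading of the displacement
definition), and lags supported by fewer than 10 tracks are dropped. The
confined-subdiffusion model is fitted by weighted nonlinear least squares
(weights 1/SEM² when available), initial guesses `r_c⁰ = √max(MSD)` and
`D_c⁰` from the first-lag secant slope over 2d, bounds `D_c ≥ 0, r_c > 0`,
standard errors from the Jacobian covariance, and up to 5 seeded jittered
restarts on failure. A fitted radius with `r_c² > 10·max(MSD)` (no plateau
inside the window, e.g. free diffusion) is flagged `unconstrained`.
Conditions are ranked by the product `D_c·r_c/1000`, reported both rounded
and exact. Pooled-curve fitting is the default; per-nucleus fitting can be
had by filtering the track table before `compute_msd`.

## Statistics (module `stats`)

One-way ANOVA with Tukey's HSD for across-treatment comparisons of focus
area and intensity; the classical equal-variance two-sample t-test for
early-versus-late area windows (Welch available by flag, since the variance
assumption of the original analysis is unstated); and a slope-comparison
t-test `t = (a₁−a₂)/√(SE₁²+SE₂²)` with Welch–Satterthwaite degrees of
freedom built from the two slope variances (the original df rule is also
unstated; both choices are switchable). All-identical data return F = 0,
p = 1 rather than an error.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analysis assumes:
Poisson counts with condition means, biphasic exponential decay, normal
area distributions per window, exact confined-OU motion, drift, and
camera noise. It does not model photobleaching or phototoxicity,
cell-cycle structure, focus merging/splitting or late heterochromatic
focus birth, 3-D structure (traversal chords are planar), or spatial
correlation between damage and chromatin state. Green tests therefore
demonstrate that the pipeline correctly inverts this generative model at
realistic noise levels — not that it would be unbiased on real movies,
where the unmodelled effects above (and the instrument's own detector)
set additional limits. Detected counts undercount the generative truth by
the optical-coincidence rate (~2–5%), which is a property the real
experiment shares, not an artifact of the implementation.

## Problem sizes

Default analyses run desk-scale: mobility parameter recovery uses 10⁴
simulated tracks of 300 frames; count recovery renders 100–200 single-frame
nuclei per condition; the test suite uses a 3-nucleus, 40-frame rendered
movie for end-to-end detection/tracking checks and 10⁴ replicates for
statistical calibration.
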
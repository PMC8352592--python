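# Methods

`chromokin` quantifies chromatin-protein dynamics and chromosome
condensation from live-cell confocal imaging of *Drosophila* polytene
nuclei: FRAP/FLIP-FRAP kinetics of chromatin remodelers and histones,
histone-fluorescence-based condensation, fiber-model compaction, and
clustering/colocalization statistics. Because raw microscopy for such
experiments is rarely redistributable, the package ships forward models
(synthetic generators) for every input it analyzes; all validation is
built on the generator/fitter round trip.

## FRAP model and normalization

A FRAP acquisition records `n_pre` pre-bleach frames, an instantaneous
bleach that removes a fraction `bleach_depth` of the ROI signal, and
`n_post` recovery frames. The first post-bleach frame defines t = 0.
Defaults follow two common protocols: 20 pre / 200 post frames at 70 ms
(cultured S2 cells) and 10 pre / 250 post frames at 648 ms (salivary
glands).

Raw traces carry three channels: bleached-ROI mean, whole-nucleus mean
and background. Analysis applies, in order:

1. **Background correction** — subtract the background channel, floor
   at zero (floored samples are logged).
2. **Double normalization** —
   `I_dn(t) = [roi(t)/mean(roi_pre)] / [whole(t)/mean(whole_pre)]`.
   Dividing by the whole-nucleus trace cancels acquisition
   (observational) photobleaching; the generators can inject a linear
   whole-cell decay to exercise this correction, and it is off by
   default.
3. **Full-scale normalization** —
   `F(t) = (I_dn(t) − I_dn(t0)) / (1 − I_dn(t0))`, pinning the
   pre-bleach mean to 1 and the first post-bleach frame to exactly 0.
   `I_dn(t0) ≥ 1` means no bleach happened and raises an error.

The recovery is fitted with the empirical double exponential

    F(t) = a (1 − e^{−k1 t}) + b (1 − e^{−k2 t}),   k1 ≥ k2 ≥ 0,

whose plateau `a + b` is the mobile fraction and whose half-time t½
solves `F(t½) = (a+b)/2` (bracketed Brent root-finding; closed form when
one component vanishes). This is an empirical exchange model, not a
reaction-diffusion model: it summarizes binding turnover at a locus and
deliberately does not resolve diffusion within the bleach strip.

Fitting uses bounded trust-region least squares over all post-bleach
frames. Initialization follows the curve shape (k1 from the time to
half the late-quartile plateau, k2 = k1/10, amplitudes split evenly)
with five jittered restarts from a fixed internal seed; the lowest-SSE
solution wins. Amplitudes are bounded at 1.2 — the mobile fraction is a
physical fraction, and the slack absorbs noise while preventing the
runaway plateau/vanishing-rate degeneracy of short acquisition windows.
If the two rates agree within 0.1 % or an amplitude falls below 1e-3
the model is refit as a single exponential (the split is
unidentifiable). The fitted mobile fraction is clipped to [0, 1] with
the raw value retained. The fitted plateau is the headline mobile
fraction; a late-frame average is reported alongside it since either
convention appears in practice.

A biphasic variant `fast_amp (1 − e^{−fast_k t}) + slope·t`
(slope ≥ 0) captures polymerase-like recovery: a promoter-exchange
burst followed by a linear elongation ramp.

## FLIP-FRAP two-compartment model

Bleaching half a nucleus and following both halves tests whole-
compartment mobility. The generator models two well-mixed compartments
(volumes v1, v2) exchanging mobile fluorophore with volumetric rate
k_ex; concentration differences relax at `k_ex (1/v1 + 1/v2)`, total
fluorescence is conserved exactly after the bleach, and an immobile
fraction can be excluded from exchange. The analysis expresses each
half as percent of its own pre-bleach mean (curves are normalized
per-curve before any averaging), reports the equilibration half-time of
the bleached-half rise (midpoint crossing, linearly interpolated), and
the gain/loss balance — bleached-half gain over unbleached-half loss —
which is 1 under conservation. Two flat curves raise a "no exchange
detected" error.

## Condensation from histone fluorescence

Histone-GFP intensity tracks nucleosome density. Stacks are
auto-brightness rescaled (percentile window, default 0.35 %/99.65 %
saturation, mapped linearly onto 0–255; applied per nucleus, with the
per-slice option left to the caller by passing slices separately) and
voxels binned on the 8-bit scale: background 0–82, white (interband)
83–148, gray (moderately condensed bands) 149–224, black
(heterochromatin) ≥ 225. Volume fractions are counted over chromatin
voxels only, pooled across nuclei for the headline numbers with
per-nucleus fractions retained for the SD. Voxel counting over the
provided slices treats them as an unbiased sample of nuclear volume.

Relative condensation combines measured volume fractions with the
genomic composition of the chromatin classes (defaults: white 5 %,
gray 25 %, black 70 % of genomic DNA, from published chromatin-state
maps): `density_c = genomic_fraction_c / volume_fraction_c`, and the
fold-condensation of c1 over c2 is the density ratio. With the default
inputs this yields gray/white ≈ 6, black/gray ≈ 24, black/white ≈ 146;
the ratios are exactly chain-consistent by construction. A zero volume
fraction produces an infinite density, flagged rather than raised.

Fiber-model compaction converts base pairs to extended-fiber length
with `L = bp · nm_per_bp / packing_ratio` (defaults 0.34 nm/bp and
6.8:1, the predicted packing ratio of an extended 11 nm nucleosomal
array; both are configuration, not constants in code). Linear
fold-compaction is extended length over mean observed length, with
first-order uncertainty propagation from the replicate SD; the
volumetric variant models fragments as cylinders and compares DNA
densities `bp / (π r² L)`.

## Clustering and colocalization

The clustering statistic is a local variance filter: per-voxel
population variance over a circular neighborhood (center distance ≤
radius; default radius 2), restricted to the nuclear mask with no
padding — out-of-mask voxels contribute neither to the local mean nor
the variance. The per-nucleus readout is the mean of the map over the
mask (units: intensity²). It is computed by mask-weighted box sums and
verified against a literal double loop. Groups of nuclei are compared
with a two-tailed t test; Welch's unequal-variance variant is the
default (group SDs of this statistic are routinely unequal), the pooled
Student variant is selectable, and both accept raw samples or
(mean, sd, n) summaries.

Manders coefficients measure channel overlap: M1 is the fraction of
channel-A intensity in voxels where channel B exceeds its threshold,
M2 the converse. Thresholds default to Otsu's method per channel with
fixed-value overrides; both thresholds used are reported. Heat maps use
a fixed 256-entry colormap LUT; the float-RGB rendering is bijective
and exactly invertible (8-bit color export is lossy and not
round-trippable).

## Synthetic data: what it does and does not emulate

Curve generators add i.i.d. Gaussian noise on the normalized scale
(default SD 0.02, chosen to match reported curve-to-curve SD bands of
a few percent; the true acquisition noise magnitude is a free
parameter). The phantom is an ellipsoidal nucleus holding a banded
chromosome — white/gray/black bands stacked along one axis, black
embedded mid-way flanked by gray — with a spherical nucleolar void,
class-intensity painting, Gaussian PSF blur, Poisson shot noise and
Gaussian read noise. Default geometry is 9 slices of 128×128 at
0.5×0.1×0.1 μm voxels; the default PSF sigma is (0.3, 1, 1) voxels —
one voxel in-plane, and smaller along z *in voxel units* because the
z-step is five times the pixel pitch, as in a real confocal stack.
Class intensities (0/115/190/255) sit inside the printed class windows
so band cores survive the blur. Label-map class counts honour the
target fractions exactly (largest-remainder rounding over the sorted
voxel list) before blur.

Limitations: curve noise is white (no detector correlations or
photobleaching drift unless injected); the phantom has no sub-band
texture, no anisotropic optical aberrations, and a single nucleolus;
FLIP-FRAP compartments are well-mixed (no intra-compartment diffusion
gradient). Passing round-trip tests therefore demonstrates correctness
of the estimators under the stated forward models, not robustness to
every artifact of real microscopy.

## Problem sizes and numerical choices

Simulation studies use 200 replicates per kinetic regime at 2 % noise
and 20 phantom seeds — enough for stable medians/means of the recovered
parameters while keeping the whole validation suite around a minute.
Root-finding tolerances are 1e-12 (absolute) for t½; least-squares
tolerances are at machine-precision level so noiseless round trips
recover parameters to better than 1e-4 relative. Ties and degenerate
inputs (constant images, flat curve pairs, zero mobile fraction, zero
volume fractions) raise typed errors or flagged sentinels as described
above. All generators are pure functions of (spec, seed); one explicit
integer seed per call, no global RNG state.

## Pipeline

`RunConfig` is a single JSON document carrying every numeric constant
(thresholds, fiber model, percentiles, genomic fractions, noise level,
seed); unknown keys are rejected and the resolved config plus its
SHA-256 hash are written next to the outputs. `make_fixtures` writes
the canonical six-fixture bundle (fast ~0.7 s and slowed ~1.7 s
S2-protocol curves, a ~3 s band curve with immobile fraction 0.14, a
slow histone-like recovery reaching ~18–20 % after 40 min, a FLIP-FRAP
pair equilibrating with t½ ≈ 30 s, and a 52/43/5 phantom) with
ground-truth JSON sidecars; ground truth is seed-independent, only the
noise realization changes. Stages run in dependency order; a failure
aborts with the stage named and completed outputs retained; identical
config + seed reproduces reports bit-for-bit.
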
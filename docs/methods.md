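# Methods

This note documents the models implemented in `coactiv`, the choices made
where the methodology is genuinely open, the synthetic study conditions the
tests run under, and what passing those tests does and does not show.

## Coordinate-based meta-analysis (ALE)

**Model.** A reported activation focus is not a point but a 3-D Gaussian
probability distribution over voxels, expressing spatial uncertainty
(between-template and between-subject variability). Per experiment, focus
kernels combine by voxelwise **maximum** into a modelled-activation (MA)
map — the non-additive rule, so several nearby peaks from one study cannot
masquerade as convergence. Across experiments the union rule

    ALE(v) = 1 − ∏ᵢ (1 − MAᵢ(v))

treats each experiment as an independent chance of "truly" activating the
voxel. Inference is random-effects in the meta-analytic sense: the null
hypothesis is random *spatial association between experiments*, not random
clustering of foci within one experiment.

**Kernel policy.** The FWHM–sample-size relationship of the published
empirical uncertainty model is not hard-coded; the default is a fixed
10-mm FWHM kernel, and `SubjectsTableFWHM` accepts any user-supplied
`n_subjects → FWHM` table so the published quantitative model can be
plugged in. Kernels are separable integrated Gaussians (per-voxel CDF
differences, not sampled densities), truncated at ±3.5 σ and renormalised
to unit mass. Volumetric smoothing (`gaussian_smooth`) uses the same
integrated kernels, so impulse responses equal exact per-voxel masses.

**Empirical null.** Two constructions of the null distribution of ALE at a
voxel under random spatial association:

* *analytic histogram* — each experiment's in-mask MA values are binned
  (width 1e-5, configurable) and the histograms combined pairwise under the
  union rule, with nearest-bin rounding (unbiased; errors accumulate as a
  random walk of ±half a bin). This is the exact distribution of the union
  of one uniformly-placed contribution per experiment, up to binning.
* *sampling* — that process simulated directly, one uniform in-mask voxel
  per experiment per draw.

p-values are `P(X ≥ ALE(v))` with ties counted as "greater or equal"
(observed values are mapped into the same bins by the same rounding, so tie
handling is exact in integer bin space). Sampling p-values use the
`(count + 1)/(n + 1)` estimator, never 0; analytic queries beyond the
support return the top bin's mass, never 0. Z maps are `Φ⁻¹(1 − p)`,
floored at −8.2 where p = 1.

**Cluster-level FWE.** Monte-Carlo: each iteration relocates every
experiment's foci to uniform random in-mask voxels, recomputes ALE,
binarises at the cluster-forming threshold (voxel p < 0.001), and records
the maximum cluster size (face adjacency by default — the conservative
reading of "cohesive"; edge/corner adjacency is configurable). The
empirical ALE null is invariant under such relocation, so it is computed
once from the observed MA maps and reused across iterations. The reported
minimum extent is the smallest k with simulated
`P(max cluster ≥ k) ≤ α` — equivalently the ceiling of the (1−α) quantile
of max sizes, with the convention that α → 1 gives k = 1. 100 simulations
are the desk-scale default; raise `n_cluster_sims` for production use.

## Subtraction analyses (seed contrasts)

Observed voxelwise ALE difference between two experiment sets, against a
null built by pooling both sets and re-dividing them at random into groups
of the original sizes (experiments selected by both seeds contribute one
token per membership — the pooled-relabelling scheme). The per-voxel
posterior probability of a true A > B difference is the mid-p estimate
`(#{perm < obs} + 0.5)/(n_perm + 1)`, avoiding 0/1 saturation; voxels above
0.95 (below 0.05) are flagged A>B (B>A). Flagged maps are intersected with
the minuend's own FWE-corrected main effect — a difference is only reported
where the minuend shows significant connectivity at all — and clusters
smaller than 20 cohesive voxels are dropped.

Both the observed and the permuted differences are computed on ALE scores,
for unit consistency with the permutation null. The literal alternative of
displaying Z-score differences is available (`observed_on="z"`); it changes
only the reported difference map, never the posterior, because comparing an
observed Z difference against permuted ALE differences would mix units.

Tests default to 1,000 permutations (desk scale); 10,000 reproduces the
production setting.

## MACM and reciprocal reseeding

`run_macm` = seed selection (≥ 1 focus whose nearest voxel lies in the
seed) followed by the ALE pipeline; because selection conditions on seed
activation, the strongest convergence lands in or abutting the seed — this
is asserted on synthetic runs. `run_macm_contrast` composes two selections
with the subtraction machinery. `reciprocal_reseed` contrasts the regions a
previous contrast discovered and intersects the result with the union of
the original seeds used as inclusive masks, reporting the directional
overlap per original seed — the circular but informative robustness check.

Fixture seeds ship as 6-mm spheres at the published working-memory
meta-analysis peaks (ventral −40/12/32 and 42/6/26; dorsal −20/10/56 and
24/12/15). The dorsal-right z = 15 is reproduced verbatim from its source
even though it is inconsistent with a posterior superior frontal location
(plausibly a typo for z ≈ 51); it is flagged rather than silently
corrected. Radius is configurable since the defining cluster extents are
not published; bilateral seeds are analysed as single union masks.

## Resting-state seed connectivity

**Nuisance model.** Per subject, after discarding the first four frames:
six motion parameters, their backward-difference derivatives (zero first
row), grey/white/CSF mean signals, the first five principal-component time
courses of the column-centred whole-brain T×V matrix, squared terms of all
non-PCA columns (squares of centred columns, re-centred), and an intercept
— 15 first-order + 5 PCA + 15 squared + 1 = **36 columns**. All columns
except the intercept are mean-centred. Residualisation uses the
pseudoinverse with one refinement pass, so residuals are orthogonal to
every column to near machine precision even for ill-conditioned designs;
rank-deficient designs are handled (dependent directions dropped, logged).

**Order of operations** (fixed, documented): discard → 5-mm FWHM volume
smoothing → nuisance regression → band-pass. A
`filter_regressors=True` variant band-passes data and regressors before
regressing (prevents confound reintroduction); it is a sensitivity option,
not the default.

**Filter.** Zero-phase FFT filter after linear detrending, with
raised-cosine transitions confined to (f_lo/2, f_lo) and (f_hi, 1.5·f_hi):
unit gain across 0.01–0.08 Hz, zero gain at and beyond half/1.5× the band
edges. The filter family is a design choice; this one meets the passband
(<5% ripple) and stopband (≥90% attenuation at f_lo/2 and 2·f_hi)
contract exactly on finite series and is idempotent up to the transition
bands.

**Seed and maps.** Seed time course = first left singular vector of the
seed voxels' cleaned time-series, unit variance, sign-aligned with the
seed-mean time course. Voxelwise Pearson correlations over grey matter are
clipped to ±(1 − 1e-7) and Fisher-Z transformed; zero-variance voxels get
z = 0 with a log entry.

**Group model.** The two-seed comparison is a within-subject paired
contrast: per-voxel paired differences of the two Fisher-Z maps, a
one-sample t statistic across subjects, voxel threshold p < 0.001 per
direction, and cluster-level FWE by sign-flipping permutation of the
subject difference maps (maximum cluster size pooled over both directions,
α = 0.05). This is the special case the non-sphericity-corrected ANOVA's
reported contrasts test, without the general flexible-factorial machinery.

## Conjunctions and functional decoding

Minimum-statistic conjunctions on already-thresholded (cluster-FWE
corrected) maps are voxelwise AND — across modalities for main effects, and
per direction for the conjunction of contrasts.

Decoding builds the pool of experiments activating region A or region B (in
network mode: a region AND at least one of its partner regions). The
baserate for side A is the a priori probability of an A membership among
all memberships in the pool; for each label with at least 5 counting units
the conditional probability of side A given the label is tested one-sided
against the baserate with an exact binomial test, both directions tested,
Bonferroni over all (label, direction) pairs. The counting unit defaults to
the **experiment** (avoids within-study dependence between foci);
`unit="focus"` implements the literal focus-level reading. Sidedness and
the unit are choices exposed as parameters, not claims about the original
analysis.

## Synthetic study conditions

**Foci databases** (`simulate_foci_db`). Experiments draw a network by
prevalence (0.4/0.4, remainder background), report one focus per member
region with the member's co-report probability (seed 1.0, partner 0.8,
cross-partner 0.05) at the region centre plus isotropic 5-mm Gaussian
jitter, plus Poisson(2) uniform background foci; subject counts uniform in
10–30; the network's label attaches with fidelity 0.9. Regions are 10-mm
spheres — commensurate with meta-analytic seed clusters and with the 5-mm
reporting jitter (~3/4 of member foci land inside their region, so seed
selection captures most network members, as in real MACM where seeds are
sizeable clusters). The default grid is a 20×22×20 box of 4-mm voxels with
an ellipsoidal mask (~2,900 voxels); the calibration checks use a 24³ box
so the mask is large relative to the kernel (see Limitations).

**BOLD cohorts** (`simulate_bold`). 20 subjects, 24×28×24 grid at 4 mm,
T = 300 frames at TR = 2.2 s, first 4 discarded. Band-limited
(0.01–0.08 Hz) unit-variance latents: grey matter is organised into
coherent ~24-mm parcels (background resting networks, coherence 0.85),
planted regions (8-mm spheres inside the grey core) share their region
latent, and targets mix source latents so the expected correlation equals
the planted r. Confounds: a global fluctuation (amplitude 1.0, per-tissue
coupling), a motion-coupled term (0.8) from emitted random-walk
realignment parameters, always-present linear+quadratic drift (1.0), two
spatially broad "physiological" modes (0.5, 24-mm smooth weight maps), and
white noise (SD 0.3). Motion/drift coupling patterns are spatially
heterogeneous and signed, and all confound amplitudes differ by tissue
compartment (CSF pulsates most, motion artefacts strongest at the rim);
grey/white/CSF are concentric geometric shells.

Two features of this design are load-bearing and deliberately realistic.
First, background grey matter must contain coherent networks: if the only
coherent grey-matter signal were the planted pair, the mean-grey regressor
would act as a targeted global-signal regression on exactly the planted
network and bias its recovered correlation negative. Second, the five
strong confound processes (global, motion, drift, two physiological modes)
give the five whole-brain PCA regressors broad structure to capture; in a
simulation without them, the PCA would lock onto the largest coherent
signal left — the planted network itself — and remove it. Both failure
modes are real hazards of mean-signal/PCA denoising at small brain sizes,
and the generator documents them by construction.

**What the generators do not emulate:** biophysical haemodynamics (balloon
models), spatial autocorrelation of scanner noise, susceptibility dropout,
registration error, physiological recordings, or non-MNI spaces. Passing
the recovery tests therefore shows the *estimators* are correct and the
denoising model removes the confounds it models — not that real
acquisitions meet these assumptions.

## Problem sizes and numerical choices

Desk-scale defaults used throughout the tests and the reproduction script:
grids of 2–8 thousand in-mask voxels, 150-experiment databases, 1,000
permutations, 100 cluster-FWE simulations, 50–200 replicates for
calibration checks, 20-subject BOLD cohorts, and a 10⁶-draw sampling null
for the null-agreement check. Null histogram bin width 1e-5 (CDF error
bounded by one bin per combination step, random-walk accumulation).
Correlation clip 1 − 1e-7 before `atanh`; Z floor −8.2; kernel truncation
3.5 σ; smoothing truncation 4 σ. Recovered Fisher Z at a planted target is
measured on the target sphere eroded by one voxel, because 5-mm volume
smoothing dilutes boundary voxels with surrounding tissue (a partial-volume
effect of the measurement, not of the estimator).

## Known limitations

* **Mask-edge effects at desk scale.** The histogram null aggregates MA
  values over the whole mask, including edge voxels where kernels are
  truncated; on masks not much larger than the kernel this makes voxel
  p-values very slightly anti-conservative (about +5% relative on the
  0.001 rate on a 24³/4-mm ellipsoid, i.e. ~0.00105 observed). The effect
  shrinks with mask size and is negligible at whole-brain scale.
* **Cluster-FWE Monte-Carlo** assumes foci are uniformly placeable across
  the mask; anatomically informed priors are out of scope.
* The paired group contrast covers the two-seed within-subject design
  only; general factorial designs with non-sphericity estimation are not
  implemented.
* Grey-mean regression removes a small share of any network's signal in
  proportion to the network's share of grey matter; at desk scale this
  leaves a residual negative bias of a few hundredths in recovered Fisher
  Z (visible in the reproduction script's `rsfc_denoised_abs_bias`).
* Talairach coordinates are rejected rather than converted; no atlas-based
  anatomical labelling is provided.
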
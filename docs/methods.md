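# Methods

## Forward model

The cell is a one-dimensional box of length `L` (default 90 µm) with
zero-flux ends. Between image acquisitions the fluorescent-protein
concentration obeys the diffusion equation; at each acquisition time a
fraction `β` of the fluorophores inside the scanned field of view is
destroyed instantaneously. The field of view defaults to the 300-pixel
(44.1 µm at 0.147 µm/pixel) acquisition window centred on the bleach
position and clipped to the cell; its placement is a modelling choice, since
only its width is fixed by the acquisition protocol.

Assumptions worth keeping in mind:

* one spatial dimension — valid when the bleached rectangle crosses the
  whole cell transversely, so recovery is dominated by motion along the
  long axis;
* a single diffusing species with no binding — appropriate for cytoplasmic
  measurements, *not* for fibre tips (see the tip analyses below);
* the imaging bleach acts on the whole field of view at one instant per
  frame. The photons of a frame are recorded before that frame's bleach is
  applied (record-then-bleach), because the collected signal precedes the
  cumulative damage of a full scan. The alternative ordering differs by
  O(β) per frame; the convention is fixed and used consistently by the
  solver, the fitter and the generator.

The intentional bleach is never simulated mechanistically. Diffusion during
the bleaching phase makes the first post-bleach profile a Gaussian rather
than a top-hat, so that profile — fitted as `A₀ − C₀ exp[−(X−X₀)²/(2σ²)]` —
*is* the initial condition, with the bleaching-phase physics absorbed
into `σ`.

## Normalization and the Gaussian fit

Measured profiles are background-subtracted (background: mean of a region
outside the cell over pre-bleach frames 4–20, 1-based), averaged across the
strip's transverse extent, and divided per position by the average of the
pre-bleach frames 4–20. Positions where that baseline is non-positive are
masked with a warning. Saturated (255) pixels are retained and flagged;
negative background-subtracted intensities are retained, since genuine
low-expression regions produce them.

Because the pre-bleach frames themselves bleach, a normalized post-bleach
profile's far field sits slightly *below* one (at
`(1−β)^n_pre / mean_i (1−β)^i` ≈ 0.984 for β ≈ 0.0018), and carries a
shoulder near the field-of-view edges where unbleached protein diffuses in.
Two consequences for the implementation:

* the Gaussian fit estimates the far-field level as a free nuisance
  parameter and reports the depth `C₀` relative to it (the returned object
  still uses the `A₀ = 1` convention). Forcing the level to exactly 1 leaks
  the offset into `σ` and `C₀` and was measured to bias the recovered `D`
  by ~7% on synthetic data;
* the standard input to the Gaussian fit is the ratio of the first
  post-bleach profile to the last pre-bleach profile
  (`isolate_bleach_profile`), which cancels the imaging-bleach history and
  the edge shoulder pointwise and leaves the intentional dip on a flat
  baseline. On noise-free synthetic movies this reduces the pipeline's `D`
  recovery error from ~2.5% to ~1%.

Fit initialisation: centre at the profile minimum, depth from the minimum
value, width from the half-depth width; bounded least squares
(`scipy.optimize.curve_fit`), far field ∈ [0.5, 1.5], depth ∈ [−0.5, 1.5],
σ ∈ (0, L]. A fitted depth below 10⁻⁶ raises the "no bleach detected" flag.

## Numerics

Crank–Nicolson finite differences on a uniform node grid with step
`L/ceil(L/0.147)` ≤ one pixel; zero-flux boundaries via ghost points, which
makes the scheme conserve trapezoidal mass exactly (verified to 10⁻¹² over
500 frames). Sub-steps per frame interval are chosen so that
`D·dt_sub ≤ 0.5 µm²`; against an exact-in-time cosine-spectral integrator on
a 10× finer grid the full 500-frame curves agree to ≤0.053% for
`D ∈ [1, 20] µm²/s`, an order of magnitude inside the 0.1% temporal-error
budget. Curve readouts are trapezoidal interval averages with interpolated
end points, so they are insensitive to where grid nodes fall relative to
the readout interval (halving the grid step changes curves by <0.2%).

## Fitting D and β

The objective is the sum of squared differences between the measured
normalized curve and the forward simulation over the fit window (presets
21–50 ≈ 7 s, 21–200 ≈ 40 s, 21–500 ≈ 110 s; windows shorter than 5 points
are rejected). Two-parameter fits use bounded least squares
(`scipy.optimize.least_squares`, `D ∈ [10⁻³, 100]`, `β ∈ [0, 0.05]`,
ftol 10⁻⁸, ≤500 evaluations) started from a half-recovery heuristic
(`D₀ ≈ σ²/2t_half`) plus two bracketing starts a factor of five away;
extra starts are skipped once a start reaches a numerically perfect fit.
For short windows the imaging bleach is too small to constrain β, so
one-parameter fits fix β = 0.

When fitting measured (or generator-produced) curves, the model curve is
multiplied by a simulated pre-bleach baseline — the normalized profile the
measurement process itself would produce with no intentional bleach — so
that model and data share the same normalization convention, including the
`(1−β)ⁿ` level and the field-of-view edge replenishment. Curves simulated
without that history (pure model round trips) are fitted with
`prebleach_history=False`.

Each curve is fitted independently. Pooling curves across cells is
deliberately not offered: cell-to-cell variation in `D` is real (the
same-cell narrow/wide pairs correlate at R = 0.98 while different cells
scatter widely), and pooling would average it away.

## Tip analyses

Tips are split into two congruent 60 × 20 px boxes (long axis `X_T`
parallel to the membrane): one intentionally bleached, one not; a congruent
cytoplasm box away from the tip is the diffusive reference. All three are
background-subtracted; normalization, where used, is to each region's own
pre-bleach (frames 4–20) mean.

* **Fractional recovery** `R_T/I_T`: bleached-box intensity at the final
  frame minus the first post-bleach frame, over the pre-bleach mean.
  Undefined (flagged) when the pre-bleach mean is non-positive.
* **Final unbleached − bleached**: mean over the final 20 frames (181–200)
  of the normalized difference. Both halves receive identical imaging
  bleach after the intentional bleach, so a persistent difference can only
  come from molecules that never exchanged — the immobile-pool signature.
* **50%-recovery class**: on the unnormalized unbleached-minus-cytoplasm
  trace, the final level is the mean of the final-window frames and the
  baseline is the value at the fast→slow transition frame; the class is the
  first slow-phase frame (10 s spacing) at which ≥50% of that recovery is
  attained — `<10 s` … `<40 s` for ranks 1–4, `<60 s` for 5–6, `>30 s`
  beyond, `no recovery` when the total recovery is non-positive or the
  level is never reached; ties resolve to the earlier class. The
  final-level estimator (final-window mean) is a package choice; the
  closed class vocabulary is exactly the set of labels the published tip
  tables use.
* **Lateral-mobility profiles**: three 3-frame-averaged `X_T` profiles
  (pre-bleach, just post-bleach, end of experiment) and the least-squares
  slope of the end profile over the unbleached half, sign positive toward
  the bleached boundary. Significance via a seeded bootstrap (1000
  resamples over the end-window frames, 95% interval), replacing a visual
  gradient assessment with a quantitative one. Bound molecules moving
  laterally along the membrane produce a significantly negative slope;
  exchange through the cytoplasm does not.
* **Dark-state control**: after bleaching an entire cell nothing can
  diffuse in, so any recovery is dark-state relaxation. The fraction is
  (plateau − first post-bleach)/pre-bleach mean, with the plateau taken as
  the mean of the last 10% of post-bleach frames; a still-rising trace
  triggers a warning.
* **Integrated density**: on Z-sum projections, background-corrected sums
  per region; the tip sum is additionally corrected by subtracting the
  cytoplasmic per-pixel signal over *half* the tip area (the tip membrane
  sits at up to ~45° to the field of view, so roughly half the projected
  tip box overlies cytoplasm). Per-voxel means are computed from the
  actual voxel dimensions (0.147 × 0.147 × 1 µm ⇒ 0.0216 µm³); note that a
  rounded voxel volume of 0.024 µm³ sometimes quoted for such settings is
  inconsistent with these dimensions.

## Synthetic-data generator

The generator emulates the acquisition protocol: 300 × 60 px frames at
0.147 µm/px with an 8-row background margin, 0.2 s scan interval, 20
pre-bleach frames, intentional bleach between frames 20 and 21, and for tip
experiments a fast-then-slow schedule. The tip schedule default is 20
pre-bleach + 155 fast + 25 slow frames (200 total, ≈285 s), chosen so the
slow phase lasts the protocol's ~250 s and the 181–200 final window lies
wholly inside it; the exact fast/slow split is a package choice, as the
protocol fixes only the totals.

* **Cytoplasm experiments** evolve the full forward model (the production
  solver) and sample it at pixel centres, so the noise-free expectation of
  the movie follows the model exactly. The intentional bleach is either a
  Gaussian survival profile or a top-hat of given width at depth 0.6.
* **Tip experiments** carry three pools on a 120-px membrane strip:
  an immobile density (never exchanges), a mobile-bound pool that relaxes
  toward `capacity × φ` at rate `k_off` (φ = fluorescent fraction of the
  free pool), and a free pool treated as well mixed across the imaged
  optical section, refilled diffusively from out-of-section protein at
  rate `k_res = D/L_res²` (default `L_res` = 6 µm, an effective
  out-of-plane reservoir distance of order the optical-section and fibre
  radius scale). Mobile-bound association is effectively diffusion-limited:
  only `k_off` and the capacity are exposed, and no fixed `k_off` value is
  asserted — the published constraint is only that exchange happens on
  sub-second-to-seconds timescales. Back-flux of bound molecules into the
  free pool is neglected (the bound pool is a tiny mass fraction of the
  cell). Optionally the mobile pool also diffuses laterally along the
  strip (`mobile_lateral_D`), the contrast case for the lateral-mobility
  test; 0.05 µm²/s is used there, a typical membrane-protein lateral
  mobility that leaves the gradient front mid-strip at the end of the
  experiment.
* **Whole-cell bleach** returns a fraction `f ∈ [0, 0.05]` of the
  pre-bleach signal with a 2 s relaxation time, emulating dark-state
  recovery.

Per-scan β defaults to 0.008 for tip movies (upper end of the fitted
per-scan range, reflecting the stronger per-pixel exposure of tip imaging)
and is a free argument everywhere. Noise is Poisson (default) or additive
Gaussian; 8-bit quantization is applied last and the clipped fraction is
recorded in the manifest. All randomness flows from the single explicit
seed; identical seeds give bit-identical movies. Every generator returns a
manifest with the true parameters and per-frame per-pool totals, so tests
can check measured statistics against generator bookkeeping instead of
against the code under test.

What the generator does *not* emulate: confocal optics (point-spread
function, pinhole, Z-sectioning), motion or drift of the embryo, detector
offsets or read noise, 2-D/3-D geometry of the fibre, and autofluorescent
background structure. Passing tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to every artefact of
real in vivo data.

## Problem sizes and numerical tolerances in the tests

The suite runs noise-free round trips over `(D, β) ∈ {1,5,10,20} ×
{0, 0.002, 0.005}` on 500-frame schedules; Monte-Carlo noise studies use
100 replicates for the Gaussian profile fit and 24 replicates (150-frame
windows) for the curve fit, sizes at which the mean-recovery assertions
have comfortable statistical margin. Tip movies are generated at full
protocol size (200 frames, 300 × 60 px). The bootstrap for lateral slopes
uses 1000 resamples. The acceptance script mirrors these sizes and
completes in about a minute on one CPU.

## Known limitations

* The 1-D model ignores transverse and out-of-plane diffusion; for
  cytoplasmic fits this is part of the method's design (bleach geometry
  makes recovery one-dimensional), but fitted `β` partially absorbs any
  residual out-of-plane exchange.
* Diffusion-plus-binding fitting of tip curves is intentionally absent:
  such fits need more free parameters than featureless in vivo recovery
  curves can constrain, which is precisely why the semi-quantitative tip
  signatures exist.
* The recovery-speed classes quantize time at the 10 s slow-frame spacing;
  exchange times below ~10 s are all reported as `<10 s`.
* `estimate_background` trusts the caller that the region lies outside the
  cell; no segmentation is attempted, and ROIs are user-supplied
  throughout.
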
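# frapdyn

In vivo FRAP (fluorescence recovery after photobleaching) analysis for
elongated cells, with explicit correction for bleaching-due-to-imaging.

Imaging fluorescently tagged proteins inside a living embryo forces a
trade-off: the high laser power needed for an acceptable signal-to-noise
ratio destroys a small fraction of the fluorophores with *every* scan, and
the intentional bleach is slow enough that the protein diffuses while it is
being applied. Ignoring either effect biases the estimated diffusion
coefficient badly. `frapdyn` implements an analysis built around both
effects, developed for Dystrophin–GFP dynamics in zebrafish muscle fibres,
and a semi-quantitative toolbox that distinguishes freely diffusing,
stably bound (immobile) and rapidly exchanging (mobile-bound) protein
pools at the fibre tips.

## The model

The concentration of *fluorescent* protein `C_f(X, t)` along the long axis
of the cell obeys

```
∂C_f/∂t = D ∂²C_f/∂X² − β Θ_FV(X) Σ_i δ(t − t_i) C_f(X, t)
```

with zero-flux boundaries at the two cell ends. `D` is the diffusion
constant (µm²/s); the second term removes a fraction `β` of the fluorophores
inside the scanned field of view (indicator `Θ_FV`) instantaneously at every
image acquisition time `t_i`. The intentional bleach is not simulated
mechanically: the first post-bleach profile is fitted with a Gaussian
`A₀ − C₀ exp[−(X − X₀)²/(2σ²)]` (far field `A₀ = 1`), which becomes the
initial condition — diffusion during the bleaching phase is thereby absorbed
into `σ`. `D` and `β` are then estimated by least squares between the
simulated and measured recovery curves (the mean normalized intensity over
the bleached region per frame).

At fibre tips, where bound pools invalidate the pure-diffusion model, three
direct analyses are used instead: the recovery curve of a half-tip bleach
(no recovery ⇒ immobile pool), the final difference between the normalized
unbleached and bleached tip halves (plateau above zero ⇒ a pool bound for
hundreds of seconds), and the speed at which the unbleached-minus-cytoplasm
trace rebounds after switching from 0.2 s to 10 s acquisition intervals
(≥50% within the first slow frame ⇒ a bound pool exchanging within seconds).

The package also contains a synthetic-experiment generator with ground-truth
manifests (three pools, Poisson/Gaussian noise, 8-bit quantization) so that
the whole stack is testable without microscope data, packaged CSV tables of
the published per-experiment fits and tip statistics, and a thin CLI
(`frapdyn simulate | fit-cytoplasm | analyze-tip`).

## Worked example

```python
from frapdyn import *
from frapdyn.fitting import FitWindow

# Published per-experiment fit table, shipped with the package
fit_table = load_fit_table()
gfp = summarize_D(fit_table, label="GFP")        # two-parameter fits to
dys = summarize_D(fit_table, label="huDysGFP")   # point 200, standard cell
print(f"GFP:      D = {gfp['mean']:.1f} um^2/s  (range {gfp['min']}-{gfp['max']}, n={gfp['n']})")
print(f"huDysGFP: D = {dys['mean']:.1f} um^2/s  (range {dys['min']}-{dys['max']}, n={dys['n']})")

# Synthetic cytoplasmic FRAP movie at known parameters, analysed end to end
sched = AcquisitionSchedule.uniform(500)          # 500 frames, 0.2 s apart
spec = SyntheticCellSpec(seed=1)                  # 90 um cell, Poisson noise
truth = ModelParams(D=9.3, beta=0.001753)
bleach = GaussianBleach(C0=0.5, X0=45.0, sigma=3.0)
movie, manifest = generate_cytoplasm_experiment(spec, truth, sched, bleach=bleach)

regions = manifest["regions"]
bg = estimate_background(movie, regions["background"])
profiles, curve = normalize_to_prebleach(movie, regions["cell_strip"], sched,
                                         bg, readout=regions["bleach_strip"])
init, _ = fit_gaussian_postbleach(isolate_bleach_profile(profiles, sched),
                                  cell_length_um=90.0)
readout = regions["bleach_strip"].x_interval_um(movie.pixel_size_um,
                                                movie.x_origin_um)
result = fit_diffusion_frap(curve, init, spec.geometry, sched,
                            FitWindow(21, 200), readout_region=readout)
print(f"fitted D = {result.D:.2f} um^2/s, beta = {result.beta:.6f} per scan")
```

Output:

```
GFP:      D = 13.2 um^2/s  (range 8.6-20.8, n=18)
huDysGFP: D = 4.4 um^2/s  (range 1.4-10.1, n=17)
fitted D = 9.48 um^2/s, beta = 0.001694 per scan
```

The headline numbers say that free GFP diffuses about three times faster
than GFP-tagged Dystrophin in muscle-fibre cytoplasm, and the synthetic
round trip shows the estimator recovering the true `(D, β)` of a noisy
8-bit movie to within a few percent.

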
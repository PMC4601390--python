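"""Synthetic FRAP experiments with known ground truth.

The generator emulates the acquisition protocol: a 300 x 60 pixel region at
0.147 um/pixel, 0.2 s scan interval, 20 pre-bleach frames with the
intentional bleach between frames 20 and 21, and for tip experiments a
fast-then-every-10-s schedule. Every stochastic output flows from one
explicit seed; 8-bit quantization is applied last, after noise.

Three experiment types:

* cytoplasm FRAP: a uniform diffusing pool on the full model cell evolved
  with the production forward model (diffusion between frames, (1 - beta)
  per scan inside the field of view, a Gaussian intentional bleach);
* tip FRAP: three pools — an immobile membrane-bound pool, a mobile
  membrane-bound pool exchanging with the free pool at rate k_off, and a
  free pool treated as well mixed in the imaged section and refilled
  diffusively from out-of-section reservoir protein;
* whole-cell bleach: the dark-state control, where a small fraction of the
  bleach-depleted signal relaxes back with a short time constant.

Each generator returns an ImageSeries plus a manifest dict recording every
true parameter and the per-frame noise-free pool totals, so tests can verify
measured statistics against generator bookkeeping rather than against the
pipeline under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    PIXEL_SIZE_UM,
    AcquisitionSchedule,
    CellGeometry,
    ConcentrationProfile,
    GaussianBleach,
    ModelParams,
    evolve_diffusion,
)
from .profiles import ImageSeries, RegionSpec

__all__ = [
    "SyntheticCellSpec",
    "generate_cytoplasm_experiment",
    "generate_tip_experiment",
    "generate_whole_cell_bleach",
    "generate_zstack_sum",
]

IMAGE_NX = 300
IMAGE_NY = 60
_BG_ROWS = 8          # rows outside the cell, used as the background region
_TIP_Y0, _TIP_H = 20, 20
_TIP_X0, _TIP_HALF_W = 30, 60
_CYTO_X0 = 180


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Ground-truth description of a synthetic cell.

    Intensities are per-pixel means on the 8-bit scale. ``tip_zone_um`` is
    the depth of the membrane-proximal zone holding the bound pools;
    ``reservoir_length_um`` sets the diffusive refill rate of the imaged
    section from out-of-section protein (k_res = D / L^2).
    """

    geometry: CellGeometry = field(default_factory=CellGeometry)
    cytoplasm_concentration: float = 100.0
    tip_zone_um: float = 2.0
    immobile_bound_density: float = 0.0
    mobile_bound_density: float = 0.0
    k_off: float = 1.0
    mobile_lateral_D: float = 0.0
    dark_state_fraction: float = 0.0
    dark_relax_time_s: float = 2.0
    background: float = 10.0
    noise: str | None = "poisson"     # None | "poisson" | "gaussian"
    gaussian_sd: float = 2.0
    seed: int = 0
    quantize_8bit: bool = True
    reservoir_length_um: float = 6.0

    def __post_init__(self) -> None:
        for name in ("cytoplasm_concentration", "immobile_bound_density",
                     "mobile_bound_density", "background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mobile_bound_density > 0 and self.k_off <= 0:
            raise ValueError("k_off must be positive when a mobile pool is present")
        if not 0.0 <= self.dark_state_fraction <= 0.05:
            raise ValueError("dark_state_fraction must lie in [0, 0.05]")
        if self.noise not in (None, "poisson", "gaussian"):
            raise ValueError("noise must be None, 'poisson' or 'gaussian'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _finalize_movie(expected: np.ndarray, spec: SyntheticCellSpec,
                    manifest: dict) -> np.ndarray:
    """Apply the noise model and 8-bit quantization; record clipping."""
    rng = spec.rng()
    if spec.noise == "poisson":
        movie = rng.poisson(np.maximum(expected, 0.0)).astype(float)
    elif spec.noise == "gaussian":
        movie = expected + rng.normal(0.0, spec.gaussian_sd, size=expected.shape)
    else:
        movie = expected.copy()
    if spec.quantize_8bit:
        movie = np.rint(movie)
        manifest["clipped_fraction"] = float(((movie < 0) | (movie > 255)).mean())
        movie = np.clip(movie, 0.0, 255.0)
    else:
        movie = np.clip(movie, 0.0, 255.0)
        manifest["clipped_fraction"] = float((expected > 255).mean())
    return movie


def _standard_regions() -> dict[str, RegionSpec]:
    return {
        "background": RegionSpec(0, 0, IMAGE_NX, _BG_ROWS, role="background"),
        "cell_strip": RegionSpec(0, _BG_ROWS, IMAGE_NX, IMAGE_NY - _BG_ROWS,
                                 role="cytoplasm"),
    }


def generate_cytoplasm_experiment(
        spec: SyntheticCellSpec, params: ModelParams,
        sched: AcquisitionSchedule | None = None,
        bleach: GaussianBleach | float = 4.0,
) -> tuple[ImageSeries, dict]:
    """Simulate a cytoplasmic FRAP movie with the production forward model.

    ``bleach`` is either the Gaussian survival profile of the intentional
    bleach or a top-hat width in pixels (bleached at depth 0.6, centred on
    the bleach position) that diffusion then smears, as in the experiment.
    The noise-free expectation of the movie follows the forward model
    exactly: diffusion between frames, (1 - beta) per scan inside the field
    of view, and the intentional bleach between frames 20 and 21.
    """
    if sched is None:
        sched = AcquisitionSchedule.uniform(n_frames=500)
    geom = spec.geometry
    x = geom.grid()
    fov_lo, fov_hi = geom.fov_um
    fov_mask = (x >= fov_lo - 1e-9) & (x <= fov_hi + 1e-9)
    c0 = spec.cytoplasm_concentration

    if isinstance(bleach, GaussianBleach):
        survival = bleach.evaluate(x) / bleach.A0
        bleach_desc = {"kind": "gaussian", "C0": bleach.C0, "X0": bleach.X0,
                       "sigma": bleach.sigma}
        strip_w_px = max(2, int(round(4 * bleach.sigma / geom.pixel_size_um)))
    else:
        width_um = float(bleach) * geom.pixel_size_um
        lo = geom.bleach_center_um - width_um / 2.0
        hi = geom.bleach_center_um + width_um / 2.0
        depth = 0.6
        survival = np.where((x >= lo) & (x <= hi), 1.0 - depth, 1.0)
        bleach_desc = {"kind": "tophat", "width_px": float(bleach), "depth": depth}
        strip_w_px = max(2, int(round(float(bleach))))
    if np.any(c0 * survival < 0):
        raise ValueError("bleach depth would produce negative intensities")

    prof = ConcentrationProfile(x, np.full_like(x, c0), time_s=sched.frame_times_s[0])
    n_frames = sched.n_frames
    pix_x = fov_lo + (np.arange(IMAGE_NX) + 0.5) * geom.pixel_size_um
    frames_1d = np.empty((n_frames, IMAGE_NX))
    fov_mass = np.empty(n_frames)

    v = prof.values.copy()
    for i in range(n_frames):
        frames_1d[i] = np.interp(pix_x, x, v)
        fov_mass[i] = v[fov_mask].sum()
        if i == n_frames - 1:
            break
        v[fov_mask] *= (1.0 - params.beta)                 # record-then-bleach
        if i + 1 == sched.bleach_after_frame:              # between frames 20/21
            v = v * survival
        dt = float(sched.frame_times_s[i + 1] - sched.frame_times_s[i])
        prof = evolve_diffusion(ConcentrationProfile(x, v), params.D, dt)
        v = prof.values

    expected = np.empty((n_frames, IMAGE_NY, IMAGE_NX))
    expected[:, :_BG_ROWS, :] = spec.background
    expected[:, _BG_ROWS:, :] = spec.background + frames_1d[:, None, :]

    regions = _standard_regions()
    x0_strip = int(round((geom.bleach_center_um - fov_lo) / geom.pixel_size_um
                         - strip_w_px / 2))
    regions["bleach_strip"] = RegionSpec(x0_strip, _BG_ROWS, strip_w_px,
                                         IMAGE_NY - _BG_ROWS, role="bleach_strip")

    manifest = {
        "experiment": "cytoplasm",
        "D": params.D, "beta": params.beta,
        "cytoplasm_concentration": c0, "background": spec.background,
        "bleach": bleach_desc, "seed": spec.seed, "noise": spec.noise,
        "x_origin_um": fov_lo,
        "fov_um": (fov_lo, fov_hi),
        "regions": regions,
        "fov_mass_per_frame": fov_mass,
        "noise_free_profiles": frames_1d,
    }
    movie = _finalize_movie(expected, spec, manifest)
    series = ImageSeries(movie, pixel_size_um=geom.pixel_size_um,
                         frame_times_s=sched.frame_times_s, x_origin_um=fov_lo)
    return series, manifest


def _tip_regions() -> dict[str, RegionSpec]:
    regions = _standard_regions()
    regions["bleached_tip"] = RegionSpec(_TIP_X0, _TIP_Y0, _TIP_HALF_W, _TIP_H,
                                         role="bleached_tip")
    regions["unbleached_tip"] = RegionSpec(_TIP_X0 + _TIP_HALF_W, _TIP_Y0,
                                           _TIP_HALF_W, _TIP_H,
                                           role="unbleached_tip")
    regions["cytoplasm"] = RegionSpec(_CYTO_X0, _TIP_Y0, _TIP_HALF_W, _TIP_H,
                                      role="cytoplasm")
    return regions


def generate_tip_experiment(
        spec: SyntheticCellSpec,
        sched: AcquisitionSchedule | None = None,
        bleach_half: str = "left",
        beta: float = 0.008,
        bleach_depth: float = 0.9,
        diffusing_D: float = 4.0,
) -> tuple[ImageSeries, dict]:
    """Simulate a fibre-tip FRAP movie with three protein pools.

    The tip occupies a 120 x 20 px strip whose long axis is X_T (parallel to
    the membrane); the left or right 60 x 20 px half is intentionally
    bleached, the other half only receives bleaching-due-to-imaging, and a
    congruent cytoplasm region serves as the diffusive reference. The free
    pool is well mixed across the imaged section and refills diffusively
    (rate D / reservoir_length^2) from unbleached out-of-section protein;
    the mobile-bound pool relaxes toward capacity x (local fluorescent
    fraction) at rate k_off; the immobile pool never exchanges. Optionally
    the mobile-bound pool also diffuses laterally along X_T
    (``mobile_lateral_D``), the contrast case for the lateral-mobility test.
    """
    if bleach_half not in ("left", "right"):
        raise ValueError("bleach_half must be 'left' or 'right'")
    if spec.mobile_bound_density > 0 and spec.cytoplasm_concentration <= 0:
        raise ValueError("mobile pool cannot refill: no cytoplasmic protein "
                         "and no exchange partner")
    if sched is None:
        sched = AcquisitionSchedule.fast_slow()
    n_frames = sched.n_frames
    c_total = spec.cytoplasm_concentration
    k_res = (diffusing_D / spec.reservoir_length_um ** 2) if c_total > 0 else 0.0

    tip_w = 2 * _TIP_HALF_W
    x_t = (np.arange(tip_w) + 0.5) * PIXEL_SIZE_UM  # tip-strip coordinates
    immobile = np.full(tip_w, spec.immobile_bound_density, dtype=float)
    capacity = np.full(tip_w, spec.mobile_bound_density, dtype=float)
    mobile = capacity.copy()        # fully occupied, fully fluorescent at start
    c = float(c_total)

    half = slice(0, _TIP_HALF_W) if bleach_half == "left" \
        else slice(_TIP_HALF_W, tip_w)

    frames_tip = np.empty((n_frames, tip_w))
    c_per_frame = np.empty(n_frames)
    im_per_frame = np.empty((n_frames, 2))   # bleached-half, unbleached-half means
    mo_per_frame = np.empty((n_frames, 2))

    def halves_mean(arr: np.ndarray) -> tuple[float, float]:
        a = float(arr[half].mean())
        other = np.ones(tip_w, dtype=bool)
        other[half] = False
        return a, float(arr[other].mean())

    for i in range(n_frames):
        frames_tip[i] = immobile + mobile
        c_per_frame[i] = c
        im_per_frame[i] = halves_mean(immobile)
        mo_per_frame[i] = halves_mean(mobile)
        if i == n_frames - 1:
            break
        # record-then-bleach: the whole image is the field of view
        c *= (1.0 - beta)
        immobile *= (1.0 - beta)
        mobile *= (1.0 - beta)
        if i + 1 == sched.bleach_after_frame:
            immobile[half] *= (1.0 - bleach_depth)
            mobile[half] *= (1.0 - bleach_depth)
        dt = float(sched.frame_times_s[i + 1] - sched.frame_times_s[i])
        if k_res > 0:
            c = c_total + (c - c_total) * math.exp(-k_res * dt)
        if spec.mobile_bound_density > 0:
            phi = c / c_total if c_total > 0 else 0.0
            target = capacity * phi
            mobile = target + (mobile - target) * math.exp(-spec.k_off * dt)
            if spec.mobile_lateral_D > 0:
                prof = evolve_diffusion(ConcentrationProfile(x_t, mobile),
                                        spec.mobile_lateral_D, dt)
                mobile = prof.values

    expected = np.empty((n_frames, IMAGE_NY, IMAGE_NX))
    expected[:, :_BG_ROWS, :] = spec.background
    expected[:, _BG_ROWS:, :] = spec.background + c_per_frame[:, None, None]
    expected[:, _TIP_Y0:_TIP_Y0 + _TIP_H, _TIP_X0:_TIP_X0 + tip_w] += \
        frames_tip[:, None, :]

    regions = _tip_regions()
    manifest = {
        "experiment": "tip",
        "beta": beta, "bleach_depth": bleach_depth, "bleach_half": bleach_half,
        "diffusing_D": diffusing_D, "k_off": spec.k_off,
        "k_res": k_res, "mobile_lateral_D": spec.mobile_lateral_D,
        "immobile_bound_density": spec.immobile_bound_density,
        "mobile_bound_density": spec.mobile_bound_density,
        "cytoplasm_concentration": c_total, "background": spec.background,
        "seed": spec.seed, "noise": spec.noise,
        "regions": regions,
        "free_per_frame": c_per_frame,
        "immobile_per_frame": im_per_frame,
        "mobile_per_frame": mo_per_frame,
        "tip_profile_per_frame": frames_tip,
    }
    movie = _finalize_movie(expected, spec, manifest)
    series = ImageSeries(movie, frame_times_s=sched.frame_times_s)
    return series, manifest


def generate_whole_cell_bleach(
        spec: SyntheticCellSpec,
        sched: AcquisitionSchedule | None = None,
        bleach_depth: float = 0.95,
        beta: float = 0.0,
) -> tuple[ImageSeries, dict]:
    """Simulate the dark-state control: the entire cell bleached at once.

    No unbleached protein remains to diffuse in; a fraction
    ``dark_state_fraction`` of the pre-bleach signal returns with time
    constant ``dark_relax_time_s``, emulating dark-state relaxation.
    """
    if sched is None:
        sched = AcquisitionSchedule.fast_slow()
    n_frames = sched.n_frames
    t = sched.frame_times_s
    t_bleach = 0.5 * (t[sched.bleach_after_frame - 1] + t[sched.bleach_after_frame])
    s0 = spec.cytoplasm_concentration
    f = spec.dark_state_fraction

    signal = np.empty(n_frames)
    decay = (1.0 - beta) ** np.arange(n_frames) if beta > 0 else np.ones(n_frames)
    for i in range(n_frames):
        if i < sched.bleach_after_frame:
            signal[i] = s0 * decay[i]
        else:
            relax = 1.0 - math.exp(-(t[i] - t_bleach) / spec.dark_relax_time_s)
            signal[i] = s0 * decay[i] * ((1.0 - bleach_depth) + f * relax)

    expected = np.empty((n_frames, IMAGE_NY, IMAGE_NX))
    expected[:, :_BG_ROWS, :] = spec.background
    expected[:, _BG_ROWS:, :] = spec.background + signal[:, None, None]

    regions = _standard_regions()
    manifest = {
        "experiment": "whole_cell",
        "dark_state_fraction": f, "dark_relax_time_s": spec.dark_relax_time_s,
        "bleach_depth": bleach_depth, "beta": beta,
        "cytoplasm_concentration": s0, "background": spec.background,
        "seed": spec.seed, "noise": spec.noise,
        "regions": regions,
        "signal_per_frame": signal,
        "expected_recovery_fraction": f,
    }
    movie = _finalize_movie(expected, spec, manifest)
    series = ImageSeries(movie, frame_times_s=sched.frame_times_s)
    return series, manifest


def generate_zstack_sum(spec: SyntheticCellSpec, ratio: float = 3.7,
                        n_z: int = 20) -> tuple[np.ndarray, dict]:
    """Synthetic Z-sum projection with a known tip:cytoplasm per-voxel ratio.

    The tip box carries the membrane signal on every pixel plus cytoplasmic
    signal on exactly half its pixels (the tip membrane sits at up to ~45
    degrees to the field of view, so roughly half the projected tip area
    overlies cytoplasm) — the configuration the half-area correction of the
    integrated-density analysis assumes.
    """
    c = spec.cytoplasm_concentration
    t_sig = ratio * c
    img = np.full((IMAGE_NY, IMAGE_NX), spec.background * n_z, dtype=float)
    regions = _tip_regions()
    tip = RegionSpec(_TIP_X0, _TIP_Y0, 2 * _TIP_HALF_W, _TIP_H, role="bleached_tip")
    cyto = regions["cytoplasm"]
    img[cyto.y_slice, cyto.x_slice] += c * n_z
    img[tip.y_slice, tip.x_slice] += t_sig * n_z
    # cytoplasm behind half of the tip area (the half nearer the cell body)
    img[tip.y_slice, tip.x0 + tip.width // 2: tip.x0 + tip.width] += c * n_z
    if spec.noise == "poisson":
        img = spec.rng().poisson(img).astype(float)
    elif spec.noise == "gaussian":
        img = img + spec.rng().normal(0.0, spec.gaussian_sd * math.sqrt(n_z),
                                      size=img.shape)
    manifest = {"experiment": "zstack_sum", "ratio": ratio, "n_z": n_z,
                "tip_region": tip, "cytoplasm_region": cyto,
                "background": spec.background, "seed": spec.seed}
    return img, manifest
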
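"""Semi-quantitative analysis of fibre-tip FRAP experiments.

A fibre tip is split into two congruent rectangles: one intentionally
bleached, the other imaged identically but not bleached. A third region in
the cytoplasm, away from the tip, receives the same bleaching-due-to-imaging
and serves as the diffusive-pool reference. Three analyses distinguish the
protein pools:

* the FRAP curve of the bleached half (lack of recovery = immobile pool);
* the final difference between normalized unbleached and bleached halves
  (a plateau above zero = pool bound for at least hundreds of seconds);
* the speed at which the unnormalized unbleached-minus-cytoplasm trace
  recovers after the switch from fast to slow acquisition (recovery of at
  least 50% within the first slow frames = a rapidly exchanging bound pool).

A whole-cell bleach control quantifies how much apparent recovery can come
from fluorophore dark-state relaxation rather than protein exchange, and the
integrated-density summary quantifies the tip:cytoplasm partitioning on sum
projections of confocal stacks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import AcquisitionSchedule
from .profiles import ImageSeries, NormalizedProfile, RegionSpec, extract_x_profile

__all__ = [
    "RECOVERY_CLASSES",
    "TipTraces",
    "TipMetrics",
    "fractional_recovery",
    "final_unbleached_minus_bleached",
    "classify_recovery_speed",
    "lateral_mobility_profiles",
    "dark_state_recovery_fraction",
    "integrated_density_summary",
    "tip_metrics",
]

# Closed vocabulary of the 50%-recovery classes (the labels the tip tables
# use; ">30 s" is the late-recovery label).
RECOVERY_CLASSES = ("<10 s", "<20 s", "<30 s", "<40 s", "<60 s", ">30 s",
                    "no recovery")


@dataclass
class TipTraces:
    """Per-frame mean intensities of the three analysis regions.

    ``bleached``, ``unbleached`` and ``cytoplasm`` are unnormalized,
    background-subtracted traces sharing one acquisition schedule.
    """

    bleached: np.ndarray
    unbleached: np.ndarray
    cytoplasm: np.ndarray
    sched: AcquisitionSchedule

    def __post_init__(self) -> None:
        n = self.sched.n_frames
        for name in ("bleached", "unbleached", "cytoplasm"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} trace must have one value per frame")
            setattr(self, name, arr)

    def normalized(self, name: str) -> np.ndarray:
        """Trace divided by its own pre-bleach (frames 4-20) mean."""
        arr = getattr(self, name)
        base = arr[self.sched.prebleach_indices()].mean()
        if base <= 0:
            raise ValueError(f"non-positive pre-bleach baseline for {name}")
        return arr / base

    @classmethod
    def from_series(cls, series: ImageSeries, sched: AcquisitionSchedule,
                    bleached: RegionSpec, unbleached: RegionSpec,
                    cytoplasm: RegionSpec, background: float) -> "TipTraces":
        if (bleached.width, bleached.height) != (unbleached.width, unbleached.height):
            raise ValueError("bleached and unbleached tip boxes must be congruent")
        return cls(series.region_trace(bleached, background),
                   series.region_trace(unbleached, background),
                   series.region_trace(cytoplasm, background), sched)


@dataclass(frozen=True)
class TipMetrics:
    """The four per-tip statistics of the tip tables."""

    cytoplasm_intensity: float
    fractional_recovery: float
    final_diff: float
    recovery_class: str

    def __post_init__(self) -> None:
        if self.recovery_class not in RECOVERY_CLASSES:
            raise ValueError(f"unknown recovery class {self.recovery_class!r}")


def fractional_recovery(bleached_trace: np.ndarray, sched: AcquisitionSchedule,
                        final_frame: int | None = None) -> float:
    """R_T / I_T: tip intensity recovery over the pre-bleach tip intensity.

    R_T is the bleached-region intensity at the final frame minus that at the
    first post-bleach frame; I_T is the mean over the pre-bleach window.
    Undefined (nan, with a warning) when I_T <= 0.
    """
    tr = np.asarray(bleached_trace, dtype=float)
    i_t = tr[sched.prebleach_indices()].mean()
    if i_t <= 0:
        warnings.warn("pre-bleach tip intensity <= 0 (over-subtracted background)")
        return float("nan")
    last = (final_frame - 1) if final_frame is not None else (sched.n_frames - 1)
    r_t = tr[last] - tr[sched.bleach_after_frame]
    return float(r_t / i_t)


def final_unbleached_minus_bleached(traces: TipTraces) -> float:
    """Mean over the final window of (normalized unbleached - bleached).

    A value above zero evidences an immobile-bound pool: both halves have
    received identical imaging bleach since the intentional bleach, so a
    persistent difference can only come from molecules that never exchanged.
    """
    idx = traces.sched.final_indices()
    if idx[-1] >= traces.sched.n_frames:
        raise ValueError("final window extends past the last frame")
    diff = traces.normalized("unbleached") - traces.normalized("bleached")
    return float(diff[idx].mean())


def _slow_phase_start(sched: AcquisitionSchedule) -> int:
    """0-based index of the first slow-phase frame."""
    if sched.n_fast_frames is None or sched.n_fast_frames >= sched.n_frames:
        raise ValueError("schedule has no slow acquisition phase")
    return int(sched.n_fast_frames)


def classify_recovery_speed(traces: TipTraces) -> str:
    """Class of the first slow frame where unbleached-minus-cytoplasm has
    recovered at least 50% of its final recovery.

    Operates on unnormalized background-subtracted traces. The final level is
    the mean of the final-window frames of d = unbleached - cytoplasm; the
    baseline is d at the fast-to-slow transition frame. Returns
    "no recovery" when the final recovery is non-positive or the 50% level is
    never attained. Classes map slow-frame rank k (10 s spacing) to
    "<10 s" ... "<40 s", "<60 s" (k = 5-6) and ">30 s" (later).
    """
    s0 = _slow_phase_start(traces.sched)
    d = traces.unbleached - traces.cytoplasm
    base = d[s0 - 1]  # last fast frame: the transition point
    final = d[traces.sched.final_indices()].mean()
    total = final - base
    if total <= 0:
        return "no recovery"
    target = base + 0.5 * total
    slow = d[s0:]
    attained = np.flatnonzero(slow >= target)
    if attained.size == 0:
        return "no recovery"
    k = int(attained[0]) + 1  # slow-frame rank, 1-based
    if k <= 4:
        return f"<{10 * k} s"
    if k <= 6:
        return "<60 s"
    return ">30 s"


def lateral_mobility_profiles(series: ImageSeries, tip_strip: RegionSpec,
                              frames: tuple[int, int, int],
                              background: float,
                              unbleached_interval_px: tuple[int, int],
                              toward_bleached: str = "left",
                              n_end_frames: int = 10,
                              n_boot: int = 1000, seed: int = 0) -> dict:
    """Profiles along the tip's long axis at three times, plus a slope test.

    ``frames`` are 1-based (pre-bleach, just after bleach, end of experiment);
    each profile is the 3-frame average over the strip. The statistic is the
    least-squares slope of the end-of-experiment profile over the unbleached
    half (pixel interval, half-open, relative to the image). The sign
    convention is positive toward the bleached boundary (``toward_bleached``
    says whether the bleached half lies to the "left" or "right"). Lateral
    diffusion of the bound pool drags recovered intensity toward the bleached
    half and shows up as a significantly negative slope; an exchange-only
    pool recovers uniformly (slope ~ 0). Significance comes from a seeded
    bootstrap over the ``n_end_frames`` frames preceding the end frame.
    """
    if toward_bleached not in ("left", "right"):
        raise ValueError("toward_bleached must be 'left' or 'right'")
    profs = [extract_x_profile(series, tip_strip, f, background,
                               average_3_frames=True) for f in frames]
    end_frame = frames[2]
    lo_px, hi_px = unbleached_interval_px
    if not tip_strip.x0 <= lo_px < hi_px <= tip_strip.x0 + tip_strip.width:
        raise ValueError("unbleached interval must lie inside the tip strip")
    cols = slice(lo_px - tip_strip.x0, hi_px - tip_strip.x0)

    # window of frames used for the end-of-experiment slope
    f_hi = end_frame
    f_lo = max(1, f_hi - n_end_frames + 1)
    window = series.data[f_lo - 1:f_hi, tip_strip.y_slice, tip_strip.x_slice]
    window = window.mean(axis=1) - background  # frames x X
    x = (np.arange(tip_strip.width) + 0.5) * series.pixel_size_um
    xu = x[cols]

    def slope_of(mean_prof: np.ndarray) -> float:
        s = float(np.polyfit(xu, mean_prof[cols], 1)[0])
        # positive = increasing toward the bleached boundary
        return -s if toward_bleached == "left" else s

    slope = slope_of(window.mean(axis=0))
    rng = np.random.default_rng(seed)
    nfr = window.shape[0]
    boot = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, nfr, size=nfr)
        boot[b] = slope_of(window[pick].mean(axis=0))
    lo_ci, hi_ci = np.percentile(boot, [2.5, 97.5])
    return {"profiles": profs, "slope": slope,
            "ci95": (float(lo_ci), float(hi_ci)),
            "significant": bool(lo_ci > 0 or hi_ci < 0)}


def dark_state_recovery_fraction(whole_cell_trace: np.ndarray,
                                 sched: AcquisitionSchedule,
                                 plateau_fraction: float = 0.1) -> float:
    """Recovery fraction after bleaching an entire cell.

    With the whole cell bleached no unbleached protein can diffuse in, so any
    recovery reflects fluorophores returning from a reversible dark state.
    Returns (post-bleach plateau - first post-bleach value) / pre-bleach
    mean, the plateau being the mean of the last ``plateau_fraction`` of
    post-bleach frames. Warns if the trace is still rising at the end.
    """
    tr = np.asarray(whole_cell_trace, dtype=float)
    pre = tr[sched.prebleach_indices()].mean()
    if pre <= 0:
        raise ValueError("non-positive pre-bleach mean")
    post = tr[sched.bleach_after_frame:]
    n_tail = max(2, int(round(plateau_fraction * post.size)))
    tail = post[-n_tail:]
    prev = post[-2 * n_tail:-n_tail]
    if prev.size and tail.mean() - prev.mean() > 2.0 * tail.std(ddof=1) / np.sqrt(n_tail):
        warnings.warn("whole-cell trace still rising at the end: no plateau reached")
    return float((tail.mean() - post[0]) / pre)


def integrated_density_summary(zsum: np.ndarray, tip_region: RegionSpec,
                               cytoplasm_region: RegionSpec, background: float,
                               n_z: int = 1) -> dict:
    """Background-corrected integrated densities on a Z-sum projection.

    The tip box inevitably contains cytoplasm behind/around the membrane
    (the tip sits at up to ~45 degrees to the field of view), so the tip sum
    is additionally corrected by subtracting the cytoplasmic per-pixel signal
    over half the tip area. ``background`` is the per-pixel, per-slice
    background and ``n_z`` the number of summed Z slices.
    """
    zsum = np.asarray(zsum, dtype=float)
    if zsum.ndim != 2:
        raise ValueError("expected a 2-D sum projection")

    def overlap(a: RegionSpec, b: RegionSpec) -> bool:
        return not (a.x0 + a.width <= b.x0 or b.x0 + b.width <= a.x0 or
                    a.y0 + a.height <= b.y0 or b.y0 + b.height <= a.y0)

    if overlap(tip_region, cytoplasm_region):
        raise ValueError("cytoplasm region overlaps the tip region")

    bg_per_px = background * n_z

    def corrected_sum(region: RegionSpec) -> tuple[float, int]:
        block = zsum[region.y_slice, region.x_slice]
        return float(block.sum() - bg_per_px * block.size), int(block.size)

    cyto_sum, a_cyto = corrected_sum(cytoplasm_region)
    tip_raw, a_tip = corrected_sum(tip_region)
    cyto_per_px = cyto_sum / a_cyto
    tip_sum = tip_raw - cyto_per_px * (a_tip / 2.0)
    tip_per_px = tip_sum / a_tip
    return {
        "tip_sum": tip_sum,
        "cytoplasm_sum": cyto_sum,
        "tip_per_voxel": tip_per_px / n_z,
        "cyto_per_voxel": cyto_per_px / n_z,
        "ratio": tip_per_px / cyto_per_px if cyto_per_px != 0 else float("nan"),
    }


def tip_metrics(traces: TipTraces) -> TipMetrics:
    """Compute the four tip-table statistics for one tip."""
    cyto = float(traces.cytoplasm[traces.sched.prebleach_indices()].mean())
    return TipMetrics(
        cytoplasm_intensity=cyto,
        fractional_recovery=fractional_recovery(traces.bleached, traces.sched),
        final_diff=final_unbleached_minus_bleached(traces),
        recovery_class=classify_recovery_speed(traces),
    )
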
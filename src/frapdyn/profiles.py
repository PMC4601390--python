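"""From raw image stacks to normalized 1-D profiles and FRAP curves.

Pixel conventions: rectangles are (x0, y0, width, height) in 0-based pixel
coordinates, half-open. Frame numbering is 1-based at the user interface
(matching the acquisition software's "images 4 to 20") and 0-based in array
indices; conversion happens here, at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .model import (
    PIXEL_SIZE_UM,
    AcquisitionSchedule,
    FrapCurve,
    GaussianBleach,
)

__all__ = [
    "ImageSeries",
    "RegionSpec",
    "NormalizedProfile",
    "estimate_background",
    "extract_x_profile",
    "normalize_to_prebleach",
    "isolate_bleach_profile",
    "fit_gaussian_postbleach",
]

ROLES = ("bleached_tip", "unbleached_tip", "cytoplasm", "background", "bleach_strip")


@dataclass(frozen=True)
class RegionSpec:
    """Axis-aligned pixel rectangle with a role label."""

    x0: int
    y0: int
    width: int
    height: int
    role: str = "bleach_strip"

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("region must be at least 1x1 pixels")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("region origin must be non-negative")
        if self.role not in ROLES:
            raise ValueError(f"unknown region role {self.role!r}")

    @property
    def x_slice(self) -> slice:
        return slice(self.x0, self.x0 + self.width)

    @property
    def y_slice(self) -> slice:
        return slice(self.y0, self.y0 + self.height)

    def x_interval_um(self, pixel_size_um: float, origin_um: float = 0.0) -> tuple[float, float]:
        """Closed micrometre interval spanned by the rectangle along X."""
        return (origin_um + self.x0 * pixel_size_um,
                origin_um + (self.x0 + self.width) * pixel_size_um)


@dataclass
class ImageSeries:
    """A T x Y x X time-lapse stack on an 8-bit intensity scale.

    X is the fibre long axis (or the tip's long axis X_T); Y is transverse.
    ``x_origin_um`` places pixel column 0 in cell coordinates so that profile
    positions agree with the model cell.
    """

    data: np.ndarray
    pixel_size_um: float = PIXEL_SIZE_UM
    frame_times_s: np.ndarray | None = None
    x_origin_um: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("image series must be a T x Y x X array")
        if self.data.shape[0] < 21:
            raise ValueError("series must include the 20-frame pre-bleach phase")
        if self.data.min() < 0 or self.data.max() > 255:
            raise ValueError("intensities must lie on the 8-bit scale [0, 255]")
        if self.frame_times_s is not None:
            self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
            if self.frame_times_s.size != self.data.shape[0]:
                raise ValueError("frame_times_s length must match frame count")

    @classmethod
    def from_tiff(cls, path, **kw) -> "ImageSeries":
        import tifffile

        return cls(tifffile.imread(path), **kw)

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    def saturated_fraction(self) -> float:
        """Fraction of saturated (255) pixels; saturation is flagged, not clipped."""
        return float((self.data >= 255).mean())

    def region_trace(self, region: RegionSpec, background: float = 0.0) -> np.ndarray:
        """Background-subtracted mean intensity of a region per frame."""
        self._check_bounds(region)
        block = self.data[:, region.y_slice, region.x_slice]
        return block.mean(axis=(1, 2)) - background

    def _check_bounds(self, region: RegionSpec) -> None:
        t, ny, nx = self.data.shape
        if region.x0 + region.width > nx or region.y0 + region.height > ny:
            raise ValueError("region exceeds image bounds")


@dataclass
class NormalizedProfile:
    """Intensity along X divided by the pre-bleach average profile."""

    x_um: np.ndarray
    values: np.ndarray
    frame: int  # 1-based frame number

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.x_um.shape != self.values.shape:
            raise ValueError("x and values must have the same shape")


def estimate_background(series: ImageSeries, bg_region: RegionSpec,
                        window: tuple[int, int] = (4, 20)) -> float:
    """Mean intensity of a region outside the cell over pre-bleach frames.

    ``window`` is 1-based inclusive (the protocol uses images 4-20).
    """
    series._check_bounds(bg_region)
    lo, hi = window
    if not 1 <= lo <= hi <= series.n_frames:
        raise ValueError("background window outside the series")
    block = series.data[lo - 1:hi, bg_region.y_slice, bg_region.x_slice]
    if block.size == 0:
        raise ValueError("background region is empty")
    return float(block.mean())


def extract_x_profile(series: ImageSeries, strip: RegionSpec, frame: int,
                      background: float = 0.0,
                      average_3_frames: bool = False) -> NormalizedProfile:
    """Background-subtracted intensity versus X, averaged over the strip's Y extent.

    ``frame`` is 1-based. With ``average_3_frames`` the previous, given and
    next frames are averaged (the convention used for lateral-mobility
    profiles); at a sequence edge the available frames are used and a warning
    is issued. Negative background-subtracted values are retained.
    """
    series._check_bounds(strip)
    if not 1 <= frame <= series.n_frames:
        raise ValueError("frame outside the series")
    i = frame - 1
    if average_3_frames:
        lo, hi = i - 1, i + 2
        if lo < 0 or hi > series.n_frames:
            warnings.warn("3-frame averaging at sequence edge: using available frames")
            lo, hi = max(lo, 0), min(hi, series.n_frames)
        frames = series.data[lo:hi]
    else:
        frames = series.data[i:i + 1]
    prof = frames[:, strip.y_slice, strip.x_slice].mean(axis=(0, 1)) - background
    x = series.x_origin_um + (strip.x0 + np.arange(strip.width) + 0.5) * series.pixel_size_um
    return NormalizedProfile(x, prof, frame=frame)


def normalize_to_prebleach(series: ImageSeries, strip: RegionSpec,
                           sched: AcquisitionSchedule, background: float,
                           readout: RegionSpec | None = None,
                           ) -> tuple[list[NormalizedProfile], FrapCurve]:
    """Divide every frame's X-profile by the pre-bleach average profile.

    Returns the normalized profiles of all frames and the FRAP curve: the
    mean normalized value over the bleached readout region per post-bleach
    frame. Grid positions where the pre-bleach average is non-positive
    (over-subtracted background) are masked with NaN and a warning is issued.
    """
    series._check_bounds(strip)
    pre = sched.prebleach_indices()
    raw = series.data[:, strip.y_slice, strip.x_slice].mean(axis=1) - background
    baseline = raw[pre].mean(axis=0)
    bad = baseline <= 0
    if bad.any():
        warnings.warn(f"pre-bleach average non-positive at {int(bad.sum())} positions; masked")
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(bad[None, :], np.nan, raw / baseline[None, :])
    x = series.x_origin_um + (strip.x0 + np.arange(strip.width) + 0.5) * series.pixel_size_um
    profiles = [NormalizedProfile(x, norm[i], frame=i + 1)
                for i in range(series.n_frames)]

    if readout is None:
        readout = strip
    if not (strip.x0 <= readout.x0 and
            readout.x0 + readout.width <= strip.x0 + strip.width):
        raise ValueError("readout region must lie within the profile strip")
    cols = slice(readout.x0 - strip.x0, readout.x0 - strip.x0 + readout.width)
    post = sched.postbleach_indices()
    curve_vals = np.nanmean(norm[:, cols], axis=1)[post]
    curve = FrapCurve(sched.frame_times_s[post], curve_vals,
                      first_frame=sched.bleach_after_frame + 1)
    return profiles, curve


def isolate_bleach_profile(profiles: list[NormalizedProfile],
                           sched: AcquisitionSchedule) -> NormalizedProfile:
    """First post-bleach profile divided pointwise by the last pre-bleach one.

    Both profiles carry the same imaging-bleach history and field-of-view
    replenishment structure, which the ratio cancels pointwise, leaving the
    intentional-bleach dip (already smeared by diffusion during the
    bleaching phase) on a flat baseline — the cleanest input for the
    Gaussian fit. The ratio's far field sits at about (1 - beta), which the
    fit's free far-field level absorbs.
    """
    post = profiles[sched.bleach_after_frame]
    pre = profiles[sched.bleach_after_frame - 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = post.values / pre.values
    return NormalizedProfile(post.x_um, ratio, frame=post.frame)


def fit_gaussian_postbleach(profile: NormalizedProfile,
                            cell_length_um: float | None = None) -> tuple[GaussianBleach, dict]:
    """Least-squares Gaussian fit to the first post-bleach normalized profile.

    Returns a Gaussian with A0 = 1 whose depth C0, centre X0 and width sigma
    are expressed relative to the profile's own far-field level. The
    far-field level is estimated as a free nuisance parameter (it sits
    slightly below 1 whenever the pre-bleach frames themselves bleach) and
    is reported in the diagnostics as ``far_field``; pinning it to exactly 1
    instead would leak the offset into sigma and C0 and bias the diffusion
    fit. Returns the Gaussian and a diagnostics dict with the residual sum
    of squares and flags. A fit with C0 <= 0 raises no error but sets the
    ``no_bleach_detected`` flag.
    """
    x = profile.x_um
    y = profile.values
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 5:
        raise ValueError("too few valid points for a Gaussian fit")
    if cell_length_um is None:
        cell_length_um = float(x[-1] - x[0] + (x[1] - x[0]))

    # Initialisation: centre at the minimum, depth from the minimum value,
    # sigma from the half-depth width.
    i_min = int(np.argmin(y))
    c0_init = max(1.0 - float(y[i_min]), 1e-3)
    half = 1.0 - c0_init / 2.0
    below = np.flatnonzero(y <= half)
    if below.size >= 2:
        sigma_init = max((x[below[-1]] - x[below[0]]) / 2.355, x[1] - x[0])
    else:
        sigma_init = 10 * (x[1] - x[0])

    def gauss(xv, a0, c0, x0, sig):
        return a0 - c0 * np.exp(-((xv - x0) ** 2) / (2.0 * sig ** 2))

    diagnostics: dict = {"converged": True, "no_bleach_detected": False}
    try:
        popt, _ = curve_fit(
            gauss, x, y, p0=[1.0, c0_init, x[i_min], sigma_init],
            bounds=([0.5, -0.5, x[0] - cell_length_um, 1e-6],
                    [1.5, 1.5, x[-1] + cell_length_um, cell_length_um]),
            maxfev=10000)
    except RuntimeError as err:  # non-convergence
        diagnostics["converged"] = False
        diagnostics["message"] = str(err)
        popt = [1.0, c0_init, x[i_min], sigma_init]
    a0, c0, x0, sigma = (float(v) for v in popt)
    if c0 <= 1e-6:  # depth indistinguishable from none on a normalized scale
        diagnostics["no_bleach_detected"] = True
        c0 = max(c0, 0.0)
    resid = y - gauss(x, a0, c0, x0, sigma)
    diagnostics["sum_of_squares"] = float(np.sum(resid ** 2))
    diagnostics["far_field"] = a0
    gb = GaussianBleach(C0=min(c0 / a0, 1.0), X0=x0, sigma=sigma)
    return gb, diagnostics
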
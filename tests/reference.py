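"""Independent reference integrators used as oracles by the test suite.

Both take a numerical route disjoint from the production Crank-Nicolson
solver: a stability-limited explicit Euler scheme on a 10x finer grid for
single diffusion steps, and a cosine-spectral (DCT-II) propagator — exact in
time for Neumann diffusion — on a 10x finer grid for full FRAP curves with
per-frame imaging-bleach events.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dct, idct

from frapdyn.model import AcquisitionSchedule, CellGeometry, GaussianBleach


def explicit_euler_evolve(x: np.ndarray, values: np.ndarray, D: float,
                          dt_total: float, refine: int = 10) -> np.ndarray:
    """Pure diffusion with zero-flux ends, explicit Euler on a finer grid.

    Returns the evolved profile sampled back on the original grid.
    """
    n_fine = (x.size - 1) * refine + 1
    xf = np.linspace(x[0], x[-1], n_fine)
    v = np.interp(xf, x, values)
    dxf = xf[1] - xf[0]
    dt = 0.2 * dxf ** 2 / D  # well inside the 0.5 stability limit
    n_steps = int(np.ceil(dt_total / dt))
    dt = dt_total / n_steps
    r = D * dt / dxf ** 2
    for _ in range(n_steps):
        lap = np.empty_like(v)
        lap[1:-1] = v[2:] - 2.0 * v[1:-1] + v[:-2]
        lap[0] = 2.0 * (v[1] - v[0])
        lap[-1] = 2.0 * (v[-2] - v[-1])
        v = v + r * lap
    return np.interp(x, xf, v)


def spectral_frap_curve(D: float, beta: float, geom: CellGeometry,
                        sched: AcquisitionSchedule, init: GaussianBleach,
                        readout_region: tuple[float, float] | None = None,
                        refine: int = 10) -> np.ndarray:
    """Full post-bleach FRAP curve via an exact-in-time spectral propagator.

    Diffusion between frames is applied in the cosine basis (exact for
    Neumann boundaries); the imaging-bleach event multiplies the in-fov
    cells by (1 - beta) after each recorded frame, mirroring the production
    record-then-bleach convention. The readout is the trapezoidal interval
    average on the fine grid, the same definition the production solver
    uses, so the comparison isolates the solver.
    """
    L = geom.length_um
    coarse = geom.grid()
    n = (coarse.size - 1) * refine
    x = (np.arange(n) + 0.5) * L / n  # cell-centred fine grid for DCT-II
    v = init.evaluate(x)
    lo, hi = geom.fov_um
    fov = (x >= lo) & (x <= hi)
    if readout_region is None:
        readout_region = (init.X0 - init.sigma, init.X0 + init.sigma)
    r0, r1 = readout_region
    k = np.pi * np.arange(n) / L
    post = sched.postbleach_indices()
    times = sched.frame_times_s[post]
    out = np.empty(times.size)

    def interval_average(vv):
        inside = (x > r0) & (x < r1)
        xs = np.concatenate([[r0], x[inside], [r1]])
        vs = np.concatenate([[np.interp(r0, x, vv)], vv[inside],
                             [np.interp(r1, x, vv)]])
        return np.trapezoid(vs, xs) / (r1 - r0)

    for i in range(times.size):
        out[i] = interval_average(v)
        if i == times.size - 1:
            break
        v[fov] *= (1.0 - beta)
        coeff = dct(v, type=2, norm="ortho")
        coeff *= np.exp(-D * k ** 2 * (times[i + 1] - times[i]))
        v = idct(coeff, type=2, norm="ortho")
    return out
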
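import numpy as np
import pytest

from frapdyn import (
    AcquisitionSchedule,
    CellGeometry,
    GaussianBleach,
    ModelParams,
    SyntheticCellSpec,
    estimate_background,
    fit_diffusion_frap,
    fit_gaussian_postbleach,
    generate_cytoplasm_experiment,
    isolate_bleach_profile,
    normalize_to_prebleach,
)
from frapdyn.fitting import FitWindow


@pytest.fixture(scope="session")
def geom():
    return CellGeometry()


@pytest.fixture(scope="session")
def sched500():
    return AcquisitionSchedule.uniform(500)


@pytest.fixture(scope="session")
def sched200():
    return AcquisitionSchedule.uniform(200)


@pytest.fixture(scope="session")
def gaussian_init():
    return GaussianBleach(C0=0.5, X0=45.0, sigma=3.0)


def run_cytoplasm_pipeline(spec: SyntheticCellSpec, params: ModelParams,
                           sched: AcquisitionSchedule, bleach,
                           window: FitWindow, geom: CellGeometry | None = None):
    """Generate a cytoplasm movie and push it through the full analysis.

    Returns the FitResult, the fitted Gaussian, and the measured curve.
    """
    series, man = generate_cytoplasm_experiment(spec, params, sched, bleach=bleach)
    regs = man["regions"]
    bg = estimate_background(series, regs["background"])
    profiles, curve = normalize_to_prebleach(series, regs["cell_strip"], sched,
                                             bg, readout=regs["bleach_strip"])
    init, diag = fit_gaussian_postbleach(isolate_bleach_profile(profiles, sched),
                                         cell_length_um=spec.geometry.length_um)
    readout = regs["bleach_strip"].x_interval_um(series.pixel_size_um,
                                                 series.x_origin_um)
    fit_geom = geom if geom is not None else spec.geometry
    res = fit_diffusion_frap(curve, init, fit_geom, sched, window,
                             readout_region=readout)
    return res, init, curve
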
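"""Shared fixtures.

The expensive coupled simulations (reference air puff, open-system
control, internal-structure ablation) are session-scoped so the whole
suite pays for each of them once.
"""

import numpy as np
import pytest

from tonosim.airjet import JetConfig, coupled_airpuff
from tonosim.biomarkers import biomarker_report
from tonosim.config import default_config
from tonosim.prestress import zero_pressure_configuration
from tonosim.units import MMHG_TO_MPA
from tonosim.workbench import build_model, run_airpuff, run_prestress


@pytest.fixture(scope="session")
def reference_cfg():
    return default_config()


@pytest.fixture(scope="session")
def reference_run(reference_cfg):
    """Prestressed, inflated reference model plus its coupled air puff."""
    model, prestress_result, state = run_prestress(reference_cfg)
    inflated = state.copy()
    model, history, report = run_airpuff(reference_cfg, model=model,
                                         state=state)
    return {"model": model, "prestress": prestress_result,
            "inflated": inflated, "history": history, "report": report,
            "cfg": reference_cfg}


@pytest.fixture(scope="session")
def constant_pressure_history(reference_run):
    """Open-system control: humors held at 15 mmHg during the puff."""
    cfg = reference_run["cfg"]
    _, history, _ = run_airpuff(cfg, model=reference_run["model"],
                                state=reference_run["inflated"],
                                constant_pressure_cavities=True)
    return history


@pytest.fixture(scope="session")
def doe_fraction(reference_cfg):
    """Quarter-fraction (8-run) factorial smoke batch at coarse scale."""
    from tonosim.workbench import run_doe
    return run_doe(reference_cfg, fraction=4)


@pytest.fixture(scope="session")
def mesh_convergence(reference_cfg):
    from tonosim.workbench import run_convergence
    return run_convergence(reference_cfg, n_range=(3, 4, 5))


@pytest.fixture(scope="session")
def ablation_reports(reference_run):
    """Biomarkers with internals (reference run) and without them."""
    from dataclasses import replace

    from tonosim.config import RunConfig
    cfg = reference_run["cfg"]
    rep = reference_run["report"]
    with_internals = {"max_iop": rep.max_iop,
                      "deflection_amplitude": rep.deflection_amplitude,
                      "peak_distance": rep.peak_distance}
    geometry = replace(cfg.geometry, include_internals=False)
    mats = {k: v for k, v in cfg.materials.items()
            if k in ("cornea", "limbus", "sclera")}
    rcfg = RunConfig(geometry=geometry, materials=mats, solver=cfg.solver,
                     jet=cfg.jet, schedule=cfg.schedule,
                     resolution=cfg.resolution)
    _, _, rep2 = run_airpuff(rcfg)
    without = {"max_iop": rep2.max_iop,
               "deflection_amplitude": rep2.deflection_amplitude,
               "peak_distance": rep2.peak_distance}
    return with_internals, without
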
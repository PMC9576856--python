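"""Pipeline orchestration: build the model, run scenarios, drive studies.

Ties the modules together behind a handful of entry points used by both
the command-line interface and programmatic callers:

* :func:`build_model` — mesh + materials + solver from a RunConfig;
* :func:`run_prestress` — zero-pressure recovery and inflation;
* :func:`run_airpuff` — the full reference pipeline to a biomarker report;
* :func:`doe_runner` / :func:`run_doe` — factorial sensitivity batches;
* :func:`run_ablation` — internal-structure influence comparison;
* :func:`run_convergence` — through-thickness mesh refinement study.
"""

from __future__ import annotations

import logging
import time
from dataclasses import replace

import numpy as np

from . import doe
from .airjet import JetConfig, coupled_airpuff, surface_pressure_field
from .biomarkers import SimulationHistory, biomarker_report
from .config import RunConfig, default_config
from .eye_model import build_eye_mesh
from .fem_engine import Model, solve_quasi_static
from .materials import (HGOMaterial, HGOParams, LinearElasticParams,
                        NeoHookeanMaterial, NeoHookeanParams,
                        StVenantKirchhoffMaterial)
from .prestress import inflate_to_iop, zero_pressure_configuration
from .units import MMHG_TO_MPA

log = logging.getLogger("tonosim")


def _material_object(params, context=""):
    if isinstance(params, HGOParams):
        return HGOMaterial(params, context)
    if isinstance(params, NeoHookeanParams):
        return NeoHookeanMaterial(params, context)
    if isinstance(params, LinearElasticParams):
        return params if context in ("zonule", "vitreous_membrane") \
            else StVenantKirchhoffMaterial(params, context)
    raise TypeError(type(params))


def build_model(cfg: RunConfig = None) -> Model:
    """Mesh the configured geometry and attach materials and solver."""
    cfg = cfg or default_config()
    mesh = build_eye_mesh(cfg.geometry, cfg.resolution.n_thickness,
                          cfg.resolution.surface)
    mats = {}
    for part, params in cfg.materials.items():
        if part in ("zonule", "vitreous_membrane"):
            mats[part] = params
        else:
            mats[part] = _material_object(params, part)
    solver = replace(cfg.solver, dt=cfg.resolution.dt)
    return Model(mesh, mats, solver=solver,
                 membrane_thickness=cfg.geometry.membrane_thickness)


def run_prestress(cfg: RunConfig = None, model: Model = None,
                  freeze_internals=True, tol=1e-3):
    """Zero-pressure recovery followed by inflation to the target IOP."""
    cfg = cfg or default_config()
    model = model or build_model(cfg)
    t0 = time.perf_counter()
    result, state = zero_pressure_configuration(
        model, cfg.schedule.target_iop_mmhg, tol=tol,
        freeze_internals=freeze_internals)
    log.info("prestress: %d iterations, residual %.2e mm, %.1f s",
             result.iterations, result.final_error, time.perf_counter() - t0)
    return model, result, state


def run_airpuff(cfg: RunConfig = None, model=None, state=None,
                constant_pressure_cavities=False):
    """Reference pipeline: prestress, inflate, coupled puff, biomarkers.

    With ``constant_pressure_cavities`` the humors are held at the target
    IOP throughout (the open-system control condition) instead of being
    closed after inflation.
    """
    cfg = cfg or default_config()
    if model is None or state is None:
        model, _, state = run_prestress(cfg)
    state = state.copy()
    if constant_pressure_cavities:
        for c in state.cavities.values():
            c.mode = "constant"
            c.p = cfg.schedule.target_iop_mmhg * MMHG_TO_MPA
    t0 = time.perf_counter()
    hist = coupled_airpuff(model, state, cfg.jet,
                           t_end=cfg.schedule.record_end,
                           dt=cfg.resolution.dt)
    if cfg.corvis_sampling:
        hist = hist.downsample()
    log.info("air puff: %d frames, %.1f s", len(hist.times),
             time.perf_counter() - t0)
    report = biomarker_report(hist)
    return model, hist, report


# ---------------------------------------------------------------------------
# factorial sensitivity
# ---------------------------------------------------------------------------

def apply_factors(cfg: RunConfig, row) -> RunConfig:
    """Reference config with one design row's factor levels substituted."""
    mats = dict(cfg.materials)
    cornea = cfg.materials["cornea"]
    pars = dict(C10=cornea.C10, k1=cornea.k1, k2=cornea.k2)
    if "C10_c" in row:
        pars["C10"] = float(row["C10_c"])
    if "k1" in row:
        pars["k1"] = float(row["k1"])
    if "k2" in row:
        pars["k2"] = float(row["k2"])
    hgo = HGOParams(rho=cornea.rho, **pars)
    mats["cornea"] = hgo
    mats["limbus"] = hgo
    if "C10_s" in row:
        mats["sclera"] = NeoHookeanParams(C10=float(row["C10_s"]),
                                          rho=cfg.materials["sclera"].rho)
    schedule = cfg.schedule
    if "IOP" in row:
        schedule = replace(schedule, target_iop_mmhg=float(row["IOP"]))
    new = RunConfig(geometry=cfg.geometry, materials=mats, solver=cfg.solver,
                    jet=cfg.jet, schedule=schedule,
                    resolution=cfg.resolution,
                    corvis_sampling=cfg.corvis_sampling)
    return new


def doe_runner(cfg: RunConfig = None, prestress_tol=5e-3,
               record_end=56.0):
    """Runner callable for :func:`tonosim.doe.run_batch`.

    Each design row gets the full pipeline at the configured (coarse)
    resolution.  For throughput the energy ledger is disabled, the
    prestress tolerance relaxed, and the recording stops shortly after
    the concavity peak: the examined biomarkers (deflection amplitude,
    peak distance, apex air pressure) are all evaluated at HC, so the
    recovery tail is not needed.  The resolution is recorded in every row.
    """
    from .biomarkers import hc_markers
    cfg = cfg or default_config()
    base_sched = replace(cfg.schedule,
                         record_end=max(record_end,
                                        cfg.schedule.puff_end - 4.0))
    cfg = RunConfig(geometry=cfg.geometry, materials=cfg.materials,
                    solver=replace(cfg.solver, track_energy=False),
                    jet=cfg.jet, schedule=base_sched,
                    resolution=replace(cfg.resolution, n_thickness=2),
                    corvis_sampling=cfg.corvis_sampling)

    def run(row):
        rcfg = apply_factors(cfg, row)
        model, _, state = run_prestress(rcfg, tol=prestress_tol)
        t0 = time.perf_counter()
        hist = coupled_airpuff(model, state, rcfg.jet,
                               t_end=rcfg.schedule.record_end,
                               dt=rcfg.resolution.dt)
        log.info("doe run: %.1f s", time.perf_counter() - t0)
        mk = hc_markers(hist)
        mk["resolution"] = (f"{rcfg.resolution.surface}"
                            f"/nt{rcfg.resolution.n_thickness}")
        return mk

    return run


def run_doe(cfg: RunConfig = None, factors=None, fraction=None,
            progress=None):
    """Full (or fractional) factorial batch; returns (design, responses).

    ``fraction = 4`` runs the balanced 8-run 2^(5-2) smoke subset instead
    of the full 32-run design.
    """
    factors = factors or doe.FactorSpec.defaults()
    if fraction:
        design = doe.fractional_factorial(factors)
    else:
        design = doe.full_factorial(factors)
    responses = doe.run_batch(design, doe_runner(cfg), progress=progress)
    return design, responses


# ---------------------------------------------------------------------------
# ablation and mesh convergence
# ---------------------------------------------------------------------------

def run_ablation(cfg: RunConfig = None) -> doe.AblationReport:
    """Air-puff biomarkers with vs without the internal structures."""
    cfg = cfg or default_config()

    def one(include_internals):
        geometry = replace(cfg.geometry, include_internals=include_internals)
        mats = cfg.materials if include_internals else {
            k: v for k, v in cfg.materials.items()
            if k in ("cornea", "limbus", "sclera")}
        rcfg = RunConfig(geometry=geometry, materials=mats,
                         solver=cfg.solver, jet=cfg.jet,
                         schedule=cfg.schedule, resolution=cfg.resolution,
                         corvis_sampling=cfg.corvis_sampling)
        _, hist, rep = run_airpuff(rcfg)
        return {"max_iop": rep.max_iop,
                "deflection_amplitude": rep.deflection_amplitude,
                "peak_distance": rep.peak_distance}

    return doe.ablation_compare(one)


def run_convergence(cfg: RunConfig = None, n_range=(3, 4, 5, 6),
                    apex_pressure_mmhg=60.0) -> doe.MeshConvergenceReport:
    """Through-thickness refinement study on the static-indentation problem.

    For each layer count: recover the zero-pressure shape, inflate to the
    target IOP with closed cavities, then apply the peak-velocity jet
    footprint as a static load and record the apex displacement.
    """
    cfg = cfg or default_config()
    # static indentation load: jet footprint scaled so the apex pressure
    # stays moderate (no dynamic snap-through in a static solve)
    v_eff = float(np.sqrt(2.0 * (apex_pressure_mmhg / cfg.jet.confinement_gain)
                          * MMHG_TO_MPA / cfg.jet.rho_air))
    disp = []
    for nt in n_range:
        rcfg = RunConfig(geometry=cfg.geometry, materials=cfg.materials,
                         solver=cfg.solver, jet=cfg.jet,
                         schedule=cfg.schedule,
                         resolution=replace(cfg.resolution, n_thickness=nt),
                         corvis_sampling=False)
        model, _, state = run_prestress(rcfg)
        x = model.X + state.u
        field = surface_pressure_field(
            x, model.mesh.outer_faces, v_eff, cfg.jet,
            model.mesh.meridian_nodes)
        st2 = solve_quasi_static(model, jet=(model.mesh.outer_faces,
                                             field.pressures),
                                 u0=state.u, cavities=state.cavities,
                                 n_steps=6)
        d = float(state.u[model.mesh.apex_node, 1]
                  - st2.u[model.mesh.apex_node, 1])
        log.info("convergence: n_thickness=%d apex displacement %.4f mm",
                 nt, d)
        disp.append(d)
    return doe.MeshConvergenceReport(n_thickness=list(n_range),
                                     apex_displacement=disp)
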
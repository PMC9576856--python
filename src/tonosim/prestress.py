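"""Zero-pressure configuration recovery and inflation to the target IOP.

The imaged (built) geometry corresponds to the eye pressurized at the in
vivo intraocular pressure, so simulations must start from the unknown
stress-free shape.  The classic fixed-point scheme recovers it: inflate
the current guess of the reference configuration, subtract the mismatch
with the target geometry from the guess, and repeat,

    X_{k+1} = X_k - (x(X_k) - x_target),

until the maximum nodal mismatch drops below tolerance.  Re-inflating
the converged reference reproduces the imaged geometry (the round-trip
property that defines the algorithm).

Inflation itself uses the humor cavities in inflow mode: a positive
input flow rate grows the tracked cavity volume, the penalty relation
p = Kc (V_target - V) sets the pressure, and once the target IOP is
reached the volumes are closed so the humors behave as trapped
incompressible fluids for the rest of the simulation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError
from .fem_engine import Model, SystemState, _solve_newton, solve_quasi_static
from .units import MMHG_TO_MPA, MPA_TO_MMHG


@dataclass
class PrestressResult:
    reference_nodes: np.ndarray      # zero-pressure nodal coordinates [mm]
    iterations: int
    final_error: float               # max nodal mismatch [mm]
    inflated_checksum: str           # sha1 of the re-inflated geometry
    history: list                    # per-iteration max error


def inflate_to_iop(model: Model, target_iop_mmhg: float = 15.0,
                   tol_mmhg: float = 0.05, max_steps: int = 40,
                   u0=None) -> SystemState:
    """Inflate the cavities with an inflow controller up to the target IOP.

    Starting from zero pressure, the tracked cavity volumes are grown (a
    positive input flow rate) until the penalty pressure reaches the
    target within ``tol_mmhg``; the cavities are then switched to closed
    mode, conserving their volumes.  Returns the equilibrium state.
    """
    p_target = target_iop_mmhg * MMHG_TO_MPA
    u = np.zeros((model.n_nodes, 3)) if u0 is None else u0.copy()
    cavs = model.make_cavities(mode="inflow")
    if abs(target_iop_mmhg) < 1e-12:
        state = SystemState(u=u, v=np.zeros_like(u), a=np.zeros_like(u),
                            cavities=cavs)
        for c in state.cavities.values():
            c.mode = "closed"
            c.V_closed = c.V
        return state

    # secant estimate of dp/dV_target per cavity, refreshed every solve;
    # the per-cavity gains ignore the cross-coupling through the shared
    # shell, so the loop only needs to land near the target -- the exact
    # equilibrium at the target pressure is enforced by the closing trim
    loop_tol = max(tol_mmhg, 0.5)
    gain = {n: c.Kc * 0.5 for n, c in cavs.items()}
    last = {n: (cavs[n].V_target, cavs[n].p) for n in cavs}
    for it in range(max_steps):
        try:
            u_new, cavs_new, _ = _solve_newton(model, u, cavs)
        except ConvergenceError:
            # inflow step too aggressive: retreat half-way and retry
            for n, c in cavs.items():
                c.V_target = 0.5 * (c.V_target + last[n][0])
            continue
        u, cavs = u_new, cavs_new
        done = all(abs(c.p - p_target) * MPA_TO_MMHG <= loop_tol
                   for c in cavs.values())
        if done:
            break
        for n, c in cavs.items():
            Vt0, p0 = last[n]
            if abs(c.V_target - Vt0) > 1e-12 and c.p != p0:
                g = (c.p - p0) / (c.V_target - Vt0)
                if g > 1e-8:
                    gain[n] = g
            last[n] = (c.V_target, c.p)
            # limited secant step toward the target pressure
            dV = (p_target - c.p) / gain[n]
            dV = np.clip(dV, -0.05 * c.V0, 0.05 * c.V0)
            c.V_target += dV
    else:
        raise ConvergenceError(
            f"inflation controller did not reach {target_iop_mmhg} mmHg")

    # trim to the exact target pressure before closure (the controller
    # lands within tol_mmhg; the closing equilibrium is at the target)
    for c in cavs.values():
        c.mode = "constant"
        c.p = p_target
    u, cavs, _ = _solve_newton(model, u, cavs)
    for c in cavs.values():
        c.mode = "closed"
        c.V_closed = c.V
    state = SystemState(u=u, v=np.zeros_like(u), a=np.zeros_like(u),
                        cavities=cavs)
    return state


def _inflate_pressure_ramp(model, target_iop_mmhg, n_steps=3):
    """Pressure-controlled inflation (inner loop of the prestress search)."""
    p = target_iop_mmhg * MMHG_TO_MPA
    targets = {name: p for name in model.mesh.cavity_faces}
    return solve_quasi_static(model, cavity_targets=targets, n_steps=n_steps)


def zero_pressure_configuration(model: Model, target_iop_mmhg: float = 15.0,
                                tol: float = 1e-3, max_iter: int = 20,
                                freeze_internals: bool = True) -> tuple:
    """Recover the stress-free reference of the imaged (inflated) geometry.

    Mutates ``model`` so its reference coordinates become the zero-pressure
    configuration, and returns ``(PrestressResult, inflated_state)`` where
    the state re-inflates the reference to the target IOP (cavities closed,
    ready for the air puff).

    With ``freeze_internals`` (default) the fixed-point update is applied
    to the corneo-scleral shell only and convergence is measured there:
    the nearly-floating soft internals (lens on its zonule) make the
    fixed-point map non-contractive, while their own prestress deformation
    is mechanically irrelevant (they settle freely during inflation).

    ``target_iop_mmhg = 0`` returns immediately (the imaged geometry is
    already stress free).
    """
    X_target = model.mesh.nodes.copy()
    if freeze_internals and len(model.spring_nodes):
        update_nodes = np.setdiff1d(np.arange(model.n_nodes),
                                    model.spring_nodes)
    else:
        update_nodes = np.arange(model.n_nodes)
    if abs(target_iop_mmhg) < 1e-12:
        state = inflate_to_iop(model, 0.0)
        checksum = _geometry_checksum(model.X)
        return (PrestressResult(model.X.copy(), 0, 0.0, checksum, []), state)

    X_k = X_target.copy()
    relax = 1.0
    err_prev = np.inf
    grow_count = 0
    history = []
    state = None
    for k in range(1, max_iter + 1):
        model.set_reference(X_k)
        state = _inflate_pressure_ramp(model, target_iop_mmhg)
        x = X_k + state.u
        mismatch = np.zeros_like(x)
        mismatch[update_nodes] = (x - X_target)[update_nodes]
        err = float(np.abs(mismatch[update_nodes]).max())
        history.append(err)
        if err < tol:
            break
        if err > err_prev:
            grow_count += 1
            if grow_count >= 2:
                relax *= 0.5
                grow_count = 0
                if relax < 0.05:
                    raise ConvergenceError(
                        "zero-pressure iteration diverged")
        err_prev = err
        X_k = X_k - relax * mismatch
    else:
        raise ConvergenceError(
            f"zero-pressure search: error {err:.2e} mm after {max_iter} "
            f"iterations (tol {tol:g})")

    # final authoritative inflation through the inflow controller
    state = inflate_to_iop(model, target_iop_mmhg)
    checksum = _geometry_checksum(model.X + state.u)
    result = PrestressResult(reference_nodes=model.X.copy(), iterations=k,
                             final_error=err, inflated_checksum=checksum,
                             history=history)
    return result, state


def _geometry_checksum(x):
    return hashlib.sha1(np.round(np.asarray(x), 6).tobytes()).hexdigest()
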
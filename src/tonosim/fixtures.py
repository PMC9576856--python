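"""Deterministic synthetic fixtures for offline testing.

Three kinds are supported, each generated from a known ground truth so
downstream modules can be validated without any simulation:

* ``stress_strain_curves`` — uniaxial stress-stretch curves sampled from
  the anisotropic constitutive law (fibre and off-fibre orientations),
  with optional multiplicative noise; used to validate parameter fitting.
* ``profile_history`` — a constructed deformation-profile time series
  with prescribed applanation instants, deflection amplitude and peak
  distance; used to validate biomarker extraction.
* ``doe_response_table`` — responses from a stated linear + interaction
  generative model on a coded factorial design; used to validate the
  effect/ANOVA machinery.

The same seed always yields bit-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import doe
from .biomarkers import ProfileFrame, SimulationHistory
from .materials import HGOParams, uniaxial_stress


@dataclass(frozen=True)
class FixtureSpec:
    kind: str                        # see module docstring
    seed: int = 0
    noise: float = 0.0               # multiplicative noise level
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("stress_strain_curves", "profile_history",
                             "doe_response_table"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def generate_fixture(spec: FixtureSpec):
    """Dispatch to the requested generator; see the per-kind functions."""
    if spec.kind == "stress_strain_curves":
        return stress_strain_curves(seed=spec.seed, noise=spec.noise,
                                    **spec.params)
    if spec.kind == "profile_history":
        return profile_history(seed=spec.seed, noise=spec.noise,
                               **spec.params)
    return doe_response_table(seed=spec.seed, noise=spec.noise,
                              **spec.params)


def stress_strain_curves(params: HGOParams = None, orientations=(0.0, 90.0),
                         stretch_max=1.08, n_points=12, noise=0.0, seed=0):
    """Uniaxial curves from the closed-form constitutive response.

    Returns a DataFrame with columns ``stretch, stress_MPa,
    orientation_deg`` (the fitter's CSV schema) plus the generating
    parameters as attrs.
    """
    params = params or HGOParams()
    rng = np.random.default_rng(seed)
    lam = np.linspace(1.005, stretch_max, n_points)
    rows = []
    for o in orientations:
        s = uniaxial_stress(lam, params, o)
        if noise > 0:
            s = s * (1.0 + noise * rng.standard_normal(len(s)))
        for l, v in zip(lam, s):
            rows.append({"stretch": l, "stress_MPa": v,
                         "orientation_deg": o})
    df = pd.DataFrame(rows)
    df.attrs["params"] = params
    return df


def profile_history(da=1.0, peak_pos=2.5, peak_height=0.12, t_hc=50.0,
                    width_ms=6.0, n_frames=41, half_width=4.0, n_arc=33,
                    base_radius=7.8, noise=0.0, seed=0):
    """Constructed profile-frame series with known DA, PD and events.

    The anterior profile is a spherical cap of radius ``base_radius``
    deformed by a central Gaussian dent whose amplitude follows a
    Gaussian pulse in time peaking at ``t_hc`` with value ``da``; a rim
    bump of height ``peak_height`` at ``+/- peak_pos`` provides the
    bending peaks (their exact positions follow from the analytic
    profile, slightly inside ``+/- peak_pos`` because of the spherical
    base curvature).
    """
    rng = np.random.default_rng(seed)
    x = np.linspace(-half_width, half_width, n_arc)
    base = np.sqrt(base_radius ** 2 - x ** 2) - base_radius    # apex at 0
    t = np.linspace(t_hc - 10.0, t_hc + 10.0, n_frames)
    frames = []
    apex = []
    for ti in t:
        amp = da * np.exp(-0.5 * ((ti - t_hc) / (width_ms / 2.355)) ** 2)
        dent = -amp * np.exp(-(x / (0.6 * peak_pos)) ** 2)
        rim = (amp / da) * peak_height * (
            np.exp(-((x - peak_pos) / 0.7) ** 2)
            + np.exp(-((x + peak_pos) / 0.7) ** 2))
        y = base + dent + rim
        if noise > 0:
            y = y + noise * rng.standard_normal(len(y))
        frames.append(ProfileFrame(time=ti, arc=x, elevation=y))
        apex.append([0.0, dent[np.argmin(np.abs(x))], 0.0])
    return SimulationHistory(times=t, apex_disp=np.asarray(apex),
                             frames=frames)


def doe_response_table(coefficients=(-2.0, 0.0, 0.0, -0.5, -4.0),
                       interactions=None, intercept=10.0, noise=0.0,
                       seed=0, factors=None):
    """Responses from a linear(+interaction) model on the coded design.

    ``response = intercept + sum_j c_j x_j + sum c_ab x_a x_b`` with the
    coded levels x in {-1, +1}; the contrast main effect of factor j is
    therefore exactly ``2 c_j``.  Returns (design, responses) frames.
    """
    rng = np.random.default_rng(seed)
    factors = factors or doe.FactorSpec.defaults()
    design = doe.full_factorial(factors)
    coded = design[[f"{f.name}_coded" for f in factors]].to_numpy(float)
    y = intercept + coded @ np.asarray(coefficients, float)
    for (a, b), c in (interactions or {}).items():
        ia = [f.name for f in factors].index(a)
        ib = [f.name for f in factors].index(b)
        y = y + c * coded[:, ia] * coded[:, ib]
    if noise > 0:
        y = y + noise * rng.standard_normal(len(y))
    responses = pd.DataFrame({"response": y, "failed": False},
                             index=design.index)
    return design, responses
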
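"""Experiment drivers: mesh convergence, factorial sensitivity, ablation.

The sensitivity study follows the classical two-level full-factorial
design: five factors (corneal matrix stiffness C10_c, fibre stiffness
k1, fibre nonlinearity k2, scleral matrix stiffness C10_s, and the IOP)
at a low and a high level, all 2^5 = 32 combinations.  The main effect
of a factor is mean(response | high) - mean(response | low); two-way
interaction effects use the standard +/- contrast product.  A Pearson
correlation matrix across the coded design and the responses summarizes
the directions of influence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, TonosimError

FACTOR_NAMES = ("C10_c", "k1", "k2", "C10_s", "IOP")

#: factor bounds: +/-50% around the reference values (C10_c 0.05 MPa,
#: k1 0.010 MPa, k2 100, C10_s 0.8 MPa, IOP 15 mmHg); the IOP span is
#: widened to the hypotonic-glaucomatous range 8-22 mmHg
DEFAULT_BOUNDS = {
    "C10_c": (0.025, 0.075),
    "k1": (0.005, 0.015),
    "k2": (50.0, 150.0),
    "C10_s": (0.4, 1.2),
    "IOP": (8.0, 22.0),
}


@dataclass(frozen=True)
class FactorSpec:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if self.name not in FACTOR_NAMES:
            raise ConfigError(f"unknown factor {self.name!r}")
        if not self.low < self.high:
            raise ConfigError(f"factor {self.name}: low must be below high")

    @classmethod
    def defaults(cls):
        return [cls(n, *DEFAULT_BOUNDS[n]) for n in FACTOR_NAMES]


def full_factorial(factors) -> pd.DataFrame:
    """All 2^k level combinations; one run per row, plus coded +/-1 columns."""
    factors = list(factors)
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate factor names")
    rows = []
    for signs in itertools.product((-1, 1), repeat=len(factors)):
        row = {}
        for s, f in zip(signs, factors):
            row[f.name] = f.low if s < 0 else f.high
            row[f"{f.name}_coded"] = s
        rows.append(row)
    df = pd.DataFrame(rows)
    df.index.name = "run"
    return df


def fractional_factorial(factors, generators=None) -> pd.DataFrame:
    """Regular 2^(5-2) fraction: 8 balanced runs over five factors.

    The first three factors form a full 2^3 base; the remaining two are
    generated as products of base columns (resolution III), so every
    factor still appears at each level in exactly half the runs.
    """
    factors = list(factors)
    if len(factors) != 5:
        raise ConfigError("the 2^(5-2) fraction needs exactly 5 factors")
    generators = generators or {3: (0, 1), 4: (0, 2)}
    base = list(itertools.product((-1, 1), repeat=3))
    rows = []
    for signs in base:
        coded = list(signs)
        for j in (3, 4):
            a, b = generators[j]
            coded.append(coded[a] * coded[b])
        row = {}
        for s, f in zip(coded, factors):
            row[f.name] = f.low if s < 0 else f.high
            row[f"{f.name}_coded"] = s
        rows.append(row)
    df = pd.DataFrame(rows)
    df.index.name = "run"
    return df


def run_batch(design: pd.DataFrame, runner, progress=None) -> pd.DataFrame:
    """Evaluate ``runner(row) -> dict`` of biomarkers for every design row.

    Individual failures are recorded (``failed = True``, reason kept) and
    the batch continues; nothing is silently dropped.
    """
    records = []
    for i, row in design.iterrows():
        rec = {"run": i}
        try:
            out = runner(row)
            rec.update(out)
            rec["failed"] = False
            rec["failure"] = ""
        except TonosimError as exc:
            rec["failed"] = True
            rec["failure"] = f"{type(exc).__name__}: {exc}"
        records.append(rec)
        if progress:
            progress(i, rec)
    return pd.DataFrame(records).set_index("run")


def main_effects(design: pd.DataFrame, responses: pd.DataFrame,
                 response_cols=None, interactions=(("C10_c", "IOP"),
                                                   ("C10_s", "IOP"))):
    """Contrast-based ANOVA effect table.

    Main effect = mean(high) - mean(low) on the coded design; interaction
    effects use the product contrast.  Also reports sums of squares
    (effect^2 * n / 4 for a two-level orthogonal design) and standardized
    effects (contrast / response standard deviation).
    """
    coded_cols = [c for c in design.columns if c.endswith("_coded")]
    if response_cols is None:
        response_cols = [c for c in responses.columns
                         if responses[c].dtype.kind == "f"]
    ok = ~responses["failed"] if "failed" in responses else \
        pd.Series(True, index=responses.index)
    X = design.loc[responses.index[ok], coded_cols].to_numpy(float)
    n = len(X)
    rows = []
    for resp in response_cols:
        y = responses.loc[responses.index[ok], resp].to_numpy(float)
        sd = float(np.std(y, ddof=1)) if n > 1 else np.nan
        for j, c in enumerate(coded_cols):
            hi, lo = X[:, j] > 0, X[:, j] < 0
            if not hi.any() or not lo.any():
                raise ConfigError(f"factor {c}: all runs at one level")
            eff = float(y[hi].mean() - y[lo].mean())
            rows.append({"response": resp, "source": c.replace("_coded", ""),
                         "kind": "main", "df": 1, "effect": eff,
                         "sum_sq": eff * eff * n / 4.0,
                         "standardized": eff / sd if sd else np.nan})
        for a, b in interactions or ():
            ia = coded_cols.index(f"{a}_coded")
            ib = coded_cols.index(f"{b}_coded")
            z = X[:, ia] * X[:, ib]
            eff = float(y[z > 0].mean() - y[z < 0].mean())
            rows.append({"response": resp, "source": f"{a}*{b}",
                         "kind": "interaction", "df": 1, "effect": eff,
                         "sum_sq": eff * eff * n / 4.0,
                         "standardized": eff / sd if sd else np.nan})
    return pd.DataFrame(rows)


def pearson_matrix(design: pd.DataFrame, responses: pd.DataFrame,
                   response_cols=None) -> pd.DataFrame:
    """Pearson correlation matrix between factors and responses.

    Zero-variance columns yield NaN entries (flagged, not erroring), the
    diagonal is exactly 1 elsewhere.
    """
    coded_cols = [c for c in design.columns if c.endswith("_coded")]
    if response_cols is None:
        response_cols = [c for c in responses.columns
                         if responses[c].dtype.kind == "f"]
    ok = ~responses["failed"] if "failed" in responses else \
        pd.Series(True, index=responses.index)
    tab = pd.concat([
        design.loc[responses.index[ok], coded_cols].rename(
            columns=lambda c: c.replace("_coded", "")),
        responses.loc[responses.index[ok], response_cols]], axis=1)
    return tab.corr(method="pearson")


def mesh_convergence_error(u_current: float, u_previous: float) -> float:
    """Percent change of the monitored displacement between two meshes.

    ``|u_c - u_p| / u_p * 100``; raises on a vanishing reference value.
    """
    if u_previous == 0:
        raise ZeroDivisionError("previous-mesh displacement is zero")
    return abs(u_current - u_previous) / abs(u_previous) * 100.0


@dataclass
class MeshConvergenceReport:
    n_thickness: list
    apex_displacement: list          # mm, one per resolution
    errors_percent: list = field(default_factory=list)

    def __post_init__(self):
        if not self.errors_percent:
            u = self.apex_displacement
            self.errors_percent = [
                mesh_convergence_error(u[i + 1], u[i])
                for i in range(len(u) - 1)]

    def to_frame(self):
        return pd.DataFrame({
            "n_thickness": self.n_thickness,
            "apex_displacement_mm": self.apex_displacement,
            "error_percent": [np.nan] + self.errors_percent})


@dataclass
class AblationReport:
    with_internals: dict             # biomarker name -> value
    without_internals: dict
    relative_differences: dict = None

    def __post_init__(self):
        if self.relative_differences is None:
            self.relative_differences = {
                k: abs(self.without_internals[k] - v) / abs(v) * 100.0
                for k, v in self.with_internals.items()}

    @property
    def max_difference_percent(self):
        return max(self.relative_differences.values())

    def to_frame(self):
        keys = list(self.with_internals)
        return pd.DataFrame({
            "biomarker": keys,
            "with_internals": [self.with_internals[k] for k in keys],
            "without_internals": [self.without_internals[k] for k in keys],
            "difference_percent": [self.relative_differences[k] for k in keys],
        })


def ablation_compare(runner) -> AblationReport:
    """Run the reference air puff with and without the internal structures.

    ``runner(include_internals) -> {"max_iop", "deflection_amplitude",
    "peak_distance"}``.  The without-model merges the humors into a single
    cavity (no lens, zonule or vitreous membrane).
    """
    with_int = runner(True)
    without = runner(False)
    return AblationReport(with_internals=with_int, without_internals=without)


def reduced_range_study(design_runner, iop_low=12.0, iop_high=15.0):
    """Factorial study over the physiological IOP range.

    Same machinery as the full-range design with the IOP factor narrowed
    to (iop_low, iop_high); returns (design, responses, effects).
    """
    factors = [FactorSpec(n, *DEFAULT_BOUNDS[n]) for n in FACTOR_NAMES[:-1]]
    factors.append(FactorSpec("IOP", iop_low, iop_high))
    design = full_factorial(factors)
    responses = design_runner(design)
    effects = main_effects(design, responses)
    return design, responses, effects
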
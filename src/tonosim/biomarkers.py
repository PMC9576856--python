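"""Corvis-style post-processing of deformation histories.

During the air pulse the cornea flattens (first applanation, A1), snaps
into a concave shape of maximal apex displacement (highest concavity,
HC), and flattens again on recovery (second applanation, A2).  The
biomarkers extracted here follow the clinical definitions: the
deflection amplitude (DA) is the apex displacement along the jet axis at
HC; the peak distance (PD) is the horizontal distance between the two
outward bending peaks of the anterior surface at HC.

The module works either on a :class:`SimulationHistory` produced by the
coupled air-puff driver or on standalone profile-frame series loaded
from CSV (columns ``time_ms, arc_mm, elevation_mm``), emulating the
instrument's 8 mm horizontal frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoApplanationError, NoConcavityError

#: half-width (mm) of the central band used for applanation flatness
FLAT_HALFWIDTH = 1.5
#: RMS deviation from the best-fit line below which the band counts as flat
FLAT_TOL_MM = 2e-3


@dataclass
class ProfileFrame:
    """Anterior-surface elevation along the central 8 mm meridian."""

    time: float                      # ms
    arc: np.ndarray                  # apex-centred positions [mm], increasing
    elevation: np.ndarray            # anterior elevation [mm]

    def __post_init__(self):
        self.arc = np.asarray(self.arc, float)
        self.elevation = np.asarray(self.elevation, float)
        if np.any(np.diff(self.arc) <= 0):
            raise ValueError("profile positions must be strictly increasing")


@dataclass
class SimulationHistory:
    """Time series emitted by the coupled air-puff simulation."""

    times: np.ndarray                           # ms
    apex_disp: np.ndarray                       # (nt, 3) apex displacement
    frames: list                                # ProfileFrame per instant
    cavity_pressure: dict = field(default_factory=dict)  # name -> mmHg array
    apex_air_pressure: np.ndarray = None        # mmHg
    jet_velocity: np.ndarray = None             # mm/ms
    cavity_volume_drift: dict = field(default_factory=dict)  # max rel drift
    energy: object = None                       # final EnergyLedger

    @property
    def apex_axial(self):
        """Inward apex displacement along the jet axis (positive)."""
        return -np.asarray(self.apex_disp)[:, 1]

    @property
    def iop(self):
        """Combined IOP trace (mmHg): maximum over the humor cavities."""
        if not self.cavity_pressure:
            return None
        return np.max(np.vstack(list(self.cavity_pressure.values())), axis=0)

    def downsample(self, n_frames=140, window=33.0):
        """Corvis-emulating resample: n frames over the recording window."""
        t0 = self.times[0]
        tt = np.linspace(t0, min(t0 + window, self.times[-1]), n_frames)
        idx = np.searchsorted(self.times, tt)
        idx = np.clip(idx, 0, len(self.times) - 1)
        return SimulationHistory(
            times=self.times[idx], apex_disp=self.apex_disp[idx],
            frames=[self.frames[i] for i in idx],
            cavity_pressure={k: v[idx] for k, v in self.cavity_pressure.items()},
            apex_air_pressure=None if self.apex_air_pressure is None
            else self.apex_air_pressure[idx],
            jet_velocity=None if self.jet_velocity is None
            else self.jet_velocity[idx])


@dataclass
class BiomarkerReport:
    t_A1: float                      # ms
    t_HC: float
    t_A2: float
    deflection_amplitude: float      # mm
    peak_distance: float             # mm
    apex_pressure_at_HC: float = np.nan   # mmHg
    max_iop: float = np.nan          # mmHg

    def __post_init__(self):
        if not self.t_A1 < self.t_HC < self.t_A2:
            raise ValueError("event ordering must be A1 < HC < A2")

    def to_dict(self):
        return {
            "t_A1_ms": self.t_A1, "t_HC_ms": self.t_HC, "t_A2_ms": self.t_A2,
            "deflection_amplitude_mm": self.deflection_amplitude,
            "peak_distance_mm": self.peak_distance,
            "apex_pressure_at_HC_mmHg": self.apex_pressure_at_HC,
            "max_iop_mmHg": self.max_iop,
        }


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def _central_fit(frame, halfwidth=FLAT_HALFWIDTH):
    """(rms deviation from best-fit line, quadratic coefficient) centrally."""
    m = np.abs(frame.arc) <= halfwidth + 1e-9
    x, y = frame.arc[m], frame.elevation[m]
    if len(x) < 3:
        raise NoApplanationError("too few profile points in the central band")
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rms = float(np.sqrt(np.mean((y - A @ coef) ** 2)))
    quad = float(np.polyfit(x, y, 2)[0])
    return rms, quad


def detect_events(history: SimulationHistory,
                  halfwidth=FLAT_HALFWIDTH, tol=FLAT_TOL_MM):
    """Times of first applanation, highest concavity and second applanation.

    HC is the instant of maximum apex displacement.  A1 (A2) is the first
    (last) instant at which the central 3 mm of the profile is flat: RMS
    deviation from its best-fit straight line below ``tol``.  When the
    discretized profile never meets the RMS threshold, the zero crossing
    of the fitted central curvature (the continuum flatness condition) is
    interpolated in time instead; if the curvature never reverses the jet
    was too weak and :class:`NoApplanationError` is raised.
    """
    axial = history.apex_axial
    hc = int(np.argmax(axial))
    if hc == 0 or hc == len(axial) - 1 or axial[hc] <= 0:
        raise NoApplanationError("no interior apex-displacement maximum")
    t = np.asarray(history.times, float)
    rms = np.empty(len(t))
    quad = np.empty(len(t))
    for i, fr in enumerate(history.frames):
        rms[i], quad[i] = _central_fit(fr, halfwidth)

    def crossing(side):
        idx = range(hc, -1, -1) if side == "A1" else range(hc, len(t))
        flat = [i for i in idx if rms[i] < tol]
        if flat:
            # first (in time) flat instant before HC / last after HC
            return t[min(flat)] if side == "A1" else t[max(flat)]
        # curvature sign-change fallback, linearly interpolated
        seq = list(idx)
        for a, b in zip(seq[:-1], seq[1:]):
            if quad[a] * quad[b] < 0:
                w = quad[a] / (quad[a] - quad[b])
                return float(t[a] + w * (t[b] - t[a]))
        raise NoApplanationError(
            f"no applanation found on the {side} side (weak jet)")

    t_a1 = crossing("A1")
    t_a2 = crossing("A2")
    t_hc = float(t[hc])
    if not t_a1 < t_hc < t_a2:
        raise NoApplanationError("events out of order; jet too weak")
    return t_a1, t_hc, t_a2


def deflection_amplitude(history: SimulationHistory) -> float:
    """Apex displacement (mm) along the jet axis at highest concavity."""
    _, t_hc, _ = detect_events(history)
    i = int(np.argmin(np.abs(np.asarray(history.times) - t_hc)))
    return float(history.apex_axial[i])


def peak_distance(frame: ProfileFrame) -> float:
    """Horizontal distance (mm) between the two bending peaks of a frame.

    Peaks are local elevation maxima refined with parabolic interpolation;
    the two highest are used.  Raises :class:`NoConcavityError` when fewer
    than two exist (no concave deformation).
    """
    x, y = frame.arc, frame.elevation
    peaks = []
    for i in range(1, len(x) - 1):
        if y[i] >= y[i - 1] and y[i] >= y[i + 1] and \
                (y[i] > y[i - 1] or y[i] > y[i + 1]):
            # parabolic sub-sample refinement
            denom = (y[i - 1] - 2 * y[i] + y[i + 1])
            if abs(denom) > 1e-15:
                d = 0.5 * (y[i - 1] - y[i + 1]) / denom
                d = np.clip(d, -1.0, 1.0)
                xs = x[i] + d * 0.5 * (x[i + 1] - x[i - 1])
                ys = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * d
            else:
                xs, ys = x[i], y[i]
            peaks.append((ys, xs))
    if len(peaks) < 2:
        raise NoConcavityError("fewer than two bending peaks in the profile")
    peaks.sort(reverse=True)
    (y1, x1), (y2, x2) = peaks[0], peaks[1]
    return float(abs(x1 - x2))


def extract_traces(history: SimulationHistory):
    """(times, IOP trace, apex air-pressure trace), pressures in mmHg."""
    t = np.asarray(history.times, float)
    iop = history.iop
    apex_p = history.apex_air_pressure
    return t, iop, apex_p


def hc_markers(history: SimulationHistory) -> dict:
    """Highest-concavity markers only (no applanation detection).

    The factorial sensitivity study examines the deflection amplitude,
    the peak distance and the apex air pressure, all evaluated at HC, so
    batch runs can stop shortly after the concavity peak; this extractor
    does not require the recovery phase needed to locate A2.
    """
    axial = history.apex_axial
    i = int(np.argmax(axial))
    if axial[i] <= 0:
        raise NoApplanationError("no inward deformation recorded")
    iop = history.iop
    return {
        "t_HC": float(history.times[i]),
        "deflection_amplitude": float(axial[i]),
        "peak_distance": peak_distance(history.frames[i]),
        "apex_pressure": np.nan if history.apex_air_pressure is None
        else float(history.apex_air_pressure[i]),
        "max_iop": np.nan if iop is None else float(np.max(iop)),
    }


def biomarker_report(history: SimulationHistory) -> BiomarkerReport:
    """Full biomarker extraction from one simulation history."""
    t_a1, t_hc, t_a2 = detect_events(history)
    i = int(np.argmin(np.abs(np.asarray(history.times) - t_hc)))
    da = float(history.apex_axial[i])
    pd_mm = peak_distance(history.frames[i])
    apex_p = np.nan if history.apex_air_pressure is None \
        else float(history.apex_air_pressure[i])
    iop = history.iop
    max_iop = np.nan if iop is None else float(np.max(iop))
    return BiomarkerReport(t_A1=t_a1, t_HC=t_hc, t_A2=t_a2,
                           deflection_amplitude=da, peak_distance=pd_mm,
                           apex_pressure_at_HC=apex_p, max_iop=max_iop)


# ---------------------------------------------------------------------------
# standalone CSV interface
# ---------------------------------------------------------------------------

def history_from_csv(path) -> SimulationHistory:
    """Load profile frames from CSV (time_ms, arc_mm, elevation_mm).

    The apex displacement trace is reconstructed from the elevation at the
    frame centre relative to the first frame.
    """
    df = pd.read_csv(path)
    frames = []
    for tval, g in df.groupby("time_ms", sort=True):
        g = g.sort_values("arc_mm")
        frames.append(ProfileFrame(time=float(tval),
                                   arc=g["arc_mm"].to_numpy(),
                                   elevation=g["elevation_mm"].to_numpy()))
    if not frames:
        raise ValueError("empty profile file")

    def centre(fr):
        i = int(np.argmin(np.abs(fr.arc)))
        return fr.elevation[i]

    e0 = centre(frames[0])
    apex = np.array([[0.0, centre(fr) - e0, 0.0] for fr in frames])
    return SimulationHistory(times=np.array([f.time for f in frames]),
                             apex_disp=apex, frames=frames)


def history_to_csv(history: SimulationHistory, path):
    rows = []
    for fr in history.frames:
        for a, e in zip(fr.arc, fr.elevation):
            rows.append((fr.time, a, e))
    pd.DataFrame(rows, columns=["time_ms", "arc_mm", "elevation_mm"]) \
        .to_csv(path, index=False)
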
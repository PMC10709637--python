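"""Fluorescence and radiolabel assay analysis for channel/scramblase activity.

The readouts quantified here come from vesicles carrying a trace of
fluorescent NBD-phospholipid (or [3H]PI for the phospholipase assay):

* dithionite assay — the membrane-impermeant reductant bleaches outer-leaflet
  NBD probe; if the vesicle carries a channel, dithionite enters and bleaches
  everything. Reports the channel-active vesicle fraction f_pore.
* BSA back-extraction — fatty-acid-free albumin extracts outer-leaflet NBD
  lipid; BSA-complexed probe fluoresces at a factor phi (~0.4) of its
  membrane value. Scramblase-active vesicles replenish the outer leaflet from
  the inner one, deepening the drop. Reports f_scr.
* PI-PLC hydrolysis — the phospholipase cleaves only outer-leaflet [3H]PI,
  ~50% in protein-free vesicles, more when a scramblase flips inner-leaflet
  PI outward.
* slow scrambling — outer-leaflet probe fraction followed over hours.

The activity fraction of a reconstitution is

    f = (F_L - F_P) / (F_L - F_Min)

with F the normalized readout 350 s after reagent addition for protein-free
(L) and proteoliposome (P) samples, and F_Min the floor if every vesicle were
active. For the BSA assay, F_Min follows from the dithionite floor and phi:

    F_BSA_Min = (1 - F_Dith_Min) * phi + F_Dith_Min
    phi       = (F_BSA_L - F_Dith_L) / (1 - F_Dith_L)

Trace kinetics are summarized with one- or two-phase exponential decays,
the phase count chosen by an extra-sum-of-squares F-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model
from scipy import stats

__all__ = [
    "FluorescenceTrace",
    "ExpFitResult",
    "ActivityFractions",
    "AssociationFit",
    "normalize_trace",
    "readout_at",
    "fit_exponential",
    "compute_phi",
    "compute_F_min_bsa",
    "activity_fraction",
    "scramblase_per_channel",
    "analyze_plc_timecourse",
    "slow_scrambling_halftime",
]

ASSAY_KINDS = ("dithionite", "bsa", "plc", "slow_scrambling")

#: Default readout time (s after reagent addition) for activity fractions.
READOUT_TIME_S = 350.0

#: Default BSA quench factor when no paired protein-free traces are available.
DEFAULT_PHI = 0.4


@dataclass
class FluorescenceTrace:
    """A timed intensity record for one assay run.

    time is in seconds (strictly increasing), intensity in arbitrary units.
    addition_time marks reagent (dithionite / BSA / PI-PLC) addition; samples
    before it form the baseline. ``normalized`` is set once the trace has been
    scaled to its baseline and re-timed to addition_time = 0.
    """

    time: np.ndarray
    intensity: np.ndarray
    addition_time: float
    assay_kind: str = "dithionite"
    label: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError(f"trace {self.label!r}: time/intensity length mismatch")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError(f"trace {self.label!r}: time must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError(f"trace {self.label!r}: non-finite intensities")
        if self.assay_kind not in ASSAY_KINDS:
            raise ValueError(f"unknown assay kind {self.assay_kind!r}")

    @property
    def baseline_mask(self) -> np.ndarray:
        return self.time < self.addition_time


@dataclass
class ExpFitResult:
    """One- or two-phase exponential decay fit of a post-addition trace.

    Phases are ordered fast to slow; amplitudes are in normalized units and
    amplitudes + plateau reproduce the value at addition time.
    """

    n_phases: int
    amplitudes: tuple[float, ...]
    rate_constants: tuple[float, ...]
    plateau: float
    half_times: tuple[float, ...] = ()
    model_selection_p: float = math.nan

    def __post_init__(self) -> None:
        self.half_times = tuple(math.log(2) / k for k in self.rate_constants)


@dataclass
class ActivityFractions:
    """Inputs and result of the activity-fraction calculation for one assay."""

    F_L: float
    F_P: float
    F_min: float
    f: float
    phi: float = DEFAULT_PHI
    Q: float | None = None
    ordering_ok: bool = True


@dataclass
class AssociationFit:
    """One-phase exponential association fit (phospholipase hydrolysis)."""

    plateau: float
    rate_constant: float
    half_time: float
    percent_hydrolysis: np.ndarray = field(default_factory=lambda: np.array([]))
    times: np.ndarray = field(default_factory=lambda: np.array([]))


def normalize_trace(trace: FluorescenceTrace) -> FluorescenceTrace:
    """Scale intensity to the mean pre-addition baseline and zero the clock.

    The baseline (all samples before addition_time) maps to 1.0 and times are
    shifted so the addition happens at t = 0.
    """
    mask = trace.baseline_mask
    if mask.sum() < 3:
        raise ValueError(
            f"trace {trace.label!r}: need >= 3 pre-addition samples for a baseline"
        )
    baseline = float(trace.intensity[mask].mean())
    if baseline <= 0:
        raise ValueError(f"trace {trace.label!r}: non-positive baseline ({baseline})")
    return FluorescenceTrace(
        time=trace.time - trace.addition_time,
        intensity=trace.intensity / baseline,
        addition_time=0.0,
        assay_kind=trace.assay_kind,
        label=trace.label,
        normalized=True,
    )


def readout_at(trace: FluorescenceTrace, t: float = READOUT_TIME_S) -> float:
    """Normalized intensity at ``t`` seconds post-addition (linear interpolation)."""
    tr = trace if trace.normalized else normalize_trace(trace)
    if t < tr.time[0] or t > tr.time[-1]:
        raise ValueError(
            f"trace {tr.label!r}: t = {t} s outside recorded range "
            f"[{tr.time[0]:.1f}, {tr.time[-1]:.1f}] s"
        )
    if t <= 0:
        return 1.0
    return float(np.interp(t, tr.time, tr.intensity))


def _decay1(t, a1, k1, plateau):
    return plateau + a1 * np.exp(-k1 * t)


def _decay2(t, a1, k1, a2, k2, plateau):
    return plateau + a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)


def fit_exponential(
    trace: FluorescenceTrace,
    max_phases: int = 2,
    alpha: float = 0.05,
) -> ExpFitResult:
    """Fit a one- or two-phase exponential decay to the post-addition segment.

    The two-phase model is kept only when the extra-sum-of-squares F-test
    rejects the one-phase model at significance ``alpha``; otherwise the
    simpler model is reported. Phases are returned fast-first.
    """
    tr = trace if trace.normalized else normalize_trace(trace)
    post = tr.time >= 0
    t = tr.time[post]
    y = tr.intensity[post]
    if t.size < 8:
        raise ValueError(f"trace {tr.label!r}: need >= 8 post-addition points")

    span = float(y[0] - y[-1])
    m1 = Model(_decay1)
    p1 = m1.make_params(a1=max(span, 1e-3), k1=1.0 / max(t[-1] / 5, 1e-6), plateau=float(y[-1]))
    p1["k1"].set(min=1e-9)
    r1 = m1.fit(y, p1, t=t)
    if not r1.success:
        raise RuntimeError(f"trace {tr.label!r}: one-phase fit failed: {r1.message}")
    ss1 = float(np.sum(r1.residual**2))

    best = ExpFitResult(
        n_phases=1,
        amplitudes=(float(r1.params["a1"].value),),
        rate_constants=(float(r1.params["k1"].value),),
        plateau=float(r1.params["plateau"].value),
        model_selection_p=math.nan,
    )
    if max_phases < 2:
        return best

    m2 = Model(_decay2)
    k_fast0 = 5.0 / max(t[-1], 1e-6) * 10
    k_slow0 = 1.0 / max(t[-1] / 3, 1e-6)
    p2 = m2.make_params(
        a1=max(span, 1e-3) / 2,
        k1=k_fast0,
        a2=max(span, 1e-3) / 2,
        k2=k_slow0,
        plateau=float(y[-1]),
    )
    p2["k1"].set(min=1e-9)
    p2["k2"].set(min=1e-9)
    try:
        r2 = m2.fit(y, p2, t=t)
        ss2 = float(np.sum(r2.residual**2))
    except Exception:
        return best
    df1 = t.size - 3
    df2 = t.size - 5
    if df2 <= 0 or ss2 <= 0 or ss2 >= ss1:
        return best
    f_stat = ((ss1 - ss2) / (df1 - df2)) / (ss2 / df2)
    p_val = float(stats.f.sf(f_stat, df1 - df2, df2))
    if p_val >= alpha:
        best.model_selection_p = p_val
        return best

    phases = sorted(
        [
            (float(r2.params["k1"].value), float(r2.params["a1"].value)),
            (float(r2.params["k2"].value), float(r2.params["a2"].value)),
        ],
        key=lambda ka: -ka[0],
    )
    return ExpFitResult(
        n_phases=2,
        amplitudes=tuple(a for _, a in phases),
        rate_constants=tuple(k for k, _ in phases),
        plateau=float(r2.params["plateau"].value),
        model_selection_p=p_val,
    )


def compute_phi(F_bsa_L: float, F_dith_L: float) -> float:
    """BSA quench factor phi = (F_BSA_L - F_Dith_L) / (1 - F_Dith_L).

    Both inputs are normalized protein-free readouts at the same time point;
    phi is the fluorescence of BSA-complexed probe relative to membrane-bound
    probe (experimentally ~0.4).
    """
    if F_dith_L >= 1.0:
        raise ZeroDivisionError("F_dith_L must be < 1 (some probe must bleach)")
    return (F_bsa_L - F_dith_L) / (1.0 - F_dith_L)


def compute_F_min_bsa(F_dith_min: float, phi: float) -> float:
    """BSA-assay floor F_BSA_Min = (1 - F_Dith_Min) * phi + F_Dith_Min."""
    if not (0.0 <= F_dith_min <= 1.0):
        raise ValueError("F_dith_min must lie in [0, 1]")
    return (1.0 - F_dith_min) * phi + F_dith_min


def activity_fraction(F_L: float, F_P: float, F_min: float) -> float:
    """Fraction of active vesicles f = (F_L - F_P) / (F_L - F_Min).

    Values above 1 (measurement noise) are clipped to 1 with a warning;
    an uninformative window (F_L <= F_min) raises.
    """
    if F_L <= F_min:
        raise ValueError(f"uninformative assay window: F_L = {F_L} <= F_min = {F_min}")
    f = (F_L - F_P) / (F_L - F_min)
    if f > 1.0:
        warnings.warn(f"activity fraction {f:.3f} > 1 clipped to 1 (noise)")
        return 1.0
    return f


def scramblase_per_channel(f_scr: float, f_pore: float) -> float:
    """Fraction of channel-active vesicles that also scramble: Q = f_scr / f_pore."""
    if f_pore <= 0:
        raise ValueError("f_pore must be > 0 (Q undefined without channel activity)")
    return f_scr / f_pore


def _assoc(t, plateau, k):
    return plateau * (1.0 - np.exp(-k * t))


def analyze_plc_timecourse(
    counts: list[tuple[float, float]],
    triton_max: float,
    untreated_offset: float,
) -> AssociationFit:
    """Phospholipase hydrolysis time course from scintillation counts.

    Counts are offset-corrected by the untreated sample and normalized to the
    Triton-disrupted maximum, giving %hydrolysis(t); a one-phase exponential
    association yields the hydrolysis plateau and half-time. Negative
    corrected counts are clipped to zero with a warning.
    """
    if triton_max <= untreated_offset:
        raise ValueError("triton_max must exceed the untreated offset")
    arr = np.asarray(counts, dtype=float)
    t = arr[:, 0]
    cpm = arr[:, 1]
    corrected = cpm - untreated_offset
    if np.any(corrected < 0):
        warnings.warn("negative offset-corrected counts clipped to 0")
        corrected = np.clip(corrected, 0.0, None)
    pct = 100.0 * corrected / (triton_max - untreated_offset)

    if float(np.ptp(pct)) < 1e-9:
        return AssociationFit(
            plateau=float(pct.mean()), rate_constant=math.nan, half_time=math.inf,
            percent_hydrolysis=pct, times=t,
        )
    m = Model(_assoc)
    params = m.make_params(plateau=float(pct.max()), k=1.0 / max(t[t > 0].min(), 1e-6))
    params["k"].set(min=1e-9)
    params["plateau"].set(min=0.0)
    res = m.fit(pct, params, t=t)
    k = float(res.params["k"].value)
    return AssociationFit(
        plateau=float(res.params["plateau"].value),
        rate_constant=k,
        half_time=math.log(2) / k,
        percent_hydrolysis=pct,
        times=t,
    )


def slow_scrambling_halftime(
    outer_fractions: list[tuple[float, float]],
    equilibrium: float | None = None,
) -> float:
    """Half-time (same units as the time axis) of slow transbilayer movement.

    ``outer_fractions`` pairs (time, outer-leaflet probe fraction) with the
    first point defining 100% outer. A one-phase exponential decay toward the
    equilibrium distribution is fitted; a flat series is flagged as no
    detectable scrambling (infinite half-time). If ``equilibrium`` is None the
    plateau floats.
    """
    arr = np.asarray(outer_fractions, dtype=float)
    if arr.shape[0] < 4:
        raise ValueError("need at least 4 time points")
    t = arr[:, 0]
    y = arr[:, 1] / arr[0, 1]

    if float(np.ptp(y)) < 1e-6:
        warnings.warn("no detectable scrambling: outer-leaflet fraction constant")
        return math.inf

    m = Model(_decay1)
    span = float(y[0] - y[-1])
    params = m.make_params(
        a1=max(span, 1e-3), k1=1.0 / max(t[-1] / 3, 1e-9), plateau=float(y[-1])
    )
    params["k1"].set(min=1e-12)
    if equilibrium is not None:
        params["plateau"].set(value=equilibrium, vary=False)
        params["a1"].set(value=1.0 - equilibrium)
    res = m.fit(y, params, t=t)
    return math.log(2) / float(res.params["k1"].value)
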
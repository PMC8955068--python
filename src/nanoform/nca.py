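"""Non-compartmental pharmacokinetics and nose-to-brain targeting metrics.

Per tissue/route profile: Cmax/Tmax read directly off the observations,
the terminal elimination rate Ke from a log-linear regression over the
last positive observations, t1/2 = ln(2)/Ke, and AUC(0-t) by the linear
trapezoidal rule without extrapolation.

Targeting statistics compare intranasal (IN) and intravenous (IV)
exposure.  With R = AUC_brain / AUC_blood per route,

    DTE% = 100 * R_IN / R_IV

is the drug targeting efficiency (100 means no preferential brain
targeting), and the direct transport percentage

    DTP% = 100 * (AUC_brain_IN - Bx) / AUC_brain_IN,
    Bx   = R_IV * AUC_blood_IN

is the fraction of IN brain exposure not attributable to redistribution
from the systemic circulation.  Algebraically DTP = 100 * (1 - 100/DTE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError, EstimationError

__all__ = [
    "ConcentrationProfile",
    "NCAResult",
    "TargetingMetrics",
    "auc_trapezoid",
    "terminal_ke",
    "cmax_tmax",
    "brain_blood_ratio",
    "dte",
    "dtp",
    "run_nca",
    "targeting_metrics",
]

TISSUES = ("brain", "blood")
ROUTES = ("IV", "IN")


@dataclass
class ConcentrationProfile:
    """Time-ordered drug levels in one tissue for one route/group."""

    tissue: str
    route: str
    group: str
    times_min: np.ndarray
    concentrations_ng_ml: np.ndarray

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise DataError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if self.route not in ROUTES:
            raise DataError(f"route must be one of {ROUTES}, got {self.route!r}")
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.concentrations_ng_ml = np.asarray(self.concentrations_ng_ml, dtype=float)
        if self.times_min.shape != self.concentrations_ng_ml.shape:
            raise DataError("times and concentrations must have equal length")
        if self.times_min.size == 0:
            raise DataError("profile is empty")
        if np.any(self.times_min < 0):
            raise DataError("times must be non-negative")
        if np.any(np.diff(self.times_min) <= 0):
            raise DataError("times must be strictly increasing (no duplicates)")
        if np.any(self.concentrations_ng_ml < 0):
            raise DataError("concentrations must be non-negative")

    def concentration_at(self, t: float) -> float:
        idx = np.flatnonzero(self.times_min == t)
        if idx.size == 0:
            raise DataError(
                f"no observation at t={t} min in {self.tissue}/{self.route} profile"
            )
        return float(self.concentrations_ng_ml[idx[0]])


@dataclass
class NCAResult:
    cmax_ng_ml: float
    tmax_min: float
    ke_per_min: float | None
    t_half_min: float | None
    auc_0_t: float

    def to_dict(self) -> dict:
        return {
            "Cmax_ng_ml": self.cmax_ng_ml, "Tmax_min": self.tmax_min,
            "Ke_per_min": self.ke_per_min, "t_half_min": self.t_half_min,
            "AUC_0_t_ng_ml_min": self.auc_0_t,
        }


@dataclass
class TargetingMetrics:
    ratio_at_time: dict[str, float]
    auc_ratio: dict[str, float]
    bx: float
    dte_percent: float
    dtp_percent: float

    def to_dict(self) -> dict:
        return {
            "brain_blood_concentration_ratio": self.ratio_at_time,
            "AUC_brain_over_AUC_blood": self.auc_ratio,
            "Bx": self.bx,
            "DTE_percent": self.dte_percent,
            "DTP_percent": self.dtp_percent,
        }


def auc_trapezoid(profile: ConcentrationProfile, t_end: float) -> float:
    """AUC(0 - t_end) by the linear trapezoidal rule.

    Integration never extrapolates: it stops at the last observation
    when ``t_end`` exceeds it.  If ``t_end`` falls inside an observed
    interval the profile is linearly interpolated at ``t_end``, which
    keeps the rule additive over adjacent intervals.
    """
    t = profile.times_min
    c = profile.concentrations_ng_ml
    if t.size < 2:
        raise EstimationError("AUC requires at least 2 observations")
    if t_end < t[0]:
        raise EstimationError(f"t_end={t_end} precedes the first observation at {t[0]}")
    if t_end >= t[-1]:
        return float(np.trapezoid(c, t))
    keep = t <= t_end
    tt = np.append(t[keep], t_end)
    cc = np.append(c[keep], np.interp(t_end, t, c))
    if tt.size == 1 or tt[-1] == tt[-2]:
        tt, cc = tt[:-1], cc[:-1]
    if tt.size < 2:
        return 0.0
    return float(np.trapezoid(cc, tt))


def terminal_ke(profile: ConcentrationProfile, n_points: int = 3) -> float:
    """Terminal elimination rate from the last ``n_points`` observations.

    Ke is minus the least-squares slope of ln(C) versus t; exact for a
    noiseless mono-exponential decline on any sampling grid.
    """
    if n_points < 2:
        raise EstimationError("terminal fit needs at least 2 points")
    if profile.times_min.size < n_points:
        raise EstimationError(
            f"profile has {profile.times_min.size} points, terminal fit needs {n_points}"
        )
    t = profile.times_min[-n_points:]
    c = profile.concentrations_ng_ml[-n_points:]
    if np.any(c <= 0):
        raise EstimationError(
            "non-positive concentration in the terminal window; "
            "shrink n_points or trim the profile"
        )
    slope = stats.linregress(t, np.log(c)).slope
    if slope >= 0:
        raise EstimationError(
            f"terminal slope {slope:.3g} is non-negative; no elimination phase detected"
        )
    return float(-slope)


def half_life(ke_per_min: float) -> float:
    """t1/2 = ln(2)/Ke, from the unrounded rate constant."""
    if ke_per_min <= 0:
        raise EstimationError("Ke must be positive")
    return math.log(2.0) / ke_per_min


def cmax_tmax(profile: ConcentrationProfile) -> tuple[float, float]:
    """Maximum observed concentration and the earliest time attaining it."""
    i = int(np.argmax(profile.concentrations_ng_ml))  # argmax takes first tie
    return float(profile.concentrations_ng_ml[i]), float(profile.times_min[i])


def brain_blood_ratio(brain: ConcentrationProfile, blood: ConcentrationProfile,
                      t: float) -> float:
    """C_brain(t) / C_blood(t) at a shared observation time (no interpolation)."""
    cb = brain.concentration_at(t)
    cp = blood.concentration_at(t)
    if cp == 0:
        raise DataError(f"blood concentration at t={t} min is zero")
    return cb / cp


def dte(auc_brain_in: float, auc_blood_in: float,
        auc_brain_iv: float, auc_blood_iv: float) -> float:
    """Drug targeting efficiency percentage."""
    for name, v in (("auc_brain_in", auc_brain_in), ("auc_blood_in", auc_blood_in),
                    ("auc_brain_iv", auc_brain_iv), ("auc_blood_iv", auc_blood_iv)):
        if v <= 0:
            raise DataError(f"{name} must be positive, got {v}")
    return 100.0 * (auc_brain_in / auc_blood_in) / (auc_brain_iv / auc_blood_iv)


def dtp(auc_brain_in: float, auc_blood_in: float,
        auc_brain_iv: float, auc_blood_iv: float) -> float:
    """Direct transport percentage (share of IN brain exposure not from blood)."""
    if auc_brain_in <= 0:
        raise DataError("auc_brain_in must be positive")
    if auc_blood_iv <= 0:
        raise DataError("auc_blood_iv must be positive")
    bx = (auc_brain_iv / auc_blood_iv) * auc_blood_in
    return 100.0 * (auc_brain_in - bx) / auc_brain_in


def run_nca(profile: ConcentrationProfile, t_end: float = 480.0,
            n_terminal: int = 3) -> NCAResult:
    """Full non-compartmental panel for one profile.

    Ke/t1/2 are reported as ``None`` when no terminal decline can be
    estimated (for example a still-rising profile).
    """
    cmax, tmax = cmax_tmax(profile)
    try:
        ke = terminal_ke(profile, n_terminal)
        thalf = half_life(ke)
    except EstimationError:
        ke, thalf = None, None
    return NCAResult(cmax, tmax, ke, thalf, auc_trapezoid(profile, t_end))


def targeting_metrics(profiles: dict[tuple[str, str], ConcentrationProfile],
                      t_end: float = 480.0,
                      ratio_time: float | None = 30.0) -> TargetingMetrics:
    """DTE/DTP and AUC ratios from the four (tissue, route) profiles.

    ``profiles`` is keyed by (tissue, route); the IV route refers to the
    reference solution and IN to the test formulation.
    """
    needed = [(ts, rt) for rt in ROUTES for ts in TISSUES]
    missing = [k for k in needed if k not in profiles]
    if missing:
        raise DataError(f"missing profiles for {missing}")
    auc = {k: auc_trapezoid(profiles[k], t_end) for k in needed}
    auc_ratio = {rt: auc[("brain", rt)] / auc[("blood", rt)] for rt in ROUTES}
    ratio_at = {}
    if ratio_time is not None:
        for rt in ROUTES:
            try:
                ratio_at[rt] = brain_blood_ratio(
                    profiles[("brain", rt)], profiles[("blood", rt)], ratio_time)
            except DataError:
                pass
    bx = auc_ratio["IV"] * auc[("blood", "IN")]
    return TargetingMetrics(
        ratio_at_time=ratio_at,
        auc_ratio=auc_ratio,
        bx=bx,
        dte_percent=dte(auc[("brain", "IN")], auc[("blood", "IN")],
                        auc[("brain", "IV")], auc[("blood", "IV")]),
        dtp_percent=dtp(auc[("brain", "IN")], auc[("blood", "IN")],
                        auc[("brain", "IV")], auc[("blood", "IV")]),
    )
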
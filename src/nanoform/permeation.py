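"""Entrapment, release/permeation bookkeeping, flux and permeability.

Franz-cell experiments sample the receptor chamber at intervals; when
each sample is replaced with fresh medium the drug mass removed in
earlier samples must be added back when accumulating the cumulative
amount permeated per unit membrane area, Q(t).  The steady-state flux
Jss is the least-squares slope of Q versus time, and the apparent
permeability coefficient is Papp = Jss / C0 for donor concentration C0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError, EstimationError

__all__ = [
    "DiffusionRun",
    "PermeationParams",
    "entrapment_efficiency",
    "cumulative_per_area",
    "percent_transferred",
    "steady_state_flux",
    "apparent_permeability",
]


@dataclass
class DiffusionRun:
    """One Franz-cell run: sampling times (h) and sampled concentrations.

    Concentrations are in ug/mL; geometry in cm2 / mL; dose in ug.
    ``replacement`` indicates that each withdrawn sample volume was
    replaced with fresh medium.
    """

    times_h: np.ndarray
    concentrations: np.ndarray
    donor_dose_ug: float
    area_cm2: float
    receptor_volume_ml: float
    sample_volume_ml: float
    replacement: bool = True

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times_h.shape != self.concentrations.shape:
            raise DataError("times and concentrations must have equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise DataError("sample times must be strictly increasing")
        if min(self.area_cm2, self.receptor_volume_ml, self.donor_dose_ug) <= 0:
            raise DataError("area, receptor volume and donor dose must be positive")
        if self.sample_volume_ml < 0 or self.sample_volume_ml >= self.receptor_volume_ml:
            raise DataError("sample volume must be in [0, receptor volume)")
        if np.any(self.concentrations < 0):
            raise DataError("sampled concentrations must be non-negative")


@dataclass
class PermeationParams:
    """Summary of a permeation run."""

    jss_ug_cm2_h: float
    papp_cm_h: float
    q_end_ug_cm2: float
    percent: float

    def to_dict(self) -> dict:
        return {
            "Jss_ug_cm2_h": self.jss_ug_cm2_h,
            "Papp_cm_h": self.papp_cm_h,
            "cumulative_ug_cm2": self.q_end_ug_cm2,
            "percent_transferred": self.percent,
        }


def entrapment_efficiency(dose_mg: float, free_mg: float) -> float:
    """Percent of the dose entrapped, from the free (unentrapped) fraction."""
    if dose_mg <= 0:
        raise DataError("dose must be positive")
    if not 0 <= free_mg <= dose_mg:
        raise DataError(
            f"free drug ({free_mg} mg) must lie between 0 and the dose ({dose_mg} mg)"
        )
    return 100.0 * (dose_mg - free_mg) / dose_mg


def cumulative_per_area(run: DiffusionRun) -> np.ndarray:
    """Cumulative amount transferred per unit area, Q(t), in ug/cm2.

    With sample replacement, the mass removed in all earlier samples is
    added back:  Q(t_n) = [C_n * V_receptor + sum_{i<n} C_i * V_sample] / area.
    Without replacement Q(t_n) = C_n * V_receptor / area.
    """
    c = run.concentrations
    q = c * run.receptor_volume_ml
    if run.replacement and run.sample_volume_ml > 0:
        removed = np.concatenate([[0.0], np.cumsum(c * run.sample_volume_ml)[:-1]])
        q = q + removed
    return q / run.area_cm2


def percent_transferred(q_end_ug_cm2: float, dose_per_area_ug_cm2: float) -> float:
    """Percent of the applied dose per area transferred by the end time."""
    if dose_per_area_ug_cm2 <= 0:
        raise DataError("dose per area must be positive")
    return 100.0 * q_end_ug_cm2 / dose_per_area_ug_cm2


def steady_state_flux(times_h, q_ug_cm2, window: slice | None = None) -> float:
    """Least-squares slope of Q versus t over the steady-state window.

    The default window drops only the first point (the lag-dominated
    origin); pass an explicit slice to override.
    """
    t = np.asarray(times_h, dtype=float)
    q = np.asarray(q_ug_cm2, dtype=float)
    window = window if window is not None else slice(1, None)
    t, q = t[window], q[window]
    if t.size < 2:
        raise EstimationError("flux estimation requires at least 2 points in window")
    if np.allclose(t, t[0]):
        raise EstimationError("degenerate time window")
    res = stats.linregress(t, q)
    return float(res.slope)


def apparent_permeability(jss_ug_cm2_h: float, donor_concentration_ug_ml: float) -> float:
    """Papp = Jss / C0, in cm/h."""
    if donor_concentration_ug_ml <= 0:
        raise DataError("donor concentration must be positive")
    return jss_ug_cm2_h / donor_concentration_ug_ml


def summarize_run(run: DiffusionRun, donor_concentration_ug_ml: float,
                  dose_per_area_ug_cm2: float | None = None,
                  window: slice | None = None) -> PermeationParams:
    """Full permeation panel for one run."""
    q = cumulative_per_area(run)
    jss = steady_state_flux(run.times_h, q, window)
    dpa = (dose_per_area_ug_cm2 if dose_per_area_ug_cm2 is not None
           else run.donor_dose_ug / run.area_cm2)
    return PermeationParams(
        jss_ug_cm2_h=jss,
        papp_cm_h=apparent_permeability(jss, donor_concentration_ug_ml),
        q_end_ug_cm2=float(q[-1]),
        percent=percent_transferred(float(q[-1]), dpa),
    )
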
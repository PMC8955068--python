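"""Synthetic study generators with known ground truth.

Three generators cover the pipeline end to end:

* ``simulate_bbd_study`` — evaluates true polynomial surfaces (on the
  transformed response scale) at each Box-Behnken run and adds Gaussian
  noise on that scale before back-transforming, so the fitted models'
  homoscedasticity assumption holds by construction.

* ``simulate_pk_study`` — a linear two-site disposition model solved in
  closed form.  IV blood is a bolus mono-exponential; IN blood is
  first-order absorption of the fraction of the dose not taken up by
  the direct nose-to-brain pathway; brain levels follow linear uptake
  from blood (rate ``kin``) with efflux ``kout`` plus, for IN, a
  first-order input of the direct-fraction depot.  Because every signal
  is a sum of exponentials, sampled profiles and their exact AUCs are
  available without a numerical stepper, and zero-noise round trips are
  exact.  Concentration noise is multiplicative log-normal (mean
  preserving) so simulated levels stay positive.

* ``simulate_permeation`` — a lagged-linear cumulative permeation curve
  converted back to the sampled receptor concentrations, honouring the
  sample-replacement bookkeeping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignMatrix, FactorDef, build_bbd
from .errors import DataError
from .nca import ConcentrationProfile
from .permeation import DiffusionRun
from .rsm import Transform, TermSet, model_matrix

__all__ = [
    "TrueSurface",
    "PKSimParams",
    "PKSimResult",
    "ExpSum",
    "simulate_bbd_study",
    "simulate_pk_study",
    "simulate_permeation",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Design-of-experiments simulator

@dataclass(frozen=True)
class TrueSurface:
    """Ground-truth response surface on the transformed scale."""

    transform: Transform
    coefficients: dict[str, float]
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


_MAX_RETRIES = 100


def simulate_bbd_study(factors: tuple[FactorDef, ...],
                       center_replicates: int,
                       truth: dict[str, TrueSurface],
                       seed: int) -> tuple[DesignMatrix, pd.DataFrame]:
    """Generate a Box-Behnken study table from known true surfaces.

    Returns the design and a DataFrame with factor columns in actual
    units plus one column per response on its original scale.  Runs
    whose noisy transformed value falls outside the back-transform's
    domain are re-drawn (warning logged, capped retries).
    """
    rng = np.random.default_rng(seed)
    design = build_bbd(factors, center_replicates)
    table = pd.DataFrame(design.actual(), columns=[f.name for f in factors])
    for name, surf in truth.items():
        terms = TermSet(surf.coefficients.keys())
        coef = np.array([surf.coefficients[t] for t in terms])
        z_true = model_matrix(terms, design.coded) @ coef
        z = z_true + rng.normal(0.0, surf.noise_sd, size=design.n_runs)
        if surf.transform.kind in ("sqrt", "inverse"):
            for _ in range(_MAX_RETRIES):
                bad = z <= 0
                if not bad.any():
                    break
                log.warning("re-drawing %d %s run(s) outside the %s domain",
                            int(bad.sum()), name, surf.transform.kind)
                z[bad] = z_true[bad] + rng.normal(0.0, surf.noise_sd,
                                                  size=int(bad.sum()))
            else:
                raise DataError(
                    f"could not generate {name} within the "
                    f"{surf.transform.kind} domain after {_MAX_RETRIES} retries"
                )
        table[name] = surf.transform.invert(z)
    return design, table


# ---------------------------------------------------------------------------
# Pharmacokinetic simulator

class ExpSum:
    """A sum of decaying exponentials sum_i a_i * exp(-lambda_i * t)."""

    def __init__(self, terms: list[tuple[float, float]]):
        for _, lam in terms:
            if lam <= 0:
                raise ValueError("exponential rates must be positive")
        self.terms = list(terms)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, lam in self.terms:
            out = out + a * np.exp(-lam * t)
        return out

    def auc(self, t_end: float | None = None) -> float:
        """Exact integral from 0 to ``t_end`` (or to infinity)."""
        total = 0.0
        for a, lam in self.terms:
            if t_end is None:
                total += a / lam
            else:
                total += a / lam * (1.0 - math.exp(-lam * t_end))
        return total

    def convolve_elimination(self, gain: float, kout: float) -> "ExpSum":
        """Response of dY/dt = gain * self(t) - kout * Y, Y(0) = 0."""
        out: list[tuple[float, float]] = []
        for a, lam in self.terms:
            if math.isclose(lam, kout, rel_tol=1e-12):
                raise ValueError(
                    "input and elimination rates coincide; choose distinct rates"
                )
            c = gain * a / (kout - lam)
            out.append((c, lam))
            out.append((-c, kout))
        return ExpSum(out)


@dataclass(frozen=True)
class PKSimParams:
    """Parameters of the synthetic brain-targeting PK study.

    Defaults are illustrative: a ~1.1 mg dose (5 mg/kg in a ~225 g rat),
    blood elimination 0.017/min with slower intranasal absorption
    0.009/min (flip-flop kinetics, so the IN terminal slope is the
    absorption rate), and brain uptake/efflux rates giving a brain/blood
    exposure ratio below 1 for IV and above 1 for IN when a direct
    nose-to-brain fraction is present.  All rates must be positive and
    pairwise distinct (the closed-form solution requires it).
    """

    dose_ug: float = 1125.0
    v_blood_ml: float = 190.0
    k_elim: float = 0.017          # 1/min, blood elimination
    ka: float = 0.009              # 1/min, IN absorption into blood
    kin: float = 0.0012            # 1/min, blood -> brain uptake
    kout: float = 0.005            # 1/min, brain efflux
    f_direct: float = 0.3          # fraction of IN dose routed nose -> brain
    kd: float = 0.01               # 1/min, direct depot -> brain input
    v_brain_ml: float = 280.0
    grid_min: tuple[float, ...] = (10.0, 30.0, 60.0, 120.0, 240.0, 480.0)
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {"k_elim": self.k_elim, "ka": self.ka, "kin": self.kin,
                 "kout": self.kout, "kd": self.kd}
        for name, v in rates.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.f_direct <= 1.0:
            raise ValueError("f_direct must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if min(self.dose_ug, self.v_blood_ml, self.v_brain_ml) <= 0:
            raise ValueError("dose and volumes must be positive")


@dataclass
class PKSimResult:
    """Sampled profiles plus the exact underlying curves."""

    params: PKSimParams
    profiles: dict[tuple[str, str], ConcentrationProfile]
    exact: dict[tuple[str, str], ExpSum]

    def true_auc(self, tissue: str, route: str,
                 t_end: float | None = None) -> float:
        """Analytic AUC of the noise-free curve (to t_end or infinity)."""
        return self.exact[(tissue, route)].auc(t_end)


def simulate_pk_study(params: PKSimParams) -> PKSimResult:
    """Simulate the four brain/blood x IV/IN concentration profiles."""
    p = params
    dose_ng = p.dose_ug * 1000.0

    blood_iv = ExpSum([(dose_ng / p.v_blood_ml, p.k_elim)])

    absorbed = (1.0 - p.f_direct) * dose_ng
    a = p.ka * absorbed / (p.v_blood_ml * (p.k_elim - p.ka))
    blood_in = ExpSum([(a, p.ka), (-a, p.k_elim)])

    brain_iv = blood_iv.convolve_elimination(p.kin, p.kout)

    brain_in_terms = blood_in.convolve_elimination(p.kin, p.kout).terms
    if p.f_direct > 0:
        depot = ExpSum([(p.kd * p.f_direct * dose_ng / p.v_brain_ml, p.kd)])
        brain_in_terms = brain_in_terms + depot.convolve_elimination(
            1.0, p.kout).terms
    brain_in = ExpSum(brain_in_terms)

    exact = {
        ("blood", "IV"): blood_iv,
        ("brain", "IV"): brain_iv,
        ("blood", "IN"): blood_in,
        ("brain", "IN"): brain_in,
    }

    rng = np.random.default_rng(p.seed)
    t = np.asarray(p.grid_min, dtype=float)
    profiles = {}
    for (tissue, route), curve in exact.items():
        c = curve(t)
        if p.noise_cv > 0:
            sigma = math.sqrt(math.log(1.0 + p.noise_cv ** 2))
            c = c * np.exp(rng.normal(-sigma ** 2 / 2.0, sigma, size=t.size))
        profiles[(tissue, route)] = ConcentrationProfile(
            tissue=tissue, route=route, group="sim",
            times_min=t, concentrations_ng_ml=np.maximum(c, 0.0),
        )
    return PKSimResult(params=p, profiles=profiles, exact=exact)


# ---------------------------------------------------------------------------
# Permeation simulator

def simulate_permeation(true_flux_ug_cm2_h: float,
                        lag_h: float = 0.0,
                        grid_h: tuple[float, ...] = (0.5, 1, 2, 3, 4, 6, 8, 10, 12),
                        noise_cv: float = 0.0,
                        seed: int = 0,
                        donor_dose_ug: float = 3000.0,
                        area_cm2: float = 5.0,
                        receptor_volume_ml: float = 50.0,
                        sample_volume_ml: float = 1.0,
                        replacement: bool = True) -> DiffusionRun:
    """Sample a lagged-linear permeation curve into a DiffusionRun.

    The true cumulative curve is Q(t) = max(0, flux * (t - lag)); the
    sampled receptor concentrations are back-calculated so that the
    replacement-corrected bookkeeping recovers Q exactly at zero noise.
    """
    if true_flux_ug_cm2_h < 0:
        raise ValueError("flux must be non-negative")
    t = np.asarray(grid_h, dtype=float)
    q = np.maximum(0.0, true_flux_ug_cm2_h * (t - lag_h))
    conc = np.empty_like(q)
    removed = 0.0
    for i in range(t.size):
        mass = q[i] * area_cm2
        if replacement and sample_volume_ml > 0:
            conc[i] = (mass - removed) / receptor_volume_ml
            removed += conc[i] * sample_volume_ml
        else:
            conc[i] = mass / receptor_volume_ml
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
        conc = conc * np.exp(rng.normal(-sigma ** 2 / 2.0, sigma, size=t.size))
    conc = np.maximum(conc, 0.0)
    return DiffusionRun(
        times_h=t, concentrations=conc,
        donor_dose_ug=donor_dose_ug, area_cm2=area_cm2,
        receptor_volume_ml=receptor_volume_ml,
        sample_volume_ml=sample_volume_ml, replacement=replacement,
    )
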
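"""Embedded study tables used as fixtures and worked-example inputs.

The 17-run Box-Behnken table carries the measured particle size (PS,
nm), entrapment efficiency (EE, %), zeta potential (ZP, mV, signed) and
24-h cumulative drug release (CDR, %) for each formulation run, with
factors in actual units (glycerol monostearate mg, poloxamer 407 %w/w,
oleic acid mg).  The pharmacokinetic table holds the published
non-compartmental parameters per formulation/tissue, including the
AUC(0-t) values the targeting statistics are computed from, and the
permeation table the published flux/permeability pairs.
"""

from __future__ import annotations

import numpy as np

from .design import DesignMatrix, FactorDef

__all__ = [
    "FACTORS",
    "bbd_run_table",
    "bbd_design_matrix",
    "response_values",
    "PK_TABLE",
    "PERMEATION_TABLE",
    "PERMEATION_DOSE_PER_AREA_UG_CM2",
    "PERMEATION_DONOR_CONC_UG_ML",
    "OPTIMAL_FORMULATION",
]

FACTORS = (
    FactorDef("GMS", 100.0, 200.0, "mg"),
    FactorDef("poloxamer", 1.0, 2.0, "% w/w"),
    FactorDef("oleic_acid", 15.0, 30.0, "mg"),
)

# run label, GMS mg, poloxamer %w/w, oleic acid mg, PS nm, EE %, ZP mV, CDR %
_BBD_ROWS = (
    ("F1", 100.0, 1.5, 30.0, 115.8, 75.2, -28.4, 84.3),
    ("F2", 150.0, 1.0, 15.0, 180.0, 67.8, -28.3, 54.2),
    ("F3", 150.0, 1.5, 22.5, 157.7, 78.9, -30.8, 69.8),
    ("F4", 150.0, 2.0, 30.0, 141.9, 81.3, -34.9, 89.6),
    ("F5", 150.0, 1.5, 22.5, 161.6, 81.4, -30.2, 70.3),
    ("F6", 100.0, 2.0, 22.5, 107.2, 59.5, -29.6, 78.6),
    ("F7", 200.0, 2.0, 22.5, 203.2, 83.8, -29.9, 75.4),
    ("F8", 150.0, 1.5, 22.5, 167.0, 83.2, -34.8, 72.3),
    ("F9", 150.0, 1.5, 22.5, 168.4, 82.9, -30.7, 71.3),
    ("F10", 100.0, 1.0, 22.5, 132.0, 61.8, -31.5, 66.9),
    ("F11", 150.0, 1.0, 30.0, 175.0, 85.3, -29.8, 80.5),
    ("F12", 200.0, 1.0, 22.5, 230.8, 91.4, -31.3, 65.7),
    ("F13", 200.0, 1.5, 30.0, 211.6, 89.5, -35.1, 82.5),
    ("F14", 100.0, 1.5, 15.0, 125.4, 54.1, -33.1, 59.3),
    ("F15", 200.0, 1.5, 15.0, 218.7, 86.9, -27.5, 57.3),
    ("F16", 150.0, 2.0, 15.0, 148.0, 65.4, -32.1, 61.4),
    ("F17", 150.0, 1.5, 22.5, 171.3, 84.3, -28.9, 71.8),
)

RESPONSE_NAMES = ("PS", "EE", "ZP", "CDR")


def bbd_run_table() -> list[dict]:
    """The 17 formulation runs as dicts of factor and response values."""
    out = []
    for label, gms, pol, oa, ps, ee, zp, cdr in _BBD_ROWS:
        out.append({
            "run": label,
            "GMS": gms, "poloxamer": pol, "oleic_acid": oa,
            "PS": ps, "EE": ee, "ZP": zp, "CDR": cdr,
        })
    return out


def bbd_design_matrix() -> DesignMatrix:
    """The 17 runs as a coded DesignMatrix, in table row order."""
    actual = np.array([[r[1], r[2], r[3]] for r in _BBD_ROWS])
    centers = np.array([f.center for f in FACTORS])
    halves = np.array([f.half_range for f in FACTORS])
    coded = (actual - centers) / halves
    coded = np.round(coded)  # table levels are exactly -1/0/+1
    return DesignMatrix(factors=FACTORS, coded=coded)


def response_values(name: str) -> np.ndarray:
    """One response column over the 17 runs, table row order."""
    idx = 4 + RESPONSE_NAMES.index(name)
    return np.array([r[idx] for r in _BBD_ROWS], dtype=float)


# Published non-compartmental parameters per (formulation, tissue).
# AUC in ng/mL x min; Ke in 1/min; Cmax ng/mL; Tmax min.
PK_TABLE = {
    ("BER-SOL (IV)", "brain"): {"Tmax": 30.0, "Cmax": 780.0, "Ke": 0.005,
                                "t_half": 128.5, "AUC_0_t": 74944.0},
    ("BER-SOL (IV)", "blood"): {"Tmax": 15.0, "Cmax": 4600.0, "Ke": 0.017,
                                "t_half": 41.5, "AUC_0_t": 313493.0},
    ("BER-SOL (IN)", "brain"): {"Tmax": 45.0, "Cmax": 748.0, "Ke": 0.005,
                                "t_half": 144.6, "AUC_0_t": 137275.0},
    ("BER-SOL (IN)", "blood"): {"Tmax": 45.0, "Cmax": 1000.0, "Ke": 0.009,
                                "t_half": 75.1, "AUC_0_t": 139171.0},
    ("BER-CTS-NLCs (IN)", "brain"): {"Tmax": 120.0, "Cmax": 1033.0, "Ke": 0.003,
                                     "t_half": 247.2, "AUC_0_t": 469403.0},
    ("BER-CTS-NLCs (IN)", "blood"): {"Tmax": 120.0, "Cmax": 1639.0, "Ke": 0.005,
                                     "t_half": 127.8, "AUC_0_t": 385609.0},
}

# Published permeation panel: flux (ug/cm2/h), 12-h cumulative amount
# (ug/cm2) and permeability coefficient (cm/h).
PERMEATION_TABLE = {
    "BER-CTS-NLCs": {"Jss": 10.63, "Q12h": 472.8, "Papp": 0.01063,
                     "percent": 78.8},
    "BER-SOL": {"Jss": 5.79, "Q12h": 271.2, "Papp": 0.00579,
                "percent": 45.2},
}

# The published cumulative/percent pairs imply a donor dose per membrane
# area of 600 ug/cm2 (472.8/0.788), and the Jss/Papp pairs imply a donor
# concentration of 1000 ug/mL; both are back-derived, not stated.
PERMEATION_DOSE_PER_AREA_UG_CM2 = 600.0
PERMEATION_DONOR_CONC_UG_ML = 1000.0

# Published optimum: factor settings, measured vs model-predicted responses.
OPTIMAL_FORMULATION = {
    "factors": {"GMS": 114.7, "poloxamer": 1.8, "oleic_acid": 30.0},
    "experimental": {"PS": 142.1, "EE": 80.3, "CDR": 85.6},
    "predicted": {"PS": 119.8, "EE": 76.1, "CDR": 88.2},
    "overall_desirability": 0.84,
}
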
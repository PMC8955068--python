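"""Transformed polynomial response-surface models on coded factors.

The workflow mirrors what formulation scientists do in Design-Expert:
fit an ordinary-least-squares polynomial to a (possibly transformed)
response over coded factors, then judge it with a Type III ANOVA, a
lack-of-fit test against pure error from replicated center points, and
the R-squared family (plain, adjusted, predicted-via-PRESS) together
with the residual SD, %CV and the "adequate precision" signal-to-noise
ratio.

Terms are named ``intercept``, ``x1``..``x3`` (linear), ``x1x2`` etc.
(two-way interactions) and ``x1^2`` etc. (squares).  All coefficients
live on the transformed response scale in coded units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .design import DesignMatrix
from .errors import (
    SingularFitError,
    TransformDomainError,
    UndefinedStatisticError,
)

__all__ = [
    "Transform",
    "IDENTITY",
    "SQRT",
    "INVERSE",
    "TermSet",
    "FittedModel",
    "AnovaTable",
    "FitStats",
    "apply_transform",
    "fit_rsm",
    "anova_type3",
    "fit_stats",
    "reduce_model",
    "predict",
]

INTERCEPT = "intercept"
LINEAR = ("x1", "x2", "x3")
INTERACTIONS = ("x1x2", "x1x3", "x2x3")
SQUARES = ("x1^2", "x2^2", "x3^2")
ALL_TERMS = (INTERCEPT,) + LINEAR + INTERACTIONS + SQUARES


# ---------------------------------------------------------------------------
# Transforms

@dataclass(frozen=True)
class Transform:
    """A variance-stabilising response transform (identity, sqrt or inverse)."""

    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "sqrt", "inverse"):
            raise ValueError(f"unknown transform kind {self.kind!r}")

    def apply(self, values):
        return apply_transform(values, self)

    def invert(self, values):
        values = np.asarray(values, dtype=float)
        if self.kind == "identity":
            return values
        if self.kind == "sqrt":
            if np.any(values < 0):
                raise TransformDomainError(
                    "cannot square-invert a negative transformed value"
                )
            return values ** 2
        if np.any(values == 0):
            raise TransformDomainError("cannot invert a zero transformed value")
        return 1.0 / values


IDENTITY = Transform("identity")
SQRT = Transform("sqrt")
INVERSE = Transform("inverse")


def apply_transform(values, spec: Transform):
    """Elementwise response transform, with domain checks naming the run."""
    values = np.asarray(values, dtype=float)
    if spec.kind == "identity":
        return values.copy()
    if spec.kind == "sqrt":
        bad = np.flatnonzero(values < 0)
        if bad.size:
            raise TransformDomainError(
                f"sqrt transform undefined for negative response at run index {bad[0]}"
            )
        return np.sqrt(values)
    bad = np.flatnonzero(values == 0)
    if bad.size:
        raise TransformDomainError(
            f"inverse transform undefined for zero response at run index {bad[0]}"
        )
    return 1.0 / values


# ---------------------------------------------------------------------------
# Term sets

_PARENTS = {
    "x1x2": ("x1", "x2"),
    "x1x3": ("x1", "x3"),
    "x2x3": ("x2", "x3"),
    "x1^2": ("x1",),
    "x2^2": ("x2",),
    "x3^2": ("x3",),
}


class TermSet(tuple):
    """Ordered, validated collection of polynomial model terms.

    The intercept is always present and hierarchy is enforced: an
    interaction or square term may only appear together with its parent
    linear terms (weak heredity).
    """

    def __new__(cls, terms):
        terms = list(terms)
        if INTERCEPT not in terms:
            terms = [INTERCEPT] + terms
        for t in terms:
            if t not in ALL_TERMS:
                raise ValueError(f"unknown model term {t!r}")
        for t in terms:
            for parent in _PARENTS.get(t, ()):
                if parent not in terms:
                    raise ValueError(
                        f"term {t!r} requires its parent linear term {parent!r}"
                    )
        ordered = [t for t in ALL_TERMS if t in terms]
        return super().__new__(cls, ordered)

    @classmethod
    def linear(cls) -> "TermSet":
        return cls(LINEAR)

    @classmethod
    def full_quadratic(cls) -> "TermSet":
        return cls(ALL_TERMS)


def _term_column(term: str, coded: np.ndarray) -> np.ndarray:
    if term == INTERCEPT:
        return np.ones(coded.shape[0])
    if term in LINEAR:
        return coded[:, LINEAR.index(term)]
    if term in INTERACTIONS:
        i, j = _PARENTS[term]
        return coded[:, LINEAR.index(i)] * coded[:, LINEAR.index(j)]
    i = _PARENTS[term][0]
    return coded[:, LINEAR.index(i)] ** 2


def model_matrix(terms: TermSet, coded: np.ndarray) -> np.ndarray:
    """Columns of the polynomial model, one per term, in TermSet order."""
    coded = np.asarray(coded, dtype=float)
    if coded.ndim == 1:
        coded = coded[None, :]
    return np.column_stack([_term_column(t, coded) for t in terms])


# ---------------------------------------------------------------------------
# Fitting

@dataclass
class FittedModel:
    """An OLS polynomial fit of a transformed response over coded factors."""

    response: str
    transform: Transform
    terms: TermSet
    coef: np.ndarray
    design: DesignMatrix
    y_transformed: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    hat_diag: np.ndarray

    @property
    def n(self) -> int:
        return self.y_transformed.size

    @property
    def p(self) -> int:
        return len(self.terms)

    @property
    def df_resid(self) -> int:
        return self.n - self.p

    def coefficients(self) -> dict[str, float]:
        return {t: float(c) for t, c in zip(self.terms, self.coef)}

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "transform": self.transform.kind,
            "terms": list(self.terms),
            "coefficients": self.coefficients(),
            "df_resid": self.df_resid,
        }


def fit_rsm(design: DesignMatrix, response_values, terms: TermSet,
            transform: Transform = IDENTITY,
            response_name: str = "response") -> FittedModel:
    """Ordinary least squares of the transformed response on coded terms."""
    terms = TermSet(terms)
    y = apply_transform(response_values, transform)
    if y.size != design.n_runs:
        raise ValueError("response length does not match design run count")
    if design.n_runs < len(terms) + 1:
        raise SingularFitError(
            f"{design.n_runs} runs cannot support {len(terms)} model terms"
        )
    X = model_matrix(terms, design.coded)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError("model matrix is rank deficient")
    ols = sm.OLS(y, X).fit()
    fitted = np.asarray(ols.fittedvalues)
    return FittedModel(
        response=response_name,
        transform=transform,
        terms=terms,
        coef=np.asarray(ols.params),
        design=design,
        y_transformed=y,
        fitted=fitted,
        residuals=y - fitted,
        hat_diag=np.asarray(ols.get_influence().hat_matrix_diag),
    )


def predict(model: FittedModel, coded_point, *, extrapolate: bool = False) -> float:
    """Evaluate the model at a coded point on the original response scale."""
    pt = np.asarray(coded_point, dtype=float)
    if not extrapolate and np.any(np.abs(pt) > 1.2):
        raise ValueError(
            f"coded point {pt.tolist()} lies outside [-1.2, 1.2]^3; "
            "pass extrapolate=True to override"
        )
    z = float((model_matrix(model.terms, pt) @ model.coef)[0])
    if model.transform.kind in ("sqrt", "inverse") and z <= 0:
        raise TransformDomainError(
            f"transformed prediction {z:.6g} outside the domain of the "
            f"{model.transform.kind} back-transform"
        )
    return float(model.transform.invert(z))


# ---------------------------------------------------------------------------
# ANOVA and diagnostics

@dataclass
class AnovaTable:
    """Type III ANOVA with a replicate-based lack-of-fit partition."""

    term_f: dict[str, float]
    term_p: dict[str, float]
    model_f: float
    model_p: float
    lof_f: float | None
    lof_p: float | None
    df_lof: int | None
    df_pe: int | None

    def to_dict(self) -> dict:
        return {
            "terms": {t: {"F": self.term_f[t], "p": self.term_p[t]}
                      for t in self.term_f},
            "model": {"F": self.model_f, "p": self.model_p},
            "lack_of_fit": None if self.lof_f is None else {
                "F": self.lof_f, "p": self.lof_p,
                "df_lof": self.df_lof, "df_pe": self.df_pe,
            },
        }


def _replicate_groups(coded: np.ndarray) -> list[np.ndarray]:
    """Indices of runs sharing identical coded settings (size > 1)."""
    keys: dict[tuple, list[int]] = {}
    for i, row in enumerate(coded):
        keys.setdefault(tuple(row.tolist()), []).append(i)
    return [np.array(ix) for ix in keys.values() if len(ix) > 1]


def _pure_error(model: FittedModel) -> tuple[float, int]:
    """Pure-error SS and df from replicate groups, on the transformed scale."""
    ss, df = 0.0, 0
    for idx in _replicate_groups(model.design.coded):
        grp = model.y_transformed[idx]
        ss += float(np.sum((grp - grp.mean()) ** 2))
        df += len(idx) - 1
    return ss, df


def anova_type3(model: FittedModel, design: DesignMatrix | None = None) -> AnovaTable:
    """Type III (partial, drop-one-term) ANOVA for a fitted model.

    Each non-intercept term's F statistic compares the full fit against
    the fit with that single column removed; the lack-of-fit test
    partitions the residual SS into pure error (within replicate groups)
    and lack of fit.  When the design has no replicates the lack-of-fit
    entries are ``None``.
    """
    design = design if design is not None else model.design
    y = model.y_transformed
    n, p = model.n, model.p
    sse = float(model.residuals @ model.residuals)
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = sst - sse
    mse = sse / (n - p)

    X = model_matrix(model.terms, design.coded)
    term_f, term_p = {}, {}
    for i, term in enumerate(model.terms):
        if term == INTERCEPT:
            continue
        Xr = np.delete(X, i, axis=1)
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        sse_r = float((y - Xr @ br) @ (y - Xr @ br))
        f = (sse_r - sse) / mse
        term_f[term] = f
        term_p[term] = float(stats.f.sf(f, 1, n - p))

    model_f = (ssr / (p - 1)) / mse
    model_p = float(stats.f.sf(model_f, p - 1, n - p))

    ss_pe, df_pe = _pure_error(model)
    if df_pe == 0:
        return AnovaTable(term_f, term_p, model_f, model_p,
                          None, None, None, None)
    df_lof = (n - p) - df_pe
    ss_lof = sse - ss_pe
    lof_f = (ss_lof / df_lof) / (ss_pe / df_pe)
    lof_p = float(stats.f.sf(lof_f, df_lof, df_pe))
    return AnovaTable(term_f, term_p, model_f, model_p,
                      lof_f, lof_p, df_lof, df_pe)


@dataclass
class FitStats:
    """Design-Expert-style goodness-of-fit panel (transformed scale)."""

    r2: float
    adj_r2: float
    pred_r2: float
    sd: float
    cv_percent: float
    adequate_precision: float

    def to_dict(self) -> dict:
        return {
            "R2": self.r2, "adjusted_R2": self.adj_r2,
            "predicted_R2": self.pred_r2, "SD": self.sd,
            "CV_percent": self.cv_percent,
            "adequate_precision": self.adequate_precision,
        }


def fit_stats(model: FittedModel, design: DesignMatrix | None = None) -> FitStats:
    """R-squared family, residual SD, %CV and adequate precision.

    Predicted R-squared uses PRESS from the leave-one-out identity
    ``e_i / (1 - h_ii)``; adequate precision is the range of fitted
    values at the design points divided by ``sqrt(p * MSE / n)``.
    """
    y = model.y_transformed
    n, p = model.n, model.p
    sse = float(model.residuals @ model.residuals)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise UndefinedStatisticError("total sum of squares is zero")
    mse = sse / (n - p)
    press = float(np.sum((model.residuals / (1.0 - model.hat_diag)) ** 2))
    sd = float(np.sqrt(mse))
    adeq = float((model.fitted.max() - model.fitted.min())
                 / np.sqrt(p * mse / n))
    return FitStats(
        r2=1.0 - sse / sst,
        adj_r2=1.0 - (sse / (n - p)) / (sst / (n - 1)),
        pred_r2=1.0 - press / sst,
        sd=sd,
        cv_percent=100.0 * sd / float(y.mean()),
        adequate_precision=adeq,
    )


# ---------------------------------------------------------------------------
# Model reduction

def _removable(term: str, terms: TermSet) -> bool:
    """A term may leave the model only if nothing remaining depends on it."""
    if term == INTERCEPT:
        return False
    return all(term not in _PARENTS.get(other, ()) for other in terms
               if other != term)


def reduce_model(model: FittedModel, alpha: float = 0.05) -> FittedModel:
    """Backward elimination by largest partial-F p-value above ``alpha``.

    The intercept never leaves and hierarchy is preserved: a linear term
    is retained while any of its interactions or its square remains.
    The model is refit after every removal.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    current = model
    while True:
        table = anova_type3(current)
        candidates = {
            t: pv for t, pv in table.term_p.items()
            if pv > alpha and _removable(t, current.terms)
        }
        if not candidates:
            return current
        worst = max(candidates, key=candidates.get)
        new_terms = TermSet([t for t in current.terms if t != worst])
        current = fit_rsm(
            current.design,
            current.transform.invert(current.y_transformed),
            new_terms,
            current.transform,
            response_name=current.response,
        )


def closed_form_linear_fit(design: DesignMatrix, response_values,
                           transform: Transform = IDENTITY) -> dict[str, float]:
    """Closed-form linear coefficients for a 3-factor BBD.

    On a Box-Behnken design the linear columns are orthogonal with sum
    of squares 8, so the coefficient for ``xj`` is
    ``(sum of y over xj=+1 runs - sum over xj=-1 runs) / 8`` and the
    intercept is the mean transformed response.  Serves as an
    independent cross-check of the OLS path.
    """
    y = apply_transform(response_values, transform)
    coefs = {INTERCEPT: float(y.mean())}
    for j, name in enumerate(LINEAR):
        col = design.coded[:, j]
        coefs[name] = float((y[col == 1].sum() - y[col == -1].sum()) / 8.0)
    return coefs
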
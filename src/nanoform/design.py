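"""Three-factor Box-Behnken designs and coded/actual factor mapping.

A Box-Behnken design (BBD) for three factors places runs at the midpoints
of the twelve edges of the factor cube — every permutation of
(+/-1, +/-1, 0) — plus a block of replicated center points.  Coded units
map the low/mid/high factor levels to -1/0/+1, so the linear model
columns are orthogonal and each carries a sum of squares of 8 for the
17-run design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import DesignError

__all__ = ["FactorDef", "DesignMatrix", "build_bbd", "to_coded", "to_actual"]


@dataclass(frozen=True)
class FactorDef:
    """A single design factor with its low/high levels in actual units."""

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise DesignError(
                f"factor {self.name!r}: low level ({self.low}) must be "
                f"strictly below high level ({self.high})"
            )

    @property
    def center(self) -> float:
        return (self.low + self.high) / 2.0

    @property
    def half_range(self) -> float:
        return (self.high - self.low) / 2.0


def to_coded(factor: FactorDef, actual: float) -> float:
    """Map an actual-unit value onto the coded -1..+1 scale.

    Extrapolation beyond the design region is allowed; values with
    ``|coded| > 1`` are simply returned as is.
    """
    return (actual - factor.center) / factor.half_range


def to_actual(factor: FactorDef, coded: float) -> float:
    """Exact inverse of :func:`to_coded`."""
    return factor.center + coded * factor.half_range


@dataclass
class DesignMatrix:
    """An ordered set of design runs in coded units.

    ``coded`` holds one row per run; generated BBDs use exact integer
    levels in {-1, 0, +1} so orthogonality checks are free of float
    drift.  ``center_mask`` flags the replicated center runs.
    """

    factors: tuple[FactorDef, ...]
    coded: np.ndarray
    center_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coded = np.asarray(self.coded, dtype=float)
        if self.coded.ndim != 2 or self.coded.shape[1] != len(self.factors):
            raise DesignError("coded matrix shape does not match factor count")
        if self.center_mask is None:
            self.center_mask = np.all(self.coded == 0.0, axis=1)
        self.center_mask = np.asarray(self.center_mask, dtype=bool)

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def n_center(self) -> int:
        return int(self.center_mask.sum())

    def actual(self) -> np.ndarray:
        """Runs converted to actual factor units, same row order."""
        centers = np.array([f.center for f in self.factors])
        halves = np.array([f.half_range for f in self.factors])
        return centers + self.coded * halves

    def coded_from_actual(self, actual_rows: np.ndarray) -> np.ndarray:
        centers = np.array([f.center for f in self.factors])
        halves = np.array([f.half_range for f in self.factors])
        return (np.asarray(actual_rows, dtype=float) - centers) / halves


def build_bbd(factors: tuple[FactorDef, ...] | list[FactorDef],
              center_replicates: int = 5) -> DesignMatrix:
    """Construct the canonical 3-factor Box-Behnken design.

    The twelve edge-midpoint rows are ordered lexicographically by
    (index of the zero coordinate, then signs of the two active
    factors); the ``center_replicates`` center rows come last.
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise DesignError(
            f"only the 3-factor Box-Behnken design is supported, got {len(factors)} factors"
        )
    if center_replicates < 0:
        raise DesignError("center_replicates must be non-negative")

    rows = []
    for zero_idx in range(3):
        active = [i for i in range(3) if i != zero_idx]
        for s1, s2 in itertools.product((-1, 1), repeat=2):
            row = [0, 0, 0]
            row[active[0]] = s1
            row[active[1]] = s2
            rows.append(row)
    rows.extend([[0, 0, 0]] * center_replicates)
    coded = np.array(rows, dtype=float)
    mask = np.zeros(len(rows), dtype=bool)
    mask[12:] = True
    return DesignMatrix(factors=factors, coded=coded, center_mask=mask)
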
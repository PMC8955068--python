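"""Study configuration: factors, responses, protocol constants.

Internally all times are minutes, concentrations ng/mL and amounts ug;
permeation runs use hours and ug/mL as is conventional for Franz-cell
work.  The permeation geometry (membrane area, donor dose/volume,
receptor and sample volumes) must be stated explicitly — published
release and permeation protocols often leave parts of the geometry
implicit, so nothing here is defaulted silently from another field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .design import FactorDef
from .errors import FormatError

__all__ = ["ResponseDef", "PermeationSettings", "SearchSettings", "StudyConfig"]


@dataclass(frozen=True)
class ResponseDef:
    """One measured response: its transform for modelling and its goal."""

    name: str
    transform: str = "identity"  # identity | sqrt | inverse
    goal: str | None = None      # minimize | maximize | None (excluded)
    units: str = ""

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "sqrt", "inverse"):
            raise FormatError(f"unknown transform {self.transform!r}")
        if self.goal not in (None, "minimize", "maximize"):
            raise FormatError(f"unknown goal {self.goal!r}")


@dataclass(frozen=True)
class PermeationSettings:
    area_cm2: float
    donor_dose_ug: float
    donor_volume_ml: float
    receptor_volume_ml: float
    sample_volume_ml: float

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise FormatError(f"permeation setting {name} must be positive, got {v}")

    @property
    def donor_concentration_ug_ml(self) -> float:
        return self.donor_dose_ug / self.donor_volume_ml

    @property
    def dose_per_area_ug_cm2(self) -> float:
        return self.donor_dose_ug / self.area_cm2


@dataclass(frozen=True)
class SearchSettings:
    """Desirability search: grid density then local refinement tolerance."""

    grid_density: int = 41
    refine_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_density < 2:
            raise FormatError("grid_density must be at least 2")
        if self.refine_tol <= 0:
            raise FormatError("refine_tol must be positive")


@dataclass
class StudyConfig:
    factors: tuple[FactorDef, ...]
    responses: tuple[ResponseDef, ...]
    n_terminal_points: int = 3
    auc_end_min: float = 480.0
    search: SearchSettings = field(default_factory=SearchSettings)
    permeation: PermeationSettings | None = None

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        self.responses = tuple(self.responses)
        if self.auc_end_min <= 0:
            raise FormatError("AUC end time must be positive")
        if self.n_terminal_points < 2:
            raise FormatError("terminal fit needs at least 2 points")

    def response(self, name: str) -> ResponseDef:
        for r in self.responses:
            if r.name == name:
                return r
        raise KeyError(f"no response named {name!r}")

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def response_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.responses)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "factors": [asdict(f) for f in self.factors],
            "responses": [asdict(r) for r in self.responses],
            "n_terminal_points": self.n_terminal_points,
            "auc_end_min": self.auc_end_min,
            "search": asdict(self.search),
        }
        if self.permeation is not None:
            d["permeation"] = asdict(self.permeation)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        return cls(
            factors=tuple(FactorDef(**f) for f in d["factors"]),
            responses=tuple(ResponseDef(**r) for r in d["responses"]),
            n_terminal_points=d.get("n_terminal_points", 3),
            auc_end_min=d.get("auc_end_min", 480.0),
            search=SearchSettings(**d.get("search", {})),
            permeation=(PermeationSettings(**d["permeation"])
                        if "permeation" in d else None),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_study_config() -> StudyConfig:
    """Configuration of the embedded formulation study.

    The permeation block uses the cell geometry consistent with the
    published cumulative-percent pairs: 600 ug/cm2 dose per area and a
    1000 ug/mL donor concentration (3 mg dose, 5 cm2, 3 mL donor).
    """
    from .fixtures import FACTORS
    return StudyConfig(
        factors=FACTORS,
        responses=(
            ResponseDef("PS", "sqrt", "minimize", "nm"),
            ResponseDef("EE", "inverse", "maximize", "%"),
            ResponseDef("ZP", "identity", None, "mV"),
            ResponseDef("CDR", "identity", "maximize", "%"),
        ),
        n_terminal_points=3,
        auc_end_min=480.0,
        permeation=PermeationSettings(
            area_cm2=5.0, donor_dose_ug=3000.0, donor_volume_ml=3.0,
            receptor_volume_ml=50.0, sample_volume_ml=1.0,
        ),
    )
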
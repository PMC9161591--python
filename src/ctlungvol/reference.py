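"""Predicted forced vital capacity from demographics.

Spirometry reference equations are almost universally linear in height and
age within each sex:

    FVC_pred (L) = alpha * height_cm + beta * age_years + gamma

Which coefficients apply depends on the population (ethnicity enters by
choosing the equation set), so equation sets are configuration data, not
code.  A placeholder default set ships with the package; swap it for the
published set appropriate to your cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .errors import EquationDomainError

__all__ = [
    "Demographics",
    "SexCoefficients",
    "ReferenceEquationSet",
    "predicted_fvc",
    "load_equation_set",
    "default_equation_set",
]


@dataclass(frozen=True)
class Demographics:
    """Sex, age (years) and height (cm) of one subject."""

    sex: str
    age: float
    height: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.age > 0:
            raise ValueError("age must be positive")
        if not self.height > 0:
            raise ValueError("height must be positive")


@dataclass(frozen=True)
class SexCoefficients:
    alpha: float  # L per cm of height
    beta: float   # L per year of age
    gamma: float  # L intercept


@dataclass(frozen=True)
class ReferenceEquationSet:
    """A named pair of per-sex linear FVC prediction equations."""

    name: str
    male: SexCoefficients
    female: SexCoefficients
    valid_age: tuple[float, float] = (18.0, 95.0)
    valid_height: tuple[float, float] = (120.0, 200.0)

    def coefficients(self, sex: str) -> SexCoefficients:
        if sex == "male":
            return self.male
        if sex == "female":
            return self.female
        raise ValueError(f"unknown sex code {sex!r}")


def predicted_fvc(d: Demographics, eq: ReferenceEquationSet) -> float:
    """Predicted FVC in litres for the given demographics.

    Out-of-range age or height triggers a warning but the prediction is
    still computed; a non-positive prediction is an error because the
    standardised volume would be meaningless.
    """
    c = eq.coefficients(d.sex)
    lo, hi = eq.valid_age
    if not lo <= d.age <= hi:
        warnings.warn(
            f"age {d.age} outside valid range [{lo}, {hi}] of equation set {eq.name!r}"
        )
    lo, hi = eq.valid_height
    if not lo <= d.height <= hi:
        warnings.warn(
            f"height {d.height} outside valid range [{lo}, {hi}] "
            f"of equation set {eq.name!r}"
        )
    fvc = c.alpha * d.height + c.beta * d.age + c.gamma
    if not fvc > 0:
        raise EquationDomainError(
            f"non-positive predicted FVC ({fvc:.3f} L) for {d} with set {eq.name!r}"
        )
    return float(fvc)


def _set_from_dict(doc: dict) -> ReferenceEquationSet:
    def coeffs(sex: str) -> SexCoefficients:
        c = doc[sex]
        return SexCoefficients(float(c["alpha"]), float(c["beta"]), float(c["gamma"]))

    kwargs = {}
    for key in ("valid_age", "valid_height"):
        if key in doc:
            kwargs[key] = tuple(float(v) for v in doc[key])
    return ReferenceEquationSet(
        name=str(doc["name"]), male=coeffs("male"), female=coeffs("female"), **kwargs
    )


def load_equation_set(path: str | Path) -> ReferenceEquationSet:
    """Load an equation set from a YAML file (see data/default_fvc.yaml)."""
    with open(path) as fh:
        return _set_from_dict(yaml.safe_load(fh))


def default_equation_set() -> ReferenceEquationSet:
    """The placeholder equation set bundled with the package."""
    text = (
        resources.files("ctlungvol").joinpath("data/default_fvc.yaml").read_text()
    )
    return _set_from_dict(yaml.safe_load(text))
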
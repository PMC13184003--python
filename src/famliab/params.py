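"""ACE variance-component parameters and kinship sharing coefficients.

The liability-threshold ACE model decomposes the variance of a latent
standard-normal liability into additive-genetic (A), common/shared
environmental (C) and unique environmental (E) components.  A relative
pair of a given kinship shares a fraction ``alpha`` of the A variance
(expected identity-by-descent sharing) and a fraction ``gamma`` (0 or 1)
of the C variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "AceParams",
    "BivariateAceParams",
    "Kinship",
    "KinshipCoefficients",
    "KINSHIP_COEFFICIENTS",
]

_TOL = 1e-12


class Kinship(str, Enum):
    """Relative-pair types distinguished by the analyses."""

    MZ_TWIN = "MZ_twin"
    DZ_TWIN = "DZ_twin"
    FULL_SIB = "full_sib"
    MATERNAL_HALF_SIB = "maternal_half_sib"
    PATERNAL_HALF_SIB = "paternal_half_sib"
    PARENT_CHILD = "parent_child"
    AUNT_UNCLE = "aunt_uncle"
    COUSIN = "cousin"


@dataclass(frozen=True)
class KinshipCoefficients:
    """Expected shared fractions of A (``alpha``) and C (``gamma``) variance."""

    kinship: Kinship
    alpha: float
    gamma: float

    def __post_init__(self) -> None:
        if self.alpha not in (1.0, 0.5, 0.25, 0.125):
            raise ValueError(f"alpha must be in {{1, 0.5, 0.25, 0.125}}, got {self.alpha}")
        if self.gamma not in (0.0, 1.0):
            raise ValueError(f"gamma must be 0 or 1, got {self.gamma}")


#: Sharing coefficients per kinship.  Full siblings and DZ twins share half of
#: the additive-genetic variance and (by the household model) all of the common
#: environment; maternal half-siblings grow up with their shared mother and so
#: share C, paternal half-siblings do not.
KINSHIP_COEFFICIENTS: dict[Kinship, KinshipCoefficients] = {
    Kinship.MZ_TWIN: KinshipCoefficients(Kinship.MZ_TWIN, 1.0, 1.0),
    Kinship.DZ_TWIN: KinshipCoefficients(Kinship.DZ_TWIN, 0.5, 1.0),
    Kinship.FULL_SIB: KinshipCoefficients(Kinship.FULL_SIB, 0.5, 1.0),
    Kinship.MATERNAL_HALF_SIB: KinshipCoefficients(Kinship.MATERNAL_HALF_SIB, 0.25, 1.0),
    Kinship.PATERNAL_HALF_SIB: KinshipCoefficients(Kinship.PATERNAL_HALF_SIB, 0.25, 0.0),
    Kinship.PARENT_CHILD: KinshipCoefficients(Kinship.PARENT_CHILD, 0.5, 0.0),
    Kinship.AUNT_UNCLE: KinshipCoefficients(Kinship.AUNT_UNCLE, 0.25, 0.0),
    Kinship.COUSIN: KinshipCoefficients(Kinship.COUSIN, 0.125, 0.0),
}

#: Kinship types where both members are drawn from the same (proband) generation.
WITHIN_GENERATION: frozenset[Kinship] = frozenset(
    {
        Kinship.MZ_TWIN,
        Kinship.DZ_TWIN,
        Kinship.FULL_SIB,
        Kinship.MATERNAL_HALF_SIB,
        Kinship.PATERNAL_HALF_SIB,
        Kinship.COUSIN,
    }
)


@dataclass(frozen=True)
class AceParams:
    """Variance shares of one trait's liability: a2 + c2 + e2 = 1."""

    a2: float
    c2: float
    e2: float

    def __post_init__(self) -> None:
        for name, v in (("a2", self.a2), ("c2", self.c2), ("e2", self.e2)):
            if v < -_TOL:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-9:
            raise ValueError(
                f"variance shares must sum to 1, got {self.a2 + self.c2 + self.e2}"
            )

    @property
    def a(self) -> float:
        return math.sqrt(max(self.a2, 0.0))

    @property
    def c(self) -> float:
        return math.sqrt(max(self.c2, 0.0))

    @property
    def e(self) -> float:
        return math.sqrt(max(self.e2, 0.0))


@dataclass(frozen=True)
class BivariateAceParams:
    """Two traits' ACE shares plus factor correlations rA, rC, rE.

    The implied within-person cross-trait (phenotypic) correlation is

        r_ph = a1*a2*rA + c1*c2*rC + e1*e2*rE

    with a_t = sqrt(a2 of trait t) etc.
    """

    trait1: AceParams
    trait2: AceParams
    rA: float
    rC: float
    rE: float

    def __post_init__(self) -> None:
        for name, r in (("rA", self.rA), ("rC", self.rC), ("rE", self.rE)):
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {r}")
        if not -1.0 - 1e-12 <= self.r_ph <= 1.0 + 1e-12:
            raise ValueError(f"implied phenotypic correlation {self.r_ph} outside [-1, 1]")

    @property
    def r_ph(self) -> float:
        t1, t2 = self.trait1, self.trait2
        return t1.a * t2.a * self.rA + t1.c * t2.c * self.rC + t1.e * t2.e * self.rE

    def factor_correlation_matrix(self, which: str) -> np.ndarray:
        r = {"A": self.rA, "C": self.rC, "E": self.rE}[which]
        return np.array([[1.0, r], [r, 1.0]])
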
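"""Henderson–Hasselbalch protonation fractions and three-class state labels.

A single independent titratable site with acid dissociation constant
``Ka = 10**-pKa`` has protonation probability

    Prob(pKa, pH) = 1 / (1 + 10**(pH - pKa)),

so at fixed pH the class boundaries on the pKa axis are ``pH ± log10(t/(1-t))``
for a probability threshold ``t``.  At pH 7 with t = 0.75 the boundaries are
6.52 and 7.48 (two-decimal display); classification uses the full-precision
values 7 ∓ log10(3) to avoid double-rounding artifacts near the boundaries.
High pKa at fixed pH means protonated (e.g. Lys, pKa 10.4, is Lys+ at pH 7);
low pKa means deprotonated (Asp-/Glu-).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .features import model_pka

__all__ = ["ProtonationClass", "ClassBoundaries", "protonation_fraction",
           "class_boundaries", "classify_pka", "classify_array",
           "null_predict"]


class ProtonationClass(str, Enum):
    PROTONATED = "protonated"
    DEPROTONATED = "deprotonated"
    TITRATING = "titrating"


@dataclass(frozen=True)
class ClassBoundaries:
    """pKa-axis class boundaries implied by a protonation-probability threshold."""

    ph: float = 7.0
    prob_threshold: float = 0.75
    lo: float = field(init=False)
    hi: float = field(init=False)

    def __post_init__(self):
        if not 0.5 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must lie in (0.5, 1)")
        width = np.log10(self.prob_threshold / (1.0 - self.prob_threshold))
        object.__setattr__(self, "lo", self.ph - width)
        object.__setattr__(self, "hi", self.ph + width)

    def display(self) -> tuple[float, float]:
        """Two-decimal boundaries for reporting."""
        return (round(self.lo, 2), round(self.hi, 2))


def protonation_fraction(pka, ph):
    """Protonation probability 1/(1 + 10**(ph - pka)); broadcasts."""
    pka = np.asarray(pka, dtype=float)
    ph = np.asarray(ph, dtype=float)
    out = 1.0 / (1.0 + np.power(10.0, ph - pka))
    return float(out) if out.ndim == 0 else out


def class_boundaries(ph: float = 7.0,
                     prob_threshold: float = 0.75) -> ClassBoundaries:
    return ClassBoundaries(ph=ph, prob_threshold=prob_threshold)


def classify_pka(pka: float, boundaries: ClassBoundaries) -> ProtonationClass:
    """Three-class protonation state of a pKa at the boundaries' pH.

    Boundaries are inclusive into the titrating class.
    """
    if pka > boundaries.hi:
        return ProtonationClass.PROTONATED
    if pka < boundaries.lo:
        return ProtonationClass.DEPROTONATED
    return ProtonationClass.TITRATING


def classify_array(pka, boundaries: ClassBoundaries) -> np.ndarray:
    """Vectorized classify_pka; returns an array of class-name strings."""
    pka = np.asarray(pka, dtype=float)
    out = np.full(pka.shape, ProtonationClass.TITRATING.value, dtype=object)
    out[pka > boundaries.hi] = ProtonationClass.PROTONATED.value
    out[pka < boundaries.lo] = ProtonationClass.DEPROTONATED.value
    return out


def null_predict(aa: str) -> float:
    """Baseline predictor: the solution (model) pKa of the residue type."""
    return model_pka(aa)
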
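"""Beta-density MAF weights for rare-variant upweighting.

w_j = p_j^(a1-1) (1-p_j)^(a2-1) / B(a1, a2), with p_j the cohort-combined
(cases + controls) minor allele frequency. This is deliberately distinct
from the external population AF used by the rarity filter. a1 is fixed at 1
by default (the standard monotone-decreasing rare-variant family); only a2
is tuned.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ..errors import DataError

__all__ = ["WeightSpec", "beta_weight", "cohort_maf"]


def beta_weight(p_j, a1: float = 1.0, a2: float = 25.0):
    """Beta-density weight at MAF ``p_j`` (scalar or array).

    Raises for p_j in {0, 1} when the shape parameters put infinite density
    there (a < 1); common variants simply receive negligible weight.
    """
    p = np.asarray(p_j, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DataError("MAF must lie in [0, 1]")
    boundary = (p == 0) | (p == 1)
    if np.any(boundary):
        if (a1 < 1 and np.any(p == 0)) or (a2 < 1 and np.any(p == 1)):
            raise DataError("Beta density is infinite at the boundary MAF")
        if (a1 > 1 and np.any(p == 0)) or (a2 > 1 and np.any(p == 1)):
            pass  # density 0 there; pdf handles it
    w = stats.beta.pdf(p, a1, a2)
    return float(w) if np.isscalar(p_j) else w


def cohort_maf(dosages: np.ndarray) -> np.ndarray:
    """Per-variant minor allele frequency from a dosage matrix.

    Missing entries are ignored; the alternate-allele frequency is folded to
    the minor allele.
    """
    dos = np.asarray(dosages, dtype=float)
    af = np.nanmean(dos, axis=0) / 2.0
    return np.minimum(af, 1.0 - af)


@dataclass
class WeightSpec:
    """Beta weight parameters with the per-variant cohort MAFs they apply to."""

    a1: float = 1.0
    a2: float = 25.0
    p_j: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.a1 < 1 or self.a2 < 1:
            raise DataError("Beta shapes must be >= 1 for finite weights")
        self.p_j = np.asarray(self.p_j, dtype=float)

    def weights(self) -> np.ndarray:
        w = beta_weight(self.p_j, self.a1, self.a2)
        if not np.all(np.isfinite(w)):
            raise DataError("non-finite Beta weights")
        return w
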
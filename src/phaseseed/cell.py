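"""Unit-cell geometry: metric tensors, volumes and d-spacings.

All coordinates are fractional; all distances in Å.  The direct metric
tensor G turns fractional difference vectors into Cartesian lengths
(``|Δx|² = Δx·G·Δx``); its inverse G* plays the same role for Miller
indices, giving the resolution of a reflection as ``d = 1/√(h·G*·h)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = ["UnitCell", "d_spacing"]


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0°, 180°)")
        if np.linalg.det(self.metric) <= 0:
            raise ValueError("cell metric tensor is not positive definite")

    @cached_property
    def metric(self) -> np.ndarray:
        """Direct-space metric tensor G (Å²)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    @cached_property
    def reciprocal_metric(self) -> np.ndarray:
        """Reciprocal-space metric tensor G* = G⁻¹ (Å⁻²)."""
        return np.linalg.inv(self.metric)

    @cached_property
    def volume(self) -> float:
        """Cell volume in Å³."""
        return float(np.sqrt(np.linalg.det(self.metric)))

    def d_spacings(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Å) for an (N, 3) array of Miller indices."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        inv_d2 = np.einsum("ni,ij,nj->n", hkl, self.reciprocal_metric, hkl)
        if np.any(inv_d2 <= 0):
            raise ValueError("reflection (0,0,0) has no d-spacing")
        return 1.0 / np.sqrt(inv_d2)

    def distance(self, frac_a: np.ndarray, frac_b: np.ndarray) -> float:
        """Cartesian distance (Å) between two fractional positions (no imaging)."""
        d = np.asarray(frac_a, float) - np.asarray(frac_b, float)
        return float(np.sqrt(d @ self.metric @ d))


def d_spacing(cell: UnitCell, hkl) -> float:
    """Resolution of a single reflection in Å.

    Raises ``ValueError`` for the forbidden index (0,0,0).
    """
    h = np.asarray(hkl, dtype=int)
    if h.shape != (3,):
        raise ValueError("hkl must be an integer triple")
    if not h.any():
        raise ValueError("reflection (0,0,0) is not a valid Bragg reflection")
    return float(cell.d_spacings(h[None, :])[0])
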
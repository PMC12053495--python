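"""Reflection sets: symmetry-unique Bragg reflection generation and storage.

A :class:`ReflectionSet` keeps one representative per symmetry orbit
(Friedel mates merged) in a pandas DataFrame, together with the cell and
space group needed to re-expand the orbits.  F(000) and systematically
absent reflections are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell import UnitCell
from .symmetry import SpaceGroup

__all__ = ["ReflectionSet", "unique_reflections", "orbit_representatives"]

_COLUMNS = [
    "h", "k", "l", "d", "centric", "phi_restricted", "epsilon", "multiplicity",
    "f_true", "phi_true", "f_obs", "e_value", "measured",
]


@dataclass
class ReflectionSet:
    """Symmetry-independent reflections with amplitudes, phases and E-values."""

    cell: UnitCell
    spacegroup: SpaceGroup
    d_min: float
    data: pd.DataFrame
    wavelength: float = 1.5406  # Cu Kα, metadata only

    @property
    def n_refl(self) -> int:
        return len(self.data)

    @property
    def hkl(self) -> np.ndarray:
        return self.data[["h", "k", "l"]].to_numpy(dtype=int)

    @property
    def allowed_phases(self) -> np.ndarray:
        """(N, 2) allowed phases for centric reflections, NaN for general."""
        phi0 = self.data["phi_restricted"].to_numpy(float)
        return np.stack([phi0, (phi0 + 180.0) % 360.0], axis=1)

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(
            self.cell, self.spacegroup, self.d_min, self.data.copy(), self.wavelength
        )

    def __repr__(self) -> str:
        n_cen = int(self.data["centric"].sum())
        return (
            f"<ReflectionSet {self.spacegroup.symbol}, {self.n_refl} reflections "
            f"to {self.d_min:.2f} Å ({n_cen} centric)>"
        )


def _lex_keys(hkl: np.ndarray) -> np.ndarray:
    """Encode (N,3) integer triples into comparable int64 keys."""
    m = int(np.abs(hkl).max()) + 1
    base = 2 * m + 1
    return ((hkl[..., 0] + m) * base + (hkl[..., 1] + m)) * base + (hkl[..., 2] + m)


def orbit_representatives(sg: SpaceGroup, hkl: np.ndarray) -> np.ndarray:
    """Lexicographically largest member of each orbit {±h·R} (vectorized)."""
    hkl = np.asarray(hkl, dtype=int)
    rots = sg.rotations  # (m,3,3)
    orbit = np.einsum("ni,mij->mnj", hkl, rots)  # (m,N,3)
    orbit = np.concatenate([orbit, -orbit], axis=0)
    keys = _lex_keys(orbit)
    best = keys.argmax(axis=0)
    return orbit[best, np.arange(hkl.shape[0])]


def unique_reflections(
    cell: UnitCell, sg: SpaceGroup, d_min: float, wavelength: float = 1.5406
) -> ReflectionSet:
    """Generate all symmetry-independent reflections with d ≥ d_min.

    Friedel mates are merged; the orbit representative is the member with
    the lexicographically largest (h, k, l).  Systematic absences from
    screw axes and centring are removed.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    # interplanar spacing never exceeds the axial intercept spacing,
    # so |h_i| <= a_i / d_min bounds the search box
    lims = [int(np.floor(ax / d_min)) for ax in (cell.a, cell.b, cell.c)]
    grids = np.meshgrid(*[np.arange(-n, n + 1) for n in lims], indexing="ij")
    hkl = np.stack([g.ravel() for g in grids], axis=1).astype(int)
    hkl = hkl[np.any(hkl != 0, axis=1)]

    inv_d2 = np.einsum("ni,ij,nj->n", hkl.astype(float), cell.reciprocal_metric, hkl.astype(float))
    keep = inv_d2 <= (1.0 / d_min**2) * (1 + 1e-12)
    hkl, inv_d2 = hkl[keep], inv_d2[keep]

    if hkl.shape[0] == 0:
        warnings.warn(f"no reflections survive d_min = {d_min} Å", stacklevel=2)
        return ReflectionSet(cell, sg, d_min, pd.DataFrame(columns=_COLUMNS), wavelength)

    # orbit representatives (Friedel included): keep h equal to its rep
    reps = orbit_representatives(sg, hkl)
    is_rep = np.all(reps == hkl, axis=1)
    hkl, inv_d2 = hkl[is_rep], inv_d2[is_rep]

    rots, trans = sg.rotations, sg.translations
    hR = np.einsum("ni,mij->mnj", hkl, rots)  # (m,N,3)
    fixes = np.all(hR == hkl[None, :, :], axis=2)  # (m,N)
    negates = np.all(hR == -hkl[None, :, :], axis=2)
    ht = np.einsum("ni,mi->mn", hkl.astype(float), trans)  # (m,N)

    epsilon = fixes.sum(axis=0)
    frac = ht - np.round(ht)
    absent = np.any(fixes & (np.abs(frac) > 1e-9), axis=0)
    centric = negates.any(axis=0)

    # restricted phase φ0 from the first negating op: φ0 = 180·(h·t) mod 180
    phi0 = np.full(hkl.shape[0], np.nan)
    if centric.any():
        first = negates.argmax(axis=0)
        phi0_all = (180.0 * ht[first, np.arange(hkl.shape[0])]) % 180.0
        phi0[centric] = phi0_all[centric]

    # orbit multiplicity = number of distinct members of {±h·R}
    orbit = np.concatenate([hR, -hR], axis=0)  # (2m,N,3)
    keys = _lex_keys(orbit)
    mult = np.array([len(set(keys[:, i])) for i in range(keys.shape[1])])

    ok = ~absent
    hkl, inv_d2 = hkl[ok], inv_d2[ok]
    df = pd.DataFrame(
        {
            "h": hkl[:, 0],
            "k": hkl[:, 1],
            "l": hkl[:, 2],
            "d": 1.0 / np.sqrt(inv_d2),
            "centric": centric[ok],
            "phi_restricted": phi0[ok],
            "epsilon": epsilon[ok],
            "multiplicity": mult[ok],
            "f_true": np.nan,
            "phi_true": np.nan,
            "f_obs": np.nan,
            "e_value": np.nan,
            "measured": True,
        }
    )
    df = df.sort_values("d", ascending=False, kind="stable").reset_index(drop=True)
    if df.empty:
        warnings.warn(f"no reflections survive d_min = {d_min} Å", stacklevel=2)
    return ReflectionSet(cell, sg, d_min, df, wavelength)
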
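"""Structure factors, E-value normalization and the amplitude R factor.

Phase convention: F(h) = Σ_j f_j·exp(+2πi h·x_j); phases are reported in
degrees on [0, 360).
"""

from __future__ import annotations

import logging

import numpy as np

from .formfactors import scattering_factor
from .reflections import ReflectionSet
from .structure import CrystalStructure

__all__ = ["calc_structure_factors", "normalize_e_values", "r_factor"]

log = logging.getLogger(__name__)


def structure_factor_array(structure: CrystalStructure, hkl: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Complex F(h) for arbitrary index/resolution arrays (one asymmetric unit
    summed over all symmetry operators)."""
    hkl = np.asarray(hkl, float)
    s2 = 1.0 / (4.0 * np.asarray(d, float) ** 2)  # (sinθ/λ)²
    F = np.zeros(hkl.shape[0], dtype=complex)
    sg = structure.spacegroup
    by_elem: dict[str, list] = {}
    for site in structure.sites:
        by_elem.setdefault(site.element, []).append(site)
    for elem, sites in by_elem.items():
        f0 = scattering_factor(elem, s2)  # (N,)
        xyz = np.array([s.frac_xyz for s in sites])  # (A,3)
        occ = np.array([s.occupancy for s in sites])
        biso = np.array([s.b_iso for s in sites])
        dw = np.exp(-np.outer(s2, biso))  # (N,A)
        contrib = np.zeros_like(F)
        for op in sg.ops:
            hx = hkl @ (op.rot @ xyz.T) + (hkl @ op.tran)[:, None]  # (N,A)
            contrib += np.einsum("na,a,na->n", np.exp(2j * np.pi * hx), occ, dw)
        F += f0 * contrib
    return F


def calc_structure_factors(structure: CrystalStructure, refs: ReflectionSet) -> ReflectionSet:
    """Fill f_true / phi_true from the atomic model (in place, returns refs).

    Centric reflections come out on one of their two allowed phases to
    numerical precision; this is asserted softly and logged if violated.
    """
    F = structure_factor_array(structure, refs.hkl, refs.data["d"].to_numpy())
    refs.data["f_true"] = np.abs(F)
    refs.data["phi_true"] = np.degrees(np.angle(F)) % 360.0
    cen = refs.data["centric"].to_numpy(bool)
    if cen.any():
        phi = refs.data.loc[cen, "phi_true"].to_numpy()
        phi0 = refs.data.loc[cen, "phi_restricted"].to_numpy()
        dev = np.abs((phi - phi0 + 90.0) % 180.0 - 90.0)
        # snap to the exactly allowed value (fixes harmless float fuzz)
        snapped = np.where((phi - phi0 + 90.0) % 360.0 < 180.0, phi0, (phi0 + 180.0) % 360.0)
        weak = refs.data.loc[cen, "f_true"].to_numpy() < 1e-8
        if np.any((dev > 1e-3) & ~weak):
            log.warning("centric phase deviates from allowed value by up to %.3g°", dev.max())
        refs.data.loc[cen, "phi_true"] = snapped
    return refs


def normalize_e_values(
    refs: ReflectionSet, n_shells: int = 10, column: str = "f_obs"
) -> ReflectionSet:
    """Normalized structure-factor amplitudes E with ⟨E²⟩ = 1.

    E²(h) = F²(h) / (ε_h · ⟨F²/ε⟩_shell) with resolution shells of equal
    population in 1/d².  Shell averaging removes the thermal/scattering
    falloff so that E is resolution independent.
    """
    f = refs.data[column].to_numpy(float)
    if np.all(np.isnan(f)):
        f = refs.data["f_true"].to_numpy(float)
    n = len(f)
    if n == 0:
        raise ValueError("cannot normalize an empty reflection set")
    shells = max(1, min(n_shells, n // 20))
    if shells < n_shells:
        log.warning("reduced E-normalization shells from %d to %d (few reflections)", n_shells, shells)
    eps = refs.data["epsilon"].to_numpy(float)
    inv_d2 = 1.0 / refs.data["d"].to_numpy(float) ** 2
    order = np.argsort(inv_d2, kind="stable")
    shell_id = np.empty(n, dtype=int)
    shell_id[order] = np.minimum((np.arange(n) * shells) // n, shells - 1)
    f2e = f**2 / eps
    e2 = np.empty(n)
    for s in range(shells):
        m = shell_id == s
        mean = f2e[m].mean()
        if mean <= 0:
            raise ValueError("shell with zero total intensity; cannot normalize")
        e2[m] = f2e[m] / mean
    refs.data["e_value"] = np.sqrt(e2)
    return refs


def r_factor(f_obs: np.ndarray, f_calc: np.ndarray, scale: bool = True) -> float:
    """Crystallographic agreement factor Rf = Σ|F_obs − s·F_calc| / ΣF_obs.

    With ``scale`` the factor s is the least-squares scale between the two
    sets; without it s = 1.
    """
    fo = np.asarray(f_obs, float)
    fc = np.asarray(f_calc, float)
    if fo.shape != fc.shape:
        raise ValueError("amplitude lists must be paired (equal length)")
    denom = fo.sum()
    if denom <= 0:
        raise ValueError("observed amplitudes are all zero")
    if scale:
        s = float(fo @ fc) / float(fc @ fc) if float(fc @ fc) > 0 else 1.0
    else:
        s = 1.0
    return float(np.abs(fo - s * fc).sum() / denom)
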
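"""Synthetic ground-truth structures and simulated diffraction data.

Generates random non-centrosymmetric crystal structures by rejection
sampling (all symmetry- and lattice-expanded atom pairs at least
``min_dist`` apart), computes error-free structure factors from them, and
optionally degrades the amplitudes with multiplicative Gaussian noise or
with a powder-like peak-overlap corruption in which the intensities of
reflections that coincide within a 2θ window are pooled and equipartitioned
— the standard worst case for naive intensity extraction from a powder
pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cell import UnitCell
from .reflections import ReflectionSet, unique_reflections
from .sf import calc_structure_factors, normalize_e_values
from .structure import AtomSite, CrystalStructure
from .symmetry import get_spacegroup

__all__ = [
    "SynthSpec",
    "PRESETS",
    "generate_structure",
    "simulate_observations",
    "corrupt_powder_overlap",
    "make_dataset",
]

_HEXAGONAL = {"P31", "R3"}
_MONOCLINIC = {"P21", "C2"}

# Peak width (°2θ, Cu Kα) at which the overlap-equipartition operator
# degrades small-cell synthetic amplitudes to the ~40% Rf regime typical
# of naive intensity extraction from laboratory powder patterns.
DEFAULT_POWDER_FWHM = 0.6


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic test structure.

    ``target_density`` is non-H atoms per 1000 Å³ of cell volume; ~70 is
    typical of close-packed organic crystals.  ``heavy_atom`` optionally
    replaces the first site with a heavy element (e.g. "Ba" or "Mo"),
    emulating heavy-atom-containing test cases.
    """

    n_asym: int = 20
    composition: tuple[tuple[str, float], ...] = (("C", 0.70), ("N", 0.15), ("O", 0.15))
    spacegroup: str = "P21"
    target_density: float = 70.0
    min_dist: float = 1.2
    d_min: float = 0.85
    b_iso_range: tuple[float, float] = (2.0, 5.0)
    amplitude_noise: float = 0.0
    heavy_atom: str | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_asym < 1:
            raise ValueError("n_asym must be at least 1")
        if self.min_dist <= 0:
            raise ValueError("min_dist must be positive")


# Size-class presets mirroring the small / medium / large test regimes
# and the powder degradation regime.
PRESETS: dict[str, SynthSpec] = {
    "small": SynthSpec(n_asym=20, d_min=0.85),
    "medium": SynthSpec(n_asym=150, d_min=1.0, b_iso_range=(3.0, 8.0)),
    "large": SynthSpec(
        n_asym=350, d_min=1.8, spacegroup="P212121", b_iso_range=(8.0, 20.0)
    ),
    "powder": SynthSpec(n_asym=20, d_min=1.0, heavy_atom="Ba"),
}


def _cell_for(spec: SynthSpec, n_total: int) -> UnitCell:
    """Cell of the right crystal system scaled to the target density."""
    volume = 1000.0 * n_total / spec.target_density
    key = get_spacegroup(spec.spacegroup).symbol
    if key in _HEXAGONAL:
        # a = b, γ = 120°, c/a ≈ 1.1
        a = (volume / (1.1 * np.sin(np.radians(120.0)))) ** (1.0 / 3.0)
        return UnitCell(a, a, 1.1 * a, 90.0, 90.0, 120.0)
    if key in _MONOCLINIC:
        beta = 100.0
        a = (volume / (1.1 * 1.25 * np.sin(np.radians(beta)))) ** (1.0 / 3.0)
        return UnitCell(a, 1.1 * a, 1.25 * a, 90.0, beta, 90.0)
    # orthorhombic-style box with unequal axes (avoids accidental extra symmetry)
    a = (volume / (1.1 * 1.25)) ** (1.0 / 3.0)
    return UnitCell(a, 1.1 * a, 1.25 * a)


def generate_structure(spec: SynthSpec, rng: np.random.Generator | None = None) -> CrystalStructure:
    """Random structure with all expanded pair distances ≥ min_dist."""
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    sg = get_spacegroup(spec.spacegroup)
    cell = _cell_for(spec, spec.n_asym * sg.n_ops)
    elements = [e for e, _ in spec.composition]
    weights = np.array([w for _, w in spec.composition], float)
    weights /= weights.sum()
    G = cell.metric
    offsets = np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)], float
    )
    placed: list[np.ndarray] = []  # all symmetry copies of accepted sites
    sites: list[AtomSite] = []
    min2 = spec.min_dist**2
    for i in range(spec.n_asym):
        elem = spec.heavy_atom if (i == 0 and spec.heavy_atom) else rng.choice(elements, p=weights)
        ok = False
        for _ in range(500):
            x = rng.uniform(0.0, 1.0, size=3)
            images = np.array([op.apply(x) for op in sg.ops])
            pool = np.concatenate([np.array(placed).reshape(-1, 3), images]) if placed else images
            # new images vs everything (incl. each other), over neighbour cells
            d = images[:, None, :] - pool[None, :, :]
            d = (d[None, :, :, :] + offsets[:, None, None, :]).reshape(-1, images.shape[0] * pool.shape[0], 3)
            d2 = np.einsum("abi,ij,abj->ab", d, G, d)
            d2[d2 < 1e-12] = np.inf  # self at zero offset
            if d2.min() >= min2:
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place atom {i + 1}/{spec.n_asym} after 500 tries; "
                "lower target_density or min_dist"
            )
        placed.extend(images)
        b = rng.uniform(*spec.b_iso_range)
        sites.append(AtomSite(element=str(elem), frac_xyz=tuple(x), b_iso=float(b)))
    return CrystalStructure(cell=cell, spacegroup=sg, sites=sites)


def simulate_observations(
    structure: CrystalStructure,
    d_min: float,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    wavelength: float = 1.5406,
) -> ReflectionSet:
    """True structure factors plus multiplicative amplitude noise.

    f_obs = f_true·(1 + ε), ε ~ N(0, σ), clipped at zero; phases are
    noise-free.  E values are computed from f_obs.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    if rng is None:
        rng = np.random.default_rng()
    refs = unique_reflections(structure.cell, structure.spacegroup, d_min, wavelength)
    calc_structure_factors(structure, refs)
    f_true = refs.data["f_true"].to_numpy(float)
    if noise_sigma > 0:
        eps = rng.normal(0.0, noise_sigma, size=f_true.size)
        refs.data["f_obs"] = np.clip(f_true * (1.0 + eps), 0.0, None)
    else:
        refs.data["f_obs"] = f_true
    normalize_e_values(refs, column="f_obs")
    return refs


def corrupt_powder_overlap(
    refs: ReflectionSet,
    fwhm_2theta: float,
    wavelength: float | None = None,
    rng: np.random.Generator | None = None,
) -> ReflectionSet:
    """Powder-style degradation by peak-overlap equipartition.

    Reflections are sorted by diffraction angle 2θ = 2·asin(λ/2d); runs of
    consecutive reflections whose 2θ gaps are below the peak width are
    unresolvable in a powder pattern, so their total multiplicity-weighted
    intensity is redistributed equally among the members.  Total intensity
    is conserved.  Deterministic; ``rng`` is accepted for interface
    symmetry with the noise model.
    """
    out = refs.copy()
    lam = wavelength if wavelength is not None else refs.wavelength
    d = out.data["d"].to_numpy(float)
    ratio = lam / (2.0 * d)
    if np.any(ratio > 1.0):
        raise ValueError("wavelength too long: 2θ undefined for the highest-resolution reflections")
    f = out.data["f_obs"].to_numpy(float)
    if np.all(np.isnan(f)):
        f = out.data["f_true"].to_numpy(float)
    mult = out.data["multiplicity"].to_numpy(float)
    if fwhm_2theta < 0:
        raise ValueError("fwhm_2theta must be non-negative")
    two_theta = 2.0 * np.degrees(np.arcsin(ratio))
    order = np.argsort(two_theta, kind="stable")
    tt = two_theta[order]
    inten = (mult * f**2)[order]
    # cluster where consecutive gaps < fwhm
    new_cluster = np.ones(tt.size, dtype=bool)
    if tt.size > 1:
        new_cluster[1:] = np.diff(tt) >= fwhm_2theta
    cluster_id = np.cumsum(new_cluster) - 1
    sums = np.bincount(cluster_id, weights=inten)
    counts = np.bincount(cluster_id)
    share = sums[cluster_id] / counts[cluster_id]
    f_new = np.empty_like(f)
    f_new[order] = np.sqrt(share / mult[order])
    out.data["f_obs"] = f_new
    normalize_e_values(out, column="f_obs")
    return out


def make_dataset(spec: SynthSpec, rng: np.random.Generator | None = None):
    """Convenience: (structure, reflection set) for one synthetic spec."""
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    structure = generate_structure(spec, rng)
    refs = simulate_observations(structure, spec.d_min, spec.amplitude_noise, rng)
    return structure, refs
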
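"""Crystal structures: asymmetric-unit atom lists with cell and symmetry."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell import UnitCell
from .symmetry import SpaceGroup

__all__ = ["AtomSite", "CrystalStructure", "ATOMIC_NUMBERS"]

# Elements the structure-factor engine supports out of the box (form
# factors come from the International Tables 4-Gaussian fits via gemmi;
# anything gemmi knows is accepted, this map is for Z bookkeeping).
ATOMIC_NUMBERS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "Na": 11, "Mg": 12, "P": 15,
    "S": 16, "Cl": 17, "K": 19, "Ca": 20, "Fe": 26, "Cu": 29, "Zn": 30,
    "Br": 35, "Mo": 42, "I": 53, "Ba": 56,
}


@dataclass(frozen=True)
class AtomSite:
    """One site of the asymmetric unit (fractional coordinates)."""

    element: str
    frac_xyz: tuple[float, float, float]
    occupancy: float = 1.0
    b_iso: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in (0, 1]")
        if self.b_iso < 0:
            raise ValueError("b_iso must be non-negative")
        object.__setattr__(self, "frac_xyz", tuple(float(x) % 1.0 for x in self.frac_xyz))


@dataclass
class CrystalStructure:
    """Ground-truth crystal structure: cell, symmetry and asymmetric unit."""

    cell: UnitCell
    spacegroup: SpaceGroup
    sites: list[AtomSite] = field(default_factory=list)

    @property
    def n_asym(self) -> int:
        """Number of non-hydrogen sites in the asymmetric unit."""
        return sum(1 for s in self.sites if s.element != "H")

    @property
    def z_max(self) -> int:
        """Atomic number of the heaviest element present."""
        from .formfactors import atomic_number

        return max(atomic_number(s.element) for s in self.sites)

    def expand_sites(self) -> tuple[np.ndarray, list[AtomSite]]:
        """All symmetry copies in the full cell: (n_ops·n_sites, 3) + sources."""
        pos = []
        src = []
        for op in self.spacegroup.ops:
            for s in self.sites:
                pos.append(op.apply(np.array(s.frac_xyz)))
                src.append(s)
        return np.array(pos).reshape(-1, 3), src

    def min_pair_distance(self) -> float:
        """Minimum distance over all symmetry- and lattice-expanded pairs (Å)."""
        pos, _ = self.expand_sites()
        G = self.cell.metric
        offsets = np.array(
            [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)], float
        )
        best = np.inf
        for off in offsets:
            d = pos[:, None, :] - pos[None, :, :] + off
            d2 = np.einsum("abi,ij,abj->ab", d, G, d)
            if not off.any():
                np.fill_diagonal(d2, np.inf)
            best = min(best, float(d2.min()))
        return float(np.sqrt(best))
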
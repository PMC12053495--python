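"""File formats: CIF/PDB structures, free-format reflection lists, config.

Reflection files are whitespace-delimited text, one reflection per line,
``h k l F [sigma] [phi]``, with ``#`` comments.  Structure reading goes
through gemmi (small-molecule CIF and PDB); the CIF writer emits the
minimal cell / symmetry-xyz / atom_site dialect this package reads back.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .cell import UnitCell
from .edm import EDMConfig
from .reflections import ReflectionSet, orbit_representatives, unique_reflections
from .seeding import SeedSpec
from .structure import AtomSite, CrystalStructure
from .symmetry import SpaceGroup, SymOp, available_spacegroups, get_spacegroup
from .synthetic import SynthSpec

__all__ = [
    "read_structure",
    "write_cif",
    "read_reflections",
    "write_reflections",
    "RunConfig",
]


def _spacegroup_from(hm: str | None, xyz_ops: list[str] | None) -> SpaceGroup:
    if xyz_ops:
        sg = SpaceGroup.from_triplets(hm or "custom", xyz_ops)
        if sg.is_centrosymmetric:
            raise ValueError("centrosymmetric space groups are outside the scope of phase seeding")
        return sg
    if hm:
        return get_spacegroup(hm)
    raise ValueError(
        "no symmetry information found; supported symbols: "
        + ", ".join(available_spacegroups())
    )


def read_structure(path: str | Path, format: str | None = None, drop_hydrogens: bool = True) -> CrystalStructure:
    """Read a CIF (small-molecule) or PDB file into a CrystalStructure.

    Hydrogens are dropped by default, matching the convention that
    structure sizes count non-H atoms.
    """
    path = Path(path)
    fmt = format or ("pdb" if path.suffix.lower() in (".pdb", ".ent") else "cif")
    if fmt == "pdb":
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        if st.cell.a == 1.0 and st.cell.volume == 1.0 or st.cell.a == 0:
            raise ValueError(f"{path.name}: missing CRYST1 unit cell")
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
        sg = _spacegroup_from(st.spacegroup_hm, None)
        sites = []
        for model in st:
            for chain in model:
                for res in chain:
                    for atom in res:
                        if drop_hydrogens and atom.element.name == "H":
                            continue
                        frac = st.cell.fractionalize(atom.pos)
                        sites.append(
                            AtomSite(
                                element=atom.element.name,
                                frac_xyz=(frac.x, frac.y, frac.z),
                                occupancy=min(1.0, float(atom.occ)) or 1.0,
                                b_iso=float(atom.b_iso),
                            )
                        )
            break  # first model only
        if not sites:
            raise ValueError(f"{path.name}: no atom records")
        return CrystalStructure(cell=cell, spacegroup=sg, sites=sites)

    small = gemmi.read_small_structure(str(path))
    if small.cell.a == 0:
        raise ValueError(f"{path.name}: missing unit cell")
    cell = UnitCell(
        small.cell.a, small.cell.b, small.cell.c,
        small.cell.alpha, small.cell.beta, small.cell.gamma,
    )
    xyz_ops = list(small.symops) if small.symops else None
    sg = _spacegroup_from(small.spacegroup_hm or None, xyz_ops)
    sites = []
    for site in small.sites:
        if drop_hydrogens and site.element.name == "H":
            continue
        sites.append(
            AtomSite(
                element=site.element.name,
                frac_xyz=(site.fract.x, site.fract.y, site.fract.z),
                occupancy=float(site.occ) if site.occ > 0 else 1.0,
                b_iso=float(site.u_iso) * 8.0 * np.pi**2 if site.u_iso > 0 else 3.0,
            )
        )
    if not sites:
        raise ValueError(f"{path.name}: no atom sites")
    return CrystalStructure(cell=cell, spacegroup=sg, sites=sites)


def write_cif(structure: CrystalStructure, path: str | Path, data_name: str = "phaseseed") -> None:
    """Minimal CIF writer (cell, symmetry xyz loop, atom_site fract loop)."""
    c = structure.cell
    lines = [
        f"data_{data_name}",
        f"_cell_length_a {c.a:.6f}",
        f"_cell_length_b {c.b:.6f}",
        f"_cell_length_c {c.c:.6f}",
        f"_cell_angle_alpha {c.alpha:.6f}",
        f"_cell_angle_beta {c.beta:.6f}",
        f"_cell_angle_gamma {c.gamma:.6f}",
        f"_symmetry_space_group_name_H-M '{structure.spacegroup.symbol}'",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
    ]
    lines += [f"  '{op.triplet()}'" for op in structure.spacegroup.ops]
    lines += [
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
        "_atom_site_U_iso_or_equiv",
    ]
    for i, s in enumerate(structure.sites, 1):
        u_iso = s.b_iso / (8.0 * np.pi**2)
        x, y, z = s.frac_xyz
        lines.append(
            f"  {s.element}{i} {s.element} {x:.6f} {y:.6f} {z:.6f} {s.occupancy:.4f} {u_iso:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_reflections(refs: ReflectionSet, path: str | Path, include_phase: bool = True) -> None:
    """Free-format text: ``h k l F [phi]`` with a commented header."""
    lines = [
        f"# phaseseed reflection list: {refs.spacegroup.symbol}, d_min {refs.d_min:.4f} A",
        f"# cell {refs.cell.a:.6f} {refs.cell.b:.6f} {refs.cell.c:.6f} "
        f"{refs.cell.alpha:.4f} {refs.cell.beta:.4f} {refs.cell.gamma:.4f}",
        "# h k l F sigma" + (" phi" if include_phase else ""),
    ]
    f = refs.data["f_obs"].to_numpy(float)
    if np.all(np.isnan(f)):
        f = refs.data["f_true"].to_numpy(float)
    phi = refs.data["phi_true"].to_numpy(float)
    for (h, k, l), fv, pv in zip(refs.hkl, f, phi):
        line = f"{h:4d} {k:4d} {l:4d} {fv:12.6g} {0.0:8.4f}"
        if include_phase and not np.isnan(pv):
            line += f" {pv:10.4f}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + "\n")


def read_reflections(
    path: str | Path,
    cell: UnitCell,
    spacegroup: SpaceGroup,
    wavelength: float = 1.5406,
) -> ReflectionSet:
    """Read ``h k l F [sigma] [phi]`` text into a ReflectionSet.

    Reflections are classified (centric flag, allowed phases, ε) from the
    given symmetry; d-spacings come from the cell.
    """
    path = Path(path)
    rows = []
    seen: dict[tuple, int] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path.name}:{lineno}: expected 'h k l F [sigma] [phi]'")
        try:
            h, k, l = (int(p) for p in parts[:3])
            nums = [float(p) for p in parts[3:]]
        except ValueError as exc:
            raise ValueError(f"{path.name}:{lineno}: non-numeric field ({exc})") from None
        if (h, k, l) in seen:
            raise ValueError(
                f"{path.name}:{lineno}: duplicate reflection ({h},{k},{l}), "
                f"first seen on line {seen[(h, k, l)]}"
            )
        seen[(h, k, l)] = lineno
        f_obs = nums[0]
        phi = nums[2] if len(nums) >= 3 else (np.nan)
        if len(nums) == 2:
            # ambiguous second column: treat as sigma (ignored) per SHELX habit
            phi = np.nan
        rows.append((h, k, l, f_obs, phi))
    if not rows:
        raise ValueError(f"{path.name}: no reflections found")
    arr = np.array(rows, dtype=float)
    hkl = arr[:, :3].astype(int)
    from .symmetry import classify_reflection

    d = cell.d_spacings(hkl)
    cen, phi0, eps, mult = [], [], [], []
    rots = spacegroup.rotations
    for hrow in hkl:
        c, allowed, e = classify_reflection(spacegroup, hrow)
        cen.append(c)
        phi0.append(allowed[0] if allowed else np.nan)
        eps.append(e)
        orbit = np.concatenate([hrow @ rots, -(hrow @ rots)], axis=0)
        mult.append(len({tuple(r) for r in orbit}))
    df = pd.DataFrame(
        {
            "h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2], "d": d,
            "centric": cen, "phi_restricted": phi0, "epsilon": eps,
            "multiplicity": mult,
            "f_true": np.nan, "phi_true": arr[:, 4],
            "f_obs": arr[:, 3], "e_value": np.nan, "measured": True,
        }
    )
    df = df.sort_values("d", ascending=False, kind="stable").reset_index(drop=True)
    return ReflectionSet(cell, spacegroup, float(d.min()), df, wavelength)


@dataclass
class RunConfig:
    """Structured run configuration (YAML round-trippable)."""

    synth: SynthSpec = field(default_factory=SynthSpec)
    seed: SeedSpec = field(default_factory=SeedSpec)
    edm: EDMConfig = field(default_factory=EDMConfig)
    grid_k: int = 4
    perc_grid: tuple[int, ...] = tuple(range(10, 101, 10))
    n_repeats: int = 5
    rng_seed: int = 0
    out_dir: str = "phaseseed_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, sub in (("synth", SynthSpec), ("seed", SeedSpec), ("edm", EDMConfig)):
            if key in raw:
                d = raw.pop(key)
                if "composition" in d:
                    d["composition"] = tuple(tuple(x) for x in d["composition"])
                if "b_iso_range" in d:
                    d["b_iso_range"] = tuple(d["b_iso_range"])
                kwargs[key] = sub(**d)
        if "perc_grid" in raw:
            raw["perc_grid"] = tuple(raw["perc_grid"])
        return cls(**kwargs, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(json.loads(json.dumps(d)), sort_keys=False))

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:12]
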
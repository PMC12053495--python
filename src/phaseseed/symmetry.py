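"""Space-group symmetry: operator algebra and reflection classification.

Operators act on fractional coordinates as ``x' = R·x + t``.  A Miller
index transforms contravariantly, ``h' = h·R`` (row vector times matrix),
and the structure-factor phase follows ``φ(h·R) = φ(h) − 360°·(h·t)``.

A reflection is *centric* (symmetry-restricted) when some rotation maps h
onto −h; combining the symmetry phase relation with Friedel's law then
pins its phase to one of two values 180° apart.  The statistical weight
ε(h) counts the rotations that fix h, and a reflection is systematically
*absent* when a rotation fixes h but the accompanying translation gives a
non-integral h·t.
"""

from __future__ import annotations

import fractions
import importlib.resources
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SymOp",
    "SpaceGroup",
    "parse_triplet",
    "get_spacegroup",
    "available_spacegroups",
    "classify_reflection",
]

_AXES = {"x": 0, "y": 1, "z": 2}


def parse_triplet(triplet: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse an xyz-style symmetry triplet like ``-x,y+1/2,-z``.

    Returns integer 3×3 rotation and a translation vector with components
    reduced into [0, 1).
    """
    rot = np.zeros((3, 3), dtype=int)
    tran = np.zeros(3)
    parts = triplet.replace(" ", "").lower().split(",")
    if len(parts) != 3:
        raise ValueError(f"malformed symmetry triplet: {triplet!r}")
    for i, part in enumerate(parts):
        # tokenize into signed terms
        terms: list[str] = []
        cur = ""
        for ch in part:
            if ch in "+-" and cur:
                terms.append(cur)
                cur = ch
            else:
                cur += ch
        if cur:
            terms.append(cur)
        for term in terms:
            sign = -1 if term.startswith("-") else 1
            body = term.lstrip("+-")
            if not body:
                raise ValueError(f"malformed term in triplet: {triplet!r}")
            if body in _AXES:
                rot[i, _AXES[body]] += sign
            else:
                tran[i] += sign * float(fractions.Fraction(body))
    tran %= 1.0
    return rot, tran


@dataclass(frozen=True)
class SymOp:
    """A single symmetry operation x' = R·x + t."""

    rot: np.ndarray
    tran: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rot", np.asarray(self.rot, dtype=int))
        object.__setattr__(self, "tran", np.asarray(self.tran, dtype=float) % 1.0)
        if abs(round(float(np.linalg.det(self.rot)))) != 1:
            raise ValueError("symmetry rotation must have determinant ±1")

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymOp":
        rot, tran = parse_triplet(triplet)
        return cls(rot, tran)

    def triplet(self) -> str:
        out = []
        for i in range(3):
            s = ""
            for j, ax in enumerate("xyz"):
                r = self.rot[i, j]
                if r:
                    s += ("+" if r > 0 and s else "-" if r < 0 else "") + ax
            t = fractions.Fraction(self.tran[i]).limit_denominator(12)
            if t:
                s += f"+{t}"
            out.append(s)
        return ",".join(out)

    def apply(self, frac_xyz: np.ndarray) -> np.ndarray:
        return (self.rot @ np.asarray(frac_xyz, float) + self.tran) % 1.0

    def __eq__(self, other) -> bool:  # modulo lattice translations
        return (
            np.array_equal(self.rot, other.rot)
            and np.allclose(self.tran % 1.0, other.tran % 1.0, atol=1e-9)
        )

    def __hash__(self) -> int:
        return hash((self.rot.tobytes(), tuple(np.round(self.tran % 1.0, 9))))


@dataclass(frozen=True)
class SpaceGroup:
    """A (non-centrosymmetric) space group as an explicit operator list."""

    symbol: str
    ops: tuple[SymOp, ...]
    is_centrosymmetric: bool = field(init=False)

    def __post_init__(self) -> None:
        ops = tuple(self.ops)
        if not any(np.array_equal(op.rot, np.eye(3, dtype=int)) and not op.tran.any() for op in ops):
            raise ValueError("operator list lacks the identity")
        inv = -np.eye(3, dtype=int)
        object.__setattr__(
            self, "is_centrosymmetric", any(np.array_equal(op.rot, inv) for op in ops)
        )
        object.__setattr__(self, "ops", ops)

    @classmethod
    def from_triplets(cls, symbol: str, triplets: list[str]) -> "SpaceGroup":
        return cls(symbol, tuple(SymOp.from_triplet(t) for t in triplets))

    @property
    def n_ops(self) -> int:
        return len(self.ops)

    @property
    def rotations(self) -> np.ndarray:
        """(m, 3, 3) stack of rotation matrices."""
        return np.stack([op.rot for op in self.ops])

    @property
    def translations(self) -> np.ndarray:
        return np.stack([op.tran for op in self.ops])

    def check_closure(self) -> bool:
        """True if the operator set is closed under composition mod lattice."""
        opset = set(self.ops)
        for p in self.ops:
            for q in self.ops:
                comp = SymOp(p.rot @ q.rot, p.rot @ q.tran + p.tran)
                if comp not in opset:
                    return False
        return True


def _load_table() -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    alias: dict[str, str] = {}
    src = importlib.resources.files("phaseseed.data").joinpath("spacegroups.txt")
    current: str | None = None
    for raw in src.read_text().splitlines():
        line = raw.rstrip()
        if not line or line.lstrip().startswith("#"):
            continue
        if not line.startswith(" "):
            names = [n.strip() for n in line.split("|")]
            current = names[0]
            table[current] = []
            for n in names:
                alias[n.upper()] = current
        else:
            if current is None:
                raise ValueError("operator line before any group header")
            table[current].append(line.strip())
    _load_table.alias = alias  # type: ignore[attr-defined]
    return table


_TABLE = _load_table()
_ALIAS = _load_table.alias  # type: ignore[attr-defined]
_CACHE: dict[str, SpaceGroup] = {}


def available_spacegroups() -> list[str]:
    return sorted(_TABLE)


def get_spacegroup(symbol: str) -> SpaceGroup:
    """Look up a supported space group by symbol (short or full H–M)."""
    key = _ALIAS.get(symbol.strip().upper())
    if key is None:
        raise ValueError(
            f"unsupported space group {symbol!r}; supported: {', '.join(available_spacegroups())}"
        )
    if key not in _CACHE:
        _CACHE[key] = SpaceGroup.from_triplets(key, _TABLE[key])
    return _CACHE[key]


def classify_reflection(sg: SpaceGroup, hkl) -> tuple[bool, tuple[float, float] | None, int]:
    """Classify one reflection: (centric, allowed phases in degrees, ε).

    ``allowed`` is ``None`` for general (acentric) reflections, else the
    two symmetry-permitted phases {φ₀, φ₀+180°}.
    """
    h = np.asarray(hkl, dtype=int)
    if not h.any():
        raise ValueError("reflection (0,0,0) cannot be classified")
    centric = False
    phi0 = None
    epsilon = 0
    for op in sg.ops:
        hR = h @ op.rot
        if np.array_equal(hR, h):
            epsilon += 1
        if np.array_equal(hR, -h):
            centric = True
            if phi0 is None:
                phi0 = (180.0 * float(h @ op.tran)) % 180.0
    allowed = (phi0, (phi0 + 180.0) % 360.0) if centric else None
    return centric, allowed, epsilon


def is_absent(sg: SpaceGroup, hkl) -> bool:
    """Systematic absence: some op fixes h with non-integral h·t."""
    h = np.asarray(hkl, dtype=int)
    for op in sg.ops:
        if np.array_equal(h @ op.rot, h):
            ht = float(h @ op.tran)
            if abs(ht - round(ht)) > 1e-9:
                return True
    return False
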
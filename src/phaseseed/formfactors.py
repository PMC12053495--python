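"""X-ray atomic scattering factors.

Backed by the International Tables 4-Gaussian parameterizations that ship
with gemmi; falls back to a point scatterer f = Z when no fit exists for
an element.
"""

from __future__ import annotations

import numpy as np

try:
    import gemmi
except ImportError:  # pragma: no cover
    gemmi = None

__all__ = ["scattering_factor", "atomic_number"]

_COEF_CACHE: dict[str, tuple[np.ndarray, np.ndarray, float] | int] = {}


def atomic_number(element: str) -> int:
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element symbol {element!r}")
    return el.atomic_number


def _coefs(element: str):
    if element not in _COEF_CACHE:
        el = gemmi.Element(element)
        if el.atomic_number == 0:
            raise ValueError(f"unknown element symbol {element!r}")
        it92 = el.it92
        if it92 is not None and len(it92.a) == 4:
            _COEF_CACHE[element] = (np.array(it92.a), np.array(it92.b), float(it92.c))
        else:  # point-scatterer fallback
            _COEF_CACHE[element] = el.atomic_number
    return _COEF_CACHE[element]


def scattering_factor(element: str, s2: np.ndarray) -> np.ndarray:
    """f(s²) for s = sinθ/λ = 1/(2d), vectorized over s².

    Returns the elastic X-ray form factor in electrons.
    """
    s2 = np.asarray(s2, dtype=float)
    co = _coefs(element)
    if isinstance(co, int):
        return np.full_like(s2, float(co))
    a, b, c = co
    return np.einsum("i,ni->n", a, np.exp(-np.outer(s2, b))) + c
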
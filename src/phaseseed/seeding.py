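"""Phase discretization, seed selection and initial phase assignment.

The pre-processing step of phase seeding: continuous phases of general
reflections are collapsed onto a coarse angular grid of k ∈ {2, 3, 4, 6}
equispaced values, and a *seed* subset of reflections receives the true
(discretized) phase while all others start from random values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reflections import ReflectionSet

__all__ = [
    "SamplingGrid",
    "SeedSpec",
    "PhaseAssignment",
    "discretize",
    "select_seed",
    "assign_initial_phases",
    "mean_phase_error",
    "SEED_MODES",
]

SEED_MODES = ("random", "hkl_sorted", "d_sorted", "e_sorted", "e_random")


@dataclass(frozen=True)
class SamplingGrid:
    """k equispaced phase sampling points {360°·j/k}."""

    k: int

    def __post_init__(self) -> None:
        if self.k not in (2, 3, 4, 6):
            raise ValueError("sampling density k must be one of 2, 3, 4, 6")

    @property
    def values(self) -> np.ndarray:
        return np.arange(self.k) * (360.0 / self.k)


@dataclass(frozen=True)
class SeedSpec:
    """How the seed of true-phased reflections is chosen.

    ``perc_seed`` is the seed size as a percentage of N_refl (all modes
    except ``hkl_sorted``, where the cubic reciprocal-space box ``h_max``
    fixes the size instead).  ``e_threshold`` applies to ``e_random``.
    """

    mode: str = "random"
    perc_seed: float = 10.0
    h_max: int | None = None
    e_threshold: float = 1.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in SEED_MODES:
            raise ValueError(f"unknown seed mode {self.mode!r}; choose from {SEED_MODES}")
        if not 0.0 <= self.perc_seed <= 100.0:
            raise ValueError("perc_seed must lie in [0, 100]")
        if self.mode == "hkl_sorted" and self.h_max is None:
            raise ValueError("hkl_sorted mode requires h_max")


@dataclass
class PhaseAssignment:
    """Per-reflection working phases: continuous φ_a and discretized φ_d."""

    phi_a: np.ndarray
    phi_d: np.ndarray
    seed_mask: np.ndarray
    grid: SamplingGrid

    @property
    def perc_seed(self) -> float:
        return 100.0 * self.seed_mask.mean() if self.seed_mask.size else 0.0


def discretize(phi_a, grid: SamplingGrid):
    """Nearest sampling point on the phase circle; ties break toward the
    smaller grid angle."""
    phi = np.atleast_1d(np.asarray(phi_a, float)) % 360.0
    diffs = np.abs((phi[:, None] - grid.values[None, :] + 180.0) % 360.0 - 180.0)
    out = grid.values[np.argmin(diffs, axis=1)]
    return out if np.ndim(phi_a) else float(out[0])


def _seed_count(perc_seed: float, n_refl: int) -> int:
    return int(np.floor(perc_seed * n_refl / 100.0 + 0.5))


def select_seed(refs: ReflectionSet, spec: SeedSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Boolean seed mask over the reflection set, one of five strategies."""
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    n = refs.n_refl
    mask = np.zeros(n, dtype=bool)
    if spec.mode == "hkl_sorted":
        mask[:] = np.abs(refs.hkl).max(axis=1) <= spec.h_max
        return mask
    n_seed = _seed_count(spec.perc_seed, n)
    if n_seed == 0:
        return mask
    if spec.mode == "random":
        idx = rng.choice(n, size=n_seed, replace=False)
    elif spec.mode == "d_sorted":
        # lowest resolution (largest d) first
        idx = np.argsort(-refs.data["d"].to_numpy(), kind="stable")[:n_seed]
    elif spec.mode == "e_sorted":
        idx = np.argsort(-refs.data["e_value"].to_numpy(), kind="stable")[:n_seed]
    else:  # e_random
        e = refs.data["e_value"].to_numpy(float)
        if np.isnan(e).all():
            raise ValueError("e_random seeding requires E values (run normalize_e_values)")
        pool = np.flatnonzero(e > spec.e_threshold)
        if pool.size < n_seed:
            raise ValueError(
                f"e_random: only {pool.size} reflections have E > {spec.e_threshold}, "
                f"cannot seed {n_seed} (max Perc_seed ≈ {100.0 * pool.size / n:.1f}%)"
            )
        idx = rng.choice(pool, size=n_seed, replace=False)
    mask[idx] = True
    return mask


def assign_initial_phases(
    refs: ReflectionSet,
    seed_mask: np.ndarray,
    grid: SamplingGrid,
    rng: np.random.Generator | None = None,
) -> PhaseAssignment:
    """Starting phases for the phasing run.

    Non-seed general reflections get uniform-random φ_a discretized to the
    grid; non-seed centric ones a random choice of their two allowed
    values.  Seed reflections carry the true phase: discretized for
    general reflections, exact for centric ones (the allowed values are a
    2-point grid already).
    """
    if rng is None:
        rng = np.random.default_rng()
    n = refs.n_refl
    seed_mask = np.asarray(seed_mask, bool)
    centric = refs.data["centric"].to_numpy(bool)
    phi_true = refs.data["phi_true"].to_numpy(float)
    allowed = refs.allowed_phases

    phi_a = rng.uniform(0.0, 360.0, size=n)
    phi_d = discretize(phi_a, grid)

    m = ~seed_mask & centric
    if m.any():
        pick = rng.integers(0, 2, size=int(m.sum()))
        phi_d[m] = allowed[m, pick]
        phi_a[m] = phi_d[m]

    m = seed_mask & ~centric
    phi_a[m] = phi_true[m]
    phi_d[m] = discretize(phi_true[m], grid)

    m = seed_mask & centric
    phi_a[m] = phi_true[m]
    phi_d[m] = phi_true[m]

    return PhaseAssignment(phi_a=phi_a, phi_d=phi_d, seed_mask=seed_mask, grid=grid)


def mean_phase_error(phi, phi_true) -> float:
    """Unweighted mean circular phase difference in degrees, in [0, 180]."""
    phi = np.asarray(getattr(phi, "phi_d", phi), float)
    phi_true = np.asarray(phi_true, float)
    if phi.shape != phi_true.shape:
        raise ValueError("phase lists must have equal length")
    if phi.size == 0:
        raise ValueError("cannot average an empty phase set")
    d = np.abs(phi - phi_true) % 360.0
    return float(np.minimum(d, 360.0 - d).mean())
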
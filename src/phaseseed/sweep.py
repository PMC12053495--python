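"""Sweep protocol: Perc_seed × sampling density × seed mode grids.

Determines, per structure, the minimum seed size that leads to structure
solution (Perc_lim) and the corresponding pre-EDM mean phase error
(MPE_lim), and aggregates those limits over cohorts of structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .edm import EDMConfig, run_edm
from .reflections import ReflectionSet
from .seeding import SamplingGrid, SeedSpec, assign_initial_phases, mean_phase_error, select_seed

__all__ = [
    "SweepResult",
    "mpe_vs_seed_curve",
    "find_perc_lim",
    "aggregate",
    "DEFAULT_PERC_GRID",
]

DEFAULT_PERC_GRID = tuple(range(10, 101, 10))


@dataclass
class SweepResult:
    """Per-(structure, sampling density, seed mode) sweep record."""

    structure_id: str
    grid_k: int
    mode: str
    records: pd.DataFrame  # per Perc_seed: n_runs, n_solved, mpe_pre, mpe_final
    perc_lim: float | None
    mpe_lim: float | None
    size_class: str = "small"


def _seed_and_assign(refs, k, mode, perc, rng, e_threshold=1.0, h_max=None):
    spec = SeedSpec(mode=mode, perc_seed=perc, h_max=h_max, e_threshold=e_threshold)
    mask = select_seed(refs, spec, rng)
    grid = SamplingGrid(k)
    return assign_initial_phases(refs, mask, grid, rng)


def mpe_vs_seed_curve(
    refs: ReflectionSet,
    k: int,
    mode: str = "random",
    perc_grid=DEFAULT_PERC_GRID,
    n_repeats: int = 5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pre-EDM MPE of the discretized phases as a function of seed size.

    Each point averages ``n_repeats`` independent seedings; no EDM is run.
    """
    if rng is None:
        rng = np.random.default_rng()
    if list(perc_grid) != sorted(perc_grid):
        raise ValueError("perc_grid must be ascending")
    phi_true = refs.data["phi_true"].to_numpy(float)
    rows = []
    for p in perc_grid:
        vals = [
            mean_phase_error(_seed_and_assign(refs, k, mode, p, rng).phi_d, phi_true)
            for _ in range(n_repeats)
        ]
        rows.append((p, float(np.mean(vals)), float(np.std(vals))))
    return pd.DataFrame(rows, columns=["perc_seed", "mpe", "mpe_std"])


def find_perc_lim(
    refs: ReflectionSet,
    k: int,
    mode: str = "random",
    perc_grid=DEFAULT_PERC_GRID,
    n_repeats: int = 5,
    edm_config: EDMConfig = EDMConfig(),
    rng: np.random.Generator | None = None,
    structure_id: str = "synthetic",
    stop_at_first: bool = True,
) -> SweepResult:
    """Smallest Perc_seed on the grid at which the majority of repeated
    seeded EDM runs solve the structure.

    MPE_lim is the mean pre-EDM MPE at that seed size.  Both are None if
    no grid point succeeds.
    """
    if rng is None:
        rng = np.random.default_rng()
    phi_true = refs.data["phi_true"].to_numpy(float)
    rows = []
    perc_lim = None
    mpe_lim = None
    for p in perc_grid:
        pre, post, solved = [], [], 0
        for _ in range(n_repeats):
            assignment = _seed_and_assign(refs, k, mode, p, rng)
            pre.append(mean_phase_error(assignment.phi_d, phi_true))
            run = run_edm(refs, assignment, edm_config)
            post.append(mean_phase_error(run.phi_final, phi_true))
            solved += int(run.solved)
        rows.append((p, n_repeats, solved, float(np.mean(pre)), float(np.mean(post))))
        if perc_lim is None and 2 * solved >= n_repeats:
            perc_lim = float(p)
            mpe_lim = float(np.mean(pre))
            if stop_at_first:
                break
    records = pd.DataFrame(
        rows, columns=["perc_seed", "n_runs", "n_solved", "mpe_pre", "mpe_final"]
    )
    return SweepResult(
        structure_id=structure_id,
        grid_k=k,
        mode=mode,
        records=records,
        perc_lim=perc_lim,
        mpe_lim=mpe_lim,
    )


def aggregate(results: list[SweepResult]) -> pd.DataFrame:
    """Summary statistics of Perc_lim / MPE_lim per (size class, k, mode).

    Unsolved structures are excluded from the distributions but counted in
    ``n_unsolved`` so they are never silently dropped.
    """
    if not results:
        raise ValueError("nothing to aggregate")
    rows = []
    key = lambda r: (r.size_class, r.grid_k, r.mode)
    groups: dict[tuple, list[SweepResult]] = {}
    for r in results:
        groups.setdefault(key(r), []).append(r)
    for (size_class, k, mode), grp in sorted(groups.items(), key=lambda kv: str(kv[0])):
        solved = [r for r in grp if r.perc_lim is not None]
        pl = np.array([r.perc_lim for r in solved], float)
        ml = np.array([r.mpe_lim for r in solved], float)
        rows.append(
            {
                "size_class": size_class,
                "grid_k": k,
                "mode": mode,
                "n_structures": len(grp),
                "n_solved": len(solved),
                "n_unsolved": len(grp) - len(solved),
                "perc_lim_mean": pl.mean() if pl.size else np.nan,
                "perc_lim_median": np.median(pl) if pl.size else np.nan,
                "perc_lim_q1": np.percentile(pl, 25) if pl.size else np.nan,
                "perc_lim_q3": np.percentile(pl, 75) if pl.size else np.nan,
                "mpe_lim_mean": ml.mean() if ml.size else np.nan,
                "mpe_lim_median": np.median(ml) if ml.size else np.nan,
            }
        )
    return pd.DataFrame(rows)
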
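"""Model/Results interface for a single phase-seeding run.

:class:`PhaseSeedingModel` binds a reflection set to a sampling density,
a seed-selection strategy and an EDM configuration; :meth:`fit` performs
the pre-processing (seed selection, discretized phase assignment) and the
dual-space phase extension/refinement, returning a
:class:`PhaseSeedingResults` with the figures of merit, the per-cycle
trace and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edm import EDMConfig, EDMRun, run_edm
from .reflections import ReflectionSet
from .seeding import (
    PhaseAssignment,
    SamplingGrid,
    SeedSpec,
    assign_initial_phases,
    mean_phase_error,
    select_seed,
)
from .structure import CrystalStructure
from .synthetic import simulate_observations

__all__ = ["PhaseSeedingModel", "PhaseSeedingResults"]


class PhaseSeedingModel:
    """Phase seeding applied to one reflection set.

    Parameters
    ----------
    reflections
        Symmetry-independent reflections with f_obs and (for scoring)
        phi_true populated.
    grid_k
        Sampling density: number of equispaced phase values in [0°, 360°).
    seed
        Seed-selection strategy and size.
    edm
        EDM engine configuration.
    """

    def __init__(
        self,
        reflections: ReflectionSet,
        grid_k: int = 4,
        seed: SeedSpec | None = None,
        edm: EDMConfig | None = None,
    ):
        self.reflections = reflections
        self.grid = SamplingGrid(grid_k)
        self.seed_spec = seed if seed is not None else SeedSpec()
        self.edm_config = edm if edm is not None else EDMConfig()

    @classmethod
    def from_structure(
        cls,
        structure: CrystalStructure,
        d_min: float,
        grid_k: int = 4,
        seed: SeedSpec | None = None,
        edm: EDMConfig | None = None,
        noise_sigma: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> "PhaseSeedingModel":
        """Build the model directly from a ground-truth atomic model."""
        refs = simulate_observations(structure, d_min, noise_sigma, rng)
        return cls(refs, grid_k=grid_k, seed=seed, edm=edm)

    def fit(self, rng_seed: int | np.random.Generator | None = None) -> "PhaseSeedingResults":
        """Run seeding + EDM once and return the results object."""
        rng = (
            rng_seed
            if isinstance(rng_seed, np.random.Generator)
            else np.random.default_rng(rng_seed)
        )
        refs = self.reflections
        mask = select_seed(refs, self.seed_spec, rng)
        assignment = assign_initial_phases(refs, mask, self.grid, rng)
        phi_true = refs.data["phi_true"].to_numpy(float)
        have_truth = not np.all(np.isnan(phi_true))
        mpe_initial = mean_phase_error(assignment.phi_d, phi_true) if have_truth else np.nan
        run = run_edm(refs, assignment, self.edm_config)
        mpe_final = mean_phase_error(run.phi_final, phi_true) if have_truth else np.nan
        return PhaseSeedingResults(
            model=self,
            assignment=assignment,
            phases=run.phi_final,
            mpe_initial=mpe_initial,
            mpe_final=mpe_final,
            rf_final=float(run.trace["rf"].iloc[-1]) if len(run.trace) else np.nan,
            solved=run.solved,
            trace=run.trace,
            stop_reason=run.stop_reason,
        )


@dataclass
class PhaseSeedingResults:
    """Outcome of one seeded phasing run."""

    model: PhaseSeedingModel
    assignment: PhaseAssignment
    phases: np.ndarray
    mpe_initial: float
    mpe_final: float
    rf_final: float
    solved: bool
    trace: pd.DataFrame
    stop_reason: str

    @property
    def n_seed(self) -> int:
        return int(self.assignment.seed_mask.sum())

    @property
    def n_cycles(self) -> int:
        return len(self.trace)

    def summary(self) -> str:
        refs = self.model.reflections
        rows = [
            ("space group", refs.spacegroup.symbol),
            ("N_refl", refs.n_refl),
            ("d_min (Å)", f"{refs.d_min:.2f}"),
            ("sampling density k", self.model.grid.k),
            ("seed mode", self.model.seed_spec.mode),
            ("Perc_seed (%)", f"{self.assignment.perc_seed:.1f}"),
            ("seed reflections", self.n_seed),
            ("pre-EDM MPE (°)", f"{self.mpe_initial:.1f}"),
            ("EDM cycles", self.n_cycles),
            ("final MPE (°)", f"{self.mpe_final:.1f}"),
            ("final Rf", f"{self.rf_final:.3f}"),
            ("stop reason", self.stop_reason),
            ("solved", self.solved),
        ]
        width = max(len(str(k)) for k, _ in rows)
        lines = ["Phase seeding results", "=" * (width + 24)]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Per-cycle MPE and Rf on twin axes; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.trace["cycle"], self.trace["mpe"], color="tab:blue", label="MPE")
        ax.set_xlabel("EDM cycle")
        ax.set_ylabel("MPE (°)", color="tab:blue")
        ax2 = ax.twinx()
        ax2.plot(self.trace["cycle"], self.trace["rf"], color="tab:red", label="Rf")
        ax2.set_ylabel("Rf", color="tab:red")
        return ax
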
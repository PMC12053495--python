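"""Map synthesis, density modification and the EDM recycling engine."""

import numpy as np
import pandas as pd
import pytest

import phaseseed as ps
from phaseseed.edm import ReciprocalMapping, fft_grid_shape


def _truncated(refs, n):
    """Copy of a reflection set keeping only the n lowest-resolution rows."""
    out = refs.copy()
    out.data = out.data.iloc[:n].reset_index(drop=True)
    out.d_min = float(out.data["d"].min())
    return out


def _full_sphere(refs, f, phi_deg):
    """Oracle expansion: every (h', F') over ops and Friedel, deduplicated."""
    sg = refs.spacegroup
    out = {}
    F = f * np.exp(1j * np.radians(phi_deg))
    for hkl, Fh in zip(refs.hkl, F):
        for op in sg.ops:
            hR = tuple(hkl @ op.rot)
            val = Fh * np.exp(-2j * np.pi * float(hkl @ op.tran))
            out.setdefault(hR, val)
            out.setdefault(tuple(-np.array(hR)), np.conj(val))
    return out


class TestSynthesis:
    def test_zero_amplitudes_zero_map(self, p21_refs):
        dmap = ps.synthesize_map(p21_refs, np.zeros(p21_refs.n_refl), np.zeros(p21_refs.n_refl))
        assert np.all(dmap.values == 0.0)

    def test_matches_direct_summation_oracle(self, p21_refs):
        refs = _truncated(p21_refs, 30)
        f = refs.data["f_true"].to_numpy()
        phi = refs.data["phi_true"].to_numpy()
        shape = (12, 12, 12)
        dmap = ps.synthesize_map(refs, f, phi, grid_shape=shape)
        sphere = _full_sphere(refs, f, phi)
        x = np.stack(
            np.meshgrid(*[np.arange(n) / n for n in shape], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        rho = np.zeros(x.shape[0], dtype=complex)
        for h, F in sphere.items():
            rho += F * np.exp(-2j * np.pi * (x @ np.array(h)))
        rho = np.real(rho) / refs.cell.volume
        assert np.allclose(dmap.values.ravel(), rho, atol=1e-8 * np.abs(rho).max())

    def test_parseval_full_sphere(self, p21_refs):
        refs = _truncated(p21_refs, 50)
        f = refs.data["f_true"].to_numpy()
        phi = refs.data["phi_true"].to_numpy()
        dmap = ps.synthesize_map(refs, f, phi)
        sphere = _full_sphere(refs, f, phi)
        lhs = sum(abs(F) ** 2 for F in sphere.values())
        rhs = refs.cell.volume**2 * (dmap.values**2).mean()
        assert lhs == pytest.approx(rhs, rel=1e-8)

    def test_grid_too_coarse_rejected(self, p21_refs):
        with pytest.raises(ValueError, match="too coarse"):
            ps.synthesize_map(p21_refs, np.ones(p21_refs.n_refl), np.zeros(p21_refs.n_refl), (6, 6, 6))


class TestModifyDensity:
    def test_keep_all_positive_identity(self, rng):
        dmap = ps.DensityMap(rng.uniform(0.1, 1.0, size=(8, 8, 8)), ps.UnitCell(5, 5, 5))
        out = ps.modify_density(dmap, 1.0)
        assert np.array_equal(out.values, dmap.values)

    def test_all_negative_zeroed(self, rng):
        dmap = ps.DensityMap(-rng.uniform(0.1, 1.0, size=(8, 8, 8)), ps.UnitCell(5, 5, 5))
        assert np.all(ps.modify_density(dmap, 0.3).values == 0.0)

    def test_keep_count_exact_on_distinct_values(self, rng):
        vals = rng.permutation(np.linspace(1.0, 2.0, 512)).reshape(8, 8, 8)
        out = ps.modify_density(ps.DensityMap(vals, ps.UnitCell(5, 5, 5)), 0.25)
        assert (out.values != 0).sum() == int(np.ceil(0.25 * 512))


class TestRoundTrip:
    def test_synthesize_recompute_identity(self, p21_refs):
        f = p21_refs.data["f_true"].to_numpy()
        phi = p21_refs.data["phi_true"].to_numpy()
        shape = fft_grid_shape(p21_refs.cell, p21_refs.d_min)
        dmap = ps.synthesize_map(p21_refs, f, phi, shape)
        phi_new, f_new = ps.recompute_phases(dmap, p21_refs)
        d = np.abs(phi_new - phi) % 360.0
        assert np.max(np.minimum(d, 360.0 - d)) < 1e-6
        assert np.allclose(f_new, f, rtol=1e-9)

    def test_recompute_snaps_centric(self, p21_refs, rng):
        # random map: recomputed centric phases still land on allowed values
        shape = fft_grid_shape(p21_refs.cell, p21_refs.d_min)
        dmap = ps.DensityMap(rng.normal(size=shape), p21_refs.cell)
        phi, _ = ps.recompute_phases(dmap, p21_refs)
        cen = p21_refs.data["centric"].to_numpy(bool)
        allowed = p21_refs.allowed_phases
        ok = np.isclose(phi[cen], allowed[cen, 0]) | np.isclose(phi[cen], allowed[cen, 1])
        assert ok.all()


class TestFreeLunch:
    def test_factor_one_adds_nothing(self, p21_refs):
        assert len(ps.free_lunch_extend(p21_refs, 1.0)) == 0

    def test_extension_set_identity(self, p21_refs):
        ext = ps.free_lunch_extend(p21_refs, 0.8)
        full = ps.unique_reflections(p21_refs.cell, p21_refs.spacegroup, p21_refs.d_min * 0.8)
        expected = set(map(tuple, full.hkl)) - set(map(tuple, p21_refs.hkl))
        assert set(map(tuple, ext[["h", "k", "l"]].to_numpy(int))) == expected
        assert not ext["measured"].any()

    def test_extrapolated_amplitudes_track_truth(self, p21_dataset):
        structure, refs = p21_dataset
        ext = ps.free_lunch_extend(refs, 0.8)
        shape = fft_grid_shape(refs.cell, refs.d_min * 0.8)
        m_meas = ReciprocalMapping(refs.hkl, refs.spacegroup, shape)
        dmap = m_meas.to_map(
            refs.data["f_true"].to_numpy(), refs.data["phi_true"].to_numpy(), refs.cell
        )
        dmap = ps.modify_density(dmap, 0.05)
        m_ext = ReciprocalMapping(ext[["h", "k", "l"]].to_numpy(int), refs.spacegroup, shape)
        f_extrap = np.abs(m_ext.from_map(dmap))
        from phaseseed.sf import structure_factor_array

        f_true_ext = np.abs(
            structure_factor_array(structure, ext[["h", "k", "l"]].to_numpy(int), ext["d"].to_numpy())
        )
        r = np.corrcoef(f_extrap, f_true_ext)[0, 1]
        assert r > 0.7


class TestRunEDM:
    def test_true_phases_are_fixed_point(self, p21_refs):
        mask = np.ones(p21_refs.n_refl, bool)
        a = ps.PhaseAssignment(
            phi_a=p21_refs.data["phi_true"].to_numpy().copy(),
            phi_d=p21_refs.data["phi_true"].to_numpy().copy(),
            seed_mask=mask,
            grid=ps.SamplingGrid(4),
        )
        run = ps.run_edm(p21_refs, a, ps.EDMConfig(n_cycles=30))
        assert run.solved
        # truncation noise moves weak-reflection phases; the attractor stays
        # within ~10° of the truth under the default 5% density truncation
        assert run.trace["mpe"].iloc[-1] < 10.0

    def test_trace_one_record_per_cycle_and_constraint(self, p21_refs, rng):
        mask = ps.select_seed(p21_refs, ps.SeedSpec("random", 50), rng)
        a = ps.assign_initial_phases(p21_refs, mask, ps.SamplingGrid(4), rng)
        run = ps.run_edm(p21_refs, a, ps.EDMConfig(n_cycles=12, stall_window=1000))
        assert list(run.trace["cycle"]) == list(range(len(run.trace)))
        assert len(run.trace) <= 12
        assert {"mpe", "rf", "map_corr"} <= set(run.trace.columns)

    def test_mean_final_mpe_nonincreasing_in_seed_size(self, p21_refs):
        rng = np.random.default_rng(0)
        cfg = ps.EDMConfig(n_cycles=80)
        means = []
        for p in (0, 20, 50, 100):
            finals = []
            for _ in range(10):
                mask = ps.select_seed(p21_refs, ps.SeedSpec("random", p), rng)
                a = ps.assign_initial_phases(p21_refs, mask, ps.SamplingGrid(3), rng)
                run = ps.run_edm(p21_refs, a, cfg)
                finals.append(run.trace["mpe"].iloc[-1])
            means.append(np.mean(finals))
        assert all(means[i + 1] <= means[i] + 3.0 for i in range(len(means) - 1))

    def test_solved_runs_have_correlated_maps(self, p21_refs, rng):
        mask = ps.select_seed(p21_refs, ps.SeedSpec("e_random", 30), rng)
        a = ps.assign_initial_phases(p21_refs, mask, ps.SamplingGrid(3), rng)
        run = ps.run_edm(p21_refs, a)
        if run.solved:
            assert run.trace["map_corr"].iloc[-1] > 0.5
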
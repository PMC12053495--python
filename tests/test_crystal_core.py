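"""Cell geometry, symmetry classification and unique-reflection generation."""

import gemmi
import numpy as np
import pytest

from phaseseed import (
    UnitCell,
    classify_reflection,
    d_spacing,
    get_spacegroup,
    unique_reflections,
)
from phaseseed.reflections import orbit_representatives
from phaseseed.symmetry import available_spacegroups, is_absent

GEMMI_NAMES = {
    "P1": "P 1",
    "P21": "P 1 21 1",
    "C2": "C 1 2 1",
    "P212121": "P 21 21 21",
    "P31": "P 31",
    "R3": "R 3",
}


class TestDSpacing:
    @pytest.mark.parametrize(
        "cell, hkl, expected",
        [
            (UnitCell(10, 10, 10), (1, 0, 0), 10.0),
            (UnitCell(3, 4, 5), (1, 1, 1), 1.0 / np.sqrt(1 / 9 + 1 / 16 + 1 / 25)),
        ],
    )
    def test_examples(self, cell, hkl, expected):
        assert d_spacing(cell, hkl) == pytest.approx(expected, rel=1e-12)

    def test_zero_index_rejected(self):
        with pytest.raises(ValueError):
            d_spacing(UnitCell(10, 10, 10), (0, 0, 0))

    def test_matches_gemmi_on_triclinic(self, rng):
        cell = UnitCell(7.1, 9.3, 11.8, 83.0, 97.5, 105.2)
        gcell = gemmi.UnitCell(7.1, 9.3, 11.8, 83.0, 97.5, 105.2)
        for _ in range(50):
            hkl = rng.integers(-8, 9, size=3)
            if not hkl.any():
                continue
            assert d_spacing(cell, hkl) == pytest.approx(
                gcell.calculate_d(list(map(int, hkl))), rel=1e-10
            )


class TestSpaceGroupTable:
    @pytest.mark.parametrize("symbol", available_spacegroups())
    def test_groups_closed_noncentrosymmetric(self, symbol):
        sg = get_spacegroup(symbol)
        assert not sg.is_centrosymmetric
        assert sg.check_closure()

    @pytest.mark.parametrize("symbol", available_spacegroups())
    def test_operator_sets_match_gemmi(self, symbol):
        sg = get_spacegroup(symbol)
        ours = {op.triplet().replace(" ", "") for op in sg.ops}
        ref = {
            gemmi.Op(op.triplet()).triplet().replace(" ", "")
            for op in gemmi.SpaceGroup(GEMMI_NAMES[symbol]).operations()
        }
        norm = lambda s: {gemmi.Op(t).triplet() for t in s}
        assert norm(ours) == norm(ref)


def _brute_force_classify(sg, hkl):
    """Oracle: explicit orbit enumeration with the phase-shift relation."""
    h = np.asarray(hkl)
    centric = False
    allowed = None
    epsilon = 0
    for op in sg.ops:
        hR = h @ op.rot
        if np.array_equal(hR, h):
            epsilon += 1
        if np.array_equal(hR, -h):
            centric = True
            if allowed is None:
                phi0 = (180.0 * float(h @ op.tran)) % 180.0
                allowed = (phi0, (phi0 + 180.0) % 360.0)
    return centric, allowed, epsilon


class TestClassification:
    def test_p1_all_acentric(self, rng):
        sg = get_spacegroup("P1")
        for _ in range(20):
            hkl = rng.integers(-6, 7, size=3)
            if not hkl.any():
                continue
            centric, allowed, eps = classify_reflection(sg, hkl)
            assert (centric, allowed, eps) == (False, None, 1)

    def test_p31_has_no_restricted_reflections(self, rng):
        # trigonal screw groups lack centric zones entirely
        sg = get_spacegroup("P31")
        for _ in range(300):
            hkl = rng.integers(-8, 9, size=3)
            if not hkl.any():
                continue
            centric, _, _ = classify_reflection(sg, hkl)
            assert not centric

    def test_p21_h0l_zone_restricted(self):
        centric, allowed, eps = classify_reflection(get_spacegroup("P21"), (1, 0, 2))
        assert centric
        assert allowed == (0.0, 180.0)
        assert eps == 1

    @pytest.mark.parametrize("symbol", available_spacegroups())
    def test_matches_bruteforce_orbit_oracle(self, symbol, rng):
        sg = get_spacegroup(symbol)
        for _ in range(1000):
            hkl = rng.integers(-10, 11, size=3)
            if not hkl.any():
                continue
            assert classify_reflection(sg, hkl) == _brute_force_classify(sg, hkl)

    @pytest.mark.parametrize("symbol", available_spacegroups())
    def test_centric_and_absence_match_gemmi(self, symbol, rng):
        sg = get_spacegroup(symbol)
        gops = gemmi.SpaceGroup(GEMMI_NAMES[symbol]).operations()
        for _ in range(300):
            hkl = [int(x) for x in rng.integers(-8, 9, size=3)]
            if not any(hkl):
                continue
            centric, _, eps = classify_reflection(sg, hkl)
            assert centric == gops.is_reflection_centric(hkl)
            assert is_absent(sg, hkl) == gops.is_systematically_absent(hkl)

    def test_allowed_phases_always_180_apart(self, rng):
        for symbol in available_spacegroups():
            sg = get_spacegroup(symbol)
            for _ in range(100):
                hkl = rng.integers(-8, 9, size=3)
                if not hkl.any():
                    continue
                centric, allowed, _ = classify_reflection(sg, hkl)
                if centric:
                    assert (allowed[1] - allowed[0]) % 360.0 == pytest.approx(180.0)


class TestUniqueReflections:
    def test_p1_cubic_count(self):
        # h²+k²+l² ≤ 4 gives 32 lattice points, halved by Friedel merging
        refs = unique_reflections(UnitCell(10, 10, 10), get_spacegroup("P1"), 5.0)
        assert refs.n_refl == 16

    def test_too_large_dmin_warns_empty(self):
        with pytest.warns(UserWarning):
            refs = unique_reflections(UnitCell(5, 5, 5), get_spacegroup("P1"), 20.0)
        assert refs.n_refl == 0

    def test_p21_subset_of_p1(self):
        cell = UnitCell(6, 7, 8, 90, 100, 90)
        p1 = unique_reflections(cell, get_spacegroup("P1"), 2.0)
        p21 = unique_reflections(cell, get_spacegroup("P21"), 2.0)
        p1_keys = set(map(tuple, p1.hkl))
        p21_keys = set(map(tuple, p21.hkl))
        assert p21_keys <= p1_keys
        assert len(p21_keys) < len(p1_keys)

    @pytest.mark.parametrize("symbol", ["P21", "C2", "P212121", "P31", "R3"])
    def test_orbit_coverage_exact(self, symbol):
        """Re-expanded orbits tile all non-absent lattice points exactly once."""
        cell = (
            UnitCell(8, 8, 9, 90, 90, 120)
            if symbol in ("P31", "R3")
            else UnitCell(7, 8, 9, 90, 100 if symbol in ("P21", "C2") else 90, 90)
        )
        sg = get_spacegroup(symbol)
        d_min = 2.0
        refs = unique_reflections(cell, sg, d_min)
        # all valid lattice points in the sphere
        p1 = unique_reflections(cell, get_spacegroup("P1"), d_min)
        full = set(map(tuple, p1.hkl)) | set(map(tuple, -p1.hkl))
        full = {h for h in full if not is_absent(sg, h)}
        covered: list[tuple] = []
        rots = sg.rotations
        for h in refs.hkl:
            orbit = np.concatenate([h @ rots, -(h @ rots)], axis=0)
            covered.extend(set(map(tuple, orbit)))
        assert len(covered) == len(set(covered))  # orbits are disjoint
        assert set(covered) == full

    def test_representative_is_orbit_lexmax(self, p21_refs):
        hkl = p21_refs.hkl
        reps = orbit_representatives(p21_refs.spacegroup, hkl)
        assert np.array_equal(reps, hkl)

    def test_f000_and_absences_excluded(self):
        cell = UnitCell(6, 7, 8, 90, 100, 90)
        refs = unique_reflections(cell, get_spacegroup("P21"), 2.0)
        keys = set(map(tuple, refs.hkl))
        assert (0, 0, 0) not in keys
        assert (0, 1, 0) not in keys  # 2₁ axial absence: 0k0 with odd k
        assert all(not is_absent(refs.spacegroup, h) for h in refs.hkl)
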
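"""Landscape analyses: Q, PMF, barriers, ensembles, φ-values, Cv, RMSD."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from mcfold import (
    ConfigError,
    EnsembleDefinition,
    InputError,
    NativeContactSet,
    assign_ensembles,
    calibrate_temperature,
    compute_q,
    contact_frequency_map,
    define_native_contacts,
    difference_map,
    folding_temperature,
    hbond_distance,
    heat_capacity,
    kabsch_rmsd,
    locate_minima_and_barriers,
    per_residue_nativeness,
    phi_values,
    pmf,
)

KB = 1.9872041e-3


@pytest.fixture(scope="module")
def peptide10():
    from mcfold import generate_fixture_peptide

    system, _ = generate_fixture_peptide(10, seed=4)
    return system


@pytest.fixture(scope="module")
def contacts10(peptide10):
    return define_native_contacts(peptide10, peptide10.coords)


class TestNativeContacts:
    def test_far_apart_residues_give_empty_set(self, peptide10):
        stretched = peptide10.coords.copy()
        # move every residue 50 Å apart along x
        for k in range(peptide10.n_atoms):
            stretched[k, 0] += 50.0 * int(peptide10.res_ids[k])
        contacts = define_native_contacts(peptide10, stretched)
        assert len(contacts) == 0

    def test_minimum_separation_excludes_neighbors(self, contacts10):
        for i, j in contacts10.pairs:
            assert j - i >= contacts10.min_separation

    def test_matches_brute_force_enumeration(self, peptide10, contacts10):
        heavy = {}
        for k in range(peptide10.n_atoms):
            if peptide10.elements[k] != "H":
                heavy.setdefault(int(peptide10.res_ids[k]), []).append(k)
        rids = sorted(heavy)
        expected = set()
        for a in range(len(rids)):
            for b in range(a + 1, len(rids)):
                if rids[b] - rids[a] < 3:
                    continue
                dmin = min(
                    np.linalg.norm(peptide10.coords[x] - peptide10.coords[y])
                    for x in heavy[rids[a]]
                    for y in heavy[rids[b]]
                )
                if dmin < 4.5:
                    expected.add((a, b))
        assert set(contacts10.pairs) == expected
        assert len(contacts10) > 0


class TestComputeQ:
    def test_reference_has_q_one(self, peptide10, contacts10):
        assert compute_q(peptide10.coords, contacts10) == 1.0

    def test_fully_stretched_has_q_zero(self, peptide10, contacts10):
        stretched = peptide10.coords.copy()
        for k in range(peptide10.n_atoms):
            stretched[k, 0] += 100.0 * int(peptide10.res_ids[k])
        assert compute_q(stretched, contacts10) == 0.0

    def test_counting_seven_of_ten(self):
        # synthetic contact set over 20 single-atom residues; break 3 of 10
        coords = np.zeros((20, 3))
        pairs = [(k, k + 10) for k in range(10)]
        for i, j in pairs:
            coords[i] = [i * 30.0, 0, 0]
            coords[j] = [i * 30.0 + 3.0, 0, 0]
        contacts = NativeContactSet(
            reference_id="toy", pairs=pairs,
            native_dists=np.full(10, 3.0), cutoff=4.5, min_separation=3,
            lam=1.2, residue_heavy=[np.array([k]) for k in range(20)],
            residue_labels=list(range(1, 21)),
        )
        broken = coords.copy()
        for i, j in pairs[:3]:
            broken[j, 1] += 50.0
        assert compute_q(coords, contacts) == 1.0
        assert compute_q(broken, contacts) == pytest.approx(0.7)

    def test_q_non_increasing_as_contacts_break(self, peptide10, contacts10):
        coords = peptide10.coords.copy()
        qs = [compute_q(coords, contacts10)]
        rids = sorted({int(r) for r in peptide10.res_ids})
        for n, rid in enumerate(reversed(rids), start=1):
            coords[peptide10.res_ids == rid] += np.array([0.0, 0.0, 100.0 * n])
            qs.append(compute_q(coords, contacts10))
        assert all(b <= a for a, b in zip(qs, qs[1:]))
        assert qs[-1] == 0.0

    def test_empty_contact_set_is_an_error(self, peptide10):
        empty = NativeContactSet("x", [], np.array([]), 4.5, 3, 1.2, [], [])
        with pytest.raises(InputError):
            compute_q(peptide10.coords, empty)


class TestPerResidueNativeness:
    def test_reference_all_ones(self, peptide10, contacts10):
        q = per_residue_nativeness(peptide10.coords, contacts10)
        with_contacts = ~np.isnan(q)
        assert with_contacts.any()
        np.testing.assert_allclose(q[with_contacts], 1.0)

    def test_contactless_residue_flagged_undefined(self, peptide10, contacts10):
        in_pairs = {i for p in contacts10.pairs for i in p}
        q = per_residue_nativeness(peptide10.coords, contacts10)
        for r in range(len(contacts10.residue_heavy)):
            if r not in in_pairs:
                assert np.isnan(q[r])

    def test_hand_count(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [0.0, 3, 0], [50.0, 0, 0]])
        contacts = NativeContactSet(
            "toy", [(0, 1), (0, 2), (0, 3)], np.array([3.0, 3.0, 3.0]),
            4.5, 0, 1.2, [np.array([k]) for k in range(4)], [1, 2, 3, 4],
        )
        moved = coords.copy()
        moved[3] = [0.0, 0, 50.0]  # also broken, 50 != 50? keep broken
        q = per_residue_nativeness(coords, contacts)
        # residue 0 has 3 contacts, of which (0,3) at 50 Å is not formed
        assert q[0] == pytest.approx(2.0 / 3.0)
        assert q[1] == 1.0 and q[2] == 1.0 and q[3] == 0.0


class TestPmf:
    def test_uniform_samples_give_flat_profile(self):
        q = np.repeat(np.linspace(0.05, 0.95, 10), 100)
        centers, F = pmf(q, 300.0, n_bins=10)
        np.testing.assert_allclose(F, 0.0, atol=1e-12)

    def test_two_bin_occupancy_formula(self):
        q = np.array([0.2] * 73 + [0.8] * 27)
        centers, F = pmf(q, 370.0, n_bins=2)
        dF = F[1] - F[0]
        assert dF == pytest.approx(-KB * 370.0 * np.log(27.0 / 73.0), abs=1e-9)
        assert dF == pytest.approx(0.731, abs=5e-4)

    def test_empty_bins_masked_not_minima(self):
        q = np.array([0.05] * 40 + [0.55] * 30 + [0.95] * 30)
        centers, F = pmf(q, 300.0, n_bins=10)
        assert np.isnan(F[2])
        minima, _ = locate_minima_and_barriers(F, centers)
        for m in minima:
            k = np.argmin(np.abs(centers - m))
            assert np.isfinite(F[k])


class TestMinimaBarriers:
    def test_constructed_double_well(self):
        minima, barriers = locate_minima_and_barriers([0.0, 1.0, 0.5])
        assert minima == [0.0, 2.0]
        assert len(barriers) == 1
        assert barriers[0].dG_from_left == pytest.approx(1.0)
        assert barriers[0].dG_from_right == pytest.approx(0.5)

    def test_flat_profile_has_no_barriers(self):
        minima, barriers = locate_minima_and_barriers([1.0, 1.0, 1.0, 1.0])
        assert barriers == []

    def test_random_profile_matches_exhaustive_scan(self, rng):
        F = rng.normal(size=50)
        minima, barriers = locate_minima_and_barriers(F)
        # independent exhaustive scan
        exp_minima = [
            k for k in range(50)
            if (k == 0 or F[k] < F[k - 1]) and (k == 49 or F[k] < F[k + 1])
        ]
        assert minima == [float(k) for k in exp_minima]
        for b, (a, c) in zip(barriers, zip(exp_minima[:-1], exp_minima[1:])):
            peak = max(F[a : c + 1])
            assert b.dG_from_left == pytest.approx(peak - F[a])
            assert b.dG_from_right == pytest.approx(peak - F[c])

    def test_shift_invariance_of_barriers(self, rng):
        F = rng.normal(size=30)
        _, b0 = locate_minima_and_barriers(F)
        _, b1 = locate_minima_and_barriers(F + 7.5)
        for x, y in zip(b0, b1):
            assert x.dG_from_left == pytest.approx(y.dG_from_left)
            assert x.dG_from_right == pytest.approx(y.dG_from_right)


def _profile(dF):
    """Three-bin double well with folded-minus-unfolded gap dF."""
    centers = np.array([0.1, 0.5, 0.9])
    return centers, np.array([0.0, 1.0, dF])


class TestFoldingTemperature:
    def test_linear_interpolation(self):
        profiles = {350.0: _profile(+0.5), 360.0: _profile(-0.5)}
        assert folding_temperature(profiles) == pytest.approx(355.0)

    def test_exact_zero_returned(self):
        profiles = {340.0: _profile(0.4), 350.0: _profile(0.0),
                    360.0: _profile(-0.4)}
        assert folding_temperature(profiles) == 350.0

    def test_three_point_hand_interpolation(self):
        profiles = {300.0: _profile(0.9), 320.0: _profile(0.3),
                    340.0: _profile(-0.6)}
        # hand interpolation between 320 and 340: 320 + 20*0.3/0.9
        assert folding_temperature(profiles) == pytest.approx(320 + 20 * 0.3 / 0.9)

    def test_no_crossing_is_outside_range(self):
        profiles = {300.0: _profile(0.9), 320.0: _profile(0.5)}
        assert folding_temperature(profiles) is None


class TestCalibration:
    def test_uniform_shift(self):
        assert calibrate_temperature(437.0, 83.0) == pytest.approx(354.0)

    def test_identity_and_round_trip(self):
        assert calibrate_temperature(400.0, 0.0) == 400.0
        assert calibrate_temperature(calibrate_temperature(400.0, 83.0), -83.0) == 400.0


class TestEnsembles:
    def test_basic_assignment(self):
        d = EnsembleDefinition({"D": (0.0, 0.35), "N": (0.7, 1.0)})
        assert assign_ensembles([0.8], d) == ["N"]
        assert assign_ensembles([0.5], d) == ["unassigned"]

    def test_boundary_closed_on_left(self):
        d = EnsembleDefinition({"D": (0.0, 0.35), "N": (0.35, 1.0)})
        assert assign_ensembles([0.35], d) == ["N"]
        assert assign_ensembles([1.0], d) == ["N"]

    def test_matches_brute_force(self, rng):
        d = EnsembleDefinition({"D": (0.0, 0.3), "I": (0.35, 0.55), "N": (0.7, 1.0)})
        qs = rng.random(500)
        labels = assign_ensembles(qs, d)
        for q, lab in zip(qs, labels):
            exp = "unassigned"
            for name, (lo, hi) in d.intervals.items():
                if lo <= q < hi:
                    exp = name
            assert lab == exp

    def test_overlap_rejected(self):
        with pytest.raises(ConfigError):
            EnsembleDefinition({"A": (0.0, 0.5), "B": (0.4, 1.0)})


class TestContactMaps:
    def test_native_frame_recovers_native_contacts(self, peptide10, contacts10):
        fmap = contact_frequency_map([peptide10.coords], peptide10)
        for i, j in contacts10.pairs:
            assert fmap[i, j] == 1.0
        nres = fmap.shape[0]
        native = set(contacts10.pairs)
        for i in range(nres):
            for j in range(i + 3, nres):
                if (i, j) not in native:
                    assert fmap[i, j] == 0.0
        np.testing.assert_allclose(fmap, fmap.T)

    def test_difference_of_identical_maps_is_zero(self, peptide10):
        fmap = contact_frequency_map([peptide10.coords], peptide10)
        np.testing.assert_allclose(difference_map(fmap, fmap), 0.0)

    def test_three_frame_hand_count(self, peptide10, contacts10):
        stretched = peptide10.coords.copy()
        for k in range(peptide10.n_atoms):
            stretched[k, 0] += 100.0 * int(peptide10.res_ids[k])
        frames = [peptide10.coords, peptide10.coords, stretched]
        fmap = contact_frequency_map(frames, peptide10)
        i, j = contacts10.pairs[0]
        assert fmap[i, j] == pytest.approx(2.0 / 3.0)

    def test_empty_ensemble_rejected(self, peptide10):
        with pytest.raises(InputError):
            contact_frequency_map([], peptide10)


class TestPhiValues:
    def _frames(self, peptide10, contacts10):
        stretched = peptide10.coords.copy()
        for k in range(peptide10.n_atoms):
            stretched[k, 0] += 100.0 * int(peptide10.res_ids[k])
        return peptide10.coords, stretched

    def test_ts_equals_native_gives_one(self, peptide10, contacts10):
        native, stretched = self._frames(peptide10, contacts10)
        df = phi_values(
            [native, native, stretched], ["N", "TS", "D"],
            [0.0, 0.0, 0.0], contacts10, 300.0,
        )
        ok = ~df["flagged"]
        assert ok.any()
        np.testing.assert_allclose(df.loc[ok, "phi"], 1.0)

    def test_ts_equals_denatured_gives_zero(self, peptide10, contacts10):
        native, stretched = self._frames(peptide10, contacts10)
        df = phi_values(
            [native, stretched, stretched], ["N", "TS", "D"],
            [0.0, 0.0, 0.0], contacts10, 300.0,
        )
        ok = ~df["flagged"]
        np.testing.assert_allclose(df.loc[ok, "phi"], 0.0, atol=1e-12)

    def test_hand_boltzmann_weights(self, peptide10, contacts10):
        native, stretched = self._frames(peptide10, contacts10)
        T = 300.0
        # two TS frames with energies differing by exactly kBT
        df = phi_values(
            [native, stretched, native, stretched],
            ["N", "D", "TS", "TS"],
            [0.0, 0.0, 0.0, KB * T],
            contacts10, T,
        )
        w_native = 1.0 / (1.0 + np.exp(-1.0))
        ok = ~df["flagged"]
        # q_i is 1 in the native frame, 0 in the stretched frame
        np.testing.assert_allclose(df.loc[ok, "phi"], w_native, atol=1e-12)

    def test_empty_ensemble_rejected(self, peptide10, contacts10):
        with pytest.raises(InputError):
            phi_values([peptide10.coords], ["N"], [0.0], contacts10, 300.0)


class TestHeatCapacity:
    def test_constant_energy_gives_zero(self):
        df = heat_capacity({300.0: np.full(100, 5.0)})
        assert df["Cv"].iloc[0] == 0.0

    def test_gaussian_fluctuation_formula(self, rng):
        E = rng.normal(0.0, 1.0, size=40_000)
        df = heat_capacity({300.0: E})
        expected = np.var(E) / (KB * 300.0**2)
        assert df["Cv"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert df["Cv"].iloc[0] == pytest.approx(1.0 / (KB * 300.0**2), rel=0.05)

    def test_shift_invariance(self, rng):
        E = rng.normal(0.0, 2.0, size=1000)
        a = heat_capacity({300.0: E})["Cv"].iloc[0]
        b = heat_capacity({300.0: E + 123.0})["Cv"].iloc[0]
        assert a == pytest.approx(b, rel=1e-9)

    def test_single_sample_rejected(self):
        with pytest.raises(InputError):
            heat_capacity({300.0: np.array([1.0])})

    def test_two_state_peak_location(self, rng):
        # two-state system: ground state E=0 (1 state), excited E=dE (g states)
        dE, g = 5.0, 200
        T_star = dE / (KB * np.log(g))  # equal-population crossover
        temps = np.linspace(0.5 * T_star, 1.5 * T_star, 21)
        samples = {}
        for T in temps:
            p_ex = g * np.exp(-dE / (KB * T)) / (1 + g * np.exp(-dE / (KB * T)))
            samples[float(T)] = dE * (rng.random(20_000) < p_ex)
        df = heat_capacity(samples)
        peak_T = df.loc[df["Cv"].idxmax(), "T"]
        spacing = temps[1] - temps[0]
        assert abs(peak_T - T_star) <= 2 * spacing


class TestKabschRmsd:
    def test_self_is_zero(self, peptide10):
        assert kabsch_rmsd(peptide10.coords, peptide10.coords) == pytest.approx(0.0, abs=1e-6)

    def test_rigid_transform_removed(self, peptide10, rng):
        from mcfold.geometry import rotation_matrix

        rot = rotation_matrix(rng.normal(size=3), 1.1)
        moved = peptide10.coords @ rot.T + np.array([4.0, 5.0, -6.0])
        assert kabsch_rmsd(peptide10.coords, moved) < 1e-9
        assert kabsch_rmsd(moved, peptide10.coords) < 1e-9

    def test_selections(self, peptide10, rng):
        moved = peptide10.coords + rng.normal(0, 0.3, size=peptide10.coords.shape)
        all_r = kabsch_rmsd(peptide10.coords, moved, peptide10, "all")
        bb_r = kabsch_rmsd(peptide10.coords, moved, peptide10, "backbone")
        ca_r = kabsch_rmsd(peptide10.coords, moved, peptide10, "ca")
        assert all_r > 0 and bb_r > 0 and ca_r > 0

    def test_planar_toy_matches_grid_search(self):
        A = np.array([[0.0, 0, 0], [2.0, 0, 0], [2.0, 1.0, 0], [0.5, 2.0, 0]])
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        B = (A + np.array([[0.1, -0.05, 0], [0, 0.12, 0], [-0.08, 0, 0],
                           [0.03, 0.06, 0]])) @ R.T + 3.0
        got = kabsch_rmsd(A, B)
        # oracle: scan in-plane rotations (plus a flip) on centered clouds
        A0 = A - A.mean(0)
        B0 = B - B.mean(0)
        best = np.inf
        flip = np.diag([1.0, -1.0, -1.0])  # proper rotation by pi about x
        for t in np.arange(0, 2 * np.pi, np.deg2rad(0.01)):
            Rz = np.array([[np.cos(t), -np.sin(t), 0],
                           [np.sin(t), np.cos(t), 0], [0, 0, 1.0]])
            for M in (Rz, Rz @ flip):
                best = min(best, np.sqrt(((A0 - B0 @ M.T) ** 2).sum() / len(A0)))
        assert got == pytest.approx(best, abs=1e-4)

    def test_errors(self, peptide10):
        with pytest.raises(InputError):
            kabsch_rmsd(peptide10.coords, peptide10.coords[:-1])
        with pytest.raises(InputError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestHbondDistance:
    def test_collinear_minimum(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        assert hbond_distance(coords, [0], [1, 2]) == pytest.approx(2.0)

    def test_matches_cdist(self, peptide10, rng):
        donors = rng.choice(peptide10.n_atoms, 5, replace=False)
        acceptors = rng.choice(peptide10.n_atoms, 7, replace=False)
        expected = cdist(peptide10.coords[donors], peptide10.coords[acceptors]).min()
        assert hbond_distance(peptide10.coords, donors, acceptors) == pytest.approx(expected)

    def test_empty_selection_rejected(self, peptide10):
        with pytest.raises(InputError):
            hbond_distance(peptide10.coords, [], [1])
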
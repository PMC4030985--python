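import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from knotfold.fixtures import extended_chain, toy_native
from knotfold.forcefield import QuasiChemicalParams
from knotfold.observables import (fes_2d, kabsch_rmsd,
                                  pathway_probability_from_barriers,
                                  project_trajectory, ss_contact_fractions,
                                  terminus_attraction)
from knotfold.ratchet import native_fraction
from knotfold.samplers import Trajectory

from .oracles import grid_search_rmsd


class TestKabschRmsd:
    def test_identical_conformations_zero(self, small_native):
        trace, _ = small_native
        assert kabsch_rmsd(trace.positions, trace.positions) == pytest.approx(
            0.0, abs=1e-12)

    def test_rigid_motion_gives_zero(self, small_native):
        trace, _ = small_native
        R = Rotation.random(random_state=5).as_matrix()
        moved = trace.positions @ R.T + np.array([1.0, -2.0, 0.5])
        assert kabsch_rmsd(trace.positions, moved) < 1e-9

    def test_matches_rotation_grid_oracle_on_four_points(self):
        rng = np.random.default_rng(17)
        a = rng.normal(size=(4, 3)) * 3
        b = rng.normal(size=(4, 3)) * 3
        assert kabsch_rmsd(a, b) == pytest.approx(
            grid_search_rmsd(a, b), abs=1e-3 + 0.02 * grid_search_rmsd(a, b))

    def test_symmetry(self, small_native):
        trace, _ = small_native
        rng = np.random.default_rng(3)
        other = trace.positions + rng.normal(scale=1.0,
                                             size=trace.positions.shape)
        assert kabsch_rmsd(trace.positions, other) == pytest.approx(
            kabsch_rmsd(other, trace.positions), rel=1e-9)

    def test_collinear_subset_rejected(self):
        line = extended_chain(10)
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_rmsd(line, line + 1.0)

    def test_subset_selection(self, small_native):
        trace, _ = small_native
        sub = np.arange(5)
        perturbed = trace.positions.copy()
        perturbed[10:] += 50.0               # far away, outside subset
        assert kabsch_rmsd(trace.positions, perturbed, sub) < 1e-9


class TestProjectTrajectory:
    def test_trajectory_ending_at_native_reaches_origin(self, small_native):
        trace, _ = small_native
        ext = extended_chain(15)
        frames = np.asarray([
            lam * trace.positions + (1 - lam) * ext
            for lam in np.linspace(0, 1, 6)
        ])
        traj = Trajectory(frames=frames, stride=1, seed=0, temperature=1.0)
        path = project_trajectory(traj, np.arange(5), np.arange(15),
                                  trace.positions)
        assert path.shape == (6, 2)
        assert path[-1, 0] < 1e-9 and path[-1, 1] < 1e-9

    def test_constant_trajectory_is_single_point(self, small_native):
        trace, _ = small_native
        frames = np.repeat(trace.positions[None], 4, axis=0)
        traj = Trajectory(frames=frames, stride=1, seed=0, temperature=1.0)
        path = project_trajectory(traj, np.arange(4, 10), np.arange(15),
                                  trace.positions)
        assert np.allclose(path, path[0])

    def test_two_phase_fixture_orders_coordinates(self, small_native):
        # substructure b forms first, then the rest collapses: the
        # b-coordinate must drop below 2 Å before the a-coordinate does
        trace, _ = small_native
        ext = extended_chain(15)
        sub_b = np.arange(8, 15)
        frames = []
        for lam in np.linspace(0, 1, 5):     # phase 1: form b only
            x = ext.copy()
            x[sub_b] = lam * trace.positions[sub_b] + (1 - lam) * ext[sub_b]
            frames.append(x)
        for lam in np.linspace(0, 1, 5):     # phase 2: rest collapses
            x = frames[4].copy()
            x[:8] = lam * trace.positions[:8] + (1 - lam) * ext[:8]
            frames.append(x)
        traj = Trajectory(frames=np.asarray(frames), stride=1, seed=0,
                          temperature=1.0)
        path = project_trajectory(traj, np.arange(8), sub_b, trace.positions)
        first_b = np.nonzero(path[:, 1] < 2.0)[0][0]
        first_a = np.nonzero(path[:, 0] < 2.0)[0][0]
        assert first_b < first_a


class TestFES:
    def test_minimum_bin_exactly_zero(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=(500, 2))
        grid = fes_2d(s, 10, kBT=1.0)
        assert np.nanmin(grid.free_energy) == 0.0

    def test_two_bin_occupancy_ratio_closed_form(self):
        # 10:1 occupancy -> deltaF = kBT ln 10
        samples = np.array([[0.25, 0.5]] * 500 + [[0.75, 0.5]] * 50)
        edges = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 1.0]))
        grid = fes_2d(samples, edges, kBT=1.3)
        dF = grid.free_energy[1, 0] - grid.free_energy[0, 0]
        assert dF == pytest.approx(1.3 * np.log(10), rel=1e-9)

    def test_equal_occupancy_zero_difference(self):
        samples = np.array([[0.25, 0.5]] * 300 + [[0.75, 0.5]] * 300)
        edges = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 1.0]))
        grid = fes_2d(samples, edges)
        assert grid.free_energy[1, 0] == pytest.approx(
            grid.free_energy[0, 0])

    def test_duplication_invariance_and_empty_bin_masking(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=(400, 2))
        edges = (np.linspace(-3, 3, 7), np.linspace(-3, 3, 7))
        g1 = fes_2d(s, edges)
        g2 = fes_2d(np.vstack([s, s]), edges)
        m = np.isfinite(g1.free_energy)
        assert np.array_equal(m, np.isfinite(g2.free_energy))
        assert np.allclose(g1.free_energy[m], g2.free_energy[m])

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            fes_2d(np.empty((0, 2)), 5)


class TestSSContactFractions:
    def _mixed_native(self):
        tr, cm = toy_native(24, "beta_hairpin_pair")
        # relabel part of the chain so all three classes appear
        tr.ss_label = (["helix"] * 8 + ["sheet"] * 8 + ["coil"] * 8)
        from knotfold.structure import build_contact_map
        return tr, build_contact_map(tr)

    def test_native_conformation_all_classes_one(self):
        tr, cm = self._mixed_native()
        st = ss_contact_fractions(tr.positions, cm)
        assert st.overall == 1.0
        for v in (st.alpha, st.beta, st.other):
            assert v is None or v == 1.0

    def test_extended_chain_all_zero(self):
        tr, cm = self._mixed_native()
        st = ss_contact_fractions(extended_chain(tr.n_beads), cm)
        assert st.overall == 0.0

    def test_class_weighted_mean_equals_overall_q(self):
        tr, cm = self._mixed_native()
        rng = np.random.default_rng(2)
        x = tr.positions + rng.normal(scale=1.2, size=tr.positions.shape)
        st = ss_contact_fractions(x, cm, 1.2)
        total = 0.0
        for cls, frac in (("alpha", st.alpha), ("beta", st.beta),
                          ("other", st.other)):
            if frac is not None:
                total += frac * st.n_pairs[cls]
        assert total / cm.n_pairs == pytest.approx(
            native_fraction(x, cm, 1.2), abs=1e-12)
        assert st.overall == pytest.approx(native_fraction(x, cm, 1.2))

    def test_zero_pair_class_reported_undefined(self):
        tr, cm = toy_native(20, "helix_hairpin")   # all-helix: no beta pairs
        st = ss_contact_fractions(tr.positions, cm)
        assert st.beta is None


class TestTerminusAttraction:
    def test_lambda_zero_gives_zero(self, small_native):
        trace, _ = small_native
        mean, se = terminus_attraction(
            [trace.positions], trace, QuasiChemicalParams(lambda_nn=0.0), 4)
        assert mean == 0.0

    def test_single_conformation_matches_brute_force(self, small_native):
        trace, _ = small_native
        qc = QuasiChemicalParams(lambda_nn=1.0, attractive_only=False)
        tl = 4
        n = trace.n_beads
        mean, se = terminus_attraction([trace.positions], trace, qc, tl)
        from knotfold.structure import AA1, build_contact_map

        cmap = build_contact_map(trace)
        native = set(map(tuple, cmap.pairs.tolist()))
        aa = [AA1.index(a) for a in trace.residue_type]
        x = trace.positions
        total = 0.0
        w, r_on = qc.switching_width, qc.nn_cutoff - qc.switching_width
        for i in range(n):
            for j in range(i + 3, n):
                if (i, j) in native:
                    continue
                if (i >= n - tl) == (j >= n - tl):
                    continue
                r = np.linalg.norm(x[i] - x[j])
                if r >= qc.nn_cutoff:
                    continue
                sw = 1.0 if r <= r_on else 0.5 * (
                    1 + np.cos(np.pi * (r - r_on) / w))
                total += qc.contact_energy[aa[i], aa[j]] * sw
        assert mean == pytest.approx(total, rel=1e-12)
        assert se == 0.0

    def test_ensemble_duplication_scales_standard_error(self, small_native):
        trace, _ = small_native
        rng = np.random.default_rng(7)
        ens = [trace.positions + rng.normal(scale=0.5,
                                            size=trace.positions.shape)
               for _ in range(8)]
        qc = QuasiChemicalParams(lambda_nn=1.0)
        m1, s1 = terminus_attraction(ens, trace, qc, 4)
        m2, s2 = terminus_attraction(ens + ens, trace, qc, 4)
        assert m2 == pytest.approx(m1, rel=1e-12)
        # duplicating an m-sample ensemble scales SE by sqrt((m-1)/(2m-1))
        m = len(ens)
        assert s2 == pytest.approx(s1 * np.sqrt((m - 1) / (2 * m - 1)),
                                   rel=1e-9)

    def test_overlong_terminus_rejected(self, small_native):
        trace, _ = small_native
        with pytest.raises(ValueError):
            terminus_attraction([trace.positions], trace,
                                QuasiChemicalParams(), trace.n_beads)


class TestPathwayProbabilities:
    def test_equal_barriers_split_evenly(self):
        assert pathway_probability_from_barriers(3.0, 3.0, 1.0) == (0.5, 0.5)

    def test_seventy_thirty_from_log_ratio_barrier_gap(self):
        kBT = 0.8
        dF = -kBT * np.log(7.0 / 3.0)
        p1, p2 = pathway_probability_from_barriers(2.0 + dF, 2.0, kBT)
        assert p1 == pytest.approx(0.7)
        assert p2 == pytest.approx(0.3)

    def test_probabilities_normalize(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            b1, b2 = rng.uniform(0, 10, size=2)
            p1, p2 = pathway_probability_from_barriers(b1, b2, 1.0)
            assert p1 + p2 == pytest.approx(1.0)
            assert 0.0 <= p1 <= 1.0

    def test_infinite_barrier_rejected(self):
        with pytest.raises(ValueError):
            pathway_probability_from_barriers(np.inf, 1.0, 1.0)
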
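import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from knotfold.fixtures import (extended_chain, parametric_knot,
                               scripted_mechanism_trajectory, toy_native)
from knotfold.knots import (KnotCore, KnottingEvent, alexander_det,
                            chain_is_knotted, classify_knot,
                            classify_mechanism, close_chain, detect_slipknot,
                            diagram_crossings, first_knotting_event,
                            kmt_simplify, knotting_probability_curve,
                            locate_core, writhe)
from knotfold.samplers import Trajectory

from .oracles import reduce_gauss_code


def _closed_trefoil(n=200, scale=3.0):
    t = np.linspace(0, 2 * np.pi, n + 1)[:-1]
    return np.stack([np.sin(t) + 2 * np.sin(2 * t),
                     np.cos(t) - 2 * np.cos(2 * t),
                     -np.sin(3 * t)], axis=1) * scale


def _closed_fig8(n=240, scale=3.0):
    t = np.linspace(0, 2 * np.pi, n + 1)[:-1]
    return np.stack([(2 + np.cos(2 * t)) * np.cos(3 * t),
                     (2 + np.cos(2 * t)) * np.sin(3 * t),
                     np.sin(4 * t)], axis=1) * scale


class TestCloseChain:
    def test_closure_of_closed_input_is_identity(self):
        pts = _closed_trefoil(60)
        closed_in = np.vstack([pts, pts[:1]])     # first == last
        out = close_chain(closed_in)
        assert np.array_equal(out, pts)

    def test_planar_arc_closes_to_unknot(self):
        t = np.linspace(0, np.pi, 50)
        arc = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1) * 10
        assert alexander_det(close_chain(arc)) == 1

    def test_open_trefoil_closes_to_trefoil(self):
        pts = parametric_knot("trefoil_right", 150)
        assert alexander_det(close_chain(pts)) == 3

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            close_chain(np.zeros((3, 3)))


class TestAlexanderDeterminant:
    @pytest.mark.parametrize("curve_fn,expected", [
        (lambda: _closed_trefoil(), 3),
        (lambda: _closed_fig8(), 5),
    ])
    def test_standard_invariant_table(self, curve_fn, expected):
        assert alexander_det(curve_fn()) == expected

    def test_planar_polygon_is_unknot(self):
        t = np.linspace(0, 2 * np.pi, 30, endpoint=False)
        ring = np.stack([np.cos(t) * 8, np.sin(t) * 8, 0 * t], axis=1)
        assert alexander_det(ring) == 1

    def test_invariant_under_reversal_rigid_motion_and_scale(self):
        rng = np.random.default_rng(0)
        for curve, det in ((_closed_trefoil(120), 3), (_closed_fig8(150), 5)):
            R = Rotation.random(random_state=7).as_matrix()
            assert alexander_det(curve[::-1]) == det
            assert alexander_det(curve @ R.T + rng.normal(size=3)) == det
            assert alexander_det(curve * 4.7) == det

    def test_kmt_preserves_knot_type_and_reduces(self):
        curve = _closed_trefoil(200)
        red = kmt_simplify(curve)
        assert len(red) < 30
        assert alexander_det(red, simplify=False) == 3

    def test_agrees_with_gauss_code_reduction_oracle(self):
        """Dual-route check: crossing-reduction on the same reduced
        diagram certifies the unknot exactly when the determinant does."""
        rng = np.random.default_rng(99)
        n_checked = 0
        for i in range(100):
            kind = ("unknot", "trefoil_right", "figure_eight")[i % 3]
            pts = parametric_knot(kind, 140, noise_A=0.25, seed=int(
                rng.integers(0, 2**31)))
            closed = kmt_simplify(close_chain(pts))
            det = alexander_det(closed, simplify=False)
            code = reduce_gauss_code(diagram_crossings(closed))
            if det == 1:
                assert len(code) == 0, f"oracle disagrees on {kind} #{i}"
            else:
                assert len(code) >= 6, f"oracle disagrees on {kind} #{i}"
            n_checked += 1
        assert n_checked == 100


class TestChirality:
    def test_right_and_left_trefoils(self):
        r = classify_knot(parametric_knot("trefoil_right", 200))
        l = classify_knot(parametric_knot("trefoil_left", 200))
        assert (r.label, r.chirality) == ("trefoil", "right")
        assert (l.label, l.chirality) == ("trefoil", "left")

    def test_mirror_flips_chirality_not_determinant(self):
        pts = parametric_knot("trefoil_right", 200)
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        a, b = classify_knot(pts), classify_knot(mirrored)
        assert a.determinant == b.determinant == 3
        assert {a.chirality, b.chirality} == {"right", "left"}

    def test_chirality_sign_anchored_to_writhe(self):
        # right-handed trefoil: positive writhe (Gauss double integral)
        pts = parametric_knot("trefoil_right", 300)
        closed = close_chain(pts)
        assert writhe(closed) > 2.0

    def test_extended_chain_is_unknot(self):
        ka = classify_knot(extended_chain(30))
        assert (ka.label, ka.chirality) == ("unknot", "n/a")

    def test_majority_vote_classification_consistent(self):
        pts = parametric_knot("trefoil_right", 200)
        assert classify_knot(pts, votes=5).label == "trefoil"


class TestLocateCore:
    def test_planted_core_with_straight_tails(self):
        body = parametric_knot("trefoil_left", 60)
        dN = body[0] - body[2]
        dN /= np.linalg.norm(dN)
        dC = body[-1] - body[-3]
        dC /= np.linalg.norm(dC)
        extN = body[0] + np.outer(np.arange(20, 0, -1) * 3.8, dN)
        extC = body[-1] + np.outer(np.arange(1, 21) * 3.8, dC)
        chain = np.vstack([extN, body, extC])       # knot occupies 21..80
        core = locate_core(chain)
        # the core must lie inside the knotted body; the exact boundary is
        # closure-sensitive (the radial arc can complete a partial knot)
        assert core.start >= 19
        assert core.end <= 82
        assert core.end - core.start >= 20

    def test_whole_chain_trefoil_core_is_majority_of_chain(self):
        pts = parametric_knot("trefoil_right", 80)
        core = locate_core(pts)
        # no tails: the core covers most of the chain, up to closure
        # sensitivity at the boundaries
        assert core.end - core.start + 1 >= 0.6 * 80

    def test_shallow_trefoil_tail_outside_core(self):
        tr, _ = toy_native(40, "shallow_trefoil")
        core = locate_core(tr.positions)
        assert core.end <= 36      # ~6-bead C-tail protrudes

    def test_unknotted_chain_rejected(self):
        with pytest.raises(ValueError, match="unknotted"):
            locate_core(extended_chain(30))

    def test_core_is_knotted_and_trims_are_not(self):
        tr, _ = toy_native(40, "shallow_trefoil")
        pts = tr.positions
        core = locate_core(pts)
        a, b = core.start - 1, core.end - 1
        assert chain_is_knotted(pts[a:b + 1])
        assert not chain_is_knotted(pts[a + 1:b + 1])
        assert not chain_is_knotted(pts[a:b])


class TestSlipknot:
    def test_straight_chain_has_none(self):
        assert detect_slipknot(extended_chain(40)) is None

    def test_fully_knotted_chain_has_none_by_definition(self):
        assert detect_slipknot(parametric_knot("trefoil_right", 100)) is None

    def test_scripted_slipknot_configuration_found(self):
        traj = scripted_mechanism_trajectory("slipknotting")
        ev = first_knotting_event(traj, persistence=5)
        pre = traj.frames[max(0, ev.frame - 10):ev.frame]
        found = any(detect_slipknot(fr) is not None for fr in pre)
        assert found
        # and the found interval is indeed knotted under closure
        for fr in pre:
            iv = detect_slipknot(fr)
            if iv is not None:
                assert chain_is_knotted(fr[iv[0] - 1:iv[1]])
                assert not chain_is_knotted(fr)
                break


class TestFirstKnottingEvent:
    def _traj_from_flags(self, flags):
        """Trajectory whose frames alternate unknotted/knotted chains
        following the given flag sequence."""
        unknot = extended_chain(40)
        knot = parametric_knot("trefoil_right", 40)
        frames = np.asarray([knot if f else unknot for f in flags])
        return Trajectory(frames=frames, stride=1, seed=0, temperature=1.0,
                          scalars={"knotted": np.asarray(flags, dtype=bool)})

    def test_never_knotted_gives_none(self):
        traj = self._traj_from_flags([False] * 30)
        assert first_knotting_event(traj, persistence=5) is None

    def test_knotted_from_frame_17(self):
        flags = [False] * 17 + [True] * 13
        traj = self._traj_from_flags(flags)
        ev = first_knotting_event(traj, persistence=5)
        assert ev.frame == 17

    def test_transient_knot_skipped(self):
        flags = [False] * 10 + [True] * 2 + [False] * 28 + [True] * 10
        traj = self._traj_from_flags(flags)
        ev = first_knotting_event(traj, persistence=5)
        assert ev.frame == 40


class TestMechanismClassifier:
    @pytest.mark.parametrize(
        "label", ["direct_threading", "slipknotting", "mousetrapping"])
    def test_scripted_mechanism_recovered(self, label):
        traj = scripted_mechanism_trajectory(label)
        ev = first_knotting_event(traj, persistence=10)
        assert ev is not None
        assert classify_mechanism(traj, ev, window=10) == label

    def test_mousetrap_loop_moves_more_than_terminus(self):
        traj = scripted_mechanism_trajectory("mousetrapping")
        ev = first_knotting_event(traj, persistence=10)
        pre = traj.frames[max(0, ev.frame - 10):ev.frame + 1]
        disp = np.linalg.norm(np.diff(pre, axis=0), axis=2)
        n = traj.n_beads
        core = ev.core_at_event
        term = np.arange(n - 10, n)
        loop = np.setdiff1d(np.arange(core.start - 1, core.end), term)
        assert disp[:, loop].mean() > 2.0 * max(disp[:, term].mean(), 1e-12)


class TestKnottingProbabilityCurve:
    def _traj(self, flags, stride=10):
        frames = np.zeros((len(flags), 4, 3))
        frames[:, :, 0] = np.arange(4) * 3.8
        return Trajectory(frames=frames, stride=stride, seed=0,
                          temperature=1.0,
                          scalars={"knotted": np.asarray(flags, dtype=bool)})

    def test_never_knotted_gives_zeros(self):
        ens = [self._traj([False] * 10) for _ in range(5)]
        frac, se = knotting_probability_curve(ens, [0, 30, 90])
        assert np.all(frac == 0.0) and np.all(se == 0.0)

    def test_half_knotted_gives_half_everywhere(self):
        ens = [self._traj([True] * 10) for _ in range(4)] + \
              [self._traj([False] * 10) for _ in range(4)]
        frac, se = knotting_probability_curve(ens, [0, 50])
        assert np.all(frac == 0.5)
        assert np.all(se == pytest.approx(np.sqrt(0.25 / 8)))

    def test_curve_equals_cdf_of_planted_knotting_times(self):
        rng = np.random.default_rng(6)
        times = rng.integers(1, 9, size=12)      # frame of first knotting
        ens = []
        for t in times:
            flags = [False] * t + [True] * (10 - t)
            ens.append(self._traj(flags, stride=10))
        grid = np.arange(0, 100, 10)
        frac, _ = knotting_probability_curve(ens, grid)
        cdf = [(times <= g // 10).mean() for g in grid]
        assert np.allclose(frac, cdf)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            knotting_probability_curve([], [0, 1])
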
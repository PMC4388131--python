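"""Visual place cells, NLMS prediction, fusion and the recalibration gate."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gridpi.place_cells import (
    GridPatternBank,
    LearningParams,
    PlaceCellBank,
    fuse_mpc,
    recalibration_trigger,
    wta_winner,
)

SIGMA = np.deg2rad(10.0)


def make_bank(n_grid=4):
    bank = PlaceCellBank(n_grid_inputs=n_grid)
    bank.recruit([(0, 0.2), (1, 1.3), (2, 4.0)], np.zeros(6))
    return bank


class TestVPC:
    def test_identical_observation_gives_unit_activity(self):
        bank = make_bank()
        act = bank.vpc_activity([(0, 0.2), (1, 1.3), (2, 4.0)], SIGMA)
        assert act[0] == pytest.approx(1.0)

    def test_distant_azimuths_give_near_zero(self):
        bank = make_bank()
        off = 10 * SIGMA
        act = bank.vpc_activity([(0, 0.2 + off), (1, 1.3 + off), (2, 4.0 + off)], SIGMA)
        assert act[0] < 1e-4

    def test_no_id_overlap_gives_zero(self):
        bank = make_bank()
        act = bank.vpc_activity([(7, 0.2), (8, 1.3)], SIGMA)
        assert act[0] == 0.0

    def test_mirror_identical_constellations_are_ambiguous(self):
        # two places whose landmark-azimuth constellations coincide (the
        # two-room aliasing) activate the same cell identically
        bank = make_bank()
        obs_room1 = [(0, 0.2), (1, 1.3), (2, 4.0)]
        obs_room2 = [(0, 0.2), (1, 1.3), (2, 4.0)]  # visually indistinguishable
        a1 = bank.vpc_activity(obs_room1, SIGMA)
        a2 = bank.vpc_activity(obs_room2, SIGMA)
        assert a1[0] == a2[0] == pytest.approx(1.0)

    def test_wrapped_azimuth_difference(self):
        bank = PlaceCellBank(n_grid_inputs=2)
        bank.recruit([(0, 0.01)], np.zeros(3))
        act = bank.vpc_activity([(0, 2 * np.pi - 0.01)], SIGMA)
        assert act[0] == pytest.approx(np.exp(-(0.02**2) / (2 * SIGMA**2)))


class TestRecruitment:
    def test_stores_constellation_profile_and_weights_row(self):
        bank = PlaceCellBank(n_grid_inputs=5)
        profile = np.linspace(0, 1, 7)
        idx = bank.recruit([(3, 0.5)], profile, action_direction=1.0)
        assert idx == 0
        np.testing.assert_array_equal(bank.profiles[0], profile)
        assert bank.weights.shape == (1, 5)
        assert bank.actions[0] == 1.0

    def test_no_deduplication(self):
        bank = PlaceCellBank(n_grid_inputs=2)
        for _ in range(2):
            bank.recruit([(0, 0.1)], np.zeros(4))
        assert bank.n_cells == 2
        assert bank.constellations[0] == bank.constellations[1]

    def test_nineteen_recruitments_give_bank_of_nineteen(self):
        bank = PlaceCellBank(n_grid_inputs=2)
        for k in range(19):
            bank.recruit([(0, 0.1 * k)], np.zeros(4))
        assert bank.n_cells == 19

    def test_json_round_trip(self, tmp_path):
        bank = make_bank()
        bank.weights[0] = [0.1, -0.2, 0.3, 0.4]
        path = str(tmp_path / "bank.json")
        bank.save(path)
        back = PlaceCellBank.load(path)
        assert back.constellations == bank.constellations
        np.testing.assert_allclose(back.weights, bank.weights)
        np.testing.assert_allclose(back.profiles[0], bank.profiles[0])


class TestWTA:
    @pytest.mark.parametrize(
        "acts,winner",
        [([0.2, 0.9, 0.1], 1), ([0.5, 0.5, 0.5], 0), ([0.3], 0)],
    )
    def test_winner_and_tie_rule(self, acts, winner):
        m, beta = wta_winner(np.array(acts))
        assert m == winner
        assert beta[m] == 1.0 and beta.sum() == 1.0


class TestNLMS:
    def test_zero_weights_predict_zero(self):
        bank = make_bank()
        assert np.all(bank.predict_vpc(np.zeros(4)) == 0.0)

    def test_gamma_zero_freezes_weights(self):
        bank = make_bank()
        w = bank.weights.copy()
        bank.nlms_update(np.array([1.0, 0, 0, 0]), np.array([1.0, 0, 0]),
                         LearningParams(lam=1.0, gamma=0))
        np.testing.assert_array_equal(bank.weights, w)

    def test_unit_rate_kills_error_in_one_step(self):
        # NLMS with lam = 1 zeroes the error on a repeated pair immediately
        bank = make_bank()
        g = np.array([0.5, 0.25, 0.0, 1.0])
        vpc = np.array([0.8, 0.1, 0.0])
        bank.nlms_update(g, vpc, LearningParams(lam=1.0))
        assert bank.predict_vpc(g)[0] == pytest.approx(0.8)

    def test_hand_computed_single_step(self):
        bank = PlaceCellBank(n_grid_inputs=2)
        bank.recruit([(0, 0.0)], np.zeros(2))
        g = np.array([1.0, 2.0])
        bank.nlms_update(g, np.array([1.0]), LearningParams(lam=0.5))
        # w += 0.5 * (1 - 0) * g / (1 + 4)
        np.testing.assert_allclose(bank.weights[0], [0.1, 0.2])

    def test_convergence_on_stationary_pair(self):
        bank = make_bank()
        g = np.array([0.2, 0.9, 0.1, 0.4])
        vpc = np.array([0.7, 0.0, 0.0])
        for _ in range(200):
            bank.nlms_update(g, vpc, LearningParams(lam=0.1))
        err = abs(bank.predict_vpc(g)[0] - 0.7)
        assert err < 1e-3

    def test_zero_energy_input_is_skipped(self):
        bank = make_bank()
        w = bank.weights.copy()
        bank.nlms_update(np.zeros(4), np.array([1.0, 0, 0]), LearningParams(lam=1.0))
        np.testing.assert_array_equal(bank.weights, w)

    @given(
        lam=st.floats(0.05, 1.0),
        g=st.lists(st.floats(-1, 1), min_size=4, max_size=4),
        target=st.floats(0, 1),
    )
    @settings(deadline=None, max_examples=60)
    def test_posterior_error_never_exceeds_prior(self, lam, g, target):
        # normalized-LMS contraction: |e_post| <= |e_prior| for lam in (0, 1]
        g = np.asarray(g)
        bank = PlaceCellBank(n_grid_inputs=4)
        bank.recruit([(0, 0.0)], np.zeros(2))
        bank.weights[0] = [0.3, -0.1, 0.2, 0.0]
        vpc = np.array([target])
        e_prior = abs(target - bank.predict_vpc(g)[0])
        bank.nlms_update(g, vpc, LearningParams(lam=lam))
        e_post = abs(target - bank.predict_vpc(g)[0])
        assert e_post <= e_prior + 1e-12


class TestFusion:
    def test_eta_extremes_and_midpoint(self):
        vpc = np.array([1.0, 0.2])
        pred = np.array([0.0, 0.6])
        np.testing.assert_array_equal(fuse_mpc(vpc, pred, 1.0), vpc)
        np.testing.assert_array_equal(fuse_mpc(vpc, pred, 0.0), pred)
        assert fuse_mpc(vpc, pred, 0.5)[0] == pytest.approx(0.5)

    def test_agreeing_inputs_are_fixed_points(self):
        a = np.array([0.3, 0.9])
        for eta in (0.0, 0.25, 0.8):
            np.testing.assert_allclose(fuse_mpc(a, a, eta), a)

    @given(
        vpc=st.lists(st.floats(0, 1), min_size=3, max_size=3),
        pred=st.lists(st.floats(-0.5, 1.5), min_size=3, max_size=3),
        eta=st.floats(0, 1),
    )
    @settings(deadline=None, max_examples=60)
    def test_fusion_bounded_by_inputs(self, vpc, pred, eta):
        vpc, pred = np.asarray(vpc), np.asarray(pred)
        mpc = fuse_mpc(vpc, pred, eta)
        lo = np.minimum(vpc, pred) - 1e-12
        hi = np.maximum(vpc, pred) + 1e-12
        assert np.all(mpc >= lo) and np.all(mpc <= hi)


class TestRecalibrationTrigger:
    def test_confident_winner_fires(self):
        params = LearningParams(thr_abs=0.7, thr_rel=0.2)
        fire, m = recalibration_trigger(np.array([0.3, 0.9]), params)
        assert fire and m == 1

    def test_ambiguous_place_blocks(self):
        params = LearningParams(thr_abs=0.7, thr_rel=0.2)
        fire, _ = recalibration_trigger(np.array([0.85, 0.9]), params)
        assert not fire

    def test_weak_winner_blocks(self):
        params = LearningParams(thr_abs=0.7, thr_rel=0.2)
        fire, _ = recalibration_trigger(np.array([0.5, 0.1]), params)
        assert not fire

    def test_single_cell_uses_absolute_only(self):
        params = LearningParams(thr_abs=0.7, thr_rel=0.2)
        assert recalibration_trigger(np.array([0.8]), params)[0]
        assert not recalibration_trigger(np.array([0.6]), params)[0]


class TestGridPatternBank:
    def test_self_match_wins_with_unit_activity(self):
        bank = GridPatternBank()
        pattern = np.zeros(12)
        pattern[[1, 5, 9]] = 1.0
        bank.recruit(pattern)
        bank.recruit(np.eye(12)[0])
        act = bank.recognize(pattern)
        assert act[0] == pytest.approx(1.0)
        assert np.argmax(act) == 0

    def test_overlap_levels_are_thirds_for_three_layers(self):
        bank = GridPatternBank()
        stored = np.zeros(12)
        stored[[0, 4, 8]] = 1.0
        bank.recruit(stored)
        two = np.zeros(12)
        two[[0, 4, 9]] = 1.0
        one = np.zeros(12)
        one[[0, 5, 9]] = 1.0
        assert bank.recognize(two)[0] == pytest.approx(2 / 3)
        assert bank.recognize(one)[0] == pytest.approx(1 / 3)

    def test_zero_input_scores_zero(self):
        bank = GridPatternBank()
        bank.recruit(np.ones(6))
        assert np.all(bank.recognize(np.zeros(6)) == 0.0)


class TestMultiroomContracts:
    def test_vision_is_ambiguous_between_rooms(self, multiroom_setup):
        # a room-1 cell fires substantially at its room-2 twin location
        from gridpi.multiroom import evaluation_pass

        tr = evaluation_pass(multiroom_setup)
        pos = tr.positions[:, 0]
        i_twin = np.argmin(np.abs(pos - 26.0))  # twin of the cell learned at x=4
        assert tr.vpc[i_twin, 2] > 0.5

    def test_mpc_disambiguates_the_aliased_cell(self, multiroom_setup):
        # at the non-learned twin location the fused winner is NOT the
        # room-1 cell: the grid prediction vetoes the visual alias
        from gridpi.multiroom import evaluation_pass

        tr = evaluation_pass(multiroom_setup)
        pos = tr.positions[:, 0]
        places = multiroom_setup.positions[multiroom_setup.place_idx, 0]
        room2 = pos > 22.5
        mpc_win = tr.winners("mpc")[room2]
        # the fused winner never jumps across rooms (errors stay local)
        assert np.abs(places[mpc_win] - pos[room2]).max() <= 1.6
        # and the specific aliased cell never wins there
        assert not np.any(mpc_win == 2)
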
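"""Actor: node dynamics, expectancy read-out, meta-plasticity, Hebbian rule."""

import numpy as np
import pytest
from scipy.special import expit

from atpsim.actor import (
    META_PSI,
    compute_expectancies,
    select_response,
    sigmoid,
    step_node,
    update_association_weights,
    update_meta_params,
)


class TestSigmoid:
    def test_midpoint(self):
        assert sigmoid(0.3, beta=5.0, th=0.3) == pytest.approx(0.5)

    def test_saturation(self):
        assert sigmoid(1e3, beta=2.0) == pytest.approx(1.0)
        assert sigmoid(-1e3, beta=2.0) == pytest.approx(0.0)

    def test_printed_example(self):
        assert sigmoid(1.0, beta=2.0, th=0.0) == pytest.approx(0.8808, abs=1e-4)


class TestNodeDynamics:
    def test_rest_is_fixed_point_without_self_excitation(self):
        u = step_node(-1.0, 0.0, tau_r=10.0, h_r=-1.0, C_r=0.0)
        assert u == pytest.approx(-1.0)

    def test_single_euler_step(self):
        # u0=0, h=-1, tau=10, no input/self-excitation -> u1 = -0.1
        u = step_node(0.0, 0.0, tau_r=10.0, h_r=-1.0, C_r=0.0, dt=1.0)
        assert u == pytest.approx(-0.1)

    def test_converges_to_rest_plus_input(self):
        u = -1.0
        for _ in range(400):
            u = step_node(u, 0.7, tau_r=5.0, h_r=-1.0, C_r=0.0)
        assert u == pytest.approx(-0.3, abs=1e-6)

    def test_matches_independent_recursion(self):
        """Backward-Euler trajectory equals an explicitly coded recursion."""
        rng = np.random.default_rng(3)
        inputs = rng.normal(0, 1, 200)
        tau_r, h_r, C_r, beta_r, dt = 5.0, -1.0, 1.2, 4.0, 1.0
        u_lib = u_ref = 0.4
        for x in inputs:
            u_lib = step_node(u_lib, x, tau_r, h_r, C_r, beta_r, dt)
            lam = 1.0 / (1.0 + np.exp(-beta_r * u_ref))
            u_ref = u_ref + (dt / tau_r) * (-u_ref + h_r + C_r * lam + x)
            assert abs(u_lib - u_ref) < 1e-12

    def test_invalid_time_constant(self):
        with pytest.raises(ValueError):
            step_node(0.0, 0.0, tau_r=0.0)


class TestExpectancies:
    META = np.array([10.0, 10.0, 0.2, 0.2])  # slope_vo, slope_vm, th_vo, th_vm

    def _reference(self, vm, vo, meta, beta_om=10.0, th_om=0.25):
        lam_vm = expit(meta[1] * (vm - meta[3]))
        lam_vo = expit(meta[0] * (vo - meta[2]))
        rew = max(0.0, lam_vm - lam_vo)
        om = expit(beta_om * (lam_vo - rew - th_om))
        return rew, om

    def test_matches_reference_composition(self):
        for vm, vo in [(0.0, 0.0), (0.9, 0.05), (0.1, 0.6), (0.5, 0.5)]:
            rew, om = compute_expectancies(vm, vo, self.META, 10.0, 0.25)
            ref_rew, ref_om = self._reference(vm, vo, self.META)
            assert rew == pytest.approx(ref_rew)
            assert om == pytest.approx(ref_om)

    def test_rectification_floor(self):
        rew, _ = compute_expectancies(0.0, 0.9, self.META, 10.0, 0.25)
        assert rew == 0.0

    def test_xor_corner(self):
        """High reward value, low omission value: Rew wins, Om suppressed."""
        rew, om = compute_expectancies(0.9, 0.0, self.META, 10.0, 0.25)
        assert rew > 0.85
        assert om < 0.05

    def test_tie_goes_to_omission(self):
        meta = np.array([5.0, 5.0, 0.3, 0.3])
        rew, om = compute_expectancies(0.5, 0.5, meta, 10.0, 0.25)
        assert rew == 0.0
        assert om > 0.5

    def test_mutual_inhibition_ablation(self):
        rew, om = compute_expectancies(
            0.9, 0.9, self.META, 10.0, 0.25, mutual_inhibition=False
        )
        # without competition both expectancies can be high at once
        assert rew > 0.9 and om > 0.9

    def test_outputs_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            vm, vo = rng.random(2)
            meta = np.array([rng.uniform(0.5, 20), rng.uniform(0.5, 20),
                             rng.random(), rng.random()])
            rew, om = compute_expectancies(vm, vo, meta, 10.0, 0.25)
            assert 0.0 <= rew <= 1.0 and 0.0 <= om <= 1.0


class TestMetaPlasticity:
    def test_zero_error_leaves_meta(self):
        meta = np.array([[4.0, 4.0, 0.5, 0.5]])
        before = meta.copy()
        update_meta_params(meta, 0.0, 1.0)
        assert np.allclose(meta, before)

    def test_congruent_sharpening_directions(self):
        meta = np.array([[4.0, 4.0, 0.5, 0.5]])
        update_meta_params(meta, 0.5, 1.0, C_j=10.0)  # omission surprise
        assert meta[0, 0] > 4.0 and meta[0, 2] < 0.5  # omission side sharpens
        assert meta[0, 1] == 4.0 and meta[0, 3] == 0.5  # reward side untouched
        update_meta_params(meta, -0.5, 1.0, C_j=10.0)  # reward surprise
        assert meta[0, 1] > 4.0 and meta[0, 3] < 0.5

    def test_signed_mode_step_and_psi(self):
        meta = np.array([[1.0, 1.0, 0.5, 0.5]])
        update_meta_params(meta, 0.5, 1.0, C_j=10.0, mode="signed")
        step = 0.5 / 10.0
        assert np.allclose(meta[0], [1.0, 1.0, 0.5, 0.5] + META_PSI * step)

    def test_clamped_at_bounds(self):
        meta = np.array([[20.0, 20.0, 0.0, 0.0]])
        update_meta_params(meta, 5.0, 1.0)
        assert meta[0, 0] == 20.0 and meta[0, 2] == 0.0

    def test_zero_input_skipped(self):
        meta = np.array([[4.0, 4.0, 0.5, 0.5]])
        before = meta.copy()
        update_meta_params(meta, 0.7, 0.0)
        assert np.allclose(meta, before)


class TestAssociationLearning:
    def _omega(self):
        return np.zeros((1, 4, 2))

    def test_silent_nodes_learn_nothing(self):
        omega = self._omega()
        update_association_weights(
            omega, np.zeros((1, 4)), np.ones((1, 2)), 0.0, -1.0
        )
        assert np.all(omega == 0.0)

    def test_reward_surprise_strengthens_executed_route(self):
        omega = self._omega()
        pre = np.array([[1.0, 0.0, 0.0, 0.0]])
        post = np.array([[1.0, 0.0]])
        update_association_weights(omega, pre, post, 0.0, -1.0, beta_sr=0.06)
        assert omega[0, 0, 0] == pytest.approx(0.06)

    def test_omission_unlearns_with_floor(self):
        omega = self._omega()
        omega[0, 0, 0] = 0.04
        pre = np.array([[1.0, 0.0, 0.0, 0.0]])
        post = np.array([[1.0, 0.0]])
        update_association_weights(omega, pre, post, 0.0, 1.0, beta_sr=0.06)
        assert omega[0, 0, 0] == 0.0  # floored, not negative

    def test_expectancy_rows_unlearn_slowly(self):
        omega = self._omega()
        omega[0, 2, 0] = omega[0, 0, 0] = 0.5
        pre = np.array([[1.0, 0.0, 1.0, 0.0]])
        post = np.array([[1.0, 0.0]])
        update_association_weights(
            omega, pre, post, 0.0, 1.0, beta_sr=0.06, beta_er=0.06,
            er_unlearn_factor=0.5,
        )
        assert omega[0, 0, 0] == pytest.approx(0.44)   # full depression
        assert omega[0, 2, 0] == pytest.approx(0.47)   # halved depression

    def test_lesions_freeze_rows(self):
        pre = np.ones((1, 4))
        post = np.ones((1, 2))
        omega = self._omega()
        update_association_weights(omega, pre, post, 0.0, -1.0, lesion_s_r=True)
        assert np.all(omega[0, 0:2] == 0.0) and np.all(omega[0, 2:4] > 0.0)
        omega = self._omega()
        update_association_weights(omega, pre, post, 0.0, -1.0, lesion_e_r=True)
        assert np.all(omega[0, 2:4] == 0.0) and np.all(omega[0, 0:2] > 0.0)

    def test_magnitude_gating_mode(self):
        omega = self._omega()
        pre = np.ones((1, 4))
        post = np.ones((1, 2))
        update_association_weights(
            omega, pre, post, delta_m=1.0, delta_o=-1.0, gate_mode="magnitude",
            beta_sr=0.1, beta_er=0.1, weight_floor=None,
        )
        assert np.all(omega[0, 0:2] == pytest.approx(0.1))   # delta_m rows
        assert np.all(omega[0, 2] == pytest.approx(-0.1))    # Om row, delta_o


class TestResponseSelection:
    def test_argmax_above_threshold(self):
        out = np.array([[0.9, 0.2], [0.1, 0.8]])
        choice = select_response(out, "two_lever", np.zeros(2), np.zeros(2), 0.5)
        assert choice.tolist() == [0, 1]

    def test_two_lever_guess_is_uniform(self):
        rng = np.random.default_rng(11)
        draws = rng.random(4000)
        out = np.full((4000, 2), 0.1)
        choice = select_response(out, "two_lever", draws, rng.random(4000), 0.5)
        assert abs(choice.mean() - 0.5) < 0.03

    def test_single_rule_guess_hits_rule_quarter_of_time(self):
        rng = np.random.default_rng(12)
        draws = rng.random(4000)
        out = np.full((4000, 2), 0.1)
        choice = select_response(out, "single_rule", draws, rng.random(4000), 0.5)
        assert abs((choice == 0).mean() - 0.25) < 0.03

    def test_exact_tie_broken_by_rng(self):
        out = np.full((4000, 2), 0.9)
        rng = np.random.default_rng(13)
        choice = select_response(out, "two_lever", rng.random(4000),
                                 rng.random(4000), 0.5)
        assert 0.45 < choice.mean() < 0.55

    def test_unknown_protocol_kind(self):
        with pytest.raises(ValueError):
            select_response(np.ones((1, 2)), "maze", np.zeros(1), np.zeros(1))
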
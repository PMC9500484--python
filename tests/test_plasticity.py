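"""Gated plasticity rules, learning episodes and lesion switches."""

import numpy as np
import pytest

from ca1sim.dynamics import NetworkState
from ca1sim.geometry import WeightState
from ca1sim.model import CA1Model
from ca1sim.params import LesionConfig, ModelParams, PlasticityParams
from ca1sim.plasticity import (
    LearningTrace,
    gate_ELL,
    gate_LT,
    gate_SA,
    update_excitatory,
    update_inhibitory,
)
from ca1sim.stimuli import gen_digit_like


class TestGates:
    def test_learning_threshold_strict(self):
        assert not gate_LT(0.0, 0.1)
        assert not gate_LT(0.1, 0.1)  # boundary: strict >
        assert gate_LT(0.2, 0.1)

    def test_stable_activation_blocked_by_flux(self):
        p = PlasticityParams()
        a = np.array([0.9])
        ema = np.array([0.1])  # strongly rising
        assert gate_SA(a, ema, np.array([0.02]), steps=1000, params=p, tau=10.0) == [False]
        assert gate_SA(a, ema, np.array([0.0]), steps=1000, params=p, tau=10.0) == [True]

    def test_stable_activation_needs_rising_deviation(self):
        p = PlasticityParams()
        a = np.array([0.5])
        assert gate_SA(a, a.copy(), np.zeros(1), 1000, p, 10.0) == [False]  # flat
        falling = np.array([0.6])
        assert gate_SA(a, falling, np.zeros(1), 1000, p, 10.0) == [False]  # declining

    def test_stable_activation_needs_history(self):
        p = PlasticityParams(delta1=5.0)
        a, ema = np.array([0.9]), np.array([0.1])
        assert gate_SA(a, ema, np.zeros(1), steps=10, params=p, tau=10.0) == [False]

    def test_absolute_deviation_variant(self):
        p = PlasticityParams(sa_absolute=True)
        a, ema = np.array([0.1]), np.array([0.6])  # declining
        assert gate_SA(a, ema, np.zeros(1), 1000, p, 10.0) == [True]

    def test_excitatory_learning_level(self):
        a = np.array([0.5, 0.5])
        assert not gate_ELL(a.copy(), a)  # converged neuron: mean dev 0
        w = np.array([0.0, 0.0])
        assert gate_ELL(w, a)  # mean dev 0.5
        assert not gate_ELL(a - 0.0039, a)  # just below the 0.004 floor


class TestExcitatoryUpdate:
    def test_dopamine_gates_everything(self):
        w = np.full((2, 3), 0.2)
        d = update_excitatory(w, np.ones(3), np.ones(2), da=0,
                              gates=np.array([True, True]), lr_exc=0.1)
        assert np.all(d == 0)

    def test_fixed_point_at_w_equals_input(self):
        a_inp = np.array([0.3, 0.6, 0.1])
        w = np.tile(a_inp, (2, 1))
        d = update_excitatory(w, a_inp, np.ones(2), 1, np.array([True, True]), 0.1)
        assert np.allclose(d, 0)

    def test_monotone_convergence_to_presynaptic_pattern(self):
        """Repeated gated updates drive w toward a_pre monotonically, an
        Oja-like contraction (scalar recurrence w += lr*a_post*(a_pre-w))."""
        w = np.zeros((1, 1))
        gaps = []
        for _ in range(200):
            d = update_excitatory(w, np.array([1.0]), np.array([0.8]), 1,
                                  np.array([True]), 0.05)
            assert d[0, 0] >= 0
            w += d
            gaps.append(1.0 - w[0, 0])
        assert all(g2 <= g1 for g1, g2 in zip(gaps, gaps[1:]))
        assert w[0, 0] == pytest.approx(1.0, abs=1e-3)

    def test_bounded_under_long_random_stimulation(self, rng):
        """Weights never leave [0, max(a_pre)] under 10^4 gated updates on
        random stimuli (no renormalization needed)."""
        w = rng.random((4, 8)) * 0.1
        for _ in range(10_000):
            a_inp = rng.random(8)
            a_p = rng.random(4)
            gates = rng.random(4) < 0.5
            w += update_excitatory(w, a_inp, a_p, 1, gates, 0.05)
            assert (w >= 0).all() and (w <= 1.0 + 1e-12).all()


class TestInhibitoryUpdate:
    def test_dopamine_and_gate(self):
        w = np.full((2, 3), -0.5)
        d = update_inhibitory(w, np.ones(3) * 0.3, np.ones(2), 0,
                              np.array([True, True]), L=1.0, tau=10.0)
        assert np.all(d == 0)
        d = update_inhibitory(w, np.ones(3) * 0.3, np.ones(2), 1,
                              np.array([False, False]), L=1.0, tau=10.0)
        assert np.all(d == 0)

    def test_homeostatic_equilibrium(self):
        a_i = np.array([0.3])
        w = np.array([[-1.0]])  # = -a_i/0.3
        d = update_inhibitory(w, a_i, np.ones(1), 1, np.array([True]), 1.0, 10.0)
        assert np.allclose(d, 0)

    def test_sign_strengthens_inhibition_above_equilibrium(self):
        a_i = np.array([0.3])
        w = np.array([[-0.5]])  # above equilibrium -1.0
        d = update_inhibitory(w, a_i, np.ones(1), 1, np.array([True]), 1.0, 10.0)
        assert d[0, 0] < 0

    def test_monotone_approach_without_overshoot(self):
        """With constant interneuron activity the weight approaches
        -a_i/0.3 from above and never crosses below it."""
        a_i = np.array([0.3])
        w = np.array([[0.0]])
        eq = -0.3 / 0.3
        for _ in range(2000):
            w += update_inhibitory(w, a_i, np.ones(1), 1, np.array([True]), 1.0, 10.0)
            assert w[0, 0] >= eq - 1e-9
        assert w[0, 0] == pytest.approx(eq, abs=1e-3)


class TestLearningTrace:
    def test_label_iff_update_mass(self):
        tr = LearningTrace(5)
        tr.record_update(np.array([1, 3]), np.array([0.2, 0.4]), task_id=7)
        labeled = tr.labels >= 0
        assert np.array_equal(labeled, tr.update_mass > 0)

    def test_last_write_wins_and_dominant(self):
        tr = LearningTrace(3)
        tr.record_update(np.array([0]), np.array([1.0]), task_id=1)
        tr.record_update(np.array([0]), np.array([0.1]), task_id=2)
        assert tr.labels[0] == 2  # last write wins
        assert tr.dominant_labels()[0] == 1  # mass-dominant label retained


@pytest.fixture(scope="module")
def stim():
    return gen_digit_like(seed=4, classes=2, per_class=1, size=20)


class TestLearnImage:
    def _model(self):
        from ca1sim.params import scaled_params

        return CA1Model(scaled_params(side=20, i_side=7), seed=2)

    def test_winner_weights_converge_to_stimulus(self, stim):
        """Sustained training on one fixed stimulus drives the winner's
        input weights toward the stimulus vector (cosine similarity > 0.99).
        Dopamine modulation is disabled so learning runs to convergence
        instead of stopping at the familiarity threshold."""
        m = self._model()
        s = stim.tasks[0][0].values
        for _ in range(6):
            m.learn(s, task_id=0, lesions=LesionConfig(no_da_modulation=True))
        winner = m.settle(s).peak_neuron
        w = m.weights.w_inp[winner]
        cos = w @ s / (np.linalg.norm(w) * np.linalg.norm(s))
        assert cos > 0.99

    def test_familiarity_stops_learning(self, stim):
        """After a successful episode, immediate re-presentation yields
        dopamine = 0 and no further weight updates."""
        m = self._model()
        s = stim.tasks[0][0].values
        first = m.learn(s, task_id=0)
        assert first.n_updated > 0
        checksum = m.weights.checksum()
        again = m.learn(s, task_id=0)
        assert again.da_at_presentation == 0
        assert again.n_updated == 0
        assert m.weights.checksum() == checksum

    def test_no_learning_lesion_freezes_weights(self, stim):
        m = self._model()
        s = stim.tasks[0][0].values
        checksum = m.weights.checksum()
        r = m.learn(s, task_id=0, lesions=LesionConfig(no_learning=True))
        assert r.n_updated == 0 and r.steps == 0
        assert m.weights.checksum() == checksum
        assert not r.is_learning_episode

    def test_no_da_lesion_runs_full_budget(self, stim):
        m = self._model()
        m.params = ModelParams(
            geometry=m.params.geometry,
            kernel=m.params.kernel,
            dynamics=m.params.dynamics,
            plasticity=PlasticityParams(t_max_episode=40),
        )
        s = stim.tasks[0][0].values
        r = m.learn(s, task_id=0, lesions=LesionConfig(no_da_modulation=True))
        assert r.steps == 40
        assert not r.learned

    def test_no_inhibitory_plasticity_lesion(self, stim):
        m = self._model()
        s = stim.tasks[0][0].values
        w_ip_before = m.weights.w_ip.copy()
        m.learn(s, task_id=0, lesions=LesionConfig(no_inhibitory_plasticity=True))
        assert np.array_equal(m.weights.w_ip, w_ip_before)
        m2 = self._model()
        m2.learn(s, task_id=0)
        assert not np.array_equal(m2.weights.w_ip, w_ip_before)

    def test_inhibitory_weights_stay_nonpositive(self, stim):
        m = self._model()
        for task in stim.tasks:
            for s in task:
                m.learn(s.values, task_id=s.task_id)
        assert (m.weights.w_ip <= 0).all()

    def test_episode_bounded_and_labels_follow_updates(self, stim):
        m = self._model()
        s = stim.tasks[1][0].values
        r = m.learn(s, task_id=1)
        assert r.steps <= m.params.plasticity.t_max_episode
        assert np.array_equal(np.flatnonzero(m.trace.labels == 1), r.updated_neurons)

    def test_contradictory_lesion_combination_rejected(self):
        with pytest.raises(ValueError):
            LesionConfig(no_learning=True, no_da_modulation=True)
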
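"""The Markov-basin local model: sampling, density, window proposals."""

import itertools
import math

import numpy as np
import pytest

import refratio as rr
from refratio.local_model import (residue_class, wrapped_normal_logpdf)
from tests.conftest import make_two_state_params


class TestParams:
    def test_default_fixture_is_valid(self, default_params):
        assert default_params.n_states == 5
        labels = {s.label for s in default_params.states}
        assert labels <= {"H", "E", "C"}
        for t in default_params.transition.values():
            np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_rows_rejected(self):
        states = [rr.BasinState(0, "H", -63, -43, 7.0)]
        with pytest.raises(ValueError):
            rr.LocalModelParams(states=states, initial=np.array([0.9]),
                                transition={"generic": np.array([[1.0]])})

    def test_residue_classes(self):
        seq = rr.Sequence("AGPAP")
        classes = [residue_class(seq, i) for i in range(5)]
        assert classes == ["generic", "glycine", "proline", "preproline",
                          "proline"]


class TestSamplePath:
    def test_degenerate_spread_concentrates_on_means(self):
        params = make_two_state_params(p_stay=1.0, spread=1e-9)
        seq = rr.Sequence("A" * 10)
        path = rr.sample_path(params, seq, np.random.default_rng(0))
        means_phi = np.array([params.states[s].mean_phi for s in path.states])
        means_psi = np.array([params.states[s].mean_psi for s in path.states])
        assert np.nanmax(np.abs(path.phi[1:] - means_phi[1:])) < 1e-6
        assert np.nanmax(np.abs(path.psi[:-1] - means_psi[:-1])) < 1e-6
        assert np.isnan(path.phi[0]) and np.isnan(path.psi[-1])

    def test_state_frequencies_match_stationary_distribution(self):
        """Empirical frequencies on a long chain agree with the stationary
        distribution solved from the transition matrix."""
        params = make_two_state_params(p_stay=0.7)
        L = 100_000
        seq = rr.Sequence("A" * L)
        path = rr.sample_path(params, seq, np.random.default_rng(7))
        t = params.transition["generic"]
        evals, evecs = np.linalg.eig(t.T)
        stat = np.real(evecs[:, np.argmax(np.real(evals))])
        stat /= stat.sum()
        freq = np.bincount(path.states, minlength=2) / L
        # 3 standard errors, correlation-corrected for persistence p_stay
        se = math.sqrt(stat[0] * stat[1] / L) * math.sqrt((1 + 0.4) / (1 - 0.4))
        assert abs(freq[0] - stat[0]) < 3 * se

    def test_fixed_seed_reproducible(self, default_params, ubiquitin):
        p1 = rr.sample_path(default_params, ubiquitin, np.random.default_rng(5))
        p2 = rr.sample_path(default_params, ubiquitin, np.random.default_rng(5))
        np.testing.assert_array_equal(p1.states, p2.states)
        np.testing.assert_array_equal(p1.phi, p2.phi)


class TestLogDensity:
    def test_single_state_model_reduces_to_emissions(self):
        params = make_two_state_params(p_stay=1.0)
        # force state 0 everywhere: initial (0.5, 0.5) but path fixed
        seq = rr.Sequence("AAAA")
        phi = np.array([np.nan, -60.0, -65.0, -70.0])
        psi = np.array([-40.0, -45.0, -50.0, np.nan])
        path = rr.DihedralPath(phi, psi, np.zeros(4, dtype=int))
        total = rr.log_density(params, path, seq)
        emis = (wrapped_normal_logpdf(phi[1:], -63.0, 10.0).sum()
                + wrapped_normal_logpdf(psi[:-1], -43.0, 10.0).sum())
        # state part: log(1/2) initial, transitions log 1 = 0
        assert total == pytest.approx(emis + math.log(0.5), abs=1e-10)

    def test_uniform_transition_state_part(self):
        params = make_two_state_params(p_stay=0.5)
        seq = rr.Sequence("AAA")
        path = rr.DihedralPath(np.array([np.nan, -63.0, -63.0]),
                               np.array([-43.0, -43.0, np.nan]),
                               np.array([0, 1, 0]))
        total = rr.log_density(params, path, seq)
        emis = (wrapped_normal_logpdf(path.phi[1], -120.0, 10.0)
                + wrapped_normal_logpdf(path.phi[2], -63.0, 10.0)
                + wrapped_normal_logpdf(path.psi[0], -43.0, 10.0)
                + wrapped_normal_logpdf(path.psi[1], 130.0, 10.0))
        assert total == pytest.approx(emis + 3 * math.log(0.5), abs=1e-10)

    def test_zero_probability_transition_gives_minus_inf(self):
        params = make_two_state_params(p_stay=1.0)
        seq = rr.Sequence("AAA")
        path = rr.DihedralPath(np.array([np.nan, -63.0, -63.0]),
                               np.array([-43.0, -43.0, np.nan]),
                               np.array([0, 1, 0]))
        assert rr.log_density(params, path, seq) == -math.inf

    def test_relabeling_invariance(self, rng):
        params = make_two_state_params(p_stay=0.7)
        swapped = rr.LocalModelParams(
            states=[rr.BasinState(0, "E", -120.0, 130.0, 10.0),
                    rr.BasinState(1, "H", -63.0, -43.0, 10.0)],
            initial=np.array([0.5, 0.5]),
            transition={"generic": np.array([[0.7, 0.3], [0.3, 0.7]])})
        seq = rr.Sequence("A" * 12)
        path = rr.sample_path(params, seq, rng)
        flipped = rr.DihedralPath(path.phi, path.psi, 1 - path.states)
        assert rr.log_density(params, path, seq) == pytest.approx(
            rr.log_density(swapped, flipped, seq), abs=1e-10)

    def test_state_chain_normalizes_by_enumeration(self):
        """Sum over all state paths of the chain part equals 1 (L = 3)."""
        params = rr.LocalModelParams.default()
        seq = rr.Sequence("AKL")
        bound = params.bind(seq)
        total = 0.0
        for s in itertools.product(range(5), repeat=3):
            total += (params.initial[s[0]] * bound.tsteps[0, s[0], s[1]]
                      * bound.tsteps[1, s[1], s[2]])
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_emission_density_normalizes_by_quadrature(self):
        from scipy.integrate import quad
        val, _ = quad(lambda x: math.exp(wrapped_normal_logpdf(x, 57.0, 25.0)),
                      -180, 180, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)


class TestProposeWindow:
    def test_locality_outside_window(self, default_params, ubiquitin, rng):
        path = rr.sample_path(default_params, ubiquitin, rng)
        new = rr.propose_window(default_params, path, (10, 10), ubiquitin, rng)
        np.testing.assert_array_equal(new.states[:9], path.states[:9])
        np.testing.assert_array_equal(new.states[10:], path.states[10:])
        np.testing.assert_array_equal(new.phi[10:], path.phi[10:])

    def test_full_window_ignores_current_path(self, default_params, ubiquitin,
                                              rng):
        p1 = rr.sample_path(default_params, ubiquitin, rng)
        p2 = rr.sample_path(default_params, ubiquitin, rng)
        L = len(ubiquitin)
        n1 = rr.propose_window(default_params, p1, (1, L), ubiquitin,
                               np.random.default_rng(3))
        n2 = rr.propose_window(default_params, p2, (1, L), ubiquitin,
                               np.random.default_rng(3))
        np.testing.assert_array_equal(n1.states, n2.states)
        np.testing.assert_array_equal(n1.phi, n2.phi)

    def test_out_of_range_window_raises(self, default_params, ubiquitin, rng):
        path = rr.sample_path(default_params, ubiquitin, rng)
        for window in [(0, 3), (5, 4), (1, 99)]:
            with pytest.raises(ValueError):
                rr.propose_window(default_params, path, window, ubiquitin, rng)

    def test_detailed_balance_on_enumerable_chain(self):
        """Empirical proposal kernel satisfies detailed balance with respect
        to the exact chain distribution on a 4-residue, 2-state model."""
        params = make_two_state_params(p_stay=0.7)
        seq = rr.Sequence("AAAA")
        bound = params.bind(seq)

        def q_prob(s):
            p = params.initial[s[0]]
            for i in range(1, 4):
                p *= bound.tsteps[i - 1, s[i - 1], s[i]]
            return p

        states_list = list(itertools.product(range(2), repeat=4))
        index = {s: i for i, s in enumerate(states_list)}
        counts = np.zeros((16, 16))
        rng = np.random.default_rng(11)
        n_prop = 100_000
        start = np.array([0, 1, 0, 1])
        path = rr.DihedralPath(
            np.array([np.nan, -63.0, -63.0, -63.0]),
            np.array([-43.0, -43.0, -43.0, np.nan]), start)
        for _ in range(n_prop):
            a = int(rng.integers(1, 5))
            b = int(rng.integers(a, 5))
            cur = rng.choice(len(states_list), p=None)
            src = states_list[int(cur)]
            path = rr.DihedralPath(path.phi, path.psi, np.array(src))
            new = rr.propose_window(params, path, (a, b), seq, rng)
            counts[index[src], index[tuple(new.states)]] += 1
        kern = counts / counts.sum(axis=1, keepdims=True)
        q = np.array([q_prob(s) for s in states_list])
        flow = q[:, None] * kern
        imbalance = np.abs(flow - flow.T) / (flow + flow.T + 1e-12)
        # relative detailed-balance violation within Monte Carlo noise
        assert np.median(imbalance[flow + flow.T > 1e-4]) < 0.1

    def test_invariance_of_state_marginals(self, default_params, protein_g):
        """Applying the proposal to exact q samples preserves marginals."""
        rng = np.random.default_rng(23)
        L = len(protein_g)
        before = np.zeros((L, 5))
        after = np.zeros((L, 5))
        for _ in range(2000):
            path = rr.sample_path(default_params, protein_g, rng)
            before[np.arange(L), path.states] += 1
            a = int(rng.integers(1, L + 1))
            b = min(int(a + rng.integers(0, 10)), L)
            new = rr.propose_window(default_params, path, (a, b), protein_g,
                                    rng)
            after[np.arange(L), new.states] += 1
        before /= before.sum(axis=1, keepdims=True)
        after /= after.sum(axis=1, keepdims=True)
        assert np.abs(before - after).max() < 0.06


class TestSsLabels:
    def test_labels_follow_states_not_angles(self, default_params, ubiquitin,
                                             rng):
        path = rr.sample_path(default_params, ubiquitin, rng)
        labels = rr.ss_labels(default_params, path)
        assert len(labels) == len(ubiquitin)
        shifted = rr.DihedralPath(np.roll(path.phi, 1), np.roll(path.psi, 1),
                                  path.states)
        shifted.phi[0] = np.nan
        shifted.psi[-1] = np.nan
        assert rr.ss_labels(default_params, shifted) == labels

    def test_unknown_state_raises(self, default_params):
        path = rr.DihedralPath(np.array([np.nan, -63.0]),
                               np.array([-43.0, np.nan]), np.array([0, 9]))
        with pytest.raises(ValueError):
            rr.ss_labels(default_params, path)
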
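"""Harmonic-superposition thermodynamics."""

import numpy as np
import pytest
from scipy.integrate import quad

from conftest import Quadratic1D, make_random_network
from ktntools import localopt, thermo
from ktntools.ktn import KTN
from ktntools.localopt import Minimum
from ktntools.tssearch import TransitionState


def _minimum(energy, log_prod, dim=3, n_zero=0, rng=None):
    rng = rng or np.random.default_rng(0)
    return Minimum(energy=float(energy), coordinates=rng.normal(size=dim),
                   log_product_freq=float(log_prod), n_zero_modes=n_zero)


class TestLnZ:
    def test_equal_records_equal_lnz(self):
        rng = np.random.default_rng(1)
        a = _minimum(-3.0, 0.7, rng=rng)
        b = _minimum(-3.0, 0.7, rng=rng)
        assert thermo.ln_z_harmonic(a, 310.0) == \
            thermo.ln_z_harmonic(b, 310.0)

    def test_boltzmann_shift(self):
        """Raising E by exactly kT lowers ln Z by exactly 1."""
        kB, T = 1.0, 2.5
        a = _minimum(-3.0, 0.7)
        b = _minimum(-3.0 + kB * T, 0.7)
        assert thermo.ln_z_harmonic(a, T, kB) - \
            thermo.ln_z_harmonic(b, T, kB) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k_spring,temperature", [(1.0, 1.0),
                                                      (2.0, 0.7),
                                                      (0.5, 3.0)])
    def test_matches_configuration_integral(self, k_spring, temperature):
        """For a 1-D quadratic well (unit mass) the harmonic partition
        function equals the quadrature of exp(-E/kT)."""
        model = Quadratic1D(k_spring)
        m = localopt.minimize(model, np.array([0.3]))
        lnz = thermo.ln_z_harmonic(m, temperature, kB=1.0)
        z_quad, _ = quad(lambda x: np.exp(-model.energy([x]) / temperature),
                         -np.inf, np.inf)
        assert np.exp(lnz) / z_quad == pytest.approx(1.0, abs=1e-6)


class TestOccupationProbabilities:
    def _net(self, minima):
        net = KTN()
        for i, m in enumerate(minima):
            m.id = i
            net.minima[i] = m
        net._next_min_id = len(minima)
        return net

    def test_single_minimum(self):
        net = self._net([_minimum(-1.0, 0.0)])
        assert thermo.occupation_probabilities(net, 310.0) == {0: 1.0}

    def test_two_identical_minima_split_evenly(self):
        rng = np.random.default_rng(2)
        net = self._net([_minimum(-1.0, 0.3, rng=rng),
                         _minimum(-1.0, 0.3, rng=rng)])
        p = thermo.occupation_probabilities(net, 310.0)
        assert p[0] == pytest.approx(0.5, abs=1e-12)
        assert p[1] == pytest.approx(0.5, abs=1e-12)

    def test_two_well_closed_form_ratio(self):
        """p1/p2 = exp(-beta dE) * exp(dlog_prod) for same-dimension wells."""
        kB, T = 1.0, 1.7
        dE, dL = 1.3, 0.4
        net = self._net([_minimum(-5.0, 1.0, dim=4),
                         _minimum(-5.0 + dE, 1.0 - dL, dim=4)])
        p = thermo.occupation_probabilities(net, T, kB)
        # ln Z = -E/kT - L + const: the higher well (energy +dE, log
        # frequency product lower by dL) is disfavoured by the Boltzmann
        # factor and favoured by its softer modes
        expect = np.exp(-dE / (kB * T)) * np.exp(dL)
        assert p[1] / p[0] == pytest.approx(expect, rel=1e-10)

    def test_probabilities_sum_to_one_on_random_networks(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            net = make_random_network(rng)
            p = thermo.occupation_probabilities(net, 310.0)
            assert sum(p.values()) == pytest.approx(1.0, abs=1e-12)

    def test_no_overflow_for_huge_energy_ranges(self):
        net = self._net([_minimum(-600.0, 0.0), _minimum(0.0, 0.0)])
        p = thermo.occupation_probabilities(net, 1.0, kB=1.0)
        assert p[0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_temperature_limit(self):
        """At beta * dE >= 50 the global minimum holds all probability."""
        net = self._net([_minimum(-60.0, 0.0), _minimum(-10.0, 0.0)])
        p = thermo.occupation_probabilities(net, 1.0, kB=1.0)
        assert p[0] == pytest.approx(1.0, abs=1e-12)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            thermo.occupation_probabilities(KTN(), 310.0)


class TestTSTRate:
    def _simple_net(self, e_min, e_ts, l_min=0.0, l_ts=0.0):
        net = KTN()
        rng = np.random.default_rng(3)
        for i, e in enumerate(e_min):
            net.minima[i] = _minimum(e, l_min, rng=rng)
            net.minima[i].id = i
        ts = TransitionState(energy=e_ts, coordinates=rng.normal(size=3),
                             negative_eigenvalue=-1.0, log_product_freq=l_ts,
                             minus_min_id=0, plus_min_id=len(e_min) - 1, id=0)
        net.transition_states[0] = ts
        return net

    def test_zero_barrier_rate_is_inverse_two_pi(self):
        net = self._simple_net([-1.0, -2.0], e_ts=-1.0)
        k = thermo.tst_rate(net, 0, 0, temperature=1.0, kB=1.0)
        assert k == pytest.approx(1.0 / (2 * np.pi), rel=1e-12)

    def test_arrhenius_factor(self):
        kB, T = 1.0, 2.0
        n1 = self._simple_net([-1.0, -9.0], e_ts=0.0)
        n2 = self._simple_net([-1.0, -9.0], e_ts=0.0 + kB * T)
        k1 = thermo.tst_rate(n1, 0, 0, T, kB)
        k2 = thermo.tst_rate(n2, 0, 0, T, kB)
        assert k2 / k1 == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_detailed_balance_on_random_networks(self):
        """p_i k_ij == p_j k_ji on 100 random instances."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            net = make_random_network(rng)
            p = thermo.occupation_probabilities(net, 200.0)
            for tid, ts in net.transition_states.items():
                i, j = ts.minus_min_id, ts.plus_min_id
                if i == j:
                    continue
                kij = thermo.tst_rate(net, tid, i, 200.0)
                kji = thermo.tst_rate(net, tid, j, 200.0)
                assert p[i] * kij == pytest.approx(p[j] * kji,
                                                   rel=1e-10, abs=1e-12)

    def test_non_adjacent_rate_rejected(self):
        net = self._simple_net([-1.0, -2.0, -3.0], e_ts=0.0)
        with pytest.raises(ValueError):
            thermo.tst_rate(net, 0, 1, temperature=1.0, kB=1.0)


class TestRegrouping:
    def _barrier_chain(self, energies, barriers):
        """Linear chain with specified minimum energies and ts energies."""
        net = KTN()
        rng = np.random.default_rng(5)
        for i, e in enumerate(energies):
            net.minima[i] = _minimum(e, 0.0, rng=rng)
            net.minima[i].id = i
        for i, b in enumerate(barriers):
            ts = TransitionState(energy=b, coordinates=rng.normal(size=3),
                                 negative_eigenvalue=-1.0,
                                 log_product_freq=0.0,
                                 minus_min_id=i, plus_min_id=i + 1, id=i)
            net.transition_states[i] = ts
        return net

    def test_zero_threshold_keeps_singletons(self):
        net = self._barrier_chain([0.0, 0.0, 0.0], [1.0, 1.0])
        grouped = thermo.regroup_free_energy(net, 0.01, 0.0, kB=1.0)
        assert len(grouped.groups) == 3

    def test_huge_threshold_merges_everything(self):
        net = self._barrier_chain([0.0, -1.0, 0.5], [2.0, 3.0])
        grouped = thermo.regroup_free_energy(net, 0.01, 1e6, kB=1.0)
        assert len(grouped.groups) == 1
        assert grouped.groups[0].occupation_probability == pytest.approx(
            1.0, abs=1e-12)

    def test_four_minimum_fixture_merges_as_designed(self):
        """Barriers {1, 5, 1} with threshold 2 (near-zero temperature, so
        free-energy barriers equal energy barriers): groups {1,2}, {3,4}."""
        net = self._barrier_chain([0.0, 0.0, 0.0, 0.0], [1.0, 5.0, 1.0])
        grouped = thermo.regroup_free_energy(net, 1e-3, 2.0, kB=1.0)
        members = sorted(tuple(sorted(g.member_min_ids))
                         for g in grouped.groups)
        assert members == [(0, 1), (2, 3)]

    def test_group_probability_equals_member_sum(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            net = make_random_network(rng)
            p = thermo.occupation_probabilities(net, 310.0)
            grouped = thermo.regroup_free_energy(net, 310.0, 0.5)
            for g in grouped.groups:
                assert g.occupation_probability == pytest.approx(
                    sum(p[i] for i in g.member_min_ids), abs=1e-12)
            assert sum(g.occupation_probability
                       for g in grouped.groups) == pytest.approx(1.0,
                                                                 abs=1e-12)

    def test_group_free_energy_monotone_under_growth(self):
        """Adding a member can only lower (or keep) the group free energy."""
        kB, T = 1.0, 1.0
        a = _minimum(-2.0, 0.0)
        b = _minimum(-1.0, 0.0)
        from scipy.special import logsumexp
        f_single = -kB * T * thermo.ln_z_harmonic(a, T, kB)
        f_both = -kB * T * logsumexp([thermo.ln_z_harmonic(a, T, kB),
                                      thermo.ln_z_harmonic(b, T, kB)])
        assert f_both <= f_single
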
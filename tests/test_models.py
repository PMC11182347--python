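"""Potential models: gradients, presets, screening, designed properties."""

import numpy as np
import pytest
from scipy import constants as sc

from ktntools import localopt
from ktntools.models import (BeadPeptide, LJCluster, debye_screening_factor,
                             make_bead_peptide, make_lj_cluster,
                             make_muller_brown, make_preset)
from ktntools.units import T_BODY, WATER_EPS_R, debye_length


def _random_configs(model, rng, n):
    for _ in range(n):
        if isinstance(model, BeadPeptide):
            dih = rng.uniform(0, 360, size=model.n_residues - 3)
            yield model.build_chain(dih) + rng.normal(scale=0.15,
                                                      size=model.dimension)
        elif isinstance(model, LJCluster):
            yield rng.normal(scale=1.2, size=model.dimension)
        else:
            yield rng.uniform(-1.5, 1.5, size=model.dimension)


@pytest.mark.parametrize("factory", [
    make_muller_brown,
    lambda: make_lj_cluster(4),
    lambda: make_lj_cluster(7),
    lambda: make_bead_peptide(10, "prot1"),
    lambda: make_bead_peptide(10, "prot3", ionic_strength=0.0),
    lambda: make_bead_peptide(8, "prot2"),
], ids=["mb", "lj4", "lj7", "pep-prot1", "pep-prot3-nosalt", "pep8-prot2"])
def test_gradient_matches_finite_differences(factory):
    """Analytic gradients agree with central differences to 1e-5 relative."""
    model = factory()
    rng = np.random.default_rng(7)
    h = 1e-6
    for x in _random_configs(model, rng, 100 // 6 + 1):
        _, g = model.energy_gradient(x)
        gfd = np.empty_like(g)
        for i in range(x.size):
            dp = np.zeros(x.size)
            dp[i] = h
            gfd[i] = (model.energy(x + dp) - model.energy(x - dp)) / (2 * h)
        scale = max(1.0, float(np.max(np.abs(gfd))))
        assert np.max(np.abs(g - gfd)) / scale < 1e-5


def test_kernel_and_numpy_paths_agree():
    """Compiled kernels reproduce the numpy reference implementation."""
    rng = np.random.default_rng(3)
    pep = make_bead_peptide(10, "prot2")
    for x in _random_configs(pep, rng, 5):
        e1, g1 = pep.energy_gradient(x)
        e2, g2 = pep.energy_gradient_numpy(x)
        assert e1 == pytest.approx(e2, abs=1e-10)
        assert np.allclose(g1, g2, atol=1e-10)
    lj = make_lj_cluster(6)
    for x in _random_configs(lj, rng, 5):
        e1, g1 = lj.energy_gradient(x)
        e2, g2 = lj.energy_gradient_numpy(x)
        assert e1 == pytest.approx(e2, rel=1e-12)
        assert np.allclose(g1, g2, rtol=1e-10, atol=1e-9)


class TestMullerBrown:
    def test_grid_descent_finds_exactly_three_minima(self, mb, mb_census):
        assert len(mb_census["minima"]) == 3
        # deepest basin is the well-known global minimum
        x_glob, e_glob = mb_census["minima"][0]
        assert e_glob == pytest.approx(-146.6995, abs=1e-3)
        assert np.allclose(x_glob, [-0.558, 1.442], atol=1e-2)

    def test_two_index1_saddles(self, mb_census):
        assert len(mb_census["saddles"]) == 2
        energies = sorted(e for _, e in mb_census["saddles"])
        assert energies[0] == pytest.approx(-72.2489, abs=1e-3)
        assert energies[1] == pytest.approx(-40.6648, abs=1e-3)


class TestLJCluster:
    def test_pair_at_lj_minimum_distance(self):
        lj = make_lj_cluster(2)
        x = np.array([0, 0, 0, 2.0 ** (1 / 6), 0, 0], dtype=float)
        assert lj.energy(x) == pytest.approx(-1.0, abs=1e-12)

    def test_energy_vanishes_at_large_separation(self):
        lj = make_lj_cluster(2)
        x = np.array([0, 0, 0, 1e4, 0, 0], dtype=float)
        assert abs(lj.energy(x)) < 1e-12

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            make_lj_cluster(1)


class TestPresets:
    def test_presets_differ_pairwise(self):
        presets = {n: make_preset(n) for n in ("prot1", "prot2", "prot3")}
        names = list(presets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert presets[a].charges != presets[b].charges

    def test_net_charge_increases_with_acidity(self):
        q = [make_preset(n).net_charge for n in ("prot1", "prot2", "prot3")]
        assert q[0] < q[1] < q[2]

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            make_preset("prot9")
        with pytest.raises(ValueError):
            make_bead_peptide(10, "nonsense")


class TestDebyeScreening:
    def test_no_salt_means_no_screening(self):
        for r in (1.0, 5.0, 50.0):
            assert debye_screening_factor(r, 0.0) == 1.0

    def test_monotone_decreasing_in_distance(self):
        rs = np.linspace(0.5, 50, 200)
        f = np.array([debye_screening_factor(r, 0.1) for r in rs])
        assert np.all(np.diff(f) < 0)

    def test_factor_at_debye_length(self):
        """exp(-1) at r = lambda_D, with lambda_D recomputed here from
        scipy constants for a 1:1 electrolyte at 310 K."""
        I, T = 0.1, 310.0
        n = I * 1000.0 * sc.N_A
        lam = np.sqrt(WATER_EPS_R * sc.epsilon_0 * sc.k * T
                      / (2.0 * n * sc.e ** 2)) * 1e10
        assert debye_length(I, T) == pytest.approx(lam, rel=1e-12)
        assert debye_screening_factor(lam, I, T) == pytest.approx(
            np.exp(-1.0), abs=1e-12)

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            debye_screening_factor(1.0, -0.1)


class TestBeadPeptide:
    def test_coulomb_zero_for_zero_charge_product(self):
        pep = make_bead_peptide(10, "prot3")  # acidic residues neutralised
        x = pep.helix_configuration()
        # zero out every charge: coulomb term must vanish identically
        pep_neutral = make_bead_peptide(10, "prot3")
        pep_neutral._qq = pep_neutral._qq * 0.0
        assert pep_neutral.coulomb_energy(x) == 0.0

    def test_salt_screening_shrinks_coulomb(self):
        x = make_bead_peptide(10, "prot1").helix_configuration()
        e_salt = make_bead_peptide(10, "prot1", 0.1).coulomb_energy(x)
        e_nosalt = make_bead_peptide(10, "prot1", 0.0).coulomb_energy(x)
        assert abs(e_salt) < abs(e_nosalt)

    def test_preset_swap_changes_only_coulomb(self):
        """Energies of two presets on one configuration differ exactly by
        the Coulomb-term difference."""
        p1 = make_bead_peptide(10, "prot1")
        p3 = make_bead_peptide(10, "prot3")
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = p1.build_chain(rng.uniform(0, 360, 7))
            de = p1.energy(x) - p3.energy(x)
            dc = p1.coulomb_energy(x) - p3.coulomb_energy(x)
            assert de == pytest.approx(dc, abs=1e-9)

    def test_chain_builder_hits_requested_dihedrals(self):
        pep = make_bead_peptide(10, "prot1")
        target = np.array([60, 180, 60, 300, 180, 60, 120], dtype=float)
        x = pep.build_chain(target)
        phi = np.rad2deg(pep.dihedral_angles(x.reshape(-1, 3))) % 360
        assert np.allclose(phi, target % 360, atol=1e-8)

    def test_helix_is_designed_ground_state(self):
        """The relaxed ideal helix lies below the relaxed ideal strand and
        keeps >= 80% of its dihedrals inside the helix window (prot1)."""
        pep = make_bead_peptide(10, "prot1")
        mh = localopt.minimize(pep, pep.helix_configuration(),
                               with_modes=False)
        ms = localopt.minimize(pep, pep.strand_configuration(),
                               with_modes=False)
        assert mh.energy < ms.energy
        phi = np.rad2deg(pep.dihedral_angles(
            mh.coordinates.reshape(-1, 3))) % 360
        in_window = np.sum((phi >= 40) & (phi <= 80))
        assert in_window >= 0.8 * phi.size

    def test_too_short_chain_rejected(self):
        with pytest.raises(ValueError):
            make_bead_peptide(4, "prot1")
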
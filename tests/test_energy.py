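"""Energy terms, the CT functional, and the full chain-rule gradient."""

import numpy as np
import pytest

from chargenn.energy import (ChargeNNForceField, EnergyBreakdown,
                             ForceFieldParameters, ct_energy,
                             harmonic_intramolecular, vdw_96, vdw_ab_from_lj)
from chargenn.spcfw import build_monomer
from chargenn.system import Configuration

from conftest import finite_difference_gradient, relative_gradient_error


class TestIntramolecular:
    def test_equilibrium_geometry_zero(self):
        m = build_monomer()
        p = ForceFieldParameters()
        u, g = harmonic_intramolecular(m, p.k_b, p.k_a, p.r_oh0, p.theta0)
        assert u == pytest.approx(0.0, abs=1e-20)
        assert np.abs(g).max() < 1e-10

    def test_stretched_bond_arithmetic(self):
        m = build_monomer()
        # stretch O-H1 by 0.1 Å along the bond
        bond = m.positions[1] - m.positions[0]
        m.positions[1] += 0.1 * bond / np.linalg.norm(bond)
        u, _ = harmonic_intramolecular(m, 500.0, 37.95, 1.012,
                                       np.deg2rad(113.24))
        assert u == pytest.approx(500.0 * 0.01, rel=1e-10)

    def test_gradient_matches_finite_differences(self, cluster_factory):
        c = cluster_factory(3, seed=1, distort=0.05)
        p = ForceFieldParameters()
        u, g = harmonic_intramolecular(c, p.k_b, p.k_a, p.r_oh0, p.theta0)
        fd = finite_difference_gradient(
            lambda cc: harmonic_intramolecular(cc, p.k_b, p.k_a, p.r_oh0,
                                               p.theta0)[0], c)
        assert relative_gradient_error(g, fd) < 1e-6


class TestVdw96:
    def test_ab_from_lj_reproduces_well(self):
        eps, sigma = 0.155, 3.166
        a, b = vdw_ab_from_lj(eps, sigma)
        r_min = 2 ** (1 / 6) * sigma
        u_min = a / r_min ** 9 - b / r_min ** 6
        assert u_min == pytest.approx(-eps, rel=1e-12)
        du = -9 * a / r_min ** 10 + 6 * b / r_min ** 7
        assert du == pytest.approx(0.0, abs=1e-12)

    def test_unit_constants_minimum(self):
        # A = B = 1: minimum at (3/2)^(1/3) ≈ 1.1447 with U ≈ −0.1481
        r = np.cbrt(1.5)
        assert 1 / r ** 9 - 1 / r ** 6 == pytest.approx(-0.14815, abs=1e-5)

    def test_two_molecule_hand_sum(self):
        a_mol = build_monomer()
        b_mol = build_monomer(center=(3.2, 0.0, 0.0))
        c = Configuration(np.concatenate([a_mol.species, b_mol.species]),
                          np.vstack([a_mol.positions, b_mol.positions]))
        p = ForceFieldParameters()
        u, _ = vdw_96(c, p)
        r = np.linalg.norm(c.positions[3] - c.positions[0])
        a, b = p.vdw_a[("O", "O")], p.vdw_b[("O", "O")]
        assert u == pytest.approx(a / r ** 9 - b / r ** 6, rel=1e-12)

    def test_vanishes_at_long_range(self):
        a_mol = build_monomer()
        b_mol = build_monomer(center=(200.0, 0.0, 0.0))
        c = Configuration(np.concatenate([a_mol.species, b_mol.species]),
                          np.vstack([a_mol.positions, b_mol.positions]))
        u, _ = vdw_96(c, ForceFieldParameters())
        assert abs(u) < 1e-10


class TestCTEnergy:
    p = ForceFieldParameters()

    def test_zero_ct_zero_energy(self):
        u, dudq = ct_energy(np.zeros(4), self.p.k_c, self.p.dq0)
        assert u == 0.0
        assert np.all(dudq == 0.0)

    def test_even_symmetry(self):
        x = np.linspace(0.001, 0.1, 25)
        up, _ = ct_energy(x, self.p.k_c, self.p.dq0)
        um, _ = ct_energy(-x, self.p.k_c, self.p.dq0)
        assert up == pytest.approx(um, rel=1e-14)

    def test_bounded_below_and_saturating(self):
        u, _ = ct_energy(np.array([1e6]), self.p.k_c, self.p.dq0)
        assert -self.p.k_c <= u < 0

    def test_force_maximal_exactly_at_reference_ct(self):
        dq = np.linspace(1e-4, 0.2, 20000)
        _, dudq = ct_energy(dq, self.p.k_c, self.p.dq0)
        peak = dq[np.argmax(np.abs(dudq))]
        assert peak == pytest.approx(self.p.dq0, rel=1e-3)

    def test_derivative_matches_finite_differences(self):
        dq = np.array([0.005, -0.02, 0.07])
        _, dudq = ct_energy(dq, self.p.k_c, self.p.dq0)
        h = 1e-8
        for i in range(3):
            dp, dm = dq.copy(), dq.copy()
            dp[i] += h
            dm[i] -= h
            fd = (ct_energy(dp, self.p.k_c, self.p.dq0)[0]
                  - ct_energy(dm, self.p.k_c, self.p.dq0)[0]) / (2 * h)
            assert fd == pytest.approx(dudq[i], rel=1e-6)


class TestParameters:
    def test_validation(self):
        with pytest.raises(ValueError):
            ForceFieldParameters(k_b=-1.0)
        with pytest.raises(ValueError):
            ForceFieldParameters(dq0=0.0)

    def test_breakdown_total_is_exact_sum(self):
        b = EnergyBreakdown(1.0, -2.0, 3.5, -0.25)
        assert b.total == 1.0 - 2.0 + 3.5 - 0.25


class TestFullGradient:
    """The primary correctness test: analytic forces vs finite differences
    through the complete chain (features → networks → Δq shift → energy)."""

    def test_monomer_zero_networks(self, monomer):
        pred_zero = __import__("chargenn").ChargePredictor.random(seed=0)
        for net in (pred_zero.net_o, pred_zero.net_h, pred_zero.net_ct):
            net.set_parameters([np.zeros_like(p) for p in net.get_parameters()])
        ff = ChargeNNForceField(pred_zero)
        b, f, _ = ff.evaluate(monomer)
        assert b.total == pytest.approx(0.0, abs=1e-12)
        assert np.abs(f).max() < 1e-10

    def test_cluster_gradient_matches_fd(self, random_predictor,
                                         cluster_factory):
        ff = ChargeNNForceField(random_predictor)
        rng = np.random.default_rng(0)
        c = cluster_factory(4, seed=6, distort=0.03)
        _, forces, _ = ff.evaluate(c)
        coords = rng.choice(c.n_atoms * 3, 10, replace=False)
        fd = finite_difference_gradient(lambda cc: ff.evaluate(cc)[0].total,
                                        c, coords=[int(k) for k in coords])
        assert relative_gradient_error(-forces, fd) < 1e-5

    def test_periodic_gradient_matches_fd(self, random_predictor,
                                          periodic_box_16):
        ff = ChargeNNForceField(random_predictor)
        _, forces, _ = ff.evaluate(periodic_box_16)
        rng = np.random.default_rng(1)
        coords = rng.choice(periodic_box_16.n_atoms * 3, 8, replace=False)
        fd = finite_difference_gradient(lambda cc: ff.evaluate(cc)[0].total,
                                        periodic_box_16,
                                        coords=[int(k) for k in coords])
        assert relative_gradient_error(-forces, fd) < 1e-5

    def test_cluster_forces_sum_and_torque_zero(self, random_predictor,
                                                cluster_factory):
        ff = ChargeNNForceField(random_predictor)
        c = cluster_factory(5, seed=9, distort=0.02)
        _, forces, _ = ff.evaluate(c)
        assert np.abs(forces.sum(axis=0)).max() < 1e-8
        torque = np.sum(np.cross(c.positions - c.positions.mean(axis=0),
                                 forces), axis=0)
        assert np.abs(torque).max() < 1e-8

    def test_energy_invariant_under_rigid_motion(self, random_predictor,
                                                 cluster_factory):
        ff = ChargeNNForceField(random_predictor)
        c = cluster_factory(4, seed=11)
        u0 = ff.evaluate(c)[0].total
        rng = np.random.default_rng(2)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        moved = c.with_positions(c.positions @ q.T + [3.0, 1.0, -2.0])
        assert ff.evaluate(moved)[0].total == pytest.approx(u0, abs=1e-10)

    def test_energy_invariant_under_lattice_translation(self, random_predictor,
                                                        periodic_box_16):
        from chargenn.system import wrap_molecules
        ff = ChargeNNForceField(random_predictor)
        u0 = ff.evaluate(periodic_box_16)[0].total
        shifted = periodic_box_16.with_positions(
            periodic_box_16.positions + np.asarray([11.4, -11.4, 22.8]))
        assert ff.evaluate(shifted)[0].total == pytest.approx(u0, rel=1e-10)
        wrapped = wrap_molecules(periodic_box_16)
        assert ff.evaluate(wrapped)[0].total == pytest.approx(u0, rel=1e-10)

    def test_neutralization_shift_gradient_is_propagated(self,
                                                         cluster_factory):
        # a predictor whose O charges are biased produces a nonzero Δq whose
        # coordinate dependence must appear in the forces; compare against FD
        import chargenn
        pred = chargenn.ChargePredictor.random(seed=8, init_scale=0.6)
        ff = ChargeNNForceField(pred)
        c = cluster_factory(3, seed=13, distort=0.02)
        _, _, info = ff.evaluate(c)
        assert info["charges"].delta_q != 0.0
        _, forces, _ = ff.evaluate(c)
        fd = finite_difference_gradient(lambda cc: ff.evaluate(cc)[0].total,
                                        c, coords=range(0, c.n_atoms * 3, 4))
        assert relative_gradient_error(-forces, fd) < 1e-5

    def test_energy_continuous_across_ct_cutoff(self, random_predictor):
        ff = ChargeNNForceField(random_predictor)
        cutoff = random_predictor.spec.ct_cutoff
        eps = 1e-7
        us, cts = [], []
        for r in (cutoff - eps, cutoff + eps):
            a_mol = build_monomer()
            b_mol = build_monomer(center=(r, 0.0, 0.0))
            c = Configuration(np.concatenate([a_mol.species, b_mol.species]),
                              np.vstack([a_mol.positions, b_mol.positions]))
            b, _, _ = ff.evaluate(c)
            us.append(b.total)
            cts.append(b.ct)
        # the CT term itself is continuous through zero at the cutoff …
        assert abs(cts[0]) < 1e-15
        assert cts[1] == 0.0
        # … so the total changes only by the smooth-terms slope over 2ε
        _, f, _ = ff.evaluate(c)
        slope_bound = (np.abs(f).max() + 1.0) * 2 * eps
        assert abs(us[0] - us[1]) < slope_bound
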
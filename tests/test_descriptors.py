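"""ICF values, feature layouts, invariances, and analytic Jacobians."""

import numpy as np
import pytest

from chargenn.descriptors import (ICFSpec, charge_feature_jacobian,
                                  charge_feature_vector, charge_features,
                                  ct_feature_jacobian, ct_feature_vector,
                                  ct_features, ct_pairs, cutoff_weight,
                                  cutoff_weight_derivative, icf_value)
from chargenn.spcfw import build_monomer
from chargenn.system import Configuration


def random_rigid_motion(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    return q, rng.uniform(-20, 20, 3)


def dimer_at(r_oo=2.8):
    from chargenn.spcfw import build_dimer_start
    return build_dimer_start(r_oo)


class TestCutoffWeight:
    def test_anchor_values(self):
        r_c = 4.4
        assert cutoff_weight(0.0, r_c) == 1.0
        assert cutoff_weight(r_c, r_c) == pytest.approx(0.0, abs=1e-15)
        assert cutoff_weight(r_c / 2, r_c) == pytest.approx(0.5)
        assert cutoff_weight(r_c + 0.1, r_c) == 0.0

    def test_smooth_at_cutoff(self):
        r_c = 4.4
        assert cutoff_weight_derivative(r_c, r_c) == pytest.approx(0.0, abs=1e-15)
        # value and derivative both approach 0 from inside
        eps = 1e-6
        assert cutoff_weight(r_c - eps, r_c) < 1e-11
        assert abs(cutoff_weight_derivative(r_c - eps, r_c)) < 1e-5

    def test_rejects_bad_cutoff(self):
        with pytest.raises(ValueError):
            cutoff_weight(1.0, -1.0)


class TestICFValue:
    def test_isolated_atom_is_zero(self):
        m = build_monomer()
        assert icf_value(m, 0, "O", intra=False, k_f=1.0, r_c=4.4) == 0.0
        assert icf_value(m, 0, "O", intra=True, k_f=1.0, r_c=4.4) == 0.0

    def test_single_neighbor_closed_form(self):
        # one neighbor at 2.0 Å: e⁻² · ½(cos(2π/4.4)+1) ≈ 0.077
        c = Configuration(
            np.array(["O", "H", "H"] * 2, dtype=object),
            np.array([[0, 0, 0], [0.95, 0, 0], [-0.3, 0.9, 0],
                      [2.0, 0, 0.0], [2.95, 0, 0], [1.7, 0.9, 0]], float))
        got = icf_value(c, 0, "O", intra=False, k_f=1.0, r_c=4.4)
        expected = np.exp(-2.0) * 0.5 * (np.cos(2.0 * np.pi / 4.4) + 1.0)
        # other-molecule O is exactly the single neighbor of class O
        assert got == pytest.approx(expected, rel=1e-12)

    def test_neighbor_label_permutation_invariant(self):
        c = dimer_at()
        v1 = icf_value(c, 0, "H", intra=True, k_f=1.0, r_c=4.4)
        swapped = Configuration(c.species.copy(), c.positions[[0, 2, 1, 3, 4, 5]])
        v2 = icf_value(swapped, 0, "H", intra=True, k_f=1.0, r_c=4.4)
        assert v1 == pytest.approx(v2, rel=1e-14)


def naive_charge_features(config, atom, spec):
    """Independent brute-force double loop over classified neighbors."""
    out = []
    mol = config.molecule_index
    mates = [a for a in range(config.n_atoms)
             if mol[a] == mol[atom] and a != atom]
    # order mates as the layout does: O first for H centers
    if config.species[atom] == "H":
        mates = sorted(mates, key=lambda a: 0 if config.species[a] == "O" else 1)
    for k_f in spec.k_f_list:
        block = [icf_value(config, atom, "O", True, k_f, spec.r_c),
                 icf_value(config, atom, "H", True, k_f, spec.r_c),
                 icf_value(config, atom, "O", False, k_f, spec.r_c),
                 icf_value(config, atom, "H", False, k_f, spec.r_c)]
        g = [[icf_value(config, a, e, False, k_f, spec.r_c)
              for e in ("O", "H")] for a in mates]
        if config.species[atom] == "O":
            block += [g[0][0] + g[1][0], g[0][1] + g[1][1],
                      g[0][0] * g[1][0], g[0][1] * g[1][1]]
        else:
            block += [g[0][0], g[0][1], g[1][0], g[1][1]]
        out.extend(block)
    return np.asarray(out)


class TestChargeFeatures:
    spec = ICFSpec()

    def test_monomer_intermolecular_slots_zero(self):
        f = charge_feature_vector(build_monomer(), 1, self.spec)
        f = f.reshape(3, 8)
        assert np.all(f[:, 2:] == 0.0)          # inter + mate slots
        assert np.all(f[:, :2] > 0.0)           # intra O and H slots

    def test_layout_width(self):
        assert self.spec.n_charge_features == 24
        f = charge_feature_vector(dimer_at(), 0, self.spec)
        assert f.shape == (24,)

    def test_matches_naive_double_loop(self):
        c = dimer_at(2.8)
        for atom in range(6):
            expected = naive_charge_features(c, atom, self.spec)
            got = charge_feature_vector(c, atom, self.spec)
            np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-15)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(42)
        from chargenn.surrogate import build_cluster
        c = build_cluster(5, seed=1)
        f0, _ = charge_features(c, self.spec)
        worst = 0.0
        for _ in range(100):
            q, t = random_rigid_motion(rng)
            moved = c.with_positions(c.positions @ q.T + t)
            f1, _ = charge_features(moved, self.spec)
            worst = max(worst, np.abs(f1 - f0).max())
        assert worst < 1e-12

    def test_hydrogen_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        from chargenn.surrogate import build_cluster
        c = build_cluster(5, seed=2)
        f0, _ = charge_features(c, self.spec)
        worst = 0.0
        for _ in range(100):
            perm = np.arange(c.n_atoms)
            for m in rng.choice(c.n_molecules, 3, replace=False):
                perm[[3 * m + 1, 3 * m + 2]] = perm[[3 * m + 2, 3 * m + 1]]
            swapped = Configuration(c.species[perm], c.positions[perm])
            f1, _ = charge_features(swapped, self.spec)
            # swapped atom a is original atom perm[a]
            worst = max(worst, np.abs(f1 - f0[perm]).max())
        assert worst < 1e-12

    def test_locality_atom_beyond_cutoff(self):
        c = dimer_at(2.8)
        far = build_monomer(center=(50.0, 0.0, 0.0))
        bigger = Configuration(np.concatenate([c.species, far.species]),
                               np.vstack([c.positions, far.positions]))
        f0, _ = charge_features(c, self.spec)
        f1, _ = charge_features(bigger, self.spec)
        np.testing.assert_array_equal(f0, f1[:6])

    def test_continuous_across_cutoff(self):
        spec = self.spec
        eps = 1e-7
        base = build_monomer()
        for r in (spec.r_c - eps, spec.r_c + eps):
            other = build_monomer(center=(r, 0.0, 0.0))
            c = Configuration(np.concatenate([base.species, other.species]),
                              np.vstack([base.positions, other.positions]))
            f = charge_feature_vector(c, 0, spec).reshape(3, 8)
            # inter-O slot of atom 0 vanishes continuously at r_c
            assert abs(f[0, 2]) < 1e-12


class TestCTFeatures:
    spec = ICFSpec()

    def test_far_pair_not_selected(self):
        a = build_monomer()
        b = build_monomer(center=(10.0, 0.0, 0.0))
        c = Configuration(np.concatenate([a.species, b.species]),
                          np.vstack([a.positions, b.positions]))
        assert len(ct_pairs(c, self.spec)) == 0
        assert ct_feature_vector(c, 0, 1, self.spec) is None

    def test_swap_exchanges_halves_blockwise(self):
        c = dimer_at(2.8)
        f_ij = ct_feature_vector(c, 0, 1, self.spec)
        f_ji = ct_feature_vector(c, 1, 0, self.spec)
        half = len(f_ij) // 2
        np.testing.assert_array_equal(f_ji[:half], f_ij[half:])
        np.testing.assert_array_equal(f_ji[half:], f_ij[:half])

    def test_matches_naive_double_loop(self):
        c = dimer_at(2.8)
        f = ct_feature_vector(c, 0, 1, self.spec)
        assert f.shape == (36,)
        r_ct = self.spec.ct_cutoff
        pos = c.positions

        def w(i, j, k_f):
            r = np.linalg.norm(pos[j] - pos[i])
            return np.exp(-k_f * r) * cutoff_weight(r, r_ct)

        expected = []
        for side, (atoms_a, atoms_b) in enumerate((((0, 1, 2), (3, 4, 5)),
                                                   ((3, 4, 5), (0, 1, 2)))):
            for k_f in self.spec.k_f_list:
                o_a, h1, h2 = atoms_a
                o_b = atoms_b[0]
                hs_b = atoms_b[1:]
                vs = {a: {"O": w(a, o_b, k_f),
                          "H": sum(w(a, hb, k_f) for hb in hs_b)}
                      for a in atoms_a}
                expected += [vs[o_a]["O"], vs[o_a]["H"],
                             vs[h1]["O"] + vs[h2]["O"],
                             vs[h1]["H"] + vs[h2]["H"],
                             vs[h1]["O"] * vs[h2]["O"],
                             vs[h1]["H"] * vs[h2]["H"]]
        # layout stores all k_f blocks of side I first, then side J
        expected = np.asarray(expected)
        np.testing.assert_allclose(f, expected, rtol=1e-12, atol=1e-15)


class TestJacobians:
    spec = ICFSpec()

    def test_no_neighbors_zero_jacobian(self):
        m = build_monomer()
        jac = charge_feature_jacobian(m, 0, self.spec)
        # intermolecular slots have no neighbors: their rows vanish
        assert np.abs(jac.reshape(3, 8, 3, 3)[:, 2:]).max() == 0.0

    @pytest.mark.parametrize("n_mol,seed", [(2, 0), (5, 3), (10, 8)])
    def test_charge_jacobian_matches_finite_differences(self, n_mol, seed,
                                                        cluster_factory):
        c = cluster_factory(n_mol, seed=seed, distort=0.03)
        atom = seed % c.n_atoms
        jac = charge_feature_jacobian(c, atom, self.spec)
        h = 1e-5
        rng = np.random.default_rng(seed)
        scale = max(np.abs(jac).max(), 1e-10)
        for k in rng.choice(c.n_atoms * 3, 6, replace=False):
            i, x = divmod(int(k), 3)
            cp = c.copy()
            cp.positions[i, x] += h
            cm = c.copy()
            cm.positions[i, x] -= h
            fd = (charge_feature_vector(cp, atom, self.spec)
                  - charge_feature_vector(cm, atom, self.spec)) / (2 * h)
            assert np.abs(fd - jac[:, i, x]).max() / scale < 1e-6

    def test_ct_jacobian_matches_finite_differences(self, cluster_factory):
        c = cluster_factory(4, seed=5, distort=0.02)
        pairs = ct_pairs(c, self.spec)
        mi, mj = pairs[0]
        jac = ct_feature_jacobian(c, int(mi), int(mj), self.spec)
        h = 1e-5
        scale = max(np.abs(jac).max(), 1e-10)
        rng = np.random.default_rng(0)
        for k in rng.choice(c.n_atoms * 3, 6, replace=False):
            i, x = divmod(int(k), 3)
            cp = c.copy()
            cp.positions[i, x] += h
            cm = c.copy()
            cm.positions[i, x] -= h
            fp = ct_feature_vector(cp, int(mi), int(mj), self.spec)
            fm = ct_feature_vector(cm, int(mi), int(mj), self.spec)
            fd = (fp - fm) / (2 * h)
            assert np.abs(fd - jac[:, i, x]).max() / scale < 1e-6

    def test_neighbor_exactly_at_cutoff_contributes_no_gradient(self):
        spec = self.spec
        base = build_monomer()
        other = build_monomer(center=(spec.r_c, 20.0, 0.0))
        other.positions[:, 1] -= 20.0          # O exactly at r_c from atom 0
        c = Configuration(np.concatenate([base.species, other.species]),
                          np.vstack([base.positions, other.positions]))
        jac = charge_feature_jacobian(c, 0, spec).reshape(3, 8, c.n_atoms, 3)
        # the inter-O slots' derivative w.r.t. the far O vanishes at r_c
        # (within roundoff of sin(π))
        assert np.abs(jac[:, 2, 3, :]).max() < 1e-17


def test_icfspec_validation():
    with pytest.raises(ValueError):
        ICFSpec(r_c=-1.0)
    with pytest.raises(ValueError):
        ICFSpec(k_f_list=(1.0, 0.5))
    with pytest.raises(ValueError):
        ICFSpec(k_f_list=())
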
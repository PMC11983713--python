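"""The flexible 3-site water energy functional with dynamic charges.

    U = Σ_I [ k_b((r_OH1 − r⁰)² + (r_OH2 − r⁰)²) + k_a(θ_I − θ⁰)² ]
      + Σ_{i<j inter} ( A_ij/r⁹ − B_ij/r⁶ )
      + k_e Σ_{i<j inter} q_i q_j / r_ij          (Ewald under PBC)
      − k_c Σ_{I<J} δq_IJ² / (δq_IJ² + 3 δq⁰²)

Harmonic terms use the no-½ convention.  The 9–6 van der Waals constants
are derived from 12–6 ε/σ by matching well depth and minimum position
(A = 2ε r_min⁹, B = 3ε r_min⁶), giving a softer repulsive wall.  The CT
term is symmetric in δq, zero at δq = 0, saturates at −k_c per pair, and
its force magnitude |∂U/∂δq| peaks exactly at δq = δq⁰ — the reference CT
producing the strongest CT force.

Forces follow the full chain rule

    dU/dR = ∂U̅/∂R + (∂U/∂q)·(dq/dF)·(dF/dR) + (∂U/∂δq)·(dδq/dF_ct)·(dF_ct/dR),

where ∂U̅/∂R collects the explicitly coordinate-dependent terms.  The
coordinate dependence of the neutralization shift Δq = Σq/N is propagated:
the cotangent of each raw charge is ∂U/∂q_i − mean_j(∂U/∂q_j).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .charges import (ChargePredictor, ChargeSet, CTSet, ct_switch,
                      ct_switch_derivative, neutralize)
from .descriptors import charge_features, charge_feature_adjoint, \
    ct_features, ct_feature_adjoint
from .ewald import EwaldSummator, coulomb_cluster
from .system import Configuration
from .units import KE_COULOMB

__all__ = [
    "ForceFieldParameters", "EnergyBreakdown", "GradientSet",
    "harmonic_intramolecular", "vdw_96", "lennard_jones_126", "ct_energy",
    "vdw_ab_from_lj", "ChargeNNForceField",
]


def vdw_ab_from_lj(epsilon: float, sigma: float) -> tuple[float, float]:
    """9–6 constants matching a 12–6 well: A = 2ε r_min⁹, B = 3ε r_min⁶."""
    r_min = 2.0 ** (1.0 / 6.0) * sigma
    return 2.0 * epsilon * r_min ** 9, 3.0 * epsilon * r_min ** 6


@dataclass
class ForceFieldParameters:
    """Every constant of the energy functional (documented defaults).

    The intramolecular constants default to the SPC/Fw values expressed in
    the no-½ convention; the O–O 9–6 constants derive from the SPC/Fw
    12–6 ε/σ.  k_c and δq⁰ are package defaults (the published tuned set is
    not reproduced here); all fields are configurable.
    """

    k_b: float = 529.581          # kcal/mol/Å², no-½ convention
    k_a: float = 37.95            # kcal/mol/rad², no-½ convention
    r_oh0: float = 1.012          # Å
    theta0: float = np.deg2rad(113.24)   # rad
    vdw_a: dict = field(default_factory=dict)   # kcal·Å⁹/mol per pair class
    vdw_b: dict = field(default_factory=dict)   # kcal·Å⁶/mol per pair class
    k_e: float = KE_COULOMB       # kcal·Å/(mol·e²)
    k_c: float = 2.0              # kcal/mol, CT strength
    dq0: float = 0.02             # e, reference CT
    r_cut: float = 5.5            # Å, real-space / vdW cutoff under PBC
    switch_width: float = 1.0     # Å, vdW switching window
    ewald_accuracy: float = 1e-8

    def __post_init__(self) -> None:
        if min(self.k_b, self.k_a, self.k_e) <= 0:
            raise ValueError("k_b, k_a, k_e must be positive")
        if self.dq0 <= 0:
            raise ValueError("δq⁰ must be positive")
        if not self.vdw_a:
            a, b = vdw_ab_from_lj(0.15539, 3.165492)
            self.vdw_a = {("O", "O"): a}
            self.vdw_b = {("O", "O"): b}
        if any(v < 0 for v in (*self.vdw_a.values(), *self.vdw_b.values())):
            raise ValueError("vdW A/B must be non-negative")


@dataclass
class EnergyBreakdown:
    """Per-term energies, kcal/mol; the total is their exact sum."""

    intra: float = 0.0
    vdw: float = 0.0
    coulomb: float = 0.0
    ct: float = 0.0

    @property
    def total(self) -> float:
        return self.intra + self.vdw + self.coulomb + self.ct

    def as_dict(self) -> dict:
        return {"U_intra": self.intra, "U_vdw": self.vdw,
                "U_coul": self.coulomb, "U_ct": self.ct, "U_total": self.total}


@dataclass
class GradientSet:
    """Forces −∂U/∂R per atom, kcal/mol/Å."""

    forces: np.ndarray

    @property
    def net_force(self) -> np.ndarray:
        return self.forces.sum(axis=0)

    def net_torque(self, positions: np.ndarray) -> np.ndarray:
        ref = positions.mean(axis=0)
        return np.sum(np.cross(positions - ref, self.forces), axis=0)


# ---------------------------------------------------------------------------
# individual terms
# ---------------------------------------------------------------------------

def harmonic_intramolecular(config: Configuration, k_b: float, k_a: float,
                            r_oh0: float, theta0: float):
    """Harmonic bonds + angle, no-½ convention.  Returns (U, ∂U/∂R)."""
    pos = config.positions.reshape(config.n_molecules, 3, 3)
    grad = np.zeros_like(pos)
    o, h1, h2 = pos[:, 0], pos[:, 1], pos[:, 2]
    u_tot = 0.0
    for h, gi in ((h1, 1), (h2, 2)):
        d = h - o
        b = np.linalg.norm(d, axis=1)
        u_tot += k_b * np.sum((b - r_oh0) ** 2)
        g = (2.0 * k_b * (b - r_oh0) / b)[:, None] * d
        grad[:, gi] += g
        grad[:, 0] -= g
    u = h1 - o
    v = h2 - o
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos_t = np.clip(np.einsum("mx,mx->m", u, v) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.sqrt(np.maximum(1.0 - cos_t ** 2, 1e-14))
    u_tot += k_a * np.sum((theta - theta0) ** 2)
    pref = 2.0 * k_a * (theta - theta0) / (-sin_t)
    uhat, vhat = u / nu[:, None], v / nv[:, None]
    dcos_dh1 = (vhat - cos_t[:, None] * uhat) / nu[:, None]
    dcos_dh2 = (uhat - cos_t[:, None] * vhat) / nv[:, None]
    grad[:, 1] += pref[:, None] * dcos_dh1
    grad[:, 2] += pref[:, None] * dcos_dh2
    grad[:, 0] -= pref[:, None] * (dcos_dh1 + dcos_dh2)
    return float(u_tot), grad.reshape(-1, 3)


def _switch(r, r_on, r_off):
    """C² switching: 1 below r_on, 0 above r_off (quintic smoothstep)."""
    t = np.clip((r - r_on) / (r_off - r_on), 0.0, 1.0)
    s = 1.0 - t ** 3 * (10.0 - 15.0 * t + 6.0 * t * t)
    inside = (r > r_on) & (r < r_off)
    ds = np.where(inside, -30.0 * t * t * (1.0 - t) ** 2 / (r_off - r_on), 0.0)
    return s, ds


def _pairwise_nonbonded(config, u_of_r, dudr_of_r, pair_class_params,
                        r_cut=None, switch_width=1.0):
    """Σ over intermolecular pairs of a radial potential, optionally switched.

    ``pair_class_params`` maps frozenset-style element pairs to parameter
    tuples consumed by u_of_r/dudr_of_r.
    """
    from .system import displacement_matrix
    d, r = displacement_matrix(config)
    mol = config.molecule_index
    inter = mol[:, None] != mol[None, :]
    sp = config.species
    is_o = config.is_oxygen
    masks = {("O", "O"): np.outer(is_o, is_o),
             ("O", "H"): np.outer(is_o, ~is_o) | np.outer(~is_o, is_o),
             ("H", "H"): np.outer(~is_o, ~is_o)}
    u_tot = 0.0
    grad = np.zeros_like(config.positions)
    for pair, par in pair_class_params.items():
        key = tuple(sorted(pair))
        mask = masks[key] & inter
        if r_cut is not None:
            mask = mask & (r <= r_cut)
        if not mask.any():
            continue
        rr = np.where(mask, r, 1.0)
        u = u_of_r(rr, par)
        dudr = dudr_of_r(rr, par)
        if r_cut is not None:
            s, ds = _switch(rr, r_cut - switch_width, r_cut)
            dudr = dudr * s + u * ds
            u = u * s
        u_tot += 0.5 * np.sum(np.where(mask, u, 0.0))
        coef = np.where(mask, dudr / rr, 0.0)
        grad += np.einsum("ij,ijx->ix", coef, -d)
    return float(u_tot), grad
    _ = sp


def vdw_96(config: Configuration, params: ForceFieldParameters):
    """9–6 van der Waals energy A/r⁹ − B/r⁶ over intermolecular pairs.

    Under PBC the potential is switched smoothly to zero over the last
    ``switch_width`` Å before r_cut; clusters use the bare untruncated form.
    """
    pair_par = {}
    for key, a in params.vdw_a.items():
        b = params.vdw_b.get(key, 0.0)
        if a != 0.0 or b != 0.0:
            pair_par[tuple(sorted(key))] = (a, b)
    r_cut = params.r_cut if config.periodic else None
    return _pairwise_nonbonded(
        config,
        lambda r, p: p[0] / r ** 9 - p[1] / r ** 6,
        lambda r, p: -9.0 * p[0] / r ** 10 + 6.0 * p[1] / r ** 7,
        pair_par, r_cut=r_cut, switch_width=params.switch_width)


def lennard_jones_126(config: Configuration, epsilon: float, sigma: float,
                      r_cut: float | None = None, switch_width: float = 1.0):
    """Standard 12–6 LJ on O–O pairs (the fixed-charge baseline's vdW)."""
    def u(r, p):
        sr6 = (p[1] / r) ** 6
        return 4.0 * p[0] * (sr6 * sr6 - sr6)

    def dudr(r, p):
        sr6 = (p[1] / r) ** 6
        return 4.0 * p[0] * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r

    return _pairwise_nonbonded(config, u, dudr, {("O", "O"): (epsilon, sigma)},
                               r_cut=r_cut, switch_width=switch_width)


def ct_energy(delta_q: np.ndarray, k_c: float, dq0: float):
    """U_ct = −k_c Σ δq²/(δq² + 3δq⁰²); returns (U, ∂U/∂δq per pair).

    Even in δq, zero at zero, bounded below by −k_c per pair; |∂U/∂δq| is
    maximal at |δq| = δq⁰.
    """
    dq = np.asarray(delta_q, dtype=float)
    c = 3.0 * dq0 * dq0
    denom = dq * dq + c
    u = -k_c * np.sum(dq * dq / denom)
    dudq = -k_c * 2.0 * dq * c / denom ** 2
    return float(u), dudq


# ---------------------------------------------------------------------------
# the full model backend
# ---------------------------------------------------------------------------

class ChargeNNForceField:
    """Energy/force backend driven by the neural charge + CT predictors.

    Charges are predicted fresh at every evaluation (a direct map — no
    iterative self-consistency), neutralized, then fed to the Coulomb term;
    pair CT feeds the additive CT term.  δq does not modify the atomic
    charges entering the Coulomb sum: the networks are trained on CM5-style
    charges that already reflect intermolecular polarization.
    """

    name = "chargenn"

    def __init__(self, predictor: ChargePredictor,
                 params: ForceFieldParameters | None = None):
        self.predictor = predictor
        self.params = params or ForceFieldParameters()
        self._ewald: EwaldSummator | None = None
        self._ewald_cell: np.ndarray | None = None

    def _get_ewald(self, cell: np.ndarray) -> EwaldSummator:
        if self._ewald is None or not np.array_equal(cell, self._ewald_cell):
            self._ewald = EwaldSummator(
                cell, r_cut=min(self.params.r_cut, 0.49 * float(min(cell))),
                accuracy=self.params.ewald_accuracy, k_e=self.params.k_e)
            self._ewald_cell = cell.copy()
        return self._ewald

    def evaluate(self, config: Configuration):
        """Returns (EnergyBreakdown, forces (N,3), info dict)."""
        p = self.params
        spec = self.predictor.spec
        if config.periodic:
            config.validate_cell(max(spec.max_cutoff, p.r_cut))

        # 1. charges
        feats, q_cache = charge_features(config, spec)
        is_o = config.is_oxygen
        q_raw, dq_df = self.predictor.raw_charges_and_gradients(feats, is_o)
        qset = neutralize(ChargeSet(q_raw))
        q = qset.charges

        # 2. charge transfer
        ct_feats, ct_cache = ct_features(config, spec)
        n_pairs = len(ct_feats)
        if n_pairs:
            g_anti, g_grad = self.predictor._ct_raw_and_grad(ct_feats, True)
            s = ct_switch(ct_cache.r_oo, spec.ct_cutoff,
                          self.predictor.ct_switch_width)
            ds = ct_switch_derivative(ct_cache.r_oo, spec.ct_cutoff,
                                      self.predictor.ct_switch_width)
            dq_pairs = g_anti * s
        else:
            g_anti = g_grad = s = ds = None
            dq_pairs = np.zeros(0)
        ctset = CTSet(ct_cache.pairs, dq_pairs)

        # 3. explicit terms
        u_intra, g_intra = harmonic_intramolecular(
            config, p.k_b, p.k_a, p.r_oh0, p.theta0)
        u_vdw, g_vdw = vdw_96(config, p)
        if config.periodic:
            u_coul, phi, f_coul = self._get_ewald(config.cell).energy(
                config.positions, q, config.molecule_index)
            g_coul = -f_coul
        else:
            u_coul, phi, f_coul = coulomb_cluster(
                config.positions, q, config.molecule_index, p.k_e)
            g_coul = -f_coul
        u_ct, du_ddq = ct_energy(dq_pairs, p.k_c, p.dq0)

        grad = g_intra + g_vdw + g_coul

        # 4. charge chain rule (with the Δq neutralization shift propagated)
        phi_raw = phi - phi.mean()
        chi_q = phi_raw[:, None] * dq_df
        grad += charge_feature_adjoint(q_cache, chi_q)

        # 5. CT chain rule (network part + distance-switch part)
        if n_pairs:
            chi_ct = (du_ddq * s)[:, None] * g_grad
            grad += ct_feature_adjoint(ct_cache, chi_ct)
            # taper term: dU/dr_OO = ∂U/∂δq · g_anti · S'(r_OO)
            coef = du_ddq * g_anti * ds / ct_cache.r_oo
            o_idx = np.arange(0, config.n_atoms, 3)
            for ip, (mi, mj) in enumerate(ct_cache.pairs):
                if coef[ip] == 0.0:
                    continue
                doo = ct_cache.d_oo[ip]          # r_OJ − r_OI, min image
                grad[o_idx[mi]] -= coef[ip] * doo
                grad[o_idx[mj]] += coef[ip] * doo

        breakdown = EnergyBreakdown(u_intra, u_vdw, u_coul, u_ct)
        info = {"charges": qset, "ct": ctset}
        return breakdown, -grad, info

    def energy(self, config: Configuration) -> float:
        return self.evaluate(config)[0].total


def total_energy_and_gradient(config: Configuration,
                              predictor: ChargePredictor,
                              params: ForceFieldParameters | None = None):
    """One-shot evaluation: (EnergyBreakdown, GradientSet, info).

    Convenience wrapper over :class:`ChargeNNForceField` for callers that
    want the forces packaged with their conservation diagnostics.
    """
    breakdown, forces, info = ChargeNNForceField(predictor, params).evaluate(config)
    return breakdown, GradientSet(forces), info
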
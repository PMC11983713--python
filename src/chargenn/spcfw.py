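"""Flexible SPC/Fw water: the fixed-charge counterpart of the neural model.

SPC/Fw is the standard flexible 3-site model: harmonic bonds and angle,
12–6 Lennard-Jones on O–O, and fixed point charges (q_O = −0.82 e,
q_H = +0.41 e).  The published constants use the ½k(Δx)² convention and are
stored that way; internally they are halved to match the package-wide no-½
harmonic convention.

Because the intramolecular terms vanish at (r⁰, θ⁰), the energy of a
minimized monomer is exactly zero, so the dimer interaction energy equals
the minimized dimer energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import (EnergyBreakdown, harmonic_intramolecular,
                     lennard_jones_126)
from .ewald import EwaldSummator, coulomb_cluster
from .system import Configuration
from .units import DEBYE_PER_E_ANGSTROM, KE_COULOMB

__all__ = ["SPCFWParameters", "SPCFWForceField", "spcfw_monomer_dipole",
           "build_monomer", "build_dimer_start", "DimerReport",
           "optimize_dimer", "dimer_report"]


@dataclass
class SPCFWParameters:
    """Published SPC/Fw constants (½k(Δx)² convention for k_b, k_a)."""

    q_o: float = -0.82            # e
    q_h: float = 0.41             # e
    r_oh0: float = 1.012          # Å
    theta0_deg: float = 113.24    # degrees
    k_b: float = 1059.162         # kcal/mol/Å² (½ convention)
    k_a: float = 75.90            # kcal/mol/rad² (½ convention)
    epsilon_oo: float = 0.15539   # kcal/mol
    sigma_oo: float = 3.165492    # Å
    k_e: float = KE_COULOMB
    r_cut: float = 5.5            # Å, nonbonded cutoff under PBC
    switch_width: float = 1.0
    ewald_accuracy: float = 1e-8

    def __post_init__(self) -> None:
        if abs(self.q_o + 2.0 * self.q_h) > 1e-12:
            raise ValueError("SPC/Fw molecule must be neutral: q_O + 2 q_H = 0")

    @property
    def theta0(self) -> float:
        return np.deg2rad(self.theta0_deg)

    def charges(self, config: Configuration) -> np.ndarray:
        return np.where(config.is_oxygen, self.q_o, self.q_h)


def spcfw_monomer_dipole(params: SPCFWParameters | None = None) -> float:
    """|μ| of the equilibrium monomer: 2|q_H| r⁰ cos(θ⁰/2), in Debye."""
    p = params or SPCFWParameters()
    return 2.0 * abs(p.q_h) * p.r_oh0 * np.cos(p.theta0 / 2.0) \
        * DEBYE_PER_E_ANGSTROM


class SPCFWForceField:
    """Energy/force backend for the fixed-charge SPC/Fw model."""

    name = "spcfw"

    def __init__(self, params: SPCFWParameters | None = None):
        self.params = params or SPCFWParameters()
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
        p = self.params
        if config.periodic:
            config.validate_cell(p.r_cut)
        u_intra, g_intra = harmonic_intramolecular(
            config, 0.5 * p.k_b, 0.5 * p.k_a, p.r_oh0, p.theta0)
        u_lj, g_lj = lennard_jones_126(
            config, p.epsilon_oo, p.sigma_oo,
            r_cut=p.r_cut if config.periodic else None,
            switch_width=p.switch_width)
        q = p.charges(config)
        if config.periodic:
            u_coul, _, f_coul = self._get_ewald(config.cell).energy(
                config.positions, q, config.molecule_index)
        else:
            u_coul, _, f_coul = coulomb_cluster(
                config.positions, q, config.molecule_index, p.k_e)
        breakdown = EnergyBreakdown(u_intra, u_lj, u_coul, 0.0)
        forces = -(g_intra + g_lj) + f_coul
        from .charges import ChargeSet
        return breakdown, forces, {"charges": ChargeSet(q, 0.0, True)}

    def energy(self, config: Configuration) -> float:
        return self.evaluate(config)[0].total


# ---------------------------------------------------------------------------
# geometry builders and the dimer workflow
# ---------------------------------------------------------------------------

def build_monomer(r_oh: float = 1.012, theta_deg: float = 113.24,
                  center=(0.0, 0.0, 0.0)) -> Configuration:
    """One water molecule in the xy-plane, bisector along +x."""
    half = np.deg2rad(theta_deg) / 2.0
    o = np.asarray(center, dtype=float)
    h1 = o + r_oh * np.array([np.cos(half), np.sin(half), 0.0])
    h2 = o + r_oh * np.array([np.cos(half), -np.sin(half), 0.0])
    return Configuration(np.array(["O", "H", "H"], dtype=object),
                         np.vstack([o, h1, h2]))


def build_dimer_start(r_oo: float = 2.9) -> Configuration:
    """Hydrogen-bonded start: molecule 0 donates an H to molecule 1's O.

    The donor O sits at the origin with one O–H bond along +x toward the
    acceptor O at (r_oo, 0, 0); the acceptor bisector is tilted out of the
    donor axis roughly as in the experimental dimer.
    """
    half = np.deg2rad(113.24) / 2.0
    r = 1.012
    d_o = np.zeros(3)
    d_h1 = np.array([r, 0.0, 0.0])
    ang = np.deg2rad(113.24)
    d_h2 = r * np.array([np.cos(ang), np.sin(ang), 0.0])
    a_o = np.array([r_oo, 0.0, 0.0])
    tilt = np.deg2rad(120.0)
    bis = np.array([np.cos(tilt), 0.0, np.sin(tilt)])   # acceptor bisector
    perp = np.array([-np.sin(tilt), 0.0, np.cos(tilt)])
    a_h1 = a_o + r * (np.cos(half) * bis + np.sin(half) * perp)
    a_h2 = a_o + r * (np.cos(half) * bis - np.sin(half) * perp)
    return Configuration(
        np.array(["O", "H", "H", "O", "H", "H"], dtype=object),
        np.vstack([d_o, d_h1, d_h2, a_o, a_h1, a_h2]))


@dataclass
class DimerReport:
    """Optimized-dimer observables.

    ``e_int`` is the intermolecular energy (vdW + Coulomb) at the minimum —
    the standard dimer interaction energy.  The harmonic strain the two
    monomers accept to reach that minimum is reported separately; the total
    relative to two relaxed monomers is ``e_int + e_strain`` (the relaxed
    monomer energy is zero by construction).
    """

    r_oo: float              # Å
    theta_a_deg: float       # acceptor angle, degrees
    e_int: float             # kcal/mol, intermolecular part
    mu_total: float          # Debye
    e_strain: float = 0.0    # kcal/mol, intramolecular deformation
    converged: bool = True
    max_force: float = 0.0
    configuration: Configuration = None


def identify_donor_acceptor(config: Configuration) -> tuple[int, int]:
    """Donor = molecule owning the H closest to the other molecule's O."""
    pos = config.positions
    contacts = []
    for donor, acceptor in ((0, 1), (1, 0)):
        o_other = pos[3 * acceptor]
        d = min(np.linalg.norm(pos[3 * donor + k] - o_other) for k in (1, 2))
        contacts.append((d, donor, acceptor))
    _, donor, acceptor = min(contacts)
    return donor, acceptor


def acceptor_angle(config: Configuration) -> float:
    """θ_A: angle between the acceptor HOH bisector and the O–O axis, deg.

    The bisector points from the acceptor O away from its hydrogens (toward
    the lone-pair side facing the donor); the axis points from the acceptor
    O to the donor O.
    """
    donor, acceptor = identify_donor_acceptor(config)
    pos = config.positions
    o_a = pos[3 * acceptor]
    u1 = pos[3 * acceptor + 1] - o_a
    u2 = pos[3 * acceptor + 2] - o_a
    bis = -(u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2))
    bis /= np.linalg.norm(bis)
    axis = pos[3 * donor] - o_a
    axis /= np.linalg.norm(axis)
    return float(np.degrees(np.arccos(np.clip(bis @ axis, -1.0, 1.0))))


def total_dipole(config: Configuration, charges: np.ndarray) -> float:
    """|Σ q_i r_i| in Debye (origin-free for a neutral system)."""
    mu = np.sum(np.asarray(charges)[:, None] * config.positions, axis=0)
    return float(np.linalg.norm(mu)) * DEBYE_PER_E_ANGSTROM


def optimize_dimer(params: SPCFWParameters | None = None,
                   start: Configuration | None = None,
                   tol: float = 1e-6) -> DimerReport:
    """Quasi-Newton minimization of the SPC/Fw dimer + observables."""
    from .md import minimize
    p = params or SPCFWParameters()
    ff = SPCFWForceField(p)
    start = start or build_dimer_start()
    result = minimize(start, ff, tol=tol)
    return dimer_report(result.configuration, ff,
                        converged=result.converged,
                        max_force=result.max_force)


def dimer_report(config: Configuration, ff: SPCFWForceField,
                 converged: bool = True, max_force: float = 0.0) -> DimerReport:
    breakdown, _, info = ff.evaluate(config)
    r_oo = float(np.linalg.norm(config.positions[3] - config.positions[0]))
    return DimerReport(
        r_oo=r_oo,
        theta_a_deg=acceptor_angle(config),
        e_int=breakdown.vdw + breakdown.coulomb,
        mu_total=total_dipole(config, info["charges"].charges),
        e_strain=breakdown.intra,
        converged=converged, max_force=max_force, configuration=config)
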
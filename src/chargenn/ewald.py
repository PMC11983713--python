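"""Point-charge electrostatics: cluster direct sums and Ewald summation.

The Ewald splitting is the standard real + reciprocal + self decomposition
for orthorhombic cells with tinfoil boundary conditions.  The splitting
parameter α and the reciprocal-space extent are chosen from a single
accuracy target so that the result is independent of α within that target.
Intramolecular (excluded) pairs are skipped in real space and the erf
complement they contribute in reciprocal space is removed explicitly.

Besides energies and forces, both routines return the per-site potential
∂U/∂q_i, which the dynamic-charge force chain rule consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf, erfc, erfcinv

from .units import KE_COULOMB

__all__ = ["coulomb_cluster", "EwaldSummator", "NonNeutralError"]


class NonNeutralError(ValueError):
    """Ewald summation requires a neutral charge set (call neutralize first)."""


def coulomb_cluster(positions: np.ndarray, charges: np.ndarray,
                    molecule_index: np.ndarray, k_e: float = KE_COULOMB):
    """Direct-sum Coulomb energy of a cluster, intermolecular pairs only.

    Returns (U, φ, forces) with φ_i = ∂U/∂q_i (the electrostatic potential
    at site i scaled by k_e) and forces = −∂U/∂R.
    """
    pos = np.asarray(positions, dtype=float)
    q = np.asarray(charges, dtype=float)
    mol = np.asarray(molecule_index)
    d = pos[None, :, :] - pos[:, None, :]
    r = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(r, np.inf)
    mask = (mol[:, None] != mol[None, :]).astype(float)
    inv_r = mask / r
    qq = np.outer(q, q)
    u = 0.5 * k_e * np.sum(qq * inv_r)
    phi = k_e * inv_r @ q
    # pair force: −dU/dR_i = −k_e q_i q_j (−1/r²)·(−d_ij/r) summed over j
    coef = k_e * qq * mask / r ** 3
    forces = np.einsum("ij,ijx->ix", coef, -d)
    return u, phi, forces


@dataclass
class EwaldSummator:
    """Reusable Ewald machinery for one orthorhombic cell.

    Parameters
    ----------
    cell : (3,) box lengths, Å.
    r_cut : real-space cutoff, Å (must satisfy r_cut ≤ min(L)/2; default
        0.49·min(L)).
    accuracy : relative truncation target for both the real-space tail and
        the reciprocal-space Gaussian (default 1e−8).
    alpha : optional explicit splitting parameter, Å⁻¹ (overrides the
        accuracy-derived value; the energy must not depend on it within the
        accuracy target).
    """

    cell: np.ndarray
    r_cut: float | None = None
    accuracy: float = 1e-8
    k_e: float = KE_COULOMB
    alpha: float | None = None

    def __post_init__(self) -> None:
        self.cell = np.asarray(self.cell, dtype=float).reshape(3)
        if self.r_cut is None:
            self.r_cut = 0.49 * float(self.cell.min())
        if self.r_cut > 0.5 * self.cell.min() + 1e-12:
            raise ValueError("real-space cutoff exceeds half the box")
        if self.alpha is None:
            self.alpha = float(erfcinv(self.accuracy)) / self.r_cut
        kmax = 2.0 * self.alpha * np.sqrt(np.log(1.0 / self.accuracy))
        nmax = np.ceil(kmax * self.cell / (2.0 * np.pi)).astype(int)
        # half reciprocal space (+k and −k contribute equally)
        ns = []
        for nx in range(-nmax[0], nmax[0] + 1):
            for ny in range(-nmax[1], nmax[1] + 1):
                for nz in range(-nmax[2], nmax[2] + 1):
                    if (nx, ny, nz) == (0, 0, 0):
                        continue
                    if nx < 0 or (nx == 0 and (ny < 0 or (ny == 0 and nz < 0))):
                        continue
                    ns.append((nx, ny, nz))
        ns = np.asarray(ns, dtype=float)
        k = 2.0 * np.pi * ns / self.cell
        k2 = np.sum(k * k, axis=1)
        keep = k2 <= kmax * kmax
        self._kvecs = k[keep]
        self._ak = np.exp(-k2[keep] / (4.0 * self.alpha ** 2)) / k2[keep]
        self._n_int = ns[keep].astype(int)

    # -- pieces ------------------------------------------------------------
    def _real_space(self, pos, q, excluded):
        d = pos[None, :, :] - pos[:, None, :]
        d -= np.round(d / self.cell) * self.cell
        r = np.linalg.norm(d, axis=-1)
        np.fill_diagonal(r, np.inf)
        include = (~excluded) & (r <= self.r_cut)
        inc = include.astype(float)
        a = self.alpha
        sc = np.where(include, erfc(a * np.where(np.isfinite(r), r, 1.0)), 0.0) / r
        qq = np.outer(q, q)
        u = 0.5 * self.k_e * np.sum(qq * sc)
        phi = self.k_e * sc @ q
        # dU/dr of the pair term: q_i q_j [−erfc(αr)/r² − 2α/√π e^{−α²r²}/r]
        dudr = np.where(include,
                        -sc / r - inc * (2.0 * a / np.sqrt(np.pi))
                        * np.exp(-(a * np.where(np.isfinite(r), r, 1.0)) ** 2) / r,
                        0.0)
        coef = self.k_e * qq * np.where(include, dudr / r, 0.0)
        forces = np.einsum("ij,ijx->ix", coef, d)
        # excluded pairs: remove the reciprocal-space erf part
        excl = excluded.copy()
        np.fill_diagonal(excl, False)
        if excl.any():
            rr = np.where(np.isfinite(r), r, 1.0)
            sc_e = np.where(excl, erf(a * rr) / rr, 0.0)
            u -= 0.5 * self.k_e * np.sum(qq * sc_e)
            phi -= self.k_e * sc_e @ q
            dudr_e = np.where(
                excl,
                (2.0 * a / np.sqrt(np.pi)) * np.exp(-(a * rr) ** 2) / rr
                - sc_e / rr, 0.0)
            coef_e = self.k_e * qq * np.where(excl, dudr_e / rr, 0.0)
            forces += np.einsum("ij,ijx->ix", -coef_e, d)
        return u, phi, forces

    def _phase_table(self, pos):
        """e^{ik·r} for every stored k via per-axis integer powers."""
        n = len(pos)
        tables = []
        for ax in range(3):
            nmax = int(self._n_int[:, ax].max(initial=0))
            nmin = int(self._n_int[:, ax].min(initial=0))
            span = max(nmax, -nmin)
            p = np.empty((span + 1, n), dtype=complex)
            p[0] = 1.0
            if span:
                base = np.exp(2j * np.pi * pos[:, ax] / self.cell[ax])
                for m in range(1, span + 1):
                    p[m] = p[m - 1] * base
            full = np.concatenate([np.conj(p[1:][::-1]), p], axis=0)
            tables.append((full, span))
        eik = np.empty((len(self._n_int), n), dtype=complex)
        (px, sx), (py, sy), (pz, sz) = tables
        eik = px[self._n_int[:, 0] + sx] \
            * py[self._n_int[:, 1] + sy] \
            * pz[self._n_int[:, 2] + sz]
        return eik

    def _reciprocal(self, pos, q):
        vol = float(np.prod(self.cell))
        eik = self._phase_table(pos)                      # (K, N)
        s = eik @ q                                       # (K,)
        pref = self.k_e * (2.0 * np.pi / vol)
        # ×2: half space stands for ±k
        u = 2.0 * pref * np.sum(self._ak * np.abs(s) ** 2)
        zi = eik * np.conj(s)[:, None]                    # (K, N)
        phi = 2.0 * pref * 2.0 * (self._ak @ zi.real)
        # F_i = 2·pref Σ_k a_k·2 q_i k Im[e^{ik r_i} S*]
        fk = 2.0 * pref * 2.0 * ((self._ak[:, None] * zi.imag).T @ self._kvecs)
        forces = q[:, None] * fk
        return u, phi, forces

    def _self_term(self, q):
        u = -self.k_e * self.alpha / np.sqrt(np.pi) * np.sum(q * q)
        phi = -2.0 * self.k_e * self.alpha / np.sqrt(np.pi) * q
        return u, phi

    # -- public ------------------------------------------------------------
    def energy(self, positions: np.ndarray, charges: np.ndarray,
               molecule_index: np.ndarray | None = None,
               neutrality_tol: float = 1e-8):
        """Total Ewald energy, per-site ∂U/∂q and forces.

        ``molecule_index`` marks intramolecular pairs as excluded; None means
        no exclusions (plain point-charge lattice).
        """
        pos = np.asarray(positions, dtype=float)
        q = np.asarray(charges, dtype=float)
        if abs(q.sum()) > neutrality_tol:
            raise NonNeutralError(
                f"net charge {q.sum():.3e} e: neutralize the charge set "
                "(subtract Δq = Σq/N) before Ewald summation")
        n = len(q)
        if molecule_index is None:
            excluded = np.zeros((n, n), dtype=bool)
        else:
            mol = np.asarray(molecule_index)
            excluded = mol[:, None] == mol[None, :]
        u_r, phi_r, f_r = self._real_space(pos, q, excluded)
        u_k, phi_k, f_k = self._reciprocal(pos, q)
        u_s, phi_s = self._self_term(q)
        return (u_r + u_k + u_s, phi_r + phi_k + phi_s, f_r + f_k)
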
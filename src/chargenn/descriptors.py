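"""Interaction-classified functions (ICFs) and their analytic derivatives.

An ICF is a radial, element-pair-resolved, cutoff-smoothed descriptor of an
atom's local environment,

    f_i^{αβ} = Σ_{j ∈ class β} exp(−k_f · r_ij) · s_c(r_ij),

with the smooth cutoff  s_c(r) = ½[cos(π r / r_c) + 1]  for r ≤ r_c and 0
beyond.  Three decay parameters k_f per interaction class resolve short-,
mid- and long-range structure.  ICFs are translationally, rotationally and
permutationally invariant and require no angular terms.

Two feature sets are built from ICFs:

* **Charge features** (24 slots per atom): for each k_f, the atom's
  intramolecular ICFs (classes O, H), its intermolecular ICFs (O, H), and
  the intermolecular ICFs of the two other atoms of its molecule.  For an
  oxygen center the two hydrogen mates are interchangeable, so their ICFs
  enter through the elementary symmetric polynomials (sum, product), which
  keeps the descriptor smooth and exactly invariant under H relabeling.

* **CT features** (36 slots per molecule pair IJ): for each k_f, ICFs of
  each atom of I restricted to neighbors in J (classes O, H) and vice versa,
  evaluated with the CT cutoff.  The two hydrogens of each molecule are
  symmetrized the same way.  Swapping I and J swaps the two 18-slot halves
  blockwise.

Besides feature values, this module provides the exact reverse-mode adjoint
(χ · dF/dR for an arbitrary cofactor χ), which is what the force evaluation
consumes, and dense per-slot Jacobians for verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import Configuration, displacement_matrix

__all__ = [
    "ICFSpec",
    "cutoff_weight",
    "cutoff_weight_derivative",
    "icf_value",
    "charge_features",
    "charge_feature_vector",
    "charge_feature_adjoint",
    "charge_feature_jacobian",
    "ct_pairs",
    "ct_features",
    "ct_feature_vector",
    "ct_feature_adjoint",
    "ct_feature_jacobian",
    "N_CHARGE_FEATURES",
    "N_CT_FEATURES",
]

#: slots per k_f in the charge feature block:
#: [intra_O, intra_H, inter_O, inter_H, mate1_O, mate1_H, mate2_O, mate2_H]
_CHARGE_BLOCK = 8
#: slots per k_f and per side in the CT block:
#: [O_vs_O, O_vs_H, Hsum_vs_O, Hsum_vs_H, Hprod_vs_O, Hprod_vs_H]
_CT_BLOCK = 6

N_CHARGE_FEATURES = 3 * _CHARGE_BLOCK   # 24 with the default three k_f
N_CT_FEATURES = 2 * 3 * _CT_BLOCK       # 36


@dataclass(frozen=True)
class ICFSpec:
    """Descriptor hyper-parameters.

    Parameters
    ----------
    r_c : float
        Radial cutoff for charge features, Å.  Default 4.4 Å, the radius at
        which ~24 surrounding molecules converge the charges.
    k_f_list : tuple of float
        Decay parameters, Å⁻¹, positive and strictly increasing.
    ct_cutoff : float
        Cutoff for charge-transfer features and pair selection, Å.  Default
        5.5 Å, where dimer CT has decayed to ~1e−5 e.
    """

    r_c: float = 4.4
    k_f_list: tuple[float, ...] = (0.5, 1.0, 2.0)
    ct_cutoff: float = 5.5

    def __post_init__(self) -> None:
        if self.r_c <= 0:
            raise ValueError("r_c must be positive")
        if self.ct_cutoff <= 0:
            raise ValueError("ct_cutoff must be positive")
        kf = np.asarray(self.k_f_list, dtype=float)
        if kf.ndim != 1 or len(kf) == 0:
            raise ValueError("k_f_list must be a non-empty sequence")
        if np.any(kf <= 0) or np.any(np.diff(kf) <= 0):
            raise ValueError("k_f values must be positive and strictly increasing")

    @property
    def n_kf(self) -> int:
        return len(self.k_f_list)

    @property
    def n_charge_features(self) -> int:
        return self.n_kf * _CHARGE_BLOCK

    @property
    def n_ct_features(self) -> int:
        return 2 * self.n_kf * _CT_BLOCK

    @property
    def max_cutoff(self) -> float:
        return max(self.r_c, self.ct_cutoff)


def cutoff_weight(r, r_c: float):
    """Smooth selection weight s_c(r) = ½[cos(π r/r_c) + 1], 0 beyond r_c."""
    if r_c <= 0:
        raise ValueError("r_c must be positive")
    r = np.asarray(r, dtype=float)
    out = np.where(r <= r_c, 0.5 * (np.cos(np.pi * np.minimum(r, r_c) / r_c) + 1.0), 0.0)
    return out if out.ndim else float(out)


def cutoff_weight_derivative(r, r_c: float):
    """d s_c/dr; vanishes at both r = 0 and r = r_c (C¹ at the cutoff)."""
    if r_c <= 0:
        raise ValueError("r_c must be positive")
    r = np.asarray(r, dtype=float)
    out = np.where(r <= r_c,
                   -0.5 * np.pi / r_c * np.sin(np.pi * np.minimum(r, r_c) / r_c),
                   0.0)
    return out if out.ndim else float(out)


def _pair_weight(r: np.ndarray, k_f: float, r_c: float) -> np.ndarray:
    """w(r) = exp(−k_f r)·s_c(r); zero beyond r_c (and on the inf diagonal)."""
    with np.errstate(over="ignore"):
        w = np.where(np.isfinite(r), np.exp(-k_f * np.where(np.isfinite(r), r, 0.0)), 0.0)
    return w * cutoff_weight(r, r_c)


def _pair_weight_derivative(r: np.ndarray, k_f: float, r_c: float) -> np.ndarray:
    rr = np.where(np.isfinite(r), r, 0.0)
    e = np.where(np.isfinite(r), np.exp(-k_f * rr), 0.0)
    return e * (-k_f * cutoff_weight(r, r_c) + cutoff_weight_derivative(r, r_c))


def icf_value(config: Configuration, center: int, element: str,
              intra: bool, k_f: float, r_c: float) -> float:
    """Single ICF: Σ over atoms j of the stated class, j ≠ center."""
    _, r = displacement_matrix(config)
    mol = config.molecule_index
    same_mol = mol == mol[center]
    sel = (config.species == element) & (same_mol if intra else ~same_mol)
    sel[center] = False
    return float(np.sum(_pair_weight(r[center, sel], k_f, r_c)))


# ---------------------------------------------------------------------------
# charge features
# ---------------------------------------------------------------------------

class _ChargeFeatureCache:
    """Intermediates reused by the adjoint pass."""

    __slots__ = ("config", "spec", "d", "r", "w", "wprime", "intra_mask",
                 "inter_mask", "class_masks", "f_inter", "features")


def charge_features(config: Configuration, spec: ICFSpec = ICFSpec()):
    """Per-atom charge feature matrix (N, 24) plus an adjoint cache."""
    if config.periodic:
        config.validate_cell(spec.max_cutoff)
    n = config.n_atoms
    nk = spec.n_kf
    d, r = displacement_matrix(config)
    mol = config.molecule_index
    same = mol[:, None] == mol[None, :]
    intra = same.copy()
    np.fill_diagonal(intra, False)
    inter = ~same
    is_o = config.is_oxygen
    class_masks = [is_o, ~is_o]              # order: O, H

    w = np.empty((nk, n, n))
    wprime = np.empty((nk, n, n))
    for k, kf in enumerate(spec.k_f_list):
        w[k] = _pair_weight(r, kf, spec.r_c)
        wprime[k] = _pair_weight_derivative(r, kf, spec.r_c)

    # f_[intra|inter][k, e, i] = Σ_j w[k,i,j] mask[i,j] class_e[j]
    f_intra = np.empty((nk, 2, n))
    f_inter = np.empty((nk, 2, n))
    for e, cm in enumerate(class_masks):
        f_intra[:, e, :] = np.einsum("kij,ij,j->ki", w, intra, cm.astype(float))
        f_inter[:, e, :] = np.einsum("kij,ij,j->ki", w, inter, cm.astype(float))

    feats = np.zeros((n, nk, _CHARGE_BLOCK))
    feats[:, :, 0] = f_intra[:, 0, :].T
    feats[:, :, 1] = f_intra[:, 1, :].T
    feats[:, :, 2] = f_inter[:, 0, :].T
    feats[:, :, 3] = f_inter[:, 1, :].T

    # mate blocks: molecule atoms are (o, h1, h2) = rows 3m, 3m+1, 3m+2
    o = np.arange(0, n, 3)
    h1, h2 = o + 1, o + 2
    for e in range(2):
        g1 = f_inter[:, e, h1]               # (nk, M)
        g2 = f_inter[:, e, h2]
        go = f_inter[:, e, o]
        # O center: symmetric functions of the two H mates
        feats[o, :, 4 + e] = (g1 + g2).T
        feats[o, :, 6 + e] = (g1 * g2).T
        # H centers: mate1 = molecule O, mate2 = the other H
        feats[h1, :, 4 + e] = go.T
        feats[h1, :, 6 + e] = g2.T
        feats[h2, :, 4 + e] = go.T
        feats[h2, :, 6 + e] = g1.T

    cache = _ChargeFeatureCache()
    cache.config, cache.spec = config, spec
    cache.d, cache.r, cache.w, cache.wprime = d, r, w, wprime
    cache.intra_mask, cache.inter_mask = intra, inter
    cache.class_masks = class_masks
    cache.f_inter = f_inter
    cache.features = feats.reshape(n, -1)
    return cache.features, cache


def charge_feature_vector(config: Configuration, atom: int,
                          spec: ICFSpec = ICFSpec()) -> np.ndarray:
    """Feature vector of a single atom (see module docstring for layout)."""
    feats, _ = charge_features(config, spec)
    return feats[atom]


def charge_feature_adjoint(cache: _ChargeFeatureCache, chi: np.ndarray) -> np.ndarray:
    """Σ_{i,s} χ[i,s] · dF[i,s]/dR  →  (N, 3).

    χ is an arbitrary cofactor array of shape (N, n_features); for force
    evaluation it is (∂U/∂q_i)(∂q_i/∂F_{i,s}).
    """
    config, spec = cache.config, cache.spec
    n, nk = config.n_atoms, spec.n_kf
    chi = chi.reshape(n, nk, _CHARGE_BLOCK)

    # fold mate slots back onto per-atom intermolecular cofactors
    c_intra = np.empty((nk, 2, n))
    c_inter = np.empty((nk, 2, n))
    o = np.arange(0, n, 3)
    h1, h2 = o + 1, o + 2
    for e in range(2):
        c_intra[:, e, :] = chi[:, :, 0 + e].T
        c_inter[:, e, :] = chi[:, :, 2 + e].T
        g1 = cache.f_inter[:, e, h1]
        g2 = cache.f_inter[:, e, h2]
        # O center's symmetric mate slots distribute onto its two hydrogens
        c_inter[:, e, h1] += chi[o, :, 4 + e].T + chi[o, :, 6 + e].T * g2
        c_inter[:, e, h2] += chi[o, :, 4 + e].T + chi[o, :, 6 + e].T * g1
        # H centers reference the molecule O and the sibling H directly
        c_inter[:, e, o] += chi[h1, :, 4 + e].T + chi[h2, :, 4 + e].T
        c_inter[:, e, h2] += chi[h1, :, 6 + e].T
        c_inter[:, e, h1] += chi[h2, :, 6 + e].T

    # C[k,i,j]: cofactor of w_k(r_ij) with center i, neighbor j
    grad = np.zeros((n, 3))
    intra_f = cache.intra_mask.astype(float)
    inter_f = cache.inter_mask.astype(float)
    for k in range(nk):
        C = np.zeros((n, n))
        for e, cm in enumerate(cache.class_masks):
            C += (np.outer(c_intra[k, e], cm) * intra_f
                  + np.outer(c_inter[k, e], cm) * inter_f)
        # symmetrized pair cofactor acting through dr_ij/dR
        G = (C + C.T) * cache.wprime[k]
        with np.errstate(invalid="ignore"):
            coef = np.where(np.isfinite(cache.r), G / cache.r, 0.0)
        grad += np.einsum("ij,ijx->ix", coef, -cache.d)
    return grad


def charge_feature_jacobian(config: Configuration, atom: int,
                            spec: ICFSpec = ICFSpec()) -> np.ndarray:
    """Dense Jacobian dF[atom]/dR of shape (n_features, N, 3)."""
    feats, cache = charge_features(config, spec)
    nf = feats.shape[1]
    jac = np.empty((nf, config.n_atoms, 3))
    for s in range(nf):
        chi = np.zeros_like(feats)
        chi[atom, s] = 1.0
        jac[s] = charge_feature_adjoint(cache, chi)
    return jac


# ---------------------------------------------------------------------------
# charge-transfer features
# ---------------------------------------------------------------------------

class _CTFeatureCache:
    __slots__ = ("config", "spec", "pairs", "w", "wprime", "d", "r",
                 "features", "r_oo", "d_oo")


def ct_pairs(config: Configuration, spec: ICFSpec = ICFSpec()) -> np.ndarray:
    """Molecule pairs (I < J) whose O–O minimum-image distance ≤ ct_cutoff."""
    if config.periodic:
        config.validate_cell(spec.max_cutoff)
    _, r = displacement_matrix(config)
    o = np.arange(0, config.n_atoms, 3)
    roo = r[np.ix_(o, o)]
    ii, jj = np.where(np.triu(roo <= spec.ct_cutoff, k=1))
    return np.column_stack([ii, jj])


def ct_features(config: Configuration, spec: ICFSpec = ICFSpec(),
                pairs: np.ndarray | None = None):
    """CT feature matrix (P, 36) for all in-range molecule pairs + cache."""
    if pairs is None:
        pairs = ct_pairs(config, spec)
    nk = spec.n_kf
    d_all, r_all = displacement_matrix(config)
    p = len(pairs)
    o = np.arange(0, config.n_atoms, 3)
    rows = o[pairs[:, 0], None] + np.arange(3) if p else np.zeros((0, 3), int)
    cols = o[pairs[:, 1], None] + np.arange(3) if p else np.zeros((0, 3), int)
    ii = rows[:, :, None]                    # (P, 3, 1)
    jj = cols[:, None, :]                    # (P, 1, 3)
    r_store = r_all[ii, jj]                  # (P, 3, 3) rows I atoms, cols J
    d_store = d_all[ii, jj]                  # (P, 3, 3, 3)
    kf = np.asarray(spec.k_f_list)[None, :, None, None]
    rr = r_store[:, None, :, :]
    sc = cutoff_weight(r_store, spec.ct_cutoff)[:, None]
    scp = cutoff_weight_derivative(r_store, spec.ct_cutoff)[:, None]
    e = np.exp(-kf * np.where(np.isfinite(rr), rr, 0.0))
    e = np.where(np.isfinite(rr), e, 0.0)
    w_store = e * sc                         # (P, nk, 3, 3)
    wp_store = e * (-kf * sc + scp)

    feats = np.zeros((p, 2, nk, _CT_BLOCK))
    for side, ww in enumerate((w_store, w_store.transpose(0, 1, 3, 2))):
        # ww[..., a, b]: a = atoms of this side (O, H1, H2); b = other side
        vs_o = ww[..., :, 0]
        vs_h = ww[..., :, 1] + ww[..., :, 2]
        feats[:, side, :, 0] = vs_o[..., 0]
        feats[:, side, :, 1] = vs_h[..., 0]
        feats[:, side, :, 2] = vs_o[..., 1] + vs_o[..., 2]
        feats[:, side, :, 3] = vs_h[..., 1] + vs_h[..., 2]
        feats[:, side, :, 4] = vs_o[..., 1] * vs_o[..., 2]
        feats[:, side, :, 5] = vs_h[..., 1] * vs_h[..., 2]

    cache = _CTFeatureCache()
    cache.config, cache.spec, cache.pairs = config, spec, pairs
    cache.w, cache.wprime, cache.d, cache.r = w_store, wp_store, d_store, r_store
    cache.features = feats.reshape(p, 2 * nk * _CT_BLOCK)
    cache.d_oo = d_store[:, 0, 0, :] if p else np.zeros((0, 3))
    cache.r_oo = r_store[:, 0, 0] if p else np.zeros(0)
    return cache.features, cache


def ct_feature_vector(config: Configuration, mol_i: int, mol_j: int,
                      spec: ICFSpec = ICFSpec()) -> np.ndarray | None:
    """CT feature vector for the ordered pair (I, J); None beyond the cutoff.

    The unordered machinery stores pairs as I < J; for J < I the two halves
    are swapped, which is the exact layout symmetry of the descriptor.
    """
    swap = mol_i > mol_j
    lo, hi = sorted((mol_i, mol_j))
    feats, cache = ct_features(config, spec, pairs=np.array([[lo, hi]]))
    if cache.r_oo[0] > spec.ct_cutoff:
        return None
    f = feats[0]
    if swap:
        half = len(f) // 2
        f = np.concatenate([f[half:], f[:half]])
    return f


def _ct_chi_to_pair_cofactors(cache: _CTFeatureCache, chi: np.ndarray) -> np.ndarray:
    """Fold per-slot cofactors into cofactors on w[k, a, b] per pair."""
    p = len(cache.pairs)
    nk = cache.spec.n_kf
    chi = chi.reshape(p, 2, nk, _CT_BLOCK)
    cof = np.zeros((p, nk, 3, 3))
    for side in range(2):
        c = chi[:, side]                     # (P, nk, 6)
        w = cache.w if side == 0 else cache.w.transpose(0, 1, 3, 2)
        add = np.zeros_like(w)
        add[:, :, 0, 0] += c[:, :, 0]
        add[:, :, 0, 1] += c[:, :, 1]
        add[:, :, 0, 2] += c[:, :, 1]
        for h, other in ((1, 2), (2, 1)):
            add[:, :, h, 0] += c[:, :, 2] + c[:, :, 4] * w[:, :, other, 0]
            hsum_other = w[:, :, other, 1] + w[:, :, other, 2]
            add[:, :, h, 1] += c[:, :, 3] + c[:, :, 5] * hsum_other
            add[:, :, h, 2] += c[:, :, 3] + c[:, :, 5] * hsum_other
        cof += add if side == 0 else add.transpose(0, 1, 3, 2)
    return cof


def ct_feature_adjoint(cache: _CTFeatureCache, chi: np.ndarray) -> np.ndarray:
    """Σ_{p,s} χ[p,s] · dF[p,s]/dR  →  (N, 3)."""
    config = cache.config
    grad = np.zeros((config.n_atoms, 3))
    if len(cache.pairs) == 0:
        return grad
    cof = _ct_chi_to_pair_cofactors(cache, chi)
    o = np.arange(0, config.n_atoms, 3)
    g = (cof * cache.wprime).sum(axis=1)             # (P, 3, 3)
    with np.errstate(invalid="ignore"):
        coef = np.where(cache.r > 0, g / cache.r, 0.0)
    pair_grad = coef[:, :, :, None] * cache.d        # d = r_b − r_a (J − I)
    rows = (o[cache.pairs[:, 0], None] + np.arange(3)).ravel()
    cols = (o[cache.pairs[:, 1], None] + np.arange(3)).ravel()
    np.add.at(grad, rows, -pair_grad.sum(axis=2).reshape(-1, 3))
    np.add.at(grad, cols, pair_grad.sum(axis=1).reshape(-1, 3))
    return grad


def ct_feature_jacobian(config: Configuration, mol_i: int, mol_j: int,
                        spec: ICFSpec = ICFSpec()) -> np.ndarray:
    """Dense Jacobian dF(IJ)/dR of shape (n_ct_features, N, 3) for I < J."""
    if mol_i > mol_j:
        raise ValueError("use the ordered pair I < J (halves swap otherwise)")
    feats, cache = ct_features(config, spec, pairs=np.array([[mol_i, mol_j]]))
    nf = feats.shape[1]
    jac = np.empty((nf, config.n_atoms, 3))
    for s in range(nf):
        chi = np.zeros_like(feats)
        chi[0, s] = 1.0
        jac[s] = ct_feature_adjoint(cache, chi)
    return jac
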
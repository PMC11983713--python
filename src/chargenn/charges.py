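"""Charge sets, neutralization, CM5 mapping, and the neural predictors.

The ChargePredictor bundles the element-specific charge networks (O and H),
the pair charge-transfer (CT) network, their feature standardizers and the
descriptor hyper-parameters.  Atomic charges are predicted per atom from the
24-slot charge features; pair CT is predicted antisymmetrically,

    δq_IJ = ½ [g(F_IJ) − g(F_JI)] · S(r_OO),

so δq_IJ = −δq_JI holds by construction.  S is a C² switching function on
the O–O distance over the last Å before the CT cutoff; it guarantees that
δq — and through it the CT energy — goes to zero exactly and smoothly as a
pair leaves the CT range.  Positive δq_IJ means electron flow I → J.

Because the per-atom networks do not constrain the total charge, the whole
system is neutralized by the uniform shift Δq = Σ_i q_i / N before any
electrostatics; Δq is typically of order 1e−4 e.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import (ICFSpec, charge_features, ct_features)
from .network import DenseNetwork, Standardizer
from .system import Configuration

__all__ = [
    "ChargeSet", "CTSet", "CM5Params", "neutralize", "cm5_from_hirshfeld",
    "ChargePredictor", "ct_switch", "ct_switch_derivative",
]


@dataclass
class ChargeSet:
    """Per-atom charges (e) with the record of the neutralization shift."""

    charges: np.ndarray
    delta_q: float = 0.0
    neutralized: bool = False

    @property
    def total(self) -> float:
        return float(np.sum(self.charges))


@dataclass
class CTSet:
    """Per-molecule-pair transferred charge δq_IJ (e), pairs stored I < J."""

    pairs: np.ndarray           # (P, 2)
    delta_q: np.ndarray         # (P,) signed: positive = electron flow I→J

    def molecular_net_charges(self, n_molecules: int) -> np.ndarray:
        """Net molecular charge from CT alone: molecule I loses −δq_IJ of
        electrons to J, i.e. gains charge +δq_IJ."""
        net = np.zeros(n_molecules)
        np.add.at(net, self.pairs[:, 0], self.delta_q)
        np.add.at(net, self.pairs[:, 1], -self.delta_q)
        return net


def neutralize(charge_set: ChargeSet) -> ChargeSet:
    """Subtract Δq = Σq/N from every atom so the system is exactly neutral."""
    q = np.asarray(charge_set.charges, dtype=float)
    if q.size == 0:
        raise ValueError("cannot neutralize an empty charge set")
    dq = float(q.sum() / q.size)
    return ChargeSet(q - dq, delta_q=dq, neutralized=True)


# ---------------------------------------------------------------------------
# CM5 mapping of Hirshfeld charges
# ---------------------------------------------------------------------------

@dataclass
class CM5Params:
    """CM5 model constants for the elements handled (H, O).

    ``atomic_d`` holds the single-atom D_Z parameters and ``pair_d`` the
    pairwise overrides (antisymmetric, stored for Z < Z′); the correction is
    T(Z,Z′)·exp(−α(r − R_Z − R_Z′)).
    """

    alpha: float = 2.474                     # Å⁻¹
    atomic_d: dict = field(default_factory=lambda: {"H": 0.0056, "O": -0.0360})
    pair_d: dict = field(default_factory=lambda: {("H", "O"): 0.1671})
    radii: dict = field(default_factory=lambda: {"H": 0.32, "O": 0.63})

    def t_pair(self, zi: str, zj: str) -> float:
        if zi == zj:
            return 0.0
        if (zi, zj) in self.pair_d:
            return self.pair_d[(zi, zj)]
        if (zj, zi) in self.pair_d:
            return -self.pair_d[(zj, zi)]
        try:
            return self.atomic_d[zi] - self.atomic_d[zj]
        except KeyError as err:
            raise KeyError(f"no CM5 parameters for element {err}") from err


def cm5_from_hirshfeld(hirshfeld: np.ndarray, config: Configuration,
                       params: CM5Params | None = None) -> ChargeSet:
    """q_i^CM5 = q_i^HPA + Σ_{j≠i} T(Z_i,Z_j)·exp(−α(r_ij − R_i − R_j)).

    The pairwise antisymmetry of T makes the mapping conserve the total
    charge exactly.
    """
    params = params or CM5Params()
    q = np.asarray(hirshfeld, dtype=float)
    if q.shape != (config.n_atoms,):
        raise ValueError("one Hirshfeld charge per atom is required")
    for s in set(config.species):
        if s not in params.radii:
            raise KeyError(f"no CM5 parameters for element {s!r}")
    out = q.copy()
    pos, sp = config.positions, config.species
    for i in range(config.n_atoms):
        for j in range(config.n_atoms):
            if i == j:
                continue
            t = params.t_pair(sp[i], sp[j])
            if t == 0.0:
                continue
            r = float(np.linalg.norm(pos[j] - pos[i]))
            out[i] += t * np.exp(-params.alpha * (r - params.radii[sp[i]]
                                                  - params.radii[sp[j]]))
    return ChargeSet(out)


# ---------------------------------------------------------------------------
# CT distance switch
# ---------------------------------------------------------------------------

def _smoothstep(t: np.ndarray) -> np.ndarray:
    """Quintic 1→0 smoothstep on t ∈ [0, 1] (C² at both ends)."""
    t = np.clip(t, 0.0, 1.0)
    return 1.0 - t ** 3 * (10.0 - 15.0 * t + 6.0 * t * t)


def _smoothstep_derivative(t: np.ndarray) -> np.ndarray:
    inside = (t > 0.0) & (t < 1.0)
    t = np.clip(t, 0.0, 1.0)
    return np.where(inside, -30.0 * t * t * (1.0 - t) ** 2, 0.0)


def ct_switch(r_oo, cutoff: float, width: float = 1.0):
    """Distance taper of δq: 1 below cutoff − width, 0 at the cutoff."""
    return _smoothstep((np.asarray(r_oo, float) - (cutoff - width)) / width)


def ct_switch_derivative(r_oo, cutoff: float, width: float = 1.0):
    return _smoothstep_derivative(
        (np.asarray(r_oo, float) - (cutoff - width)) / width) / width


# ---------------------------------------------------------------------------
# the bundled predictor
# ---------------------------------------------------------------------------

@dataclass
class ChargePredictor:
    """Element-specific charge networks + pair CT network + standardizers."""

    net_o: DenseNetwork
    net_h: DenseNetwork
    net_ct: DenseNetwork
    spec: ICFSpec = ICFSpec()
    x_std_o: Standardizer | None = None
    x_std_h: Standardizer | None = None
    x_std_ct: Standardizer | None = None
    y_std_o: Standardizer | None = None
    y_std_h: Standardizer | None = None
    y_std_ct: Standardizer | None = None
    ct_switch_width: float = 1.0

    def __post_init__(self) -> None:
        nf, nct = self.spec.n_charge_features, self.spec.n_ct_features
        self.x_std_o = self.x_std_o or Standardizer.identity(nf)
        self.x_std_h = self.x_std_h or Standardizer.identity(nf)
        self.x_std_ct = self.x_std_ct or Standardizer.identity(nct)
        self.y_std_o = self.y_std_o or Standardizer.identity(1)
        self.y_std_h = self.y_std_h or Standardizer.identity(1)
        self.y_std_ct = self.y_std_ct or Standardizer.identity(1)

    @classmethod
    def random(cls, spec: ICFSpec = ICFSpec(), hidden=(64, 64, 64, 64),
               seed: int = 0, init_scale: float = 1.0) -> "ChargePredictor":
        """Seeded random networks (useful for smoke tests and gradient checks)."""
        rng = np.random.default_rng(seed)
        return cls(
            DenseNetwork(spec.n_charge_features, hidden, rng=rng, init_scale=init_scale),
            DenseNetwork(spec.n_charge_features, hidden, rng=rng, init_scale=init_scale),
            DenseNetwork(spec.n_ct_features, hidden, rng=rng, init_scale=init_scale),
            spec=spec)

    # -- atomic charges ----------------------------------------------------
    def raw_charges(self, features: np.ndarray, is_oxygen: np.ndarray) -> np.ndarray:
        q = np.empty(len(features))
        for net, xs, ys, mask in (
                (self.net_o, self.x_std_o, self.y_std_o, is_oxygen),
                (self.net_h, self.x_std_h, self.y_std_h, ~is_oxygen)):
            if mask.any():
                q[mask] = ys.inverse(net.forward(xs.transform(features[mask])))
        return q

    def raw_charges_and_gradients(self, features, is_oxygen):
        """Charges plus dq_i/dF_{i,s} (chain through both standardizers)."""
        q = np.empty(len(features))
        dq = np.empty_like(features)
        for net, xs, ys, mask in (
                (self.net_o, self.x_std_o, self.y_std_o, is_oxygen),
                (self.net_h, self.x_std_h, self.y_std_h, ~is_oxygen)):
            if mask.any():
                y, g = net.value_and_input_gradient(xs.transform(features[mask]))
                q[mask] = ys.inverse(y)
                dq[mask] = g * (ys.std[0] / xs.std)
        return q, dq

    def predict_charges(self, config: Configuration) -> ChargeSet:
        feats, _ = charge_features(config, self.spec)
        return neutralize(ChargeSet(self.raw_charges(feats, config.is_oxygen)))

    # -- pair charge transfer ---------------------------------------------
    def _ct_raw_and_grad(self, feats: np.ndarray, want_grad: bool):
        """Antisymmetrized network output for pair features stored as (I, J).

        Returns g_anti (P,) and, if requested, its gradient with respect to
        the stored (I, J)-ordered feature slots.
        """
        half = feats.shape[1] // 2
        swapped = np.concatenate([feats[:, half:], feats[:, :half]], axis=1)
        xs, ys = self.x_std_ct, self.y_std_ct
        if not want_grad:
            y_ij = self.net_ct.forward(xs.transform(feats))
            y_ji = self.net_ct.forward(xs.transform(swapped))
            return 0.5 * ys.std[0] * (y_ij - y_ji), None
        y_ij, g_ij = self.net_ct.value_and_input_gradient(xs.transform(feats))
        y_ji, g_ji = self.net_ct.value_and_input_gradient(xs.transform(swapped))
        g_ij = g_ij / xs.std
        g_ji = g_ji / xs.std
        # map the swapped-input gradient back to the (I, J) slot order
        g_ji = np.concatenate([g_ji[:, half:], g_ji[:, :half]], axis=1)
        val = 0.5 * ys.std[0] * (y_ij - y_ji)
        grad = 0.5 * ys.std[0] * (g_ij - g_ji)
        return val, grad

    def predict_ct(self, config: Configuration) -> CTSet:
        feats, cache = ct_features(config, self.spec)
        if len(feats) == 0:
            return CTSet(cache.pairs, np.zeros(0))
        raw, _ = self._ct_raw_and_grad(feats, want_grad=False)
        s = ct_switch(cache.r_oo, self.spec.ct_cutoff, self.ct_switch_width)
        return CTSet(cache.pairs, raw * s)

    def predict_pair_ct(self, config: Configuration, mol_i: int, mol_j: int) -> float:
        """δq for one ordered pair; 0 beyond the CT cutoff; δq_IJ = −δq_JI."""
        ct = self.predict_ct(config)
        lo, hi = sorted((mol_i, mol_j))
        sign = 1.0 if mol_i < mol_j else -1.0
        match = (ct.pairs[:, 0] == lo) & (ct.pairs[:, 1] == hi)
        if not match.any():
            return 0.0
        return float(sign * ct.delta_q[match][0])

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        """Self-describing npz archive (layout, standardizers, β, weights)."""
        arrays = {
            "layout": np.asarray(
                "charge features: per k_f [intra_O, intra_H, inter_O, inter_H, "
                "mateSum_O, mateSum_H, mateProd_O, mateProd_H]; "
                "CT features: halves (I, J), per k_f [O_vs_O, O_vs_H, "
                "Hsum_vs_O, Hsum_vs_H, Hprod_vs_O, Hprod_vs_H]"),
            "r_c": np.asarray(self.spec.r_c),
            "k_f_list": np.asarray(self.spec.k_f_list),
            "ct_cutoff": np.asarray(self.spec.ct_cutoff),
            "ct_switch_width": np.asarray(self.ct_switch_width),
        }
        for name, net in (("o_", self.net_o), ("h_", self.net_h), ("ct_", self.net_ct)):
            arrays.update(net.to_arrays(prefix=name))
        for name, st in (("xo", self.x_std_o), ("xh", self.x_std_h),
                         ("xct", self.x_std_ct), ("yo", self.y_std_o),
                         ("yh", self.y_std_h), ("yct", self.y_std_ct)):
            arrays[f"{name}_mean"] = st.mean
            arrays[f"{name}_std"] = st.std
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ChargePredictor":
        with np.load(path, allow_pickle=False) as z:
            arrays = dict(z)
        spec = ICFSpec(float(arrays["r_c"]),
                       tuple(float(k) for k in arrays["k_f_list"]),
                       float(arrays["ct_cutoff"]))
        std = {name: Standardizer(arrays[f"{name}_mean"], arrays[f"{name}_std"])
               for name in ("xo", "xh", "xct", "yo", "yh", "yct")}
        return cls(
            DenseNetwork.from_arrays(arrays, "o_"),
            DenseNetwork.from_arrays(arrays, "h_"),
            DenseNetwork.from_arrays(arrays, "ct_"),
            spec=spec,
            x_std_o=std["xo"], x_std_h=std["xh"], x_std_ct=std["xct"],
            y_std_o=std["yo"], y_std_h=std["yh"], y_std_ct=std["yct"],
            ct_switch_width=float(arrays["ct_switch_width"]))
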
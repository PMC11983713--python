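"""Surrogate charge/CT labels and configuration sampling.

Quantum-chemistry (CM5) reference charges are expensive; this module
replaces them with a closed-form surrogate that has the same statistical
structure the learning pipeline assumes: smooth, local, rigid-motion
invariant, environment-dependent atomic charges, plus pairwise
hydrogen-bond charge transfer that decays to ~1e−5 of its amplitude at the
5.5 Å CT cutoff.  Labels are exactly reproducible from the parameter set
and seed.

    q_H   = q_H^base + a · Σ_{O′ intermolecular} exp(−b·r_HO′)·s_c(r_HO′; r_c)
    q_O   = −(q_H1 + q_H2) + Σ_J δq_IJ                (molecule I's oxygen)
    δq_IJ = c · [ Σ_{H∈I, O_J} − Σ_{H∈J, O_I} ] exp(−λ·r_HO)·s_c(r_HO; r_ct)

δq is antisymmetric by construction; a donor H close to the acceptor O
dominates its side of the difference, so the sign follows the electron-flow
convention (positive = flow I → J).  Optional Gaussian label noise emulates
the scatter of quantum-chemistry reference charges.

Configurations are sampled with gas-phase Langevin MD of water clusters
using the in-repo SPC/Fw backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .charges import ChargeSet, CTSet
from .descriptors import ICFSpec, charge_features, ct_features, cutoff_weight
from .md import run_md
from .spcfw import SPCFWForceField, build_monomer
from .system import Configuration, displacement_matrix

__all__ = ["SurrogateParams", "sample_cluster_configurations",
           "surrogate_charges", "surrogate_ct", "build_cluster",
           "make_training_set", "TrainingSet"]


@dataclass
class SurrogateParams:
    """Parameters of the surrogate label generator.

    Defaults give charge ranges and fluctuation scales resembling CM5 water
    charges (±0.41 e base, polarization responses of a few 1e−3 e) and CT of
    ~1e−3 e per hydrogen bond.
    """

    q_h_base: float = 0.41        # e
    amplitude: float = 0.05       # e, polarization response amplitude
    decay: float = 1.5            # Å⁻¹, polarization decay
    ct_amplitude: float = 0.02    # e
    ct_decay: float = 2.0         # Å⁻¹ → δq(5.5 Å O–O) ≈ 1e−5 · amplitude
    noise: float = 0.002          # e, Gaussian label noise
    seed: int = 0
    r_c: float = 4.4              # Å, polarization cutoff
    r_ct: float = 5.5             # Å, CT cutoff

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.ct_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")

    @property
    def q_o_base(self) -> float:
        return -2.0 * self.q_h_base


def build_cluster(n_molecules: int, seed: int = 0, min_oo: float = 2.6,
                  density_radius_factor: float = 1.45) -> Configuration:
    """Random compact water cluster (rejection-packed, then randomly oriented).

    The radius scales as n^{1/3} at roughly liquid density; used as the
    starting point for sampling MD.
    """
    rng = np.random.default_rng(seed)
    radius = density_radius_factor * n_molecules ** (1.0 / 3.0) + 1.0
    centers = []
    while len(centers) < n_molecules:
        x = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(x) > radius:
            continue
        if centers and np.min(np.linalg.norm(np.asarray(centers) - x, axis=1)) < min_oo:
            continue
        centers.append(x)
    species, positions = [], []
    for c in centers:
        mono = build_monomer(center=(0, 0, 0))
        # random rotation via QR
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        positions.append(mono.positions @ q.T + c)
        species.extend(mono.species)
    return Configuration(np.asarray(species, dtype=object),
                         np.vstack(positions))


def sample_cluster_configurations(n_molecules: int, n_frames: int,
                                  temperature: float = 298.15, seed: int = 0,
                                  stride: int = 50, dt: float = 1.0,
                                  equilibration_steps: int = 2000,
                                  evaporation_radius: float | None = None,
                                  ) -> list[Configuration]:
    """Gas-phase NVT frames of an (H₂O)_n cluster from the SPC/Fw backend.

    Frames in which any molecule has evaporated (O atom beyond the radius
    bound from the center of mass) are discarded and replaced by further
    sampling; callers needing the discard count use
    :func:`_sample_with_report`, which returns ``(frames, n_discarded)``.
    """
    frames, _ = _sample_with_report(
        n_molecules, n_frames, temperature, seed, stride, dt,
        equilibration_steps, evaporation_radius)
    return frames


def _sample_with_report(n_molecules, n_frames, temperature, seed, stride, dt,
                        equilibration_steps, evaporation_radius):
    if n_frames <= 0:
        return [], 0
    if evaporation_radius is None:
        evaporation_radius = 1.45 * n_molecules ** (1.0 / 3.0) + 6.0
    ff = SPCFWForceField()
    config = build_cluster(n_molecules, seed=seed)
    n_discarded = 0
    frames: list[Configuration] = []
    # equilibrate, then harvest in chunks until enough frames survive
    traj = run_md(config, ff, ensemble="NVT", temperature=temperature,
                  dt=dt, steps=equilibration_steps, seed=seed,
                  stride=equilibration_steps, friction=0.005)
    config = traj.frames[-1]
    attempt = 0
    while len(frames) < n_frames and attempt < 5:
        need = n_frames - len(frames)
        traj = run_md(config, ff, ensemble="NVT", temperature=temperature,
                      dt=dt, steps=need * stride, seed=seed + 1 + attempt,
                      stride=stride, friction=0.005)
        for frame in traj.frames[1:]:
            com = np.average(frame.positions, axis=0, weights=frame.masses)
            o_pos = frame.positions[frame.is_oxygen]
            if np.max(np.linalg.norm(o_pos - com, axis=1)) > evaporation_radius:
                n_discarded += 1
                continue
            frames.append(frame)
        config = traj.frames[-1]
        attempt += 1
    return frames[:n_frames], n_discarded


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def _polarization_terms(config: Configuration, params: SurrogateParams) -> np.ndarray:
    """Per-H polarization sum Σ_{O' inter} exp(−b r)·s_c(r); zero for O."""
    _, r = displacement_matrix(config)
    mol = config.molecule_index
    inter = mol[:, None] != mol[None, :]
    is_o = config.is_oxygen
    w = np.where(np.isfinite(r), np.exp(-params.decay * np.where(np.isfinite(r), r, 0.0)), 0.0)
    w *= cutoff_weight(r, params.r_c) * inter * is_o[None, :]
    terms = w.sum(axis=1)
    terms[is_o] = 0.0
    return terms


def surrogate_ct(config: Configuration, mol_i: int, mol_j: int,
                 params: SurrogateParams | None = None) -> float:
    """Pairwise CT label δq_IJ (e); 0 beyond the CT cutoff; antisymmetric."""
    params = params or SurrogateParams()
    ct = surrogate_ct_all(config, params,
                          pairs=np.array([sorted((mol_i, mol_j))]))
    if len(ct.delta_q) == 0:
        return 0.0
    sign = 1.0 if mol_i < mol_j else -1.0
    return float(sign * ct.delta_q[0])


def surrogate_ct_all(config: Configuration, params: SurrogateParams | None = None,
                     pairs: np.ndarray | None = None) -> CTSet:
    """CT labels for all molecule pairs within the CT cutoff (stored I < J)."""
    params = params or SurrogateParams()
    from .descriptors import ct_pairs as _ct_pairs
    spec = ICFSpec(r_c=params.r_c, ct_cutoff=params.r_ct)
    if pairs is None:
        pairs = _ct_pairs(config, spec)
    else:
        _, r = displacement_matrix(config)
        o = np.arange(0, config.n_atoms, 3)
        keep = np.array([r[o[i], o[j]] <= params.r_ct for i, j in pairs])
        pairs = pairs[keep] if len(pairs) else pairs
    if len(pairs) == 0:
        return CTSet(np.zeros((0, 2), dtype=int), np.zeros(0))
    _, r = displacement_matrix(config)
    o = np.arange(0, config.n_atoms, 3)
    dq = np.empty(len(pairs))
    for ip, (mi, mj) in enumerate(pairs):
        ai, aj = o[mi], o[mj]
        # H of I → O of J minus H of J → O of I
        donor_ij = sum(_ct_kernel(r[ai + k, aj], params) for k in (1, 2))
        donor_ji = sum(_ct_kernel(r[aj + k, ai], params) for k in (1, 2))
        dq[ip] = params.ct_amplitude * (donor_ij - donor_ji)
    return CTSet(np.asarray(pairs), dq)


def _ct_kernel(r: float, params: SurrogateParams) -> float:
    return float(np.exp(-params.ct_decay * r) * cutoff_weight(r, params.r_ct))


def surrogate_charges(config: Configuration, params: SurrogateParams | None = None,
                      rng=None) -> ChargeSet:
    """Smooth environment-dependent charge labels (see module docstring).

    Noise (if enabled) is drawn from ``rng`` or a fresh generator seeded by
    ``params.seed``; pass an explicit generator when labelling many frames.
    """
    params = params or SurrogateParams()
    pol = _polarization_terms(config, params)
    q = np.where(config.is_oxygen, 0.0, params.q_h_base + params.amplitude * pol)
    # oxygens balance their molecule, then CT net charges are added on O
    h_sum = q.reshape(-1, 3)[:, 1:].sum(axis=1)
    ct = surrogate_ct_all(config, params)
    net = ct.molecular_net_charges(config.n_molecules)
    q[config.is_oxygen] = -h_sum + net
    if params.noise > 0:
        rng = np.random.default_rng(params.seed) if rng is None else rng
        q = q + rng.normal(0.0, params.noise, size=q.shape)
    return ChargeSet(q)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class TrainingSet:
    """Features + labels with a frozen train/validation/test split."""

    features_o: np.ndarray
    labels_o: np.ndarray
    features_h: np.ndarray
    labels_h: np.ndarray
    features_ct: np.ndarray
    labels_ct: np.ndarray
    split_o: dict = field(default_factory=dict)    # name -> index array
    split_h: dict = field(default_factory=dict)
    split_ct: dict = field(default_factory=dict)
    clean_labels_o: np.ndarray | None = None
    clean_labels_h: np.ndarray | None = None
    params: SurrogateParams | None = None
    seed: int = 0

    def subset(self, element: str, part: str):
        f, y, s = {"O": (self.features_o, self.labels_o, self.split_o),
                   "H": (self.features_h, self.labels_h, self.split_h),
                   "CT": (self.features_ct, self.labels_ct, self.split_ct)}[element]
        idx = s[part]
        return f[idx], y[idx]

    def save(self, path) -> None:
        arrays = {"seed": np.asarray(self.seed)}
        for el, f, y in (("o", self.features_o, self.labels_o),
                         ("h", self.features_h, self.labels_h),
                         ("ct", self.features_ct, self.labels_ct)):
            arrays[f"features_{el}"] = f
            arrays[f"labels_{el}"] = y
        for el, split in (("o", self.split_o), ("h", self.split_h),
                          ("ct", self.split_ct)):
            for part, idx in split.items():
                arrays[f"split_{el}_{part}"] = idx
        if self.clean_labels_o is not None:
            arrays["clean_labels_o"] = self.clean_labels_o
            arrays["clean_labels_h"] = self.clean_labels_h
        if self.params is not None:
            from dataclasses import asdict
            p = asdict(self.params)
            arrays["param_names"] = np.asarray(sorted(p), dtype="U32")
            arrays["param_values"] = np.asarray([p[k] for k in sorted(p)], dtype=float)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainingSet":
        with np.load(path, allow_pickle=False) as z:
            a = dict(z)
        splits = {el: {} for el in ("o", "h", "ct")}
        for key in a:
            if key.startswith("split_"):
                _, el, part = key.split("_", 2)
                splits[el][part] = a[key]
        params = None
        if "param_names" in a:
            params = SurrogateParams(**{
                n: (int(v) if n == "seed" else float(v))
                for n, v in zip(a["param_names"], a["param_values"])})
        return cls(a["features_o"], a["labels_o"], a["features_h"],
                   a["labels_h"], a["features_ct"], a["labels_ct"],
                   splits["o"], splits["h"], splits["ct"],
                   a.get("clean_labels_o"), a.get("clean_labels_h"),
                   params, int(a["seed"]))


def _three_way_split(n: int, n_train: int, n_val: int, rng) -> dict:
    perm = rng.permutation(n)
    return {"train": perm[:n_train], "val": perm[n_train:n_train + n_val],
            "test": perm[n_train + n_val:]}


def make_training_set(n_clusters: int, cluster_size: int = 25,
                      params: SurrogateParams | None = None, seed: int = 0,
                      spec: ICFSpec | None = None,
                      train_fraction: float = 0.4, n_validation: int = 50,
                      frames: list | None = None) -> TrainingSet:
    """Features + surrogate labels from sampled cluster frames.

    The split mirrors the reference protocol (40% of the pool for training,
    a small fixed validation set, remainder for testing), applied per label
    family.  Everything is reproducible from (params, seed).
    """
    params = params or SurrogateParams()
    spec = spec or ICFSpec(r_c=params.r_c, ct_cutoff=params.r_ct)
    if frames is None:
        frames = sample_cluster_configurations(cluster_size, n_clusters,
                                               seed=seed)
    rng = np.random.default_rng(seed + 1)
    fo, yo, fh, yh, fct, yct, co, ch = [], [], [], [], [], [], [], []
    for frame in frames:
        feats, _ = charge_features(frame, spec)
        noisy = surrogate_charges(frame, params, rng=rng).charges
        clean_params = SurrogateParams(**{**params.__dict__, "noise": 0.0})
        clean = surrogate_charges(frame, clean_params).charges
        is_o = frame.is_oxygen
        fo.append(feats[is_o])
        yo.append(noisy[is_o])
        co.append(clean[is_o])
        fh.append(feats[~is_o])
        yh.append(noisy[~is_o])
        ch.append(clean[~is_o])
        ctf, cache = ct_features(frame, spec)
        if len(ctf):
            ct = surrogate_ct_all(frame, params, pairs=cache.pairs)
            fct.append(ctf)
            yct.append(ct.delta_q)
    nf = spec.n_charge_features
    def _cat(parts, width=None):
        if not parts:
            return np.zeros(0) if width is None else np.zeros((0, width))
        return np.concatenate(parts)
    fo, yo, co = _cat(fo, nf), _cat(yo), _cat(co)
    fh, yh, ch = _cat(fh, nf), _cat(yh), _cat(ch)
    fct = np.concatenate(fct) if fct else np.zeros((0, spec.n_ct_features))
    yct = np.concatenate(yct) if yct else np.zeros(0)

    n_val = min(n_validation, max(1, len(yo) // 20))
    split_o = _three_way_split(len(yo), int(train_fraction * len(yo)), n_val, rng)
    split_h = _three_way_split(len(yh), int(train_fraction * len(yh)), n_val, rng)
    split_ct = _three_way_split(len(yct), int(train_fraction * len(yct)),
                                min(n_val, max(0, len(yct) // 20)), rng)
    return TrainingSet(fo, yo, fh, yh, fct, yct, split_o, split_h, split_ct,
                       co, ch, params, seed)
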
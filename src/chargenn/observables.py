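"""Analysis observables: RDF, dipoles, IR spectra, diffusion, H_vap,
tetrahedral order, and droplet layer statistics.

All routines consume plain arrays or :class:`~chargenn.md.Trajectory`
frames and return numpy arrays/dataclasses; TSV export goes through
:func:`chargenn.io.write_tsv`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import Configuration, displacement_matrix
from .units import DEBYE_PER_E_ANGSTROM, NUCLEAR_Z, R_GAS

__all__ = [
    "radial_distribution", "molecular_dipoles", "total_dipole_moment",
    "ir_spectrum", "self_diffusion", "DiffusionResult",
    "heat_of_vaporization", "tetrahedral_order", "TetrahedralOrderResult",
    "layer_statistics", "LayerStatistics",
]

#: fs⁻¹ → cm⁻¹
_FS_TO_WAVENUMBER = 1.0e15 / 2.99792458e10


def radial_distribution(frames, pair: tuple[str, str] = ("O", "O"),
                        dr: float = 0.05, r_max: float | None = None):
    """Standard histogram g(r) estimator for periodic frames.

    Returns (r_centers, g).  Normalization is by ideal-gas shell counts at
    the partner density, so uniform random frames give g ≈ 1.
    """
    frames = list(frames)
    cell = frames[0].cell
    if cell is None:
        raise ValueError("radial_distribution requires periodic frames")
    if r_max is None:
        r_max = 0.5 * float(cell.min())
    if r_max > 0.5 * cell.min() + 1e-12:
        raise ValueError(f"r_max {r_max} exceeds half the box {cell.min() / 2}")
    edges = np.arange(0.0, r_max + dr, dr)
    hist = np.zeros(len(edges) - 1)
    volume = float(np.prod(cell))
    el_a, el_b = pair
    n_a = n_b = 0
    for frame in frames:
        sel_a = np.flatnonzero(frame.species == el_a)
        sel_b = np.flatnonzero(frame.species == el_b)
        n_a, n_b = len(sel_a), len(sel_b)
        _, r = displacement_matrix(frame)
        rr = r[np.ix_(sel_a, sel_b)].ravel()
        hist += np.histogram(rr[np.isfinite(rr)], bins=edges)[0]
    hist /= len(frames)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho_b = n_b / volume
    same = el_a == el_b
    ideal = n_a * rho_b * shell_vol
    if same:
        ideal = n_a * ((n_b - 1) / volume) * shell_vol
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal > 0, hist / ideal, 0.0)
    return centers, g


def nuclear_charge_center(config: Configuration) -> np.ndarray:
    """Per-molecule Σ Z_i r_i / Σ Z_i (the dipole origin convention)."""
    z = np.asarray([NUCLEAR_Z[s] for s in config.species])
    pos = config.positions.reshape(-1, 3, 3)
    zz = z.reshape(-1, 3)
    return np.einsum("ma,max->mx", zz, pos) / zz.sum(axis=1)[:, None]


def molecular_dipoles(config: Configuration,
                      charges: np.ndarray | None = None) -> np.ndarray:
    """Per-molecule dipole vectors (Debye) about the nuclear charge center.

    For a neutral molecule the origin drops out; for CT-charged molecules
    the nuclear-charge-center origin is the stated convention.
    """
    q = config.charges if charges is None else np.asarray(charges)
    if q is None:
        raise ValueError("charges are required")
    origin = nuclear_charge_center(config)
    pos = config.positions.reshape(-1, 3, 3)
    rel = pos - origin[:, None, :]
    mu = np.einsum("ma,max->mx", q.reshape(-1, 3), rel)
    return mu * DEBYE_PER_E_ANGSTROM


def total_dipole_moment(config: Configuration,
                        charges: np.ndarray | None = None) -> np.ndarray:
    """System dipole vector Σ q_i r_i in Debye (meaningful when neutral)."""
    q = config.charges if charges is None else np.asarray(charges)
    return np.sum(np.asarray(q)[:, None] * config.positions, axis=0) \
        * DEBYE_PER_E_ANGSTROM


def ir_spectrum(times_fs: np.ndarray, dipoles: np.ndarray,
                correction: str = "harmonic", window: bool = True):
    """IR intensity from the dipole autocorrelation function.

    Parameters
    ----------
    times_fs : uniform timestamps, fs.
    dipoles : (T, 3) total dipole per frame (any consistent unit).
    correction : 'harmonic' applies the harmonic quantum correction factor
        βħω/(1 − e^{−βħω}) ∝ ω/(1 − e^{−βħω}) at 298.15 K (shape only —
        intensities are reported unnormalized); 'none' returns the classical
        spectrum.

    Returns (wavenumber cm⁻¹, intensity arbitrary units).
    """
    times_fs = np.asarray(times_fs, dtype=float)
    mu = np.atleast_2d(np.asarray(dipoles, dtype=float))
    if mu.ndim == 2 and mu.shape[0] == 3 and mu.shape[1] != 3 and len(times_fs) == mu.shape[1]:
        mu = mu.T
    if mu.shape[0] != len(times_fs):
        mu = mu.reshape(len(times_fs), -1)
    n = len(times_fs)
    if n < 8:
        raise ValueError("trajectory too short for a spectrum")
    dt = float(times_fs[1] - times_fs[0])
    if not np.allclose(np.diff(times_fs), dt, rtol=1e-6):
        raise ValueError("uniform time stride required")
    mu = mu - mu.mean(axis=0)
    # one-sided autocorrelation, FFT-based, averaged over components
    nfft = 2 * n
    acf = np.zeros(n)
    for comp in mu.T:
        f = np.fft.rfft(comp, nfft)
        c = np.fft.irfft(f * np.conj(f), nfft)[:n]
        acf += c.real
    acf /= np.arange(n, 0, -1)             # unbiased normalization
    if window:
        acf = acf * np.hanning(2 * n)[n:]
    spec = np.abs(np.fft.rfft(acf, nfft))
    freq = np.fft.rfftfreq(nfft, d=dt)     # fs⁻¹
    wavenumber = freq * _FS_TO_WAVENUMBER
    if correction == "harmonic":
        from .units import KB
        # βħω/(1−exp(−βħω)); ħω/kT with ω in cm⁻¹: hc·ν̃/kT
        hc_over_kt = 2.85914e-3 / (KB * 298.15)  # kcal/mol per cm⁻¹ / kT
        x = hc_over_kt * wavenumber
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(x > 0, x / (1.0 - np.exp(-x)), 1.0)
        spec = spec * q
    elif correction != "none":
        raise ValueError("correction must be 'harmonic' or 'none'")
    return wavenumber, spec


@dataclass
class DiffusionResult:
    d: float                     # 10⁻⁵ cm²/s
    slope: float                 # Å²/fs
    msd: np.ndarray
    lag_times: np.ndarray
    ballistic_flag: bool
    exponent: float


def self_diffusion(times_fs: np.ndarray, positions: np.ndarray,
                   fit_window: tuple[float, float] = (0.2, 0.8)) -> DiffusionResult:
    """Einstein-relation D from the MSD slope (positions must be unwrapped).

    ``positions`` is (T, N, 3); the least-squares slope over the stated
    fractional lag-time window gives D = slope/6, reported in 10⁻⁵ cm²/s.
    A log-log exponent ≫ 1 flags ballistic (non-diffusive) motion.
    """
    pos = np.asarray(positions, dtype=float)
    t = np.asarray(times_fs, dtype=float)
    n = len(t)
    lags = np.arange(1, n)
    msd = np.empty(len(lags))
    for k, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        msd[k] = np.mean(np.sum(d * d, axis=-1))
    lag_t = t[lags] - t[0]
    lo = max(1, int(fit_window[0] * len(lags)))
    hi = max(lo + 2, int(fit_window[1] * len(lags)))
    a = np.vstack([lag_t[lo:hi], np.ones(hi - lo)]).T
    slope, _ = np.linalg.lstsq(a, msd[lo:hi], rcond=None)[0]
    pos_msd = msd[lo:hi] > 0
    if pos_msd.sum() > 2:
        exponent = float(np.polyfit(np.log(lag_t[lo:hi][pos_msd]),
                                    np.log(msd[lo:hi][pos_msd]), 1)[0])
    else:
        exponent = 0.0
    # Å²/fs → 10⁻⁵ cm²/s: 1 Å²/fs = 1e-1 cm²/s = 1e4 × 1e-5 cm²/s
    d_units = slope / 6.0 * 1.0e4
    return DiffusionResult(float(d_units), float(slope), msd, lag_t,
                           exponent > 1.5, exponent)


def heat_of_vaporization(mean_interaction_energy: float,
                         temperature: float) -> float:
    """H_vap = −⟨E_int⟩ + RT, kcal/mol (per-molecule liquid E_int)."""
    return -mean_interaction_energy + R_GAS * temperature


@dataclass
class TetrahedralOrderResult:
    q_per_oxygen: np.ndarray     # NaN where excluded
    mean: float
    n_excluded: int


def tetrahedral_order(config: Configuration) -> TetrahedralOrderResult:
    """Errington–Debenedetti q = 1 − 3/8 Σ_{j<k} (cos ψ_jk + ⅓)² over the
    4 nearest O neighbors of each O (minimum image under PBC)."""
    o_idx = np.flatnonzero(config.is_oxygen)
    d, r = displacement_matrix(config)
    q = np.full(len(o_idx), np.nan)
    n_excluded = 0
    for m, i in enumerate(o_idx):
        rr = r[i, o_idx]
        order = np.argsort(rr)
        neigh = o_idx[order[:4]]
        if len(neigh) < 4 or not np.isfinite(rr[order[:4]]).all():
            n_excluded += 1
            continue
        vecs = d[i, neigh]
        vecs = vecs / np.linalg.norm(vecs, axis=1)[:, None]
        s = 0.0
        for a in range(3):
            for b in range(a + 1, 4):
                s += (vecs[a] @ vecs[b] + 1.0 / 3.0) ** 2
        q[m] = 1.0 - 3.0 / 8.0 * s
    valid = np.isfinite(q)
    return TetrahedralOrderResult(q, float(q[valid].mean()) if valid.any()
                                  else np.nan, n_excluded)


@dataclass
class LayerStatistics:
    """Spherical-shell statistics of a droplet, averaged over frames."""

    edges: np.ndarray            # Å from droplet center
    vcd: np.ndarray              # e/nm³ (atomic charges), NaN for empty shells
    pha: np.ndarray              # fraction of H among shell atoms
    atom_counts: np.ndarray
    mol_counts: np.ndarray
    net_mol_vcd: np.ndarray      # e/nm³ from net molecular charges
    mol_charge_edges: np.ndarray
    mol_charge_hist: np.ndarray  # (n_shells, n_charge_bins)
    total_charge: float          # mean per-frame total charge, e
    whole_pha: float

    @property
    def shell_volumes_nm3(self) -> np.ndarray:
        v = 4.0 / 3.0 * np.pi * (self.edges[1:] ** 3 - self.edges[:-1] ** 3)
        return v * 1.0e-3        # Å³ → nm³


def layer_statistics(frames, shell_width: float = 1.0,
                     r_max: float | None = None,
                     mol_charge_bins: np.ndarray | None = None) -> LayerStatistics:
    """Shell-resolved VCD/PHA/molecular-charge statistics of a droplet.

    The droplet center is the instantaneous center of mass of each frame;
    atoms are binned by their distance for VCD and PHA, molecules by their
    center of mass for the charge histogram and the net-molecular-charge
    VCD.  Empty shells are reported as NaN (missing), not zero.
    """
    frames = list(frames)
    if frames[0].charges is None:
        raise ValueError("frames must carry per-atom charges")
    if r_max is None:
        r_max = 0.0
        for f in frames:
            com = np.average(f.positions, axis=0, weights=f.masses)
            r_max = max(r_max, float(np.linalg.norm(f.positions - com,
                                                    axis=1).max()))
        r_max += shell_width
    edges = np.arange(0.0, r_max + shell_width, shell_width)
    nsh = len(edges) - 1
    if mol_charge_bins is None:
        mol_charge_bins = np.linspace(-0.05, 0.05, 41)
    charge_sum = np.zeros(nsh)
    h_count = np.zeros(nsh)
    atom_count = np.zeros(nsh)
    mol_count = np.zeros(nsh)
    mol_charge_sum = np.zeros(nsh)
    mol_hist = np.zeros((nsh, len(mol_charge_bins) - 1))
    total_charge = 0.0
    h_total = 0
    atom_total = 0
    for f in frames:
        com = np.average(f.positions, axis=0, weights=f.masses)
        r_atom = np.linalg.norm(f.positions - com, axis=1)
        idx = np.clip(np.digitize(r_atom, edges) - 1, 0, nsh - 1)
        np.add.at(charge_sum, idx, f.charges)
        np.add.at(atom_count, idx, 1.0)
        np.add.at(h_count, idx, (~f.is_oxygen).astype(float))
        total_charge += f.charges.sum()
        h_total += int((~f.is_oxygen).sum())
        atom_total += f.n_atoms
        # molecular binning by center of mass
        m = f.masses.reshape(-1, 3)
        mol_com = np.einsum("ma,max->mx", m, f.positions.reshape(-1, 3, 3)) \
            / m.sum(axis=1)[:, None]
        r_mol = np.linalg.norm(mol_com - com, axis=1)
        midx = np.clip(np.digitize(r_mol, edges) - 1, 0, nsh - 1)
        mol_q = f.charges.reshape(-1, 3).sum(axis=1)
        np.add.at(mol_count, midx, 1.0)
        np.add.at(mol_charge_sum, midx, mol_q)
        for sh in range(nsh):
            sel = midx == sh
            if sel.any():
                mol_hist[sh] += np.histogram(mol_q[sel], bins=mol_charge_bins)[0]
    nf = len(frames)
    vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3) * 1.0e-3
    with np.errstate(invalid="ignore", divide="ignore"):
        vcd = np.where(atom_count > 0, charge_sum / nf / vol, np.nan)
        pha = np.where(atom_count > 0, h_count / atom_count, np.nan)
        net_vcd = np.where(mol_count > 0, mol_charge_sum / nf / vol, np.nan)
    return LayerStatistics(edges, vcd, pha, atom_count / nf, mol_count / nf,
                           net_vcd, mol_charge_bins, mol_hist / nf,
                           total_charge / nf, h_total / atom_total)

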
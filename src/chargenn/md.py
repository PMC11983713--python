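"""Dynamics and minimization driving any energy backend.

Backends expose ``evaluate(config) -> (EnergyBreakdown, forces, info)``; the
integrator is agnostic to whether charges are fixed (SPC/Fw) or predicted by
the neural model, which is exactly what makes NVE conservation a test of the
full analytic-gradient chain.

NVE uses velocity Verlet; NVT uses the BAOAB Langevin splitting with a
mandatory seed.  The model is fully flexible (no constraints), so the
instantaneous temperature is 2·KE/(3N·k_B).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .energy import EnergyBreakdown
from .system import Configuration
from .units import FORCE_TO_ACC, KB, KE_TO_KCAL

__all__ = ["MDState", "Trajectory", "MinimizeResult", "velocity_verlet_step",
           "run_md", "minimize", "MDBlowupError", "kinetic_energy",
           "instantaneous_temperature", "draw_maxwell_velocities"]

#: forces beyond this magnitude abort the run, kcal/mol/Å
FORCE_BLOWUP_THRESHOLD = 1.0e4


class MDBlowupError(RuntimeError):
    """Raised when forces exceed the numerical-blow-up threshold."""


def kinetic_energy(masses: np.ndarray, velocities: np.ndarray) -> float:
    """KE in kcal/mol from amu masses and Å/fs velocities."""
    return 0.5 * float(np.sum(masses[:, None] * velocities ** 2)) * KE_TO_KCAL


def instantaneous_temperature(masses: np.ndarray, velocities: np.ndarray) -> float:
    ke = kinetic_energy(masses, velocities)
    return 2.0 * ke / (3.0 * len(masses) * KB)


def draw_maxwell_velocities(config: Configuration, temperature: float,
                            rng) -> np.ndarray:
    """Maxwell–Boltzmann velocities (Å/fs) with the COM drift removed."""
    m = config.masses
    sigma = np.sqrt(KB * temperature / (m * KE_TO_KCAL))
    v = rng.normal(size=(config.n_atoms, 3)) * sigma[:, None]
    v -= np.average(v, axis=0, weights=m)
    return v


@dataclass
class MDState:
    """One point of a trajectory: configuration + energetics."""

    config: Configuration
    time: float                      # fs
    breakdown: EnergyBreakdown
    forces: np.ndarray
    info: dict = field(default_factory=dict)

    @property
    def kinetic_energy(self) -> float:
        return kinetic_energy(self.config.masses, self.config.velocities)

    @property
    def temperature(self) -> float:
        return instantaneous_temperature(self.config.masses,
                                         self.config.velocities)

    @property
    def total_energy(self) -> float:
        return self.breakdown.total + self.kinetic_energy


@dataclass
class Trajectory:
    """Uniform-stride frames plus a step-resolved energy log."""

    frames: list                     # list of Configuration (with charges)
    times: np.ndarray                # fs, one per frame
    energy_log: dict                 # arrays: step, time, U terms, KE, T
    ct_log: list = field(default_factory=list)   # CTSet per frame when present

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def stride_fs(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


def _check_forces(forces: np.ndarray, time: float) -> None:
    fmax = float(np.abs(forces).max()) if forces.size else 0.0
    if not np.isfinite(fmax) or fmax > FORCE_BLOWUP_THRESHOLD:
        raise MDBlowupError(
            f"|force| = {fmax:.3g} kcal/mol/Å at t = {time} fs exceeds "
            f"{FORCE_BLOWUP_THRESHOLD:g}; integration aborted")


def velocity_verlet_step(state: MDState, dt: float, backend) -> MDState:
    """One standard velocity-Verlet update (time advanced by dt, fs)."""
    config = state.config
    m = config.masses[:, None]
    acc = state.forces * FORCE_TO_ACC / m
    v_half = config.velocities + 0.5 * dt * acc
    new = config.copy()
    new.positions = config.positions + dt * v_half
    breakdown, forces, info = backend.evaluate(new)
    _check_forces(forces, state.time + dt)
    new.velocities = v_half + 0.5 * dt * forces * FORCE_TO_ACC / m
    return MDState(new, state.time + dt, breakdown, forces, info)


def _baoab_step(state: MDState, dt: float, backend, friction: float,
                temperature: float, rng) -> MDState:
    """BAOAB Langevin splitting; friction in fs⁻¹."""
    config = state.config
    m = config.masses[:, None]
    acc = state.forces * FORCE_TO_ACC / m
    v = config.velocities + 0.5 * dt * acc
    x = config.positions + 0.5 * dt * v
    c1 = np.exp(-friction * dt)
    sigma = np.sqrt(KB * temperature / (config.masses * KE_TO_KCAL))[:, None]
    v = c1 * v + np.sqrt(1.0 - c1 * c1) * sigma * rng.normal(size=v.shape)
    x = x + 0.5 * dt * v
    new = config.copy()
    new.positions = x
    breakdown, forces, info = backend.evaluate(new)
    _check_forces(forces, state.time + dt)
    new.velocities = v + 0.5 * dt * forces * FORCE_TO_ACC / m
    return MDState(new, state.time + dt, breakdown, forces, info)


def run_md(config: Configuration, backend, ensemble: str = "NVE",
           temperature: float = 298.15, dt: float = 1.0, steps: int = 1000,
           seed: int | None = None, stride: int = 10,
           friction: float = 0.001, initialize_velocities: bool = True,
           log_stride: int = 1) -> Trajectory:
    """Integrate `steps` MD steps; frames recorded every `stride` steps.

    Parameters follow the gas-phase protocol defaults (NVT at 298.15 K,
    dt = 1 fs); `friction` is the Langevin collision rate in fs⁻¹ (default
    1 ps⁻¹).  The seed is mandatory for NVT.
    """
    ensemble = ensemble.upper()
    if ensemble not in ("NVE", "NVT"):
        raise ValueError("ensemble must be NVE or NVT")
    if ensemble == "NVT" and seed is None:
        raise ValueError("NVT (Langevin) requires an explicit seed")
    rng = np.random.default_rng(seed)

    config = config.copy()
    if config.velocities is None:
        config.velocities = (draw_maxwell_velocities(config, temperature, rng)
                             if initialize_velocities
                             else np.zeros_like(config.positions))
    breakdown, forces, info = backend.evaluate(config)
    _check_forces(forces, 0.0)
    state = MDState(config, 0.0, breakdown, forces, info)

    frames, times, ct_log = [], [], []
    log = {k: [] for k in ("step", "time", "U_intra", "U_vdw", "U_coul",
                           "U_ct", "U_total", "KE", "E_total", "T")}

    def record_frame(st: MDState) -> None:
        snap = st.config.copy()
        if "charges" in st.info:
            snap.charges = st.info["charges"].charges.copy()
        frames.append(snap)
        times.append(st.time)
        if "ct" in st.info:
            ct_log.append(st.info["ct"])

    def record_log(step: int, st: MDState) -> None:
        b = st.breakdown
        ke = st.kinetic_energy
        for k, v in (("step", step), ("time", st.time), ("U_intra", b.intra),
                     ("U_vdw", b.vdw), ("U_coul", b.coulomb), ("U_ct", b.ct),
                     ("U_total", b.total), ("KE", ke),
                     ("E_total", b.total + ke), ("T", st.temperature)):
            log[k].append(v)

    record_frame(state)
    record_log(0, state)
    for step in range(1, steps + 1):
        if ensemble == "NVE":
            state = velocity_verlet_step(state, dt, backend)
        else:
            state = _baoab_step(state, dt, backend, friction, temperature, rng)
        if step % stride == 0:
            record_frame(state)
        if step % log_stride == 0:
            record_log(step, state)
    return Trajectory(frames, np.asarray(times),
                      {k: np.asarray(v) for k, v in log.items()}, ct_log)


@dataclass
class MinimizeResult:
    configuration: Configuration
    energy: float
    max_force: float
    converged: bool
    n_iterations: int


def minimize(config: Configuration, backend, tol: float = 1e-6,
             max_iterations: int = 20000) -> MinimizeResult:
    """Quasi-Newton descent to max-|force| < tol (kcal/mol/Å)."""
    shape = config.positions.shape

    def fun(x):
        c = config.with_positions(x.reshape(shape))
        breakdown, forces, _ = backend.evaluate(c)
        return breakdown.total, -forces.ravel()

    res = optimize.minimize(
        fun, config.positions.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iterations, "gtol": tol * 1e-3,
                 "ftol": 1e-15, "maxcor": 30})
    x = res.x
    n_iter = int(res.nit)
    # alternate quasi-Newton restarts until the force criterion truly holds
    # (a single L-BFGS run can stall on stiff-bond/soft-contact conditioning)
    for round_ in range(6):
        c = config.with_positions(x.reshape(shape))
        _, forces, _ = backend.evaluate(c)
        if np.abs(forces).max() < tol:
            break
        method = "BFGS" if round_ % 2 == 0 else "L-BFGS-B"
        res2 = optimize.minimize(
            fun, x, jac=True, method=method,
            options={"maxiter": 2000, "gtol": tol * 1e-2}
            if method == "BFGS" else
            {"maxiter": 5000, "gtol": tol * 1e-3, "ftol": 1e-16, "maxcor": 40})
        x = res2.x
        n_iter += int(res2.nit)
    # Newton polish with an FD Hessian of the analytic gradient: quasi-Newton
    # line searches lose precision near stiff-bond minima, Newton does not
    n_dof = x.size
    if n_dof <= 300:
        for _ in range(8):
            _, g = fun(x)
            if np.abs(g).max() < 0.3 * tol:
                break
            h = 1e-5
            hess = np.empty((n_dof, n_dof))
            for k in range(n_dof):
                xp, xm = x.copy(), x.copy()
                xp[k] += h
                xm[k] -= h
                hess[k] = (fun(xp)[1] - fun(xm)[1]) / (2 * h)
            hess = 0.5 * (hess + hess.T)
            # shift any soft/negative curvature (rigid-body modes)
            w, v = np.linalg.eigh(hess)
            w = np.where(np.abs(w) < 1e-8, 1e-8, w)
            step = -(v @ ((v.T @ g) / np.abs(w)))
            if not np.isfinite(step).all():
                break
            # backtracking on the gradient norm
            g0 = np.linalg.norm(g)
            for damp in (1.0, 0.5, 0.25, 0.1):
                if np.linalg.norm(fun(x + damp * step)[1]) < g0:
                    x = x + damp * step
                    break
            else:
                break
    c = config.with_positions(x.reshape(shape))
    _, forces, _ = backend.evaluate(c)
    energy = backend.evaluate(c)[0].total
    fmax = float(np.abs(forces).max())
    return MinimizeResult(c, energy, fmax, fmax < tol, n_iter)
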
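"""Shared fixtures: geometries, random clusters, predictors, boxes."""

import numpy as np
import pytest

from chargenn.charges import ChargePredictor
from chargenn.spcfw import SPCFWForceField, build_monomer, build_dimer_start
from chargenn.surrogate import build_cluster
from chargenn.system import Configuration


@pytest.fixture()
def monomer():
    return build_monomer()


@pytest.fixture()
def dimer():
    return build_dimer_start()


@pytest.fixture()
def cluster_factory():
    """Random compact clusters with optional thermal distortion."""

    def make(n_molecules, seed=0, distort=0.0):
        config = build_cluster(n_molecules, seed=seed)
        if distort:
            rng = np.random.default_rng(seed + 1000)
            config.positions = config.positions + rng.normal(
                0.0, distort, config.positions.shape)
        return config

    return make


def make_periodic_box(n_side=(2, 2, 4), box=11.4, seed=4, jitter=0.1):
    """Molecules on a jittered grid in an orthorhombic cell (16 by default)."""
    rng = np.random.default_rng(seed)
    nx, ny, nz = n_side
    species, positions = [], []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                m = build_monomer()
                q, r = np.linalg.qr(rng.normal(size=(3, 3)))
                q *= np.sign(np.diag(r))
                c = np.array([(i + 0.5) * box / nx, (j + 0.5) * box / ny,
                              (k + 0.5) * box / nz])
                positions.append(m.positions @ q.T + c + rng.normal(0, jitter, 3))
                species.extend(m.species)
    return Configuration(np.asarray(species, dtype=object),
                         np.vstack(positions), cell=[box] * 3)


@pytest.fixture(scope="session")
def periodic_box_16():
    return make_periodic_box()


@pytest.fixture(scope="session")
def equilibrated_box_16():
    """16-molecule box thermalized briefly with the SPC/Fw backend."""
    from chargenn.md import run_md
    box = make_periodic_box()
    traj = run_md(box, SPCFWForceField(), ensemble="NVT", temperature=298.15,
                  dt=0.5, steps=2000, seed=11, stride=2000, friction=0.01)
    return traj.frames[-1]


@pytest.fixture(scope="session")
def random_predictor():
    """Seeded random networks — exercises the full chain without training."""
    return ChargePredictor.random(seed=2, init_scale=0.3)


def finite_difference_gradient(energy_fn, config, coords=None, h=1e-5):
    """Central-difference dU/dR for selected flat coordinate indices."""
    n3 = config.n_atoms * 3
    coords = range(n3) if coords is None else coords
    out = {}
    for k in coords:
        i, x = divmod(k, 3)
        cp = config.copy()
        cp.positions[i, x] += h
        cm = config.copy()
        cm.positions[i, x] -= h
        out[k] = (energy_fn(cp) - energy_fn(cm)) / (2.0 * h)
    return out


def relative_gradient_error(analytic_grad, fd_dict):
    """max |fd − analytic| over coordinates, relative to the gradient scale."""
    flat = analytic_grad.ravel()
    scale = max(np.abs(flat).max(), 1e-6)
    return max(abs(fd - flat[k]) for k, fd in fd_dict.items()) / scale
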
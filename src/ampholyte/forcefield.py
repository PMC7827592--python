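"""Interaction potentials of the coarse-grained model.

Three terms only: harmonic bonds U_h = (k_h/2)(r-b)^2, a truncated-shifted
purely repulsive Lennard-Jones (WCA) excluded volume between all bead
pairs, and Coulomb electrostatics U = z_i z_j l_B / r (in k_BT) handled by
an Ewald sum in the periodic box.  There are no angular or torsional
terms, no exclusions for bonded pairs, and solvent enters only through
the Bjerrum length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .ewald import EwaldSolver
from .topology import Topology

__all__ = [
    "ForceFieldParams",
    "harmonic_energy",
    "wca_energy",
    "coulomb_energy",
    "total_energy",
    "forces",
]


@dataclass(frozen=True)
class ForceFieldParams:
    """Force-field constants (energies in k_BT, lengths in nm).

    ``r_cut_wca`` defaults to 0.4 nm as in the reference parameterisation,
    which is slightly beyond the Lennard-Jones minimum 2^(1/6)*sigma =
    0.3985 nm, so the shifted potential retains a ~3.5e-4 k_BT step at the
    cutoff.  Set ``exact_wca_cutoff=True`` to truncate exactly at the
    minimum instead (continuous potential).

    ``bjerrum_length = 0`` switches electrostatics off entirely and
    ``epsilon_wca = 0`` switches the excluded volume off; both are used by
    the ideal-limit oracles.
    """

    k_h: float = 400.0           # bond stiffness, k_BT / nm^2
    epsilon_wca: float = 1.0     # k_BT
    sigma_wca: float = 0.355     # nm
    r_cut_wca: float = 0.4       # nm
    bjerrum_length: float = 0.71  # nm
    temperature: float = 300.0   # K (bookkeeping only; energies are in k_BT)
    exact_wca_cutoff: bool = False
    ewald_accuracy: float = 1e-3

    def __post_init__(self) -> None:
        if self.k_h <= 0 or self.sigma_wca <= 0 or self.r_cut_wca <= 0:
            raise ValueError("force-field lengths and stiffness must be positive")
        if self.epsilon_wca < 0 or self.bjerrum_length < 0:
            raise ValueError("epsilon_wca and bjerrum_length must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def wca_cutoff(self) -> float:
        if self.exact_wca_cutoff:
            return 2.0 ** (1.0 / 6.0) * self.sigma_wca
        return self.r_cut_wca

    def make_solver(self, box_length: float) -> EwaldSolver | None:
        if self.bjerrum_length <= 0:
            return None
        return EwaldSolver(
            box_length, self.bjerrum_length, accuracy=self.ewald_accuracy
        )


def harmonic_energy(r, b, k_h=400.0):
    """Harmonic bond energy (k_h/2)(r-b)^2, k_BT; zero at r = b."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("bond length must be non-negative")
    e = 0.5 * k_h * (r - b) ** 2
    return e if e.ndim else float(e)


def wca_energy(r, eps=1.0, sigma=0.355, r_cut=0.4):
    """Truncated-shifted repulsive Lennard-Jones (WCA) energy, k_BT.

    U = 4*eps[(sigma/r)^12 - (sigma/r)^6] + eps for r <= r_cut, else 0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("WCA energy undefined at r = 0 (overlapping beads)")
    s6 = (sigma / r) ** 6
    e = np.where(r <= r_cut, 4.0 * eps * (s6 * s6 - s6) + eps, 0.0)
    return e if e.ndim else float(e)


def coulomb_energy(r, z_i, z_j, l_B=0.71):
    """Bare Coulomb pair energy z_i z_j l_B / r, k_BT."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("Coulomb energy undefined at r = 0")
    e = z_i * z_j * l_B / r
    return e if e.ndim else float(e)


def _active_arrays(state, topology: Topology):
    n = topology.n_fixed + state.n_h
    pos = np.ascontiguousarray(state.positions[:n], dtype=np.float64)
    q = topology.charges(state.ionised, state.n_h)[:n]
    return pos, np.ascontiguousarray(q), n


def total_energy(
    state, topology: Topology, ff: ForceFieldParams, solver: EwaldSolver | None = None
) -> float:
    """Total potential energy of the periodic system, k_BT.

    Bonded + WCA (minimum image) + Ewald electrostatics.  The box must be
    electroneutral whenever electrostatics is enabled.
    """
    pos, q, n = _active_arrays(state, topology)
    L = state.box_length
    dummy = np.zeros((1, 3))
    e = _kernels.bond_energy_forces(
        pos, topology.bonds, topology.bond_b0, ff.k_h, L, dummy, False
    )
    e_wca, _ = _kernels.pair_energy_forces(
        pos, q, n, L, 0.0, 0.0, 0.0,
        ff.epsilon_wca, ff.sigma_wca, ff.wca_cutoff, dummy, False,
    )
    e += e_wca
    if ff.bjerrum_length > 0:
        if solver is None:
            solver = ff.make_solver(L)
        e += solver.energy(pos, q)
    return float(e)


def forces(
    state, topology: Topology, ff: ForceFieldParams, solver: EwaldSolver | None = None
) -> np.ndarray:
    """Per-bead forces -grad U for the active particles, k_BT/nm."""
    pos, q, n = _active_arrays(state, topology)
    L = state.box_length
    f = np.zeros((n, 3))
    _kernels.bond_energy_forces(
        pos, topology.bonds, topology.bond_b0, ff.k_h, L, f, True
    )
    _kernels.pair_energy_forces(
        pos, q, n, L, 0.0, 0.0, 0.0,
        ff.epsilon_wca, ff.sigma_wca, ff.wca_cutoff, f, True,
    )
    if ff.bjerrum_length > 0:
        if solver is None:
            solver = ff.make_solver(L)
        f += solver.forces(pos, q)
    return f
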
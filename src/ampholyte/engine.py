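"""Hybrid constant-pH Monte Carlo / Langevin-dynamics sampler.

The sampler alternates cycles of (i) reaction moves that toggle the
protonation state of titratable side chains while inserting or deleting a
free hydrogen ion, and (ii) Langevin molecular dynamics that relaxes the
coordinates.  A deprotonation (direction xi = +1 of HA <-> A- + H+ or
BH+ <-> B + H+) lowers the site charge by one and inserts an H+ at a
uniform random position; a protonation (xi = -1) raises the site charge
by one and deletes a uniformly chosen H+.  Proposals are accepted with

    P_acc = min[1, exp(-beta dU + xi (pH - pKA) ln 10)],

so in the non-interacting limit the per-site ionisation reproduces the
Henderson-Hasselbalch curve exactly, while electrostatic interactions
(through dU) produce charge regulation.  Electroneutrality is exact after
every move by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import _kernels
from .forcefield import ForceFieldParams, total_energy
from .topology import Topology

__all__ = [
    "SystemState",
    "ProtocolConfig",
    "RunResult",
    "acceptance_probability",
    "reaction_move",
    "langevin_step",
    "run_constant_pH",
    "ConstantPHSimulation",
]

LN10 = math.log(10.0)


@dataclass
class SystemState:
    """Dynamic state: coordinates, velocities, ionisation flags, ion pool.

    Positions are wrapped into [0, L); ``images`` counts how many box
    lengths each particle has crossed so trajectories can be unwrapped.
    Hydrogen-ion slots beyond ``n_h`` are inactive storage.
    """

    positions: np.ndarray   # (n_slots, 3) nm, wrapped
    velocities: np.ndarray  # (n_slots, 3) reduced units (kBT = m = 1)
    images: np.ndarray      # (n_slots, 3) int64
    ionised: np.ndarray     # (n_sites,) bool
    n_h: int
    box_length: float

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(),
            self.velocities.copy(),
            self.images.copy(),
            self.ionised.copy(),
            self.n_h,
            self.box_length,
        )

    def n_active(self, topology: Topology) -> int:
        return topology.n_fixed + self.n_h

    def charges(self, topology: Topology) -> np.ndarray:
        return topology.charges(self.ionised, self.n_h)

    def total_charge(self, topology: Topology) -> float:
        n = self.n_active(topology)
        return float(np.sum(self.charges(topology)[:n]))

    def unwrapped_positions(self) -> np.ndarray:
        return self.positions + self.images * self.box_length


@dataclass(frozen=True)
class ProtocolConfig:
    """Sampling protocol (times in units of tau = sigma sqrt(m/eps)).

    The production defaults mirror the reference protocol: 1e5 cycles of
    10 reaction moves followed by 100 velocity-Verlet Langevin steps of
    dt = 0.01 tau at damping gamma = 1/tau, discarding the first 20% of
    cycles as equilibration.
    """

    pH: float = 7.0
    dt: float = 0.01
    gamma: float = 1.0
    cycles: int = 100_000
    reaction_moves_per_cycle: int = 10
    md_steps_per_cycle: int = 100
    equilibration_fraction: float = 0.2
    seed: int = 0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise ValueError("equilibration fraction must be in [0, 1)")


def acceptance_probability(delta_U: float, pH: float, pKA: float, xi: int) -> float:
    """Constant-pH acceptance min[1, exp(-dU + xi (pH - pKA) ln10)], dU in k_BT."""
    if xi not in (+1, -1):
        raise ValueError("xi must be +1 (deprotonation) or -1 (protonation)")
    arg = -delta_U + xi * (pH - pKA) * LN10
    if arg >= 0.0:
        return 1.0
    return math.exp(arg)


class ConstantPHSimulation:
    """Mutable sampler bound to one (topology, state, force field, protocol).

    Keeps the Ewald reciprocal-space structure factor cached across
    reaction moves, updating it incrementally on acceptance and rebuilding
    it after every MD block.
    """

    def __init__(
        self,
        topology: Topology,
        state: SystemState,
        ff: ForceFieldParams,
        cfg: ProtocolConfig,
    ):
        if topology.h_capacity == 0 and topology.n_sites > 0:
            raise ValueError("topology has no hydrogen-ion pool; call with_ions first")
        self.topology = topology
        self.state = state
        self.ff = ff
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.solver = ff.make_solver(state.box_length)
        self.q = topology.charges(state.ionised, state.n_h)
        if self.solver is not None:
            if abs(self.state.total_charge(topology)) > 1e-9:
                raise ValueError("constant-pH sampling requires an electroneutral box")
            self._kvecs = self.solver.kvecs
            self._kint = self.solver.kint
            self._nmax = self.solver.nmax
            self._coef = self.solver.coef
            self._prefactor = self.solver.prefactor
            self._rc = self.solver.r_cut
            self._alpha = self.solver.alpha
            self._self_pref = ff.bjerrum_length * self._alpha / math.sqrt(math.pi)
        else:
            self._kvecs = np.zeros((0, 3))
            self._kint = np.zeros((0, 3), dtype=np.int64)
            self._nmax = 0
            self._coef = np.zeros(0)
            self._prefactor = 0.0
            self._rc = 0.0
            self._alpha = 0.0
            self._self_pref = 0.0
        self._s_re = np.zeros(len(self._coef))
        self._s_im = np.zeros(len(self._coef))
        self._ds_re = np.zeros(len(self._coef))
        self._ds_im = np.zeros(len(self._coef))
        self.refresh_kspace()
        # tau = sigma sqrt(m/eps) with m = 1, eps = 1 kBT -> tau = sigma in nm units
        self._tau = ff.sigma_wca
        self.n_accepted = 0
        self.n_proposed = 0

    # -- cached-state helpers ---------------------------------------------

    @property
    def n(self) -> int:
        return self.state.n_active(self.topology)

    def refresh_kspace(self) -> None:
        if self.solver is None:
            return
        n = self.n
        _kernels.structure_factor(
            self.state.positions[:n], self.q[:n], n, self._kint, self._nmax,
            self.state.box_length, self._s_re, self._s_im,
        )

    def _maxwell_boltzmann(self) -> np.ndarray:
        return self.rng.standard_normal(3)

    # -- reaction move -----------------------------------------------------

    def reaction_move(self, rng: Optional[np.random.Generator] = None) -> bool:
        """One constant-pH reaction proposal; returns True if accepted."""
        rng = self.rng if rng is None else rng
        topo = self.topology
        state = self.state
        if topo.n_sites == 0:
            raise ValueError("no titratable sites in the system")
        s = int(rng.integers(topo.n_sites))
        # symmetric proposal: pick the reaction direction at random and reject
        # outright if the site is not in the matching state (keeps the chain
        # aperiodic even when every compatible proposal is accepted)
        deprotonate = bool(rng.integers(2))
        self.n_proposed += 1
        particle = int(topo.site_particle[s])
        acid = topo.site_valency[s] < 0
        ion = bool(state.ionised[s])
        # neutral acid (HA) or ionised base (BH+) currently carries the proton
        has_proton = (acid and not ion) or (not acid and ion)
        if deprotonate != has_proton:
            return False
        n = self.n
        pos = state.positions
        L = state.box_length
        lB = self.ff.bjerrum_length
        eps = self.ff.epsilon_wca
        sigma = self.ff.sigma_wca
        rcut = self.ff.wca_cutoff

        if deprotonate:
            xi = +1
            dq_site = -1.0
            if state.n_h >= topo.h_capacity:
                return False  # pool exhausted (cannot occur with default sizing)
            r_ion = rng.random(3) * L
            q_ion = 1.0
        else:
            xi = -1
            dq_site = +1.0
            if state.n_h == 0:
                return False  # no H+ available to delete
            h_pick = int(rng.integers(state.n_h))
            slot = topo.h_start + h_pick
            r_ion = pos[slot].copy()
            q_ion = -1.0  # charge increment of the deletion

        # -- energy difference ------------------------------------------------
        delta_U = 0.0
        q_site_old = self.q[particle]
        if lB > 0.0:
            delta_U += _kernels.delta_real_charge(
                pos, self.q, n, L, lB, self._alpha, self._rc, particle, dq_site
            )
        # apply the site toggle provisionally so the ion term sees it
        self.q[particle] += dq_site
        if deprotonate:
            delta_U += _kernels.particle_interaction_energy(
                pos, self.q, n, L, lB, self._alpha, self._rc,
                eps, sigma, rcut, r_ion, 1.0, -1,
            )
        else:
            delta_U -= _kernels.particle_interaction_energy(
                pos, self.q, n, L, lB, self._alpha, self._rc,
                eps, sigma, rcut, r_ion, 1.0, slot,
            )
        if lB > 0.0:
            # Ewald self term -lB alpha/sqrt(pi) sum q^2 changes with both the
            # site toggle and the ion insertion/deletion
            d_sq = (
                (q_site_old + dq_site) ** 2
                - q_site_old**2
                + (1.0 if deprotonate else -1.0)
            )
            delta_U -= self._self_pref * d_sq
        if lB > 0.0:
            dpos = np.vstack([pos[particle], r_ion])
            dqs = np.array([dq_site, q_ion])
            delta_U += _kernels.kspace_delta(
                self._kvecs, self._coef, self._prefactor,
                self._s_re, self._s_im, dpos, dqs, self._ds_re, self._ds_im,
            )

        p_acc = acceptance_probability(
            delta_U, self.cfg.pH, float(topo.site_pKA[s]), xi
        )
        if rng.random() >= p_acc:
            self.q[particle] -= dq_site  # revert
            return False

        # -- commit -----------------------------------------------------------
        state.ionised[s] = not ion
        if deprotonate:
            slot = topo.h_start + state.n_h
            pos[slot] = r_ion
            state.velocities[slot] = self._maxwell_boltzmann()
            state.images[slot] = 0
            self.q[slot] = 1.0
            state.n_h += 1
        else:
            last = topo.h_start + state.n_h - 1
            if slot != last:
                pos[slot] = pos[last]
                state.velocities[slot] = state.velocities[last]
                state.images[slot] = state.images[last]
            self.q[last] = 0.0
            state.n_h -= 1
        if self.solver is not None:
            self._s_re += self._ds_re
            self._s_im += self._ds_im
        self.n_accepted += 1
        return True

    # -- molecular dynamics -------------------------------------------------

    def run_md(self, n_steps: int, rng: Optional[np.random.Generator] = None) -> None:
        """Integrate ``n_steps`` Langevin velocity-Verlet steps."""
        rng = self.rng if rng is None else rng
        n = self.n
        state = self.state
        dt = self.cfg.dt * self._tau
        gamma = self.cfg.gamma / self._tau
        if gamma > 0.0:
            scale = math.sqrt(2.0 * gamma / dt)  # kBT = m = 1
            noise = rng.standard_normal((n_steps, n, 3)) * scale
        else:
            noise = np.zeros((n_steps, n, 3))
        forces_buf = np.empty((n, 3))
        phase_re = np.empty((n, len(self._coef)))
        phase_im = np.empty((n, len(self._coef)))
        status = _kernels.md_block(
            state.positions[:n], state.velocities[:n], state.images[:n],
            self.q[:n], n, self.topology.bonds, self.topology.bond_b0,
            self.ff.k_h, state.box_length, self.ff.bjerrum_length,
            self._alpha, self._rc, self.ff.epsilon_wca, self.ff.sigma_wca,
            self.ff.wca_cutoff, self._kvecs, self._kint, self._nmax,
            self._coef, self._prefactor,
            self._s_re, self._s_im, dt, gamma, n_steps, noise, forces_buf,
            phase_re, phase_im,
        )
        if status != 0:
            raise RuntimeError(
                "Langevin integration unstable: displacement exceeded half "
                "the box in one step"
            )
        self.refresh_kspace()

    # -- observables --------------------------------------------------------

    def measure(self) -> dict[str, float]:
        topo = self.topology
        state = self.state
        acid = topo.acid_sites
        base = topo.base_sites
        out: dict[str, float] = {}
        out["alpha_acid"] = (
            float(state.ionised[acid].mean()) if len(acid) else math.nan
        )
        out["alpha_base"] = (
            float(state.ionised[base].mean()) if len(base) else math.nan
        )
        site_charge = float(
            np.sum(topo.site_valency[state.ionised.astype(bool)])
        )
        out["z"] = site_charge / topo.n_chains
        unwrapped = state.unwrapped_positions()
        re_vals = []
        rg_vals = []
        for c in range(topo.n_chains):
            bb = topo.chain_backbone_indices(c)
            re_vals.append(float(np.linalg.norm(unwrapped[bb[-1]] - unwrapped[bb[0]])))
            beads = unwrapped[topo.chain_indices(c)]
            centred = beads - beads.mean(axis=0)
            rg_vals.append(float(np.sqrt((centred**2).sum(axis=1).mean())))
        out["Re"] = float(np.mean(re_vals))
        out["Rg"] = float(np.mean(rg_vals))
        out["n_h"] = float(state.n_h)
        return out

    def potential_energy(self) -> float:
        return total_energy(self.state, self.topology, self.ff, self.solver)


# -- functional wrappers around the simulation object ------------------------


def reaction_move(
    state: SystemState,
    topology: Topology,
    ff: ForceFieldParams,
    pH: float,
    rng: np.random.Generator,
) -> tuple[SystemState, bool]:
    """Single constant-pH reaction move (state is modified in place)."""
    sim = ConstantPHSimulation(topology, state, ff, ProtocolConfig(pH=pH))
    accepted = sim.reaction_move(rng)
    return state, accepted


def langevin_step(
    state: SystemState,
    topology: Topology,
    ff: ForceFieldParams,
    cfg: ProtocolConfig,
    rng: np.random.Generator,
) -> SystemState:
    """Single Langevin velocity-Verlet step (state is modified in place)."""
    sim = ConstantPHSimulation(topology, state, ff, cfg)
    sim.run_md(1, rng)
    return state


# -- full runs ---------------------------------------------------------------

_SERIES_KEYS = ("alpha_acid", "alpha_base", "z", "Re", "Rg", "n_h", "energy")


@dataclass
class RunResult:
    """Per-cycle observable time series of one constant-pH run."""

    cfg: ProtocolConfig
    series: dict[str, np.ndarray]
    label: str = ""
    acceptance_rate: float = math.nan
    metadata: dict = field(default_factory=dict)

    @property
    def pH(self) -> float:
        return self.cfg.pH

    @property
    def n_cycles(self) -> int:
        return len(next(iter(self.series.values())))

    def production(self, key: str) -> np.ndarray:
        """Series after discarding the configured equilibration fraction."""
        x = self.series[key]
        start = int(round(self.cfg.equilibration_fraction * len(x)))
        return x[start:]

    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for key, arr in self.series.items():
                f.create_dataset(key, data=arr)
            f.attrs["config"] = json.dumps(asdict(self.cfg))
            f.attrs["label"] = self.label
            f.attrs["acceptance_rate"] = self.acceptance_rate
            f.attrs["metadata"] = json.dumps(self.metadata)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "RunResult":
        import h5py

        with h5py.File(path, "r") as f:
            series = {key: f[key][...] for key in f.keys()}
            cfg = ProtocolConfig(**json.loads(f.attrs["config"]))
            return cls(
                cfg=cfg,
                series=series,
                label=str(f.attrs["label"]),
                acceptance_rate=float(f.attrs["acceptance_rate"]),
                metadata=json.loads(f.attrs["metadata"]),
            )


def run_constant_pH(
    topology: Topology,
    state: SystemState,
    ff: ForceFieldParams,
    cfg: ProtocolConfig,
    record_energy: bool = True,
    xyz_path: str | Path | None = None,
    xyz_every: int = 1000,
) -> RunResult:
    """Run the full cycle protocol and collect per-cycle observables.

    Each cycle performs ``reaction_moves_per_cycle`` reaction moves then
    ``md_steps_per_cycle`` Langevin steps; observables are sampled once
    per cycle after the MD block.  The returned series cover all cycles;
    use :meth:`RunResult.production` to drop the equilibration fraction.
    """
    sim = ConstantPHSimulation(topology, state, ff, cfg)
    n = sim.n
    state.velocities[:n] = sim.rng.standard_normal((n, 3))
    series = {key: np.empty(cfg.cycles) for key in _SERIES_KEYS}
    xyz_file = open(xyz_path, "w") if xyz_path is not None else None
    try:
        for cycle in range(cfg.cycles):
            for _ in range(cfg.reaction_moves_per_cycle):
                sim.reaction_move()
            if cfg.md_steps_per_cycle > 0:
                sim.run_md(cfg.md_steps_per_cycle)
            obs = sim.measure()
            for key in _SERIES_KEYS[:-1]:
                series[key][cycle] = obs[key]
            series["energy"][cycle] = (
                sim.potential_energy() if record_energy else math.nan
            )
            if xyz_file is not None and cycle % xyz_every == 0:
                _write_xyz_frame(xyz_file, sim, comment=f"cycle={cycle}")
    finally:
        if xyz_file is not None:
            xyz_file.close()
    acc = sim.n_accepted / max(sim.n_proposed, 1)
    # exact integer electroneutrality check after the full run
    assert abs(state.total_charge(topology)) < 1e-9
    return RunResult(
        cfg=cfg,
        series=series,
        label=topology.label or topology.sequence,
        acceptance_rate=acc,
        metadata={
            "sequence": topology.sequence,
            "n_chains": topology.n_chains,
            "n_salt_pairs": topology.n_salt_pairs,
            "box_length": state.box_length,
        },
    )


_XYZ_ELEMENTS = {0: "C", 1: "O", 2: "N", 3: "H", 4: "Na", 5: "Cl"}


def _write_xyz_frame(fh, sim: ConstantPHSimulation, comment: str = "") -> None:
    topo = sim.topology
    n = sim.n
    fh.write(f"{n}\n{comment}\n")
    pos = sim.state.positions
    for i in range(n):
        el = _XYZ_ELEMENTS[int(topo.kind[i])]
        fh.write(f"{el} {pos[i, 0]:.4f} {pos[i, 1]:.4f} {pos[i, 2]:.4f}\n")
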
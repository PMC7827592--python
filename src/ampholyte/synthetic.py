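"""Scenario construction and synthetic inputs with known ground truth.

Everything the pipeline consumes is generated here: the catalogue of
reference peptide systems (five acid/base compositions, diblock and
alternating sequences, 10 chains with 100 salt pairs in a 25.513 nm box,
i.e. 5 mM per ionisable-group species and 10 mM added salt), initial
particle configurations, and synthetic potentiometric/NMR records built
by inverting the data-reduction formulas so round-trip recovery can be
asserted to numerical precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from .engine import ProtocolConfig, RunResult, SystemState, run_constant_pH
from .experiment import DEFAULT_PKW, ShiftRecord, TitrationRecord
from .forcefield import ForceFieldParams
from .ideal import Composition
from .residues import DEFAULT_RESIDUES
from .topology import PeptideSpec, Topology, build_topology

__all__ = [
    "AVOGADRO",
    "box_length_for_concentration",
    "concentration_in_box",
    "Scenario",
    "reference_scenarios",
    "make_scenario",
    "chain_length_family",
    "initial_configuration",
    "run_scenario",
    "synth_titration_record",
    "synth_shift_record",
]

#: exact SI Avogadro constant, 1/mol
AVOGADRO = 6.02214076e23

_NM3_PER_LITRE = 1e24


def box_length_for_concentration(n_groups: int, conc: float) -> float:
    """Cubic box edge (nm) holding ``n_groups`` particles at ``conc`` mol/L."""
    if n_groups <= 0 or conc <= 0:
        raise ValueError("n_groups and conc must be positive")
    volume_nm3 = n_groups / (AVOGADRO * conc) * _NM3_PER_LITRE
    return volume_nm3 ** (1.0 / 3.0)


def concentration_in_box(n_particles: int, box_length: float) -> float:
    """Concentration (mol/L) of ``n_particles`` in a cubic box of edge nm."""
    volume_litre = box_length**3 / _NM3_PER_LITRE
    return n_particles / (AVOGADRO * volume_litre)


#: per-species ionisable-group concentration of the reference systems, mol/L
GROUP_CONCENTRATION = 5e-3
#: added 1:1 salt concentration of the reference systems, mol/L
SALT_CONCENTRATION = 10e-3


@dataclass
class Scenario:
    """A fully specified simulated system plus its default pH sweep."""

    name: str
    spec: PeptideSpec
    box_length: float
    n_salt_pairs: int
    pH_values: tuple[float, ...] = ()
    protocol: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_length <= 0:
            raise ValueError("box length must be positive")

    @property
    def composition(self) -> Composition:
        return Composition.from_sequence(self.spec.sequence)

    def build_topology(self) -> Topology:
        topo = build_topology(self.spec)
        topo.label = self.name
        return topo.with_ions(self.n_salt_pairs)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "sequence": self.spec.sequence,
            "n_chains": self.spec.n_chains,
            "box_length_nm": self.box_length,
            "n_salt_pairs": self.n_salt_pairs,
            "pH_values": list(self.pH_values),
            "protocol": dict(self.protocol),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scenario":
        return cls(
            name=d["name"],
            spec=PeptideSpec(d["sequence"], d["n_chains"], d["name"]),
            box_length=d["box_length_nm"],
            n_salt_pairs=d["n_salt_pairs"],
            pH_values=tuple(d.get("pH_values", ())),
            protocol=dict(d.get("protocol", {})),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _default_pH_grid(sequence: str) -> tuple[float, ...]:
    comp = Composition.from_sequence(sequence)
    pkas = [pka for pka, _, _ in comp.groups]
    lo = math.floor(min(pkas) - 3)
    hi = math.ceil(max(pkas) + 3)
    return tuple(float(p) for p in range(lo, hi + 1))


def make_scenario(
    name: str,
    sequence: str,
    n_chains: int = 10,
    pH_values: Sequence[float] | None = None,
    seed: int = 0,
    protocol: Mapping[str, object] | None = None,
) -> Scenario:
    """Scenario at the reference concentrations for an arbitrary system size.

    The box edge is set so each ionisable-group species (acid count is
    assumed equal to base count) sits at 5 mM, and the salt pair count so
    the added salt is 10 mM, matching the reference conditions at any
    chain count or length.
    """
    comp = Composition.from_sequence(sequence)
    n_groups = n_chains * max(comp.n_acid, comp.n_base)
    L = box_length_for_concentration(n_groups, GROUP_CONCENTRATION)
    volume_litre = L**3 / _NM3_PER_LITRE
    n_salt = round(SALT_CONCENTRATION * AVOGADRO * volume_litre)
    return Scenario(
        name=name,
        spec=PeptideSpec(sequence, n_chains, name),
        box_length=L,
        n_salt_pairs=int(n_salt),
        pH_values=tuple(pH_values) if pH_values is not None else _default_pH_grid(sequence),
        protocol=dict(protocol or {}),
        seed=seed,
    )


_CATALOGUE_ROWS = [
    # (diblock name, diblock seq, alternating name, alternating seq)
    ("Lys5-Asp5", "KKKKKDDDDD", "(Lys-Asp)5", "KDKDKDKDKD"),
    ("Glu5-His5", "EEEEEHHHHH", "(Glu-His)5", "EHEHEHEHEH"),
    ("Tyr5-Lys5", "YYYYYKKKKK", "(Tyr-Lys)5", "YKYKYKYKYK"),
    ("Acid5-Base5", "aaaaabbbbb", "(Acid-Base)5", "ababababab"),
    ("Tyr5-His5", "YYYYYHHHHH", "(Tyr-His)5", "YHYHYHYHYH"),
]


def reference_scenarios(n_chains: int = 10) -> dict[str, Scenario]:
    """The ten reference systems: five compositions x {diblock, alternating}.

    With the default ``n_chains=10`` each system has 100 salt pairs and a
    25.513 nm box; smaller chain counts rescale the box and salt to hold
    the same concentrations (useful for quick runs).
    """
    catalogue: dict[str, Scenario] = {}
    for dname, dseq, aname, aseq in _CATALOGUE_ROWS:
        catalogue[dname] = make_scenario(dname, dseq, n_chains)
        catalogue[aname] = make_scenario(aname, aseq, n_chains)
    return catalogue


def chain_length_family(
    n_repeats: Sequence[int] = (5, 10, 20), n_chains: int = 10
) -> dict[str, Scenario]:
    """Lys_n-Asp_n and (Lys-Asp)_n systems of growing chain length N = 2n.

    Box and salt are rescaled with the group count so the per-species
    concentration stays 5 mM and the added salt 10 mM.
    """
    catalogue: dict[str, Scenario] = {}
    for n in n_repeats:
        dname = f"Lys{n}-Asp{n}"
        aname = f"(Lys-Asp){n}"
        catalogue[dname] = make_scenario(dname, "K" * n + "D" * n, n_chains)
        catalogue[aname] = make_scenario(aname, "KD" * n, n_chains)
    return catalogue


# -- initial configurations ---------------------------------------------------

# separation below which the WCA repulsion exceeds ~50 kBT (in units of sigma)
_MIN_SEP_FACTOR = 0.80


def initial_configuration(
    scenario: Scenario,
    rng: np.random.Generator | int | None = None,
    ff: ForceFieldParams | None = None,
) -> SystemState:
    """Electroneutral starting state: chains as non-overlapping random walks.

    Chains are grown as off-lattice random walks with every bond at its
    rest length, rejecting placements closer than 0.8 sigma to any placed
    bead (where the WCA energy would exceed ~50 k_BT); ions are placed
    uniformly with the same clearance.  The peptide starts fully
    protonated (acids neutral, bases ionised) with the matching fixed
    neutralising anions and an empty hydrogen-ion pool, mirroring a
    peptide salt dissolved in acid; the box is electroneutral and every
    ionisation state is reachable from here.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng if rng is not None else scenario.seed)
    ff = ff or ForceFieldParams()
    topo = scenario.build_topology()
    L = scenario.box_length
    sigma = ff.sigma_wca
    min_sep = _MIN_SEP_FACTOR * sigma if ff.epsilon_wca > 0 else 0.0

    n_slots = topo.n_slots
    pos = np.zeros((n_slots, 3))
    placed: list[int] = []

    def clear_of(p: np.ndarray, exclude_last: int = 0) -> bool:
        if min_sep == 0.0 or not placed:
            return True
        idx = placed[: len(placed) - exclude_last] if exclude_last else placed
        if not idx:
            return True
        d = pos[idx] - p
        d -= L * np.round(d / L)
        return bool(np.min(np.einsum("ij,ij->i", d, d)) >= min_sep * min_sep)

    registry = DEFAULT_RESIDUES

    def place(particle: int, p: np.ndarray) -> None:
        pos[particle] = p
        placed.append(particle)

    max_chain_attempts = 200
    for c in range(topo.n_chains):
        for attempt in range(max_chain_attempts):
            trial_placed_start = len(placed)
            start = rng.random(3) * L
            if not clear_of(start):
                continue
            ok = True
            prev = start.copy()
            for i, code in enumerate(scenario.spec.sequence):
                res = registry[code]
                if i == 0:
                    p_c = start
                else:
                    p_c = None
                    for _ in range(50):
                        step = rng.standard_normal(3)
                        step *= 0.382 / np.linalg.norm(step)
                        cand = prev + step
                        if clear_of(cand):
                            p_c = cand
                            break
                    if p_c is None:
                        ok = False
                        break
                particle = c * 2 * len(scenario.spec.sequence) + 2 * i
                place(particle, p_c)
                p_s = None
                for _ in range(50):
                    step = rng.standard_normal(3)
                    step *= res.bond_length_sidechain / np.linalg.norm(step)
                    cand = p_c + step
                    if clear_of(cand):
                        p_s = cand
                        break
                if p_s is None:
                    ok = False
                    break
                place(particle + 1, p_s)
                prev = p_c
            if ok:
                break
            del placed[trial_placed_start:]
        else:
            raise RuntimeError(
                f"could not place chain {c} without severe overlap; box too small"
            )

    # ions: salt plus the fixed neutralising anions; the H+ pool starts empty
    # because every site starts in its protonated state
    n_h0 = 0
    n_ions = 2 * topo.n_salt_pairs + topo.n_extra_anions
    ion_start = topo.n_peptide_beads
    for k in range(n_ions):
        for _ in range(1000):
            p = rng.random(3) * L
            if clear_of(p):
                break
        else:
            raise RuntimeError("could not place ions without severe overlap")
        place(ion_start + k, p)

    images = np.floor(pos / L).astype(np.int64)
    pos -= images * L

    state = SystemState(
        positions=pos,
        velocities=np.zeros((n_slots, 3)),
        images=images,
        # fully protonated start: acids neutral (HA), bases ionised (BH+)
        ionised=topo.site_valency > 0,
        n_h=n_h0,
        box_length=L,
    )
    assert abs(state.total_charge(topo)) < 1e-9
    return state


def run_scenario(
    scenario: Scenario,
    pH: float,
    seed: int = 0,
    ff: ForceFieldParams | None = None,
    **protocol_overrides,
) -> RunResult:
    """Build and run one scenario at one pH; returns the observable series."""
    ff = ff or ForceFieldParams()
    params = {**dict(scenario.protocol), **protocol_overrides}
    cfg = ProtocolConfig(pH=pH, seed=seed, **params)
    topo = scenario.build_topology()
    state = initial_configuration(scenario, rng=seed, ff=ff)
    result = run_constant_pH(topo, state, ff, cfg)
    result.metadata["scenario"] = scenario.name
    return result


# -- synthetic experimental records -------------------------------------------


def synth_titration_record(
    z_of_pH: Callable[[np.ndarray], np.ndarray],
    pH_values: Sequence[float] | np.ndarray = tuple(np.linspace(2.5, 11.5, 25)),
    x_TFA: float = 0.0,
    noise_pH: float = 0.0,
    rng: np.random.Generator | int | None = None,
    V_HCl: float = 2.0,
    c_HCl: float = 0.01,
    c_NaOH: float = 0.01,
    c_peptide: float = 1e-3,
    z_max: int = 5,
    pKw: float = DEFAULT_PKW,
) -> TitrationRecord:
    """Invert the proton balance to fabricate a titration with known truth.

    For each pH the NaOH volume consistent with the ground-truth charge is
    solved in closed form (the balance is linear in V_NaOH).  Optional
    Gaussian noise perturbs the reported pH only; the exact truth is kept
    in ``record.metadata`` for round-trip tests.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pH = np.asarray(sorted(pH_values), dtype=float)
    z_true = np.asarray(z_of_pH(pH), dtype=float)
    c_H = 10.0 ** (-pH)
    c_OH = 10.0 ** (pH - pKw)
    w = c_OH - c_H
    z_prime = z_true - z_max * x_TFA
    V = V_HCl * (z_prime * c_peptide - c_HCl - w) / (w - c_NaOH)
    if np.any(V < 0):
        raise ValueError("ground truth implies negative titrant volumes")
    if np.any(np.diff(V) < 0):
        raise ValueError("ground truth implies non-monotone titrant volumes")
    pH_meas = pH + (rng.normal(0.0, noise_pH, len(pH)) if noise_pH > 0 else 0.0)
    return TitrationRecord(
        V_HCl=V_HCl,
        c_HCl=c_HCl,
        V_NaOH=V,
        c_NaOH=c_NaOH,
        pH=pH_meas,
        c_peptide=c_peptide,
        z_max=z_max,
        pKw=pKw,
        metadata={"z_true": z_true, "x_TFA_true": x_TFA, "pH_true": pH},
    )


def synth_shift_record(
    alpha_of_pH: Callable[[np.ndarray], np.ndarray],
    delta_min: float,
    delta_max: float,
    group_type: str = "base",
    pH_values: Sequence[float] | np.ndarray = tuple(np.linspace(2.0, 12.0, 21)),
    noise: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> ShiftRecord:
    """Fabricate an NMR chemical-shift record from a known ionisation curve."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if not delta_max > delta_min:
        raise ValueError("delta_max must exceed delta_min")
    pH = np.asarray(pH_values, dtype=float)
    alpha = np.asarray(alpha_of_pH(pH), dtype=float)
    span = delta_max - delta_min
    if group_type == "base":
        delta = delta_max - alpha * span
    else:
        delta = delta_min + alpha * span
    if noise > 0:
        delta = delta + rng.normal(0.0, noise, len(pH))
    return ShiftRecord(
        pH=pH,
        delta=delta,
        delta_min=delta_min,
        delta_max=delta_max,
        group_type=group_type,
        metadata={"alpha_true": alpha},
    )
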
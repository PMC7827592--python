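"""Bead/bond topology for multi-chain two-bead peptide systems.

A chain of ``N`` residues maps onto ``N`` backbone beads C connected by
harmonic bonds of length ``b_CC`` plus one titratable side-chain bead per
residue (A for acids, B for bases) attached by a residue-specific bond.
Explicit ions (hydrogen ions, salt cations/anions) occupy additional
particle slots appended after the peptide beads; the hydrogen-ion slots
form a variable-occupancy pool managed by the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .residues import DEFAULT_RESIDUES, ResidueParams

__all__ = [
    "BEAD_BACKBONE",
    "BEAD_SIDECHAIN_ACID",
    "BEAD_SIDECHAIN_BASE",
    "BEAD_HYDROGEN",
    "BEAD_CATION",
    "BEAD_ANION",
    "BOND_LENGTH_CC",
    "PeptideSpec",
    "Topology",
    "build_topology",
]

# bead kind codes (stable: used in XYZ dumps and debug tables)
BEAD_BACKBONE = 0
BEAD_SIDECHAIN_ACID = 1
BEAD_SIDECHAIN_BASE = 2
BEAD_HYDROGEN = 3
BEAD_CATION = 4
BEAD_ANION = 5

_KIND_NAMES = {
    BEAD_BACKBONE: "C",
    BEAD_SIDECHAIN_ACID: "A",
    BEAD_SIDECHAIN_BASE: "B",
    BEAD_HYDROGEN: "H",
    BEAD_CATION: "Na",
    BEAD_ANION: "Cl",
}

#: backbone-backbone equilibrium bond length, nm (common to all residue pairs)
BOND_LENGTH_CC = 0.382


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide sequence replicated over ``n_chains`` identical chains."""

    sequence: str
    n_chains: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @classmethod
    def diblock(
        cls,
        acid: str,
        base: str,
        n: int,
        n_chains: int = 1,
        acid_first: bool = False,
        label: str = "",
    ) -> "PeptideSpec":
        """Diblock sequence: a block of ``n`` bases then ``n`` acids (or reversed)."""
        seq = acid * n + base * n if acid_first else base * n + acid * n
        return cls(seq, n_chains, label or f"{base}{n}-{acid}{n}")

    @classmethod
    def alternating(
        cls,
        acid: str,
        base: str,
        n: int,
        n_chains: int = 1,
        acid_first: bool = False,
        label: str = "",
    ) -> "PeptideSpec":
        """Alternating sequence of ``n`` acid/base pairs."""
        pair = acid + base if acid_first else base + acid
        return cls(pair * n, n_chains, label or f"({base}-{acid}){n}")


@dataclass
class Topology:
    """Static particle table of one simulated system.

    Peptide beads come first (chain-major, residue-minor, backbone before
    side chain), then salt cations, salt anions, any extra neutralising
    anions, and finally the hydrogen-ion slot pool whose occupancy the
    constant-pH sampler varies between 0 and ``h_capacity``.
    """

    kind: np.ndarray          # (n_slots,) int8 bead-kind codes
    chain: np.ndarray         # (n_slots,) int32, -1 for ions
    residue: np.ndarray       # (n_slots,) int32, -1 for ions
    fixed_charge: np.ndarray  # (n_slots,) float64; ions carry their valency here
    bonds: np.ndarray         # (n_bonds, 2) int32
    bond_b0: np.ndarray       # (n_bonds,) float64, equilibrium lengths in nm
    site_particle: np.ndarray  # (n_sites,) int32 particle index of titratable beads
    site_pKA: np.ndarray       # (n_sites,) float64
    site_valency: np.ndarray   # (n_sites,) int8 ionised-state valency (-1 acid, +1 base)
    n_chains: int
    residues_per_chain: int
    n_salt_pairs: int = 0
    n_extra_anions: int = 0
    h_capacity: int = 0
    sequence: str = ""
    label: str = ""

    @property
    def n_slots(self) -> int:
        return len(self.kind)

    @property
    def n_peptide_beads(self) -> int:
        return 2 * self.n_chains * self.residues_per_chain

    @property
    def n_fixed(self) -> int:
        """Particles always present (peptide beads + salt + extra anions)."""
        return self.n_slots - self.h_capacity

    @property
    def h_start(self) -> int:
        return self.n_fixed

    @property
    def n_sites(self) -> int:
        return len(self.site_particle)

    @property
    def acid_sites(self) -> np.ndarray:
        return np.flatnonzero(self.site_valency < 0)

    @property
    def base_sites(self) -> np.ndarray:
        return np.flatnonzero(self.site_valency > 0)

    def with_ions(
        self, n_salt_pairs: int, n_extra_anions: int | None = None
    ) -> "Topology":
        """Return a copy extended with salt ions and the hydrogen-ion pool.

        ``n_extra_anions`` defaults to the number of base sites: the
        neutralising counterions (chloride/TFA in the experiments) that
        accompany a fully protonated peptide.  Starting from the fully
        protonated state with these fixed anions, the free-H+ inventory is
        n_ionised_acid + n_neutral_base >= 0, so every physical ionisation
        state is reachable by charge-conserving reaction moves.  The
        hydrogen pool capacity is the total site count, the hard upper
        bound on that inventory.
        """
        if self.h_capacity or self.n_salt_pairs:
            raise ValueError("topology already has ions attached")
        n_base = len(self.base_sites)
        if n_extra_anions is None:
            n_extra_anions = n_base
        h_capacity = self.n_sites
        n_new = 2 * n_salt_pairs + n_extra_anions + h_capacity
        kind = np.concatenate(
            [
                self.kind,
                np.full(n_salt_pairs, BEAD_CATION, dtype=np.int8),
                np.full(n_salt_pairs + n_extra_anions, BEAD_ANION, dtype=np.int8),
                np.full(h_capacity, BEAD_HYDROGEN, dtype=np.int8),
            ]
        )
        minus1 = np.full(n_new, -1, dtype=np.int32)
        fixed_charge = np.concatenate(
            [
                self.fixed_charge,
                np.ones(n_salt_pairs),
                -np.ones(n_salt_pairs + n_extra_anions),
                np.ones(h_capacity),  # occupied H slots carry +1
            ]
        )
        return replace(
            self,
            kind=kind,
            chain=np.concatenate([self.chain, minus1]),
            residue=np.concatenate([self.residue, minus1]),
            fixed_charge=fixed_charge,
            n_salt_pairs=n_salt_pairs,
            n_extra_anions=n_extra_anions,
            h_capacity=h_capacity,
        )

    def charges(self, ionised: np.ndarray, n_h: int) -> np.ndarray:
        """Per-slot charge vector for given site states and H+ count.

        Unoccupied hydrogen slots (index >= h_start + n_h) get charge 0 so
        the vector can be used directly with an active-particle slice.
        """
        q = self.fixed_charge.copy()
        q[self.h_start + n_h :] = 0.0
        idx = self.site_particle[np.asarray(ionised, dtype=bool)]
        q[idx] += self.site_valency[np.asarray(ionised, dtype=bool)]
        return q

    def chain_backbone_indices(self, chain: int) -> np.ndarray:
        """Particle indices of the backbone beads of one chain, in order."""
        n = self.residues_per_chain
        return np.arange(chain * 2 * n, (chain + 1) * 2 * n, 2, dtype=np.int64)

    def chain_indices(self, chain: int) -> np.ndarray:
        """All particle indices of one chain."""
        n = self.residues_per_chain
        return np.arange(chain * 2 * n, (chain + 1) * 2 * n, dtype=np.int64)

    def debug_table(self) -> str:
        """Plain-text bead and bond tables for debugging."""
        lines = ["# index\tkind\tchain\tresidue\tfixed_charge"]
        for i in range(self.n_slots):
            lines.append(
                f"{i}\t{_KIND_NAMES[int(self.kind[i])]}\t{self.chain[i]}"
                f"\t{self.residue[i]}\t{self.fixed_charge[i]:+.0f}"
            )
        lines.append("# bond_i\tbond_j\tb0_nm")
        for (i, j), b0 in zip(self.bonds, self.bond_b0):
            lines.append(f"{i}\t{j}\t{b0:.3f}")
        return "\n".join(lines)


def build_topology(
    spec: PeptideSpec,
    registry: Mapping[str, ResidueParams] | None = None,
) -> Topology:
    """Build the bead/bond topology for a peptide spec.

    Every residue contributes a backbone bead and a side-chain bead; the
    side chain of an acid/base residue is registered as a titratable site
    carrying the residue's reference pK_A.
    """
    registry = DEFAULT_RESIDUES if registry is None else registry
    seq = spec.sequence
    if not seq:
        raise ValueError("empty peptide sequence")
    for code in seq:
        if code not in registry:
            raise KeyError(f"unknown residue code {code!r}")

    n_res = len(seq)
    n_beads = 2 * n_res * spec.n_chains
    kind = np.empty(n_beads, dtype=np.int8)
    chain = np.empty(n_beads, dtype=np.int32)
    residue = np.empty(n_beads, dtype=np.int32)
    bonds: list[tuple[int, int]] = []
    bond_b0: list[float] = []
    site_particle: list[int] = []
    site_pKA: list[float] = []
    site_valency: list[int] = []

    for c in range(spec.n_chains):
        base = c * 2 * n_res
        for i, code in enumerate(seq):
            res = registry[code]
            ic = base + 2 * i
            kind[ic] = BEAD_BACKBONE
            kind[ic + 1] = (
                BEAD_SIDECHAIN_ACID if res.group_type == "acid" else BEAD_SIDECHAIN_BASE
            )
            chain[ic : ic + 2] = c
            residue[ic : ic + 2] = i
            bonds.append((ic, ic + 1))
            bond_b0.append(res.bond_length_sidechain)
            if i > 0:
                bonds.append((ic - 2, ic))
                bond_b0.append(BOND_LENGTH_CC)
            if res.group_type in ("acid", "base"):
                site_particle.append(ic + 1)
                site_pKA.append(res.pKA)
                site_valency.append(res.ionized_valency)

    return Topology(
        kind=kind,
        chain=chain,
        residue=residue,
        fixed_charge=np.zeros(n_beads),
        bonds=np.asarray(bonds, dtype=np.int32).reshape(-1, 2),
        bond_b0=np.asarray(bond_b0),
        site_particle=np.asarray(site_particle, dtype=np.int32),
        site_pKA=np.asarray(site_pKA),
        site_valency=np.asarray(site_valency, dtype=np.int8),
        n_chains=spec.n_chains,
        residues_per_chain=n_res,
        sequence=seq,
        label=spec.label,
    )
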
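"""Per-residue parameters of the two-bead peptide model.

Each amino acid is reduced to a backbone bead C plus one titratable
side-chain bead (A for acids, B for bases).  The table shipped with the
package covers the five natural amino acids used in the reference
simulations (Asp, Glu, His, Tyr, Lys) and the two hypothetical residues
``a``/``b`` that share pK_A = 6 so that the acid/base asymmetry vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

__all__ = [
    "ResidueParams",
    "DEFAULT_RESIDUES",
    "load_residue_table",
    "write_residue_table",
]


@dataclass(frozen=True)
class ResidueParams:
    """Coarse-grained parameters of a single amino-acid type.

    Parameters
    ----------
    code : str
        One-letter residue code (case sensitive: ``a``/``b`` are the
        hypothetical acid/base).
    name : str
        Full residue name.
    pKA : float
        Acidity constant of the ionisable side chain.
    group_type : {"acid", "base", "none"}
        Whether the side chain is a weak acid, a weak base, or inert.
    bond_length_sidechain : float
        Equilibrium backbone-to-side-chain bond length in nm.
    """

    code: str
    name: str
    pKA: float
    group_type: str
    bond_length_sidechain: float

    def __post_init__(self) -> None:
        if self.group_type not in ("acid", "base", "none"):
            raise ValueError(f"unknown group_type {self.group_type!r}")
        if not self.bond_length_sidechain > 0:
            raise ValueError("bond_length_sidechain must be positive")

    @property
    def ionized_valency(self) -> int:
        """Charge of the side chain in its ionised state (e units)."""
        if self.group_type == "acid":
            return -1
        if self.group_type == "base":
            return +1
        return 0


def _builtin_table() -> dict[str, ResidueParams]:
    rows = [
        ("D", "aspartic acid", 3.65, "acid", 0.327),
        ("E", "glutamic acid", 4.25, "acid", 0.436),
        ("H", "histidine", 6.00, "base", 0.453),
        ("Y", "tyrosine", 10.07, "acid", 0.648),
        ("K", "lysine", 10.54, "base", 0.589),
        ("a", "hypothetical acid", 6.00, "acid", 0.355),
        ("b", "hypothetical base", 6.00, "base", 0.355),
    ]
    return {
        code: ResidueParams(code, name, pka, kind, blen)
        for code, name, pka, kind, blen in rows
    }


DEFAULT_RESIDUES: Mapping[str, ResidueParams] = _builtin_table()


def load_residue_table(path: str | Path | None = None) -> dict[str, ResidueParams]:
    """Load a residue parameter table from a TSV file.

    Columns: ``code  name  pKA  group_type  bond_length_nm``.  With no
    argument the table shipped with the package is loaded (identical to
    :data:`DEFAULT_RESIDUES`).
    """
    if path is None:
        ref = resources.files("ampholyte").joinpath("data/residues.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, ResidueParams] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code, name, pka, kind, blen = line.split("\t")
        table[code] = ResidueParams(code, name, float(pka), kind, float(blen))
    return table


def write_residue_table(table: Mapping[str, ResidueParams], path: str | Path) -> None:
    """Write a residue table in the same TSV format read by :func:`load_residue_table`."""
    lines = ["# code\tname\tpKA\tgroup_type\tbond_length_nm"]
    for res in table.values():
        lines.append(
            f"{res.code}\t{res.name}\t{res.pKA}\t{res.group_type}"
            f"\t{res.bond_length_sidechain}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
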
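"""Reduction of experimental titration and NMR records to charge curves.

Potentiometric titration: a peptide dissolved in HCl is titrated with
NaOH; the peptide charge follows from the proton balance

    z = [V_HCl c_HCl - V_NaOH c_NaOH + (c_OH - c_H)(V_HCl + V_NaOH)]
        / (c_peptide V_HCl)  +  z_max x_TFA,

with c_H = 10^-pH and c_OH = 10^(pH - pKw).  The trifluoroacetate mole
fraction x_TFA (excess counterions in the synthesised sample) is unknown
a priori and is calibrated by anchoring the curve to a known charge at
one pH.  The balance is reliable only at intermediate pH (roughly
3 < pH < 11) because c_H/c_OH amplify pH and pKw errors at the extremes.

NMR: the ionisation degree of a reporter group follows from its chemical
shift between the fully-protonated and fully-deprotonated plateaus:
alpha_base = (d_max - d)/(d_max - d_min), alpha_acid = (d - d_min)/(d_max - d_min).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PKW",
    "TitrationRecord",
    "ShiftRecord",
    "titration_charge",
    "calibrate_xTFA",
    "nmr_alpha",
]

#: ion product of water at 25 degC (concentration scale); user-overridable
DEFAULT_PKW = 13.997


@dataclass
class TitrationRecord:
    """One potentiometric titration: NaOH volume vs measured pH."""

    V_HCl: float                 # mL, initial HCl volume
    c_HCl: float                 # mol/L
    V_NaOH: np.ndarray           # mL per titration point, non-decreasing
    c_NaOH: float                # mol/L
    pH: np.ndarray               # measured pH per point
    c_peptide: float             # mol/L of peptide chains
    z_max: int = 5               # number of basic side chains per peptide
    pKw: float = DEFAULT_PKW
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.V_NaOH = np.asarray(self.V_NaOH, dtype=float)
        self.pH = np.asarray(self.pH, dtype=float)
        if self.V_HCl <= 0 or self.c_HCl <= 0 or self.c_NaOH <= 0 or self.c_peptide <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if np.any(self.V_NaOH < 0) or np.any(np.diff(self.V_NaOH) < 0):
            raise ValueError("V_NaOH must be non-negative and non-decreasing")
        if len(self.V_NaOH) != len(self.pH):
            raise ValueError("V_NaOH and pH must have the same length")

    @property
    def reliable_mask(self) -> np.ndarray:
        """Points inside the 3 < pH < 11 window where the balance is trusted."""
        return (self.pH > 3.0) & (self.pH < 11.0)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"V_NaOH_mL": self.V_NaOH, "pH": self.pH})
        header = (
            f"# V_HCl_mL={self.V_HCl} c_HCl_M={self.c_HCl} c_NaOH_M={self.c_NaOH}"
            f" c_peptide_M={self.c_peptide} z_max={self.z_max} pKw={self.pKw}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TitrationRecord":
        with open(path) as fh:
            header = fh.readline()
            df = pd.read_csv(fh)
        kv = dict(tok.split("=") for tok in header.lstrip("#").split())
        return cls(
            V_HCl=float(kv["V_HCl_mL"]),
            c_HCl=float(kv["c_HCl_M"]),
            V_NaOH=df["V_NaOH_mL"].to_numpy(),
            c_NaOH=float(kv["c_NaOH_M"]),
            pH=df["pH"].to_numpy(),
            c_peptide=float(kv["c_peptide_M"]),
            z_max=int(kv["z_max"]),
            pKw=float(kv["pKw"]),
        )


@dataclass
class ShiftRecord:
    """Chemical shifts of one reporter group across a pH series."""

    pH: np.ndarray
    delta: np.ndarray        # ppm
    delta_min: float         # ppm, plateau
    delta_max: float         # ppm, plateau
    group_type: str          # "acid" or "base"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pH = np.asarray(self.pH, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if not self.delta_max > self.delta_min:
            raise ValueError("delta_max must exceed delta_min")
        if self.group_type not in ("acid", "base"):
            raise ValueError("group_type must be acid or base")

    def to_csv(self, path: str | Path) -> None:
        header = (
            f"# delta_min_ppm={self.delta_min} delta_max_ppm={self.delta_max}"
            f" group_type={self.group_type}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            pd.DataFrame({"pH": self.pH, "delta_ppm": self.delta}).to_csv(
                fh, index=False
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ShiftRecord":
        with open(path) as fh:
            header = fh.readline()
            df = pd.read_csv(fh)
        kv = dict(tok.split("=") for tok in header.lstrip("#").split())
        return cls(
            pH=df["pH"].to_numpy(),
            delta=df["delta_ppm"].to_numpy(),
            delta_min=float(kv["delta_min_ppm"]),
            delta_max=float(kv["delta_max_ppm"]),
            group_type=kv["group_type"],
        )


def titration_charge(record: TitrationRecord, x_TFA: float = 0.0) -> np.ndarray:
    """Peptide charge per titration point from the proton balance."""
    if x_TFA < 0:
        raise ValueError("x_TFA must be non-negative")
    pH = record.pH
    if np.any(pH < 0) or np.any(pH > 14):
        raise ValueError("pH outside [0, 14]")
    c_H = 10.0 ** (-pH)
    c_OH = 10.0 ** (pH - record.pKw)
    num = (
        record.V_HCl * record.c_HCl
        - record.V_NaOH * record.c_NaOH
        + (c_OH - c_H) * (record.V_HCl + record.V_NaOH)
    )
    return num / (record.c_peptide * record.V_HCl) + record.z_max * x_TFA


def calibrate_xTFA(
    record: TitrationRecord, anchor: tuple[float, float]
) -> float:
    """Solve for the x_TFA that puts the reduced curve through an anchor.

    ``anchor = (pH*, z*)``.  The reduced charge is affine in x_TFA with
    slope z_max, so the solution is closed-form; the curve at x_TFA = 0 is
    linearly interpolated in pH at the anchor.  Standard anchors are
    (6.0, z at pH 6) and the fully charged plateau (5.0, +z_max).
    """
    pH_star, z_star = anchor
    lo, hi = float(np.min(record.pH)), float(np.max(record.pH))
    if not lo <= pH_star <= hi:
        raise ValueError(
            f"anchor pH {pH_star} outside the record's range [{lo}, {hi}]"
        )
    z0 = titration_charge(record, x_TFA=0.0)
    order = np.argsort(record.pH)
    z_at_anchor = float(np.interp(pH_star, record.pH[order], z0[order]))
    return (z_star - z_at_anchor) / record.z_max


def nmr_alpha(
    record: ShiftRecord, clip: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Degree of ionisation per pH point from chemical shifts.

    Returns ``(alpha, out_of_bounds)`` where the flag marks points whose
    raw value left [0, 1] (plateau noise); values are clipped unless
    ``clip=False``.
    """
    span = record.delta_max - record.delta_min
    if record.group_type == "base":
        alpha = (record.delta_max - record.delta) / span
    else:
        alpha = (record.delta - record.delta_min) / span
    flag = (alpha < 0.0) | (alpha > 1.0)
    if clip:
        alpha = np.clip(alpha, 0.0, 1.0)
    return alpha, flag
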
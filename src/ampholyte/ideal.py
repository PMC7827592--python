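"""Ideal (Henderson-Hasselbalch) titration reference.

An isolated weak acid HA <-> A- + H+ or base BH+ <-> B + H+ ionises
according to

    acid:  pH - pKA = log10( alpha / (1 - alpha) )
    base:  pH - pKA = log10( (1 - alpha) / alpha )

so alpha_acid = 1/(1 + 10^(pKA - pH)) and alpha_base = 1/(1 + 10^(pH - pKA)).
The ideal net charge of an ampholyte is the valency-weighted sum of the
per-group ionisation degrees, z(pH) = sum_i alpha_i(pH) z_i, which is
strictly decreasing in pH; its unique root is the ideal isoelectric point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .residues import DEFAULT_RESIDUES, ResidueParams

__all__ = [
    "Composition",
    "hh_alpha",
    "ideal_net_charge",
    "ideal_isoelectric_point",
    "ideal_curve",
]


@dataclass(frozen=True)
class Composition:
    """Ionisable-group composition: (pKA, group_type, count) triples."""

    groups: tuple[tuple[float, str, int], ...]

    def __post_init__(self) -> None:
        for pka, kind, count in self.groups:
            if kind not in ("acid", "base"):
                raise ValueError(f"group_type must be acid or base, got {kind!r}")
            if int(count) != count or count <= 0:
                raise ValueError("counts must be positive integers")

    @classmethod
    def from_sequence(
        cls,
        sequence: str,
        registry: Mapping[str, ResidueParams] | None = None,
    ) -> "Composition":
        """Collect ionisable groups of a one-letter sequence."""
        registry = DEFAULT_RESIDUES if registry is None else registry
        counts: dict[tuple[float, str], int] = {}
        for code in sequence:
            res = registry[code]
            if res.group_type == "none":
                continue
            key = (res.pKA, res.group_type)
            counts[key] = counts.get(key, 0) + 1
        return cls(tuple((pka, kind, n) for (pka, kind), n in sorted(counts.items())))

    @property
    def n_acid(self) -> int:
        return sum(n for _, kind, n in self.groups if kind == "acid")

    @property
    def n_base(self) -> int:
        return sum(n for _, kind, n in self.groups if kind == "base")


def hh_alpha(pH, pKA, group_type: str):
    """Ideal degree of ionisation of an isolated acid or base group.

    Vectorised over ``pH``; strictly increasing in pH for acids and
    strictly decreasing for bases.
    """
    pH = np.asarray(pH, dtype=float)
    if group_type == "acid":
        alpha = 1.0 / (1.0 + 10.0 ** (pKA - pH))
    elif group_type == "base":
        alpha = 1.0 / (1.0 + 10.0 ** (pH - pKA))
    else:
        raise ValueError(f"group_type must be acid or base, got {group_type!r}")
    return alpha if alpha.ndim else float(alpha)


def ideal_net_charge(pH, comp: Composition):
    """Ideal net charge z(pH) = sum_i count_i * alpha_i(pH) * z_i, in e."""
    pH = np.asarray(pH, dtype=float)
    z = np.zeros_like(pH)
    for pka, kind, count in comp.groups:
        valency = -1 if kind == "acid" else +1
        z = z + count * valency * hh_alpha(pH, pka, kind)
    return z if z.ndim else float(z)


def ideal_isoelectric_point(comp: Composition, tol: float = 1e-8) -> float:
    """Ideal isoelectric point: the unique root of the ideal net charge.

    Solved by bisection on [min pKA - 10, max pKA + 10] (the net charge is
    monotone decreasing in pH, so bracketing bisection always converges);
    refined until |z| < ``tol``.  Requires at least one acid and one base
    group, otherwise the charge never changes sign.
    """
    if comp.n_acid == 0 or comp.n_base == 0:
        raise ValueError(
            "isoelectric point requires both acid and base groups in the composition"
        )
    pkas = [pka for pka, _, _ in comp.groups]
    lo, hi = min(pkas) - 10.0, max(pkas) + 10.0
    # z(lo) > 0 > z(hi); bisect to machine precision in pH, then check tol in z
    root = brentq(lambda p: ideal_net_charge(p, comp), lo, hi, xtol=1e-12)
    assert abs(ideal_net_charge(root, comp)) < tol
    return float(root)


def ideal_curve(
    pH_grid: Sequence[float] | np.ndarray,
    comp: Composition,
) -> dict[str, np.ndarray]:
    """Ideal reference curves on a pH grid.

    Returns per-grid-point mean acid ionisation, mean base ionisation
    (count-weighted over species), and net charge.
    """
    pH = np.asarray(pH_grid, dtype=float)
    a_acid = np.zeros_like(pH)
    a_base = np.zeros_like(pH)
    for pka, kind, count in comp.groups:
        if kind == "acid":
            a_acid += count * hh_alpha(pH, pka, "acid")
        else:
            a_base += count * hh_alpha(pH, pka, "base")
    if comp.n_acid:
        a_acid /= comp.n_acid
    if comp.n_base:
        a_base /= comp.n_base
    return {
        "pH": pH,
        "alpha_acid": a_acid,
        "alpha_base": a_base,
        "z": ideal_net_charge(pH, comp),
    }
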
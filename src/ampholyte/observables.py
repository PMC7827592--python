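"""Trajectory analysis: conformation metrics, correlated errors, curves.

Per-cycle Monte Carlo series are strongly autocorrelated, so naive
standard errors underestimate the uncertainty.  Errors here are corrected
with the integrated autocorrelation time tau_int (initial-positive-
sequence truncation), SE = s * sqrt(2 tau_int / N), and cross-checked by
a blocking (batch-means) estimate.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import RunResult
from .ideal import Composition, ideal_curve, ideal_isoelectric_point

__all__ = [
    "end_to_end_distance",
    "radius_of_gyration",
    "correlated_error",
    "blocking_error",
    "TitrationCurve",
    "ConformationCurve",
    "build_titration_curve",
]


def end_to_end_distance(chain_positions: np.ndarray) -> float:
    """Distance between the first and last backbone beads, nm.

    ``chain_positions`` must be the unwrapped backbone coordinates of one
    chain, in order.  Wrapped coordinates would fold the distance back
    into the box and are rejected by the callers that hold image flags.
    """
    pos = np.asarray(chain_positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 2 or pos.shape[1] != 3:
        raise ValueError("need an (n>=2, 3) array of backbone positions")
    return float(np.linalg.norm(pos[-1] - pos[0]))


def radius_of_gyration(positions: np.ndarray) -> float:
    """Root-mean-square distance of beads from their centroid, nm."""
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 1 or pos.shape[1] != 3:
        raise ValueError("need an (n>=1, 3) array of positions")
    centred = pos - pos.mean(axis=0)
    return float(np.sqrt((centred**2).sum(axis=1).mean()))


def _autocorrelation(x: np.ndarray) -> np.ndarray:
    """Normalised autocorrelation function via FFT."""
    n = len(x)
    x = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real
    acov /= np.arange(n, 0, -1)  # unbiased normalisation
    if acov[0] == 0:
        return np.ones(n)
    return acov / acov[0]


def correlated_error(series: Sequence[float] | np.ndarray) -> tuple[float, float, float]:
    """(mean, correlation-corrected standard error, tau_int) of a series.

    tau_int = 1/2 + sum_k rho(k), summed up to the first negative
    autocorrelation estimate (initial-positive-sequence rule), so an
    uncorrelated series gives tau_int = 1/2 and SE = s/sqrt(N).  A
    constant series returns SE = 0 and tau_int = nan.  Series shorter
    than ~50 tau_int give untrustworthy estimates and raise a warning.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("empty series")
    mean = float(x.mean())
    if n == 1:
        return mean, math.nan, math.nan
    var = float(x.var(ddof=1))
    if var == 0.0:
        return mean, 0.0, math.nan
    rho = _autocorrelation(x)
    tau = 0.5
    for k in range(1, n):
        if rho[k] <= 0.0:
            break
        tau += rho[k]
    se = math.sqrt(var * 2.0 * tau / n)
    if n < 50.0 * tau:
        warnings.warn(
            f"series length {n} < 50 tau_int ({tau:.1f}); "
            "the error estimate is unreliable",
            stacklevel=2,
        )
    return mean, se, float(tau)


def blocking_error(
    series: Sequence[float] | np.ndarray, n_blocks: int = 32
) -> tuple[float, float]:
    """(mean, standard error) from non-overlapping block averages."""
    x = np.asarray(series, dtype=float)
    n_blocks = min(n_blocks, len(x))
    if n_blocks < 2:
        return float(x.mean()), math.nan
    usable = (len(x) // n_blocks) * n_blocks
    blocks = x[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(x.mean()), float(blocks.std(ddof=1) / math.sqrt(n_blocks))


_CURVE_COLUMNS = [
    "pH", "alpha_acid", "alpha_acid_se", "alpha_base", "alpha_base_se",
    "z", "z_se", "Re_nm", "Re_se", "Rg_nm", "Rg_se",
    "alpha_acid_HH", "alpha_base_HH", "z_HH",
]


@dataclass
class TitrationCurve:
    """Simulated titration/conformation curves with their ideal reference.

    ``table`` has one row per pH with simulated means, correlation-
    corrected standard errors, and the matching Henderson-Hasselbalch
    (ideal) columns.
    """

    table: pd.DataFrame
    label: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def pH(self) -> np.ndarray:
        return self.table["pH"].to_numpy()

    def ideal_pI(self) -> float:
        comp = Composition.from_sequence(self.metadata["sequence"])
        return ideal_isoelectric_point(comp)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(
            json.dumps({"label": self.label, **self.metadata}, indent=2)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TitrationCurve":
        table = pd.read_csv(path)
        sidecar = Path(path).with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(table=table, label=meta.get("label", ""), metadata=meta)


@dataclass
class ConformationCurve:
    """Chain-dimension view of a pH sweep: R_e and R_g with errors."""

    table: pd.DataFrame  # columns: pH, Re_nm, Re_se, Rg_nm, Rg_se
    chain_length: int
    label: str = ""

    @classmethod
    def from_titration_curve(cls, curve: "TitrationCurve") -> "ConformationCurve":
        cols = ["pH", "Re_nm", "Re_se", "Rg_nm", "Rg_se"]
        n_res = len(curve.metadata.get("sequence", ""))
        return cls(table=curve.table[cols].copy(), chain_length=n_res,
                   label=curve.label)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def build_titration_curve(runs: Iterable[RunResult]) -> TitrationCurve:
    """Reduce a pH sweep of runs to one titration/conformation curve.

    All runs must share the same scenario (sequence, chain count, box,
    salt) and differ only in pH.  Production series are averaged with
    correlation-corrected errors and the ideal reference is attached.
    """
    runs = sorted(runs, key=lambda r: r.pH)
    if not runs:
        raise ValueError("no runs given")
    meta0 = {k: v for k, v in runs[0].metadata.items()}
    for r in runs[1:]:
        if r.metadata != meta0:
            raise ValueError("runs mix different scenarios; refusing to average")
    rows = []
    for r in runs:
        row = {"pH": r.pH}
        for key, col in [
            ("alpha_acid", "alpha_acid"),
            ("alpha_base", "alpha_base"),
            ("z", "z"),
            ("Re", "Re_nm"),
            ("Rg", "Rg_nm"),
        ]:
            x = r.production(key)
            if np.all(np.isnan(x)):  # e.g. alpha_acid of a base-only chain
                row[col] = math.nan
                row[_se_name(col)] = math.nan
                continue
            mean, se, _ = correlated_error(x)
            row[col] = mean
            row[_se_name(col)] = se
        rows.append(row)
    table = pd.DataFrame(rows)
    comp = Composition.from_sequence(meta0.get("sequence", runs[0].label))
    ref = ideal_curve(table["pH"].to_numpy(), comp)
    table["alpha_acid_HH"] = ref["alpha_acid"]
    table["alpha_base_HH"] = ref["alpha_base"]
    table["z_HH"] = ref["z"]
    table = table[_CURVE_COLUMNS]
    return TitrationCurve(table=table, label=runs[0].label, metadata=meta0)


def _se_name(col: str) -> str:
    return {"Re_nm": "Re_se", "Rg_nm": "Rg_se"}.get(col, f"{col}_se")
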
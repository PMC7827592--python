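"""Summary figure panels: titration curves and conformation vs pH."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .observables import TitrationCurve

__all__ = ["plot_titration_panel", "plot_conformation_panel"]


def plot_titration_panel(curve: TitrationCurve, path: str | Path) -> None:
    """Net charge and per-group ionisation vs pH with the ideal reference."""
    t = curve.table
    fig, (ax_z, ax_a) = plt.subplots(1, 2, figsize=(9, 3.6), sharex=True)
    ax_z.errorbar(t["pH"], t["z"], yerr=t["z_se"], fmt="s", label="simulation")
    ax_z.plot(t["pH"], t["z_HH"], "-", label="ideal (HH)")
    ax_z.set_xlabel("pH")
    ax_z.set_ylabel("net charge z / e")
    ax_z.legend()
    ax_a.errorbar(
        t["pH"], t["alpha_acid"], yerr=t["alpha_acid_se"], fmt="v", label="acid"
    )
    ax_a.errorbar(
        t["pH"], t["alpha_base"], yerr=t["alpha_base_se"], fmt="^", label="base"
    )
    ax_a.plot(t["pH"], t["alpha_acid_HH"], "--", color="grey")
    ax_a.plot(t["pH"], t["alpha_base_HH"], ":", color="grey")
    ax_a.set_xlabel("pH")
    ax_a.set_ylabel("degree of ionisation")
    ax_a.set_ylim(-0.05, 1.05)
    ax_a.legend()
    fig.suptitle(curve.label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_conformation_panel(curves: list[TitrationCurve], path: str | Path) -> None:
    """End-to-end distance vs pH for one or more scenarios."""
    fig, ax = plt.subplots(figsize=(5, 3.6))
    for curve in curves:
        t = curve.table
        ax.errorbar(t["pH"], t["Re_nm"], yerr=t["Re_se"], fmt="o-", label=curve.label)
    ax.set_xlabel("pH")
    ax.set_ylabel(r"$R_e$ / nm")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
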
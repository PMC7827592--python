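"""Independent reference implementations used as test oracles.

Deliberately simple, vectorised numpy code kept separate from the package
kernels so the two paths share no implementation.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import erfc


def ewald_energy_reference(
    pos: np.ndarray,
    q: np.ndarray,
    L: float,
    lB: float,
    alpha_L: float = 8.0,
    nmax: int = 10,
) -> float:
    """Textbook Ewald sum (full k space, tight cutoffs), energy in k_BT.

    alpha = alpha_L / L makes erfc(alpha * L/2) ~ 1.5e-8, so the
    minimum-image real-space sum and an nmax = 10 reciprocal cutoff give
    ~7-digit accuracy for small systems.
    """
    pos = np.asarray(pos, float)
    q = np.asarray(q, float)
    n = len(q)
    alpha = alpha_L / L

    # real space, minimum image
    d = pos[:, None, :] - pos[None, :, :]
    d -= L * np.round(d / L)
    r = np.sqrt((d**2).sum(axis=-1))
    iu = np.triu_indices(n, k=1)
    e_real = lB * np.sum(q[iu[0]] * q[iu[1]] * erfc(alpha * r[iu]) / r[iu])

    # full reciprocal space
    e_recip = 0.0
    two_pi = 2.0 * np.pi
    for nx, ny, nz in itertools.product(range(-nmax, nmax + 1), repeat=3):
        if nx == 0 and ny == 0 and nz == 0:
            continue
        if nx * nx + ny * ny + nz * nz > nmax * nmax:
            continue
        k = two_pi / L * np.array([nx, ny, nz])
        k2 = k @ k
        s = np.sum(q * np.exp(1j * pos @ k))
        e_recip += np.exp(-k2 / (4 * alpha**2)) / k2 * abs(s) ** 2
    e_recip *= 2.0 * np.pi * lB / L**3

    e_self = -lB * alpha / np.sqrt(np.pi) * np.sum(q**2)
    return float(e_real + e_recip + e_self)
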
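"""Eyring-Polanyi conversion between rate constants and activation barriers.

    k = (k_B T / h) exp(-dG / (k_B T))

with transmission coefficient 1 and CODATA constants (scipy.constants).
Used to compare computed unbinding barriers with experimental k_off
values: a dissociation rate of 0.0823 s^-1 at 298 K corresponds to a
barrier of about 18.93 kcal/mol.
"""

from __future__ import annotations

import numpy as np
from scipy import constants

__all__ = ["barrier_from_rate", "rate_from_barrier", "KCAL_PER_MOL_IN_J"]

KCAL_PER_MOL_IN_J = constants.calorie * 1000.0 / constants.Avogadro


def barrier_from_rate(k, T):
    """Activation free energy dG (kcal/mol) from a rate constant k (s^-1).

    dG = k_B T ln(k_B T / (h k)).  Strictly decreasing in k; k equal to
    the prefactor k_B T / h gives a zero barrier.
    """
    k = np.asarray(k, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(k <= 0):
        raise ValueError("rate constant must be positive")
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    kbT = constants.Boltzmann * T
    dg_joule = kbT * np.log(kbT / (constants.Planck * k))
    out = dg_joule / KCAL_PER_MOL_IN_J
    return float(out) if out.ndim == 0 else out


def rate_from_barrier(dg, T):
    """Rate constant k (s^-1) from an activation free energy dG (kcal/mol).

    Exact inverse of :func:`barrier_from_rate`.
    """
    dg = np.asarray(dg, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    kbT = constants.Boltzmann * T
    out = (kbT / constants.Planck) * np.exp(-dg * KCAL_PER_MOL_IN_J / kbT)
    return float(out) if out.ndim == 0 else out
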
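"""Polymer scaling of the radius of gyration: Rg ≈ R0 · N^ν.

Globular monomeric proteins follow an empirical power law relating Rg to
chain length N.  A dimer whose Rg sits on the monomeric reference line
despite being two chains behaves, sizewise, like a single compact protein —
the signature of an obligate, intertwined dimer.  This module fits the power
law in log-log space and measures the log-space deviation of query proteins
from a reference line.

The bundled default reference parameters (R0 = 2.2 Å, ν = 0.38) are a
documented stand-in of the right order for compact globular proteins, not a
published fit; analyses that depend on the reference line should pass their
own calibrated (R0, ν).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_REFERENCE",
    "ScalingFit",
    "fit_power_law",
    "reference_deviation",
]

#: Stand-in (R0 Å, ν) for the monomeric-protein reference line.
DEFAULT_REFERENCE = (2.2, 0.38)


@dataclass
class ScalingFit:
    prefactor: float  # R0, Å
    exponent: float  # ν
    residuals: np.ndarray  # log-space, per point
    n_points: int

    def predict(self, N) -> np.ndarray:
        return self.prefactor * np.asarray(N, dtype=float) ** self.exponent


def fit_power_law(points) -> ScalingFit:
    """Least-squares fit of log Rg = log R0 + ν log N.

    ``points`` is an iterable of (N, Rg) with N ≥ 2 and Rg > 0.  Noiseless
    power-law data is recovered exactly (up to floating point).
    """
    pts = [(int(n), float(rg)) for n, rg in points]
    if len(pts) < 3:
        raise ValueError(f"need at least 3 points to fit, got {len(pts)}")
    N = np.array([p[0] for p in pts], dtype=float)
    Rg = np.array([p[1] for p in pts], dtype=float)
    if np.any(N < 2):
        raise ValueError("all N must be >= 2")
    if np.any(Rg <= 0):
        raise ValueError("all Rg must be > 0")
    x, y = np.log(N), np.log(Rg)
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (intercept + slope * x)
    return ScalingFit(prefactor=float(np.exp(intercept)), exponent=float(slope),
                      residuals=residuals, n_points=len(pts))


def reference_deviation(query: tuple[float, float],
                        reference: tuple[float, float] = DEFAULT_REFERENCE) -> float:
    """Log-space residual of one (N, Rg) point from a reference power law.

    residual = log Rg − [log R0 + ν log N]; 0 means exactly on the line,
    log 2 means an Rg twice the line's prediction.
    """
    n, rg = query
    if n <= 0 or rg <= 0:
        raise ValueError("N and Rg must be positive")
    r0, nu = reference
    if r0 <= 0:
        raise ValueError("reference prefactor must be positive")
    return float(math.log(rg) - (math.log(r0) + nu * math.log(n)))
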
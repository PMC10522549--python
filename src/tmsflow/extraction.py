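"""Flow-dependent first-pass extraction (generalized Renkin-Crone).

Rb-82 uptake saturates with flow: the unidirectional uptake constant is
``K1 = F * E(F)`` with extraction ``E(F) = 1 - a*exp(-b/F)``.  The constants
``a = 0.77, b = 0.63`` are the ones conventionally used with the Rb-82
one-tissue model; they are exposed so model-mismatch experiments can supply
an independent set.

``K1`` and flow share units (mL/min/g); ``K1 <= F`` always, and ``K1/F -> 1``
as flow goes to zero, which is why low scar flows are the well-conditioned
regime for this tracer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["RenkinCrone", "DEFAULT_EXTRACTION", "renkin_crone_k1"]


@dataclass(frozen=True)
class RenkinCrone:
    a: float = 0.77
    b: float = 0.63

    def __post_init__(self) -> None:
        if not 0 <= self.a < 1:
            raise ValueError("a must lie in [0, 1)")
        if self.b <= 0:
            raise ValueError("b must be positive")

    def k1(self, mbf):
        """Uptake constant K1 (mL/min/g) for flow mbf (mL/min/g)."""
        mbf = np.asarray(mbf, dtype=float)
        if np.any(mbf < 0):
            raise ValueError("mbf must be >= 0")
        with np.errstate(divide="ignore"):
            out = np.where(mbf > 0, mbf * (1 - self.a * np.exp(-self.b / np.maximum(mbf, 1e-300))), 0.0)
        return float(out) if out.ndim == 0 else out

    def invert(self, k1: float, hi: float = 20.0) -> float:
        """Flow whose uptake constant equals ``k1`` (strictly monotone map)."""
        if k1 < 0:
            raise ValueError("k1 must be >= 0")
        if k1 == 0.0:
            return 0.0
        while self.k1(hi) < k1:
            hi *= 2.0
            if hi > 1e6:
                raise ValueError("k1 outside invertible range")
        return float(brentq(lambda m: self.k1(m) - k1, 0.0, hi, xtol=1e-12))


DEFAULT_EXTRACTION = RenkinCrone()


def renkin_crone_k1(mbf, model: RenkinCrone = DEFAULT_EXTRACTION):
    """Convenience wrapper: K1 for flow under the default constant set."""
    return model.k1(mbf)
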
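"""Exact frame-domain convolution with an exponential washout kernel.

The one-tissue model needs ``C_a (x) exp(-k2 t)`` evaluated as *frame
averages* on a mixed 5/10-s grid.  Since re-binned TAC values are frame
averages, the input is treated as piecewise constant over frames, for which
the compartment ODE ``dy/dt = c(t) - k2*y`` has a closed-form update per
frame; both the end-of-frame state and the frame average are exact.  This
makes the forward model and the fitted model identical operators (no
quadrature error), and makes boxcar-input solutions exact by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["exp_conv_frame_avg"]


def exp_conv_frame_avg(
    durations: np.ndarray, values: np.ndarray, k2_per_s: float
) -> np.ndarray:
    """Frame averages of ``int_0^t c(tau) exp(-k2 (t - tau)) dtau``.

    ``values`` are frame-average input concentrations treated as constant
    within each frame; ``durations`` in seconds; ``k2_per_s`` >= 0.
    Supports broadcasting: ``values`` may be (n_frames,) or (m, n_frames);
    the result has the same shape.  Output units: input units * seconds.
    """
    durations = np.asarray(durations, dtype=float)
    values = np.asarray(values, dtype=float)
    one_d = values.ndim == 1
    values = np.atleast_2d(values)
    m, n = values.shape
    if durations.size != n:
        raise ValueError("values and durations length mismatch")
    if k2_per_s < 0:
        raise ValueError("k2 must be >= 0")

    out = np.empty_like(values)
    y = np.zeros(m)
    if k2_per_s == 0.0:
        for i in range(n):
            d = durations[i]
            c = values[:, i]
            out[:, i] = y + c * d / 2.0
            y = y + c * d
    else:
        k = k2_per_s
        for i in range(n):
            d = durations[i]
            c = values[:, i]
            kd = k * d
            if kd < 1e-8:
                # series limit to avoid cancellation
                out[:, i] = y + c * d / 2.0
                y = y + c * d
            else:
                phi = np.exp(-kd)
                steady = c / k
                out[:, i] = steady + (y - steady) * (1.0 - phi) / kd
                y = steady + (y - steady) * phi
    return out[0] if one_d else out
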
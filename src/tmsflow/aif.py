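"""Arterial input function models for the two Rb-82 infusion profiles.

The bolus (50 mL/min) input is a gamma-variate first pass plus a
recirculation bump and a slowly declining tail.  The slow infusion
(20 mL/min) delivers the same activity over a longer time and is modelled by
convolving the bolus form with a normalized 36-s boxcar, which preserves the
injected dose (curve area) while widening and lowering the peak.

``generate_aif`` returns frame averages on the acquisition schedule.  When a
seed is supplied, mild per-scan physiologic variability (peak amplitude and
timing jitter) is applied, reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .framing import FramingSchedule, TimeActivityCurve

__all__ = ["AifParams", "continuous_aif", "generate_aif", "SLOW_BOXCAR_S"]

SLOW_BOXCAR_S = 36.0  # infusion-spread boxcar width for the 20 mL/min profile


@dataclass(frozen=True)
class AifParams:
    profile: str = "bolus_50"        # "bolus_50" or "slow_20"
    peak_time_s: float = 30.0        # peak time of the underlying bolus
    peak_amplitude: float = 150.0    # kBq/mL at the bolus peak
    width_shape: float = 3.0         # gamma-variate shape (larger = narrower)
    tail_fraction: float = 0.15      # late tail level relative to peak
    recirculation_fraction: float = 0.12
    arrival_time_s: float = 10.0
    amplitude_jitter: float = 0.05   # per-scan lognormal-ish amplitude sd
    timing_jitter_s: float = 2.0     # per-scan peak-time sd

    def __post_init__(self) -> None:
        if self.profile not in ("bolus_50", "slow_20"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be > 0")
        if not 0 <= self.tail_fraction < 1:
            raise ValueError("tail_fraction must lie in [0, 1)")
        if self.peak_time_s <= self.arrival_time_s:
            raise ValueError("peak must occur after arrival")
        if self.width_shape <= 0:
            raise ValueError("width_shape must be > 0")


def _bolus_form(t: np.ndarray, p: AifParams) -> np.ndarray:
    """Continuous bolus curve: gamma variate + recirculation + tail."""
    t = np.asarray(t, dtype=float)
    t0, tp, alpha, amp = p.arrival_time_s, p.peak_time_s - p.arrival_time_s, p.width_shape, p.peak_amplitude
    x = np.maximum(t - t0, 0.0) / tp
    first = amp * x**alpha * np.exp(alpha * (1.0 - x))
    # recirculation: broader, delayed gamma bump
    t1 = p.peak_time_s + 25.0
    tp2, a2 = 2.0 * tp, 2.0
    x2 = np.maximum(t - t1, 0.0) / tp2
    recirc = p.recirculation_fraction * amp * x2**a2 * np.exp(a2 * (1.0 - x2))
    # sustained tail: rises over ~30 s, declines with a long time constant
    tt = np.maximum(t - t0, 0.0)
    tail = p.tail_fraction * amp * (1.0 - np.exp(-tt / 30.0)) * np.exp(-tt / 600.0)
    return first + recirc + tail


def continuous_aif(t: np.ndarray, params: AifParams) -> np.ndarray:
    """Continuous-time input curve (kBq/mL) for either infusion profile."""
    t = np.asarray(t, dtype=float)
    if params.profile == "bolus_50":
        return _bolus_form(t, params)
    # slow infusion: sliding 36-s mean of the bolus form (area-preserving)
    w = SLOW_BOXCAR_S
    n_sub = 36
    offsets = (np.arange(n_sub) + 0.5) * (w / n_sub)
    grid = t[:, None] - offsets[None, :]
    return _bolus_form(grid, params).mean(axis=1)


def generate_aif(
    params: AifParams,
    schedule: FramingSchedule,
    seed: int | np.random.Generator | None = None,
) -> TimeActivityCurve:
    """Frame-averaged arterial input on the acquisition schedule.

    With a seed, peak amplitude and timing receive mild reproducible
    physiologic jitter; without one the curve is the deterministic default.
    """
    if seed is not None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        scale = float(np.exp(rng.normal(0.0, params.amplitude_jitter)))
        shift = float(rng.normal(0.0, params.timing_jitter_s))
        params = replace(
            params,
            peak_amplitude=params.peak_amplitude * scale,
            peak_time_s=max(params.peak_time_s + shift, params.arrival_time_s + 5.0),
            amplitude_jitter=params.amplitude_jitter,
        )
    dt = 0.5
    values = np.empty(schedule.n_frames)
    for i, (start, dur) in enumerate(schedule.frames):
        tt = start + (np.arange(int(round(dur / dt))) + 0.5) * dt
        values[i] = float(np.mean(continuous_aif(tt, params)))
    return TimeActivityCurve(
        schedule=schedule,
        values=values,
        region_label=f"arterial_input[{params.profile}]",
        decay_corrected=True,
    )
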
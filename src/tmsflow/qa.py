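"""Automated quality screen: eight technical-error checks per dynamic study.

Each detector produces a boolean flag plus the numeric evidence it was
judged on, so thresholds stay auditable.  The eight checks: inconsistent
frame duration, scanner saturation, inaccurate blood-curve peak,
inappropriate blood-peak width, flat blood-curve tail, gradual patient
motion, abrupt patient motion, and spillover fraction > 0.60.  Only the
spillover bound is a published constant; the remaining thresholds are
conservative defaults exposed through :class:`QAConfig` and validated by
round trip against the artifact injector.

Peak-time and peak-width windows are measured from acquisition start (the
acquisition begins with the injection in this protocol).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .framing import TimeActivityCurve, build_default_schedule
from .phantom import PhantomStudy

__all__ = ["QAConfig", "QACheck", "QAReport", "qa_check", "QA_CHECK_NAMES"]

QA_CHECK_NAMES = (
    "inconsistent_frame_duration",
    "scanner_saturation",
    "inaccurate_blood_peak",
    "inappropriate_peak_width",
    "flat_blood_tail",
    "gradual_motion",
    "abrupt_motion",
    "spillover_gt_060",
)


@dataclass(frozen=True)
class QAConfig:
    input_location: str = "la_aorta"
    saturation_rel_tol: float = 1e-9      # clipping leaves consecutive frames
                                          # *exactly* at the ceiling; smooth
                                          # physiologic curves never tie to
                                          # this precision
    saturation_min_frames: int = 2        # consecutive plateau frames
    peak_window_bolus_s: tuple[float, float] = (10.0, 90.0)
    peak_window_slow_s: tuple[float, float] = (10.0, 150.0)
    fwhm_window_bolus_s: tuple[float, float] = (10.0, 45.0)
    fwhm_window_slow_s: tuple[float, float] = (20.0, 90.0)
    tail_window_s: float = 60.0           # trailing window for the tail fit
    flat_tail_slope_frac: float = 0.001   # |slope| < 0.1% of peak per second
    flat_tail_min_level: float = 0.30     # ... and tail mean > 30% of peak
    motion_min_signal_s: float = 90.0     # centroid evaluated from here on
    motion_drift_sectors: float = 1.0
    motion_jump_sectors: float = 1.0
    spillover_bound: float = 0.60         # published bound


@dataclass(frozen=True)
class QACheck:
    flag: bool
    evidence: float
    note: str = ""


@dataclass
class QAReport:
    checks: dict[str, QACheck]

    def __post_init__(self) -> None:
        missing = set(QA_CHECK_NAMES) - set(self.checks)
        if missing:
            raise ValueError(f"QA report missing checks {sorted(missing)}")

    @property
    def overall_pass(self) -> bool:
        return not any(c.flag for c in self.checks.values())

    def flagged(self) -> tuple[str, ...]:
        return tuple(n for n in QA_CHECK_NAMES if self.checks[n].flag)

    def to_dict(self) -> dict:
        return {
            "overall_pass": self.overall_pass,
            "checks": {n: asdict(c) for n, c in self.checks.items()},
        }


def _fwhm_s(tac: TimeActivityCurve) -> float:
    """Full width at half maximum of the frame staircase, by linear
    interpolation of frame-mid samples around the global peak."""
    t = tac.schedule.mids
    v = tac.values
    j = int(np.argmax(v))
    half = v[j] / 2.0
    # walk left
    left = t[0]
    for i in range(j, 0, -1):
        if v[i - 1] < half:
            left = np.interp(half, [v[i - 1], v[i]], [t[i - 1], t[i]])
            break
    # walk right
    right = t[-1]
    for i in range(j, len(v) - 1):
        if v[i + 1] < half:
            right = np.interp(half, [v[i + 1], v[i]], [t[i + 1], t[i]])
            break
    return float(right - left)


def _angular_centroid_deg(study: PhantomStudy, frame: int) -> float:
    """Direction of the area-weighted uptake distribution in one frame.

    A perfusion defect makes the distribution anisotropic; rigid rotation of
    the sector values rotates this direction by the same angle."""
    grid = study.grid
    theta = np.deg2rad(grid.angle_deg[:-1])
    w = study.tissue[:-1, frame] * grid.area_fraction[:-1]
    vec = np.sum(w * np.exp(1j * theta))
    return float(np.rad2deg(np.angle(vec)))


def qa_check(study: PhantomStudy, cfg: QAConfig = QAConfig()) -> QAReport:
    """Run all eight detectors on one study; deterministic."""
    if cfg.input_location not in study.blood:
        raise ValueError(f"study has no blood curve at {cfg.input_location!r}")
    blood = study.blood_tac(cfg.input_location)
    sched = study.schedule
    checks: dict[str, QACheck] = {}

    # 1. frame durations versus the declared protocol schedule
    declared = study.spec.schedule
    same = sched.frames == declared.frames
    max_diff = (
        0.0
        if same
        else float(
            np.max(np.abs(sched.durations - declared.durations))
            if sched.n_frames == declared.n_frames
            else np.inf
        )
    )
    checks["inconsistent_frame_duration"] = QACheck(not same, max_diff, "max |dt| difference (s)")

    # 2. scanner saturation: plateau of consecutive frames at the blood max
    v = blood.values
    vmax = float(np.max(v))
    near = v >= (1.0 - cfg.saturation_rel_tol) * vmax
    run = best = 0
    for flag in near:
        run = run + 1 if flag else 0
        best = max(best, run)
    checks["scanner_saturation"] = QACheck(
        best >= cfg.saturation_min_frames, float(best), "longest plateau (frames)"
    )

    # 3/4. blood peak time and width against profile-specific windows
    slow = study.profile == "slow_20"
    peak_win = cfg.peak_window_slow_s if slow else cfg.peak_window_bolus_s
    fwhm_win = cfg.fwhm_window_slow_s if slow else cfg.fwhm_window_bolus_s
    peak_t = float(sched.mids[int(np.argmax(v))])
    checks["inaccurate_blood_peak"] = QACheck(
        not peak_win[0] <= peak_t <= peak_win[1], peak_t, "peak time (s)"
    )
    width = _fwhm_s(blood)
    checks["inappropriate_peak_width"] = QACheck(
        not fwhm_win[0] <= width <= fwhm_win[1], width, "FWHM (s)"
    )

    # 5. flat tail: near-zero slope at a substantial level over the last 60 s
    t_tail = sched.total_duration_s - cfg.tail_window_s
    sel = sched.starts >= t_tail - 1e-9
    tt, vv = sched.mids[sel], v[sel]
    slope = float(np.polyfit(tt, vv, 1)[0])
    tail_mean = float(np.mean(vv))
    flat = (
        abs(slope) < cfg.flat_tail_slope_frac * vmax
        and tail_mean > cfg.flat_tail_min_level * vmax
    )
    checks["flat_blood_tail"] = QACheck(
        flat, slope / vmax * 100.0, "tail slope (% of peak per s)"
    )

    # 6/7. motion: angular drift of the uptake-distribution direction.
    # Jumps are read off a median-of-3 filtered centroid series (noise spikes
    # are isolated, a real step persists); drift is the least-squares slope
    # times the observed span (robust to endpoint noise).
    sector_deg = 360.0 / study.grid.n_angular
    frames = [
        i for i, (s, _) in enumerate(sched.frames) if s >= cfg.motion_min_signal_s
    ]
    cent = np.array([_angular_centroid_deg(study, i) for i in frames])
    cent = np.rad2deg(np.unwrap(np.deg2rad(cent))) / sector_deg
    if cent.size > 2:
        filt = cent.copy()
        filt[1:-1] = np.median(np.stack([cent[:-2], cent[1:-1], cent[2:]]), axis=0)
        max_jump = float(np.max(np.abs(np.diff(filt))))
        tt = sched.mids[frames]
        drift = float(abs(np.polyfit(tt, cent, 1)[0]) * (tt[-1] - tt[0]))
    else:
        max_jump = 0.0
        drift = 0.0
    abrupt = max_jump > cfg.motion_jump_sectors
    gradual = (drift > cfg.motion_drift_sectors) and not abrupt
    checks["gradual_motion"] = QACheck(gradual, drift, "fitted drift (sectors)")
    checks["abrupt_motion"] = QACheck(abrupt, max_jump, "max frame jump (sectors)")

    # 8. spillover: largest fitted blood fraction across segment curves
    max_vb = _max_segment_spillover(study, blood)
    checks["spillover_gt_060"] = QACheck(
        max_vb > cfg.spillover_bound, max_vb, "max fitted v_b"
    )
    return QAReport(checks)


def _max_segment_spillover(study: PhantomStudy, blood: TimeActivityCurve) -> float:
    """Fit the one-tissue model to each segment-average curve and return the
    largest spillover fraction (the scar segments are the sensitive ones)."""
    from .kinetics import _conv_min, _k2_grid, _linear_solve

    sched = study.schedule
    grid = study.grid
    seg_curves = np.stack(
        [study.tissue[grid.segment_of == sid].mean(axis=0) for sid in range(1, 18)]
    )
    w = sched.durations / sched.durations.sum()
    b = blood.values
    best_cost = np.full(17, np.inf)
    best_vb = np.zeros(17)
    for k2 in _k2_grid():
        conv = _conv_min(sched, b, k2)
        _, beta, cost = _linear_solve(conv, b, seg_curves, w)
        better = cost < best_cost
        best_cost[better] = cost[better]
        best_vb[better] = beta[better]
    return float(np.max(best_vb))
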
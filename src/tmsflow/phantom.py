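"""Ground-truth phantom studies for low-flow accuracy benchmarking.

A phantom patient is a fine-grid map of true resting flow with a contiguous
transmural-scar wedge, a viable border band and normal myocardium, imaged in
three consecutive rest scans with either infusion profile.  Tissue curves are
generated by the one-tissue forward model with flow-dependent (Renkin-Crone)
extraction, attenuated by partial-volume recovery and contaminated by blood
spillover; per-frame Gaussian noise mimics the count statistics of corrected,
frame-averaged data.  Candidate arterial-input locations carry configurable
scale/contamination bias so the "underestimated arterial input" mechanism of
inter-package discordance can be reproduced on demand.

Eight injectable artifact kinds mirror the eight automated quality-screen
checks, so the screen can be validated by round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np

from .aif import AifParams, generate_aif
from .conv import exp_conv_frame_avg
from .extraction import DEFAULT_EXTRACTION, RenkinCrone
from .framing import FramingSchedule, TimeActivityCurve, build_default_schedule
from .segments import PolarGrid

__all__ = [
    "GroundTruthFlowMap",
    "InputLocationBias",
    "PhantomSpec",
    "PhantomStudy",
    "ARTIFACT_KINDS",
    "make_flow_map",
    "random_phantom_spec",
    "forward_tissue_tac",
    "simulate_phantom",
    "inject_artifact",
]

ARTIFACT_KINDS = (
    "frame_duration",
    "saturation",
    "blood_peak",
    "peak_width",
    "flat_tail",
    "gradual_motion",
    "abrupt_motion",
    "spillover_excess",
)

#: default truth bands, mL/min/g
SCAR_BAND = (0.15, 0.35)
BORDER_BAND = (0.35, 0.60)
NORMAL_BAND = (0.55, 1.00)

#: scar/normal K1 contrast window accepted when drawing flows; emulates the
#: study-population selection for visually obvious transmural defects
#: (relative uptake in the scar ~40-47% of maximum).
SCAR_UPTAKE_CONTRAST_WINDOW = (0.33, 0.43)


@dataclass(frozen=True)
class GroundTruthFlowMap:
    """True rMBF per fine sector with scar / border / normal strata."""

    grid: PolarGrid
    true_mbf: np.ndarray
    scar_mask: np.ndarray
    border_mask: np.ndarray
    scar_band: tuple[float, float] = SCAR_BAND

    def __post_init__(self) -> None:
        object.__setattr__(self, "true_mbf", np.asarray(self.true_mbf, dtype=float))
        object.__setattr__(self, "scar_mask", np.asarray(self.scar_mask, dtype=bool))
        object.__setattr__(self, "border_mask", np.asarray(self.border_mask, dtype=bool))
        n = self.grid.n_sectors
        for name in ("true_mbf", "scar_mask", "border_mask"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length != grid sectors")
        if np.any(self.true_mbf < 0):
            raise ValueError("true_mbf must be >= 0")
        if np.any(self.scar_mask & self.border_mask):
            raise ValueError("scar and border masks overlap")
        lo, hi = self.scar_band
        scar = self.true_mbf[self.scar_mask]
        if scar.size and (scar.min() < lo - 1e-9 or scar.max() > hi + 1e-9):
            raise ValueError("scar flows outside the configured truth band")
        if self.scar_mask.any():
            comps = self.grid.connected_components(self.scar_mask)
            if len(comps) != 1:
                raise ValueError("scar mask must be contiguous on the grid")

    @property
    def normal_mask(self) -> np.ndarray:
        return ~(self.scar_mask | self.border_mask)

    @property
    def scar_pct_lv(self) -> float:
        return float(100.0 * self.grid.area_fraction[self.scar_mask].sum())

    @property
    def area_weighted_mean_mbf(self) -> float:
        return float(np.average(self.true_mbf, weights=self.grid.area_fraction))


@dataclass(frozen=True)
class InputLocationBias:
    """Arterial-input distortion at a named sampling location.

    ``scale`` multiplies the true input; ``contamination`` mixes in the
    area-weighted mean myocardial curve (adjacent-tissue spill-in).  The left
    atrium / aorta location is the unbiased reference.
    """

    scale: float = 1.0
    contamination: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.contamination < 0:
            raise ValueError("contamination must be >= 0")


DEFAULT_INPUT_LOCATIONS: dict[str, InputLocationBias] = {
    "la_aorta": InputLocationBias(1.0, 0.0),
    "lv_cavity": InputLocationBias(0.85, 0.05),
    "mv_plane": InputLocationBias(0.80, 0.05),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to regenerate a phantom study bit-exactly."""

    flow_map: GroundTruthFlowMap
    aif: AifParams = AifParams()
    n_rest_scans: int = 3
    pv_recovery: float = 0.85
    blood_spillover_fraction: float | np.ndarray = 0.10
    noise_level: float = 1.0
    flow_jitter_sd: float = 0.05    # per-scan physiologic rest-flow modulation
    k2_per_min: float = 0.15        # tissue washout rate
    schedule: FramingSchedule = field(default_factory=build_default_schedule)
    input_locations: Mapping[str, InputLocationBias] = field(
        default_factory=lambda: dict(DEFAULT_INPUT_LOCATIONS)
    )
    artifact_plan: tuple[tuple[int, str, dict], ...] = ()
    scan_profiles: tuple[str, ...] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rest_scans < 1:
            raise ValueError("n_rest_scans must be >= 1")
        if not 0 < self.pv_recovery <= 1:
            raise ValueError("pv_recovery must lie in (0, 1]")
        spill = np.asarray(self.blood_spillover_fraction, dtype=float)
        if np.any(spill < 0) or np.any(spill >= 1):
            raise ValueError("spillover fractions must lie in [0, 1)")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.scan_profiles is not None and len(self.scan_profiles) != self.n_rest_scans:
            raise ValueError("scan_profiles length must equal n_rest_scans")
        for scan_idx, kind, _ in self.artifact_plan:
            if kind not in ARTIFACT_KINDS:
                raise ValueError(f"unknown artifact kind {kind!r}")
            if not 0 <= scan_idx < self.n_rest_scans:
                raise ValueError("artifact scan index out of range")

    def spillover_per_sector(self) -> np.ndarray:
        spill = np.asarray(self.blood_spillover_fraction, dtype=float)
        if spill.ndim == 0:
            return np.full(self.flow_map.grid.n_sectors, float(spill))
        if spill.size != self.flow_map.grid.n_sectors:
            raise ValueError("per-sector spillover length mismatch")
        return spill


@dataclass
class PhantomStudy:
    """One simulated rest scan: blood curves per candidate input location,
    a tissue curve per fine sector, and the generating truth."""

    schedule: FramingSchedule
    blood: dict[str, TimeActivityCurve]
    tissue: np.ndarray                     # (n_sectors, n_frames), kBq/mL
    flow_map: GroundTruthFlowMap
    spec: PhantomSpec
    scan_index: int
    profile: str
    flow_scale: float = 1.0                # per-scan physiologic state
    artifacts: tuple[str, ...] = ()
    noisy: bool = False

    @property
    def grid(self) -> PolarGrid:
        return self.flow_map.grid

    def blood_tac(self, location: str = "la_aorta") -> TimeActivityCurve:
        if location not in self.blood:
            raise KeyError(
                f"input location {location!r} not in study "
                f"(have {sorted(self.blood)})"
            )
        return self.blood[location]

    def tissue_tac(self, sector: int) -> TimeActivityCurve:
        return TimeActivityCurve(
            schedule=self.schedule,
            values=self.tissue[sector],
            region_label=f"sector_{sector}",
            noisy=self.noisy,
        )


# ---------------------------------------------------------------------------
# flow-map construction
# ---------------------------------------------------------------------------

def make_flow_map(
    grid: PolarGrid,
    rng: np.random.Generator,
    scar_center_deg: float,
    scar_extent_deg: float,
    border_margin_deg: float = 15.0,
    scar_band: tuple[float, float] = SCAR_BAND,
    border_band: tuple[float, float] = BORDER_BAND,
    normal_band: tuple[float, float] = NORMAL_BAND,
    sector_jitter: float = 0.05,
    extraction: RenkinCrone = DEFAULT_EXTRACTION,
    contrast_window: tuple[float, float] = SCAR_UPTAKE_CONTRAST_WINDOW,
) -> GroundTruthFlowMap:
    """Draw a ground-truth flow map with a transmural wedge scar.

    Region levels are drawn uniformly from their bands; the (scar, normal)
    pair is redrawn until the implied uptake contrast K1(scar)/K1(normal)
    falls in ``contrast_window``, emulating selection of patients with
    visually obvious transmural defects.  Per-sector multiplicative jitter
    (clipped back into each region's band) adds smooth heterogeneity.
    """
    scar_mask = grid.wedge_mask(scar_center_deg, scar_extent_deg)
    wide = grid.wedge_mask(scar_center_deg, scar_extent_deg + 2 * border_margin_deg)
    border_mask = wide & ~scar_mask

    lo_c, hi_c = contrast_window
    for _ in range(500):
        scar_val = rng.uniform(*scar_band)
        normal_val = rng.uniform(*normal_band)
        if lo_c <= extraction.k1(scar_val) / extraction.k1(normal_val) <= hi_c:
            break
    else:
        raise RuntimeError("could not draw an acceptable scar/normal contrast")
    border_val = rng.uniform(*border_band)

    n = grid.n_sectors
    jitter = 1.0 + rng.normal(0.0, sector_jitter, size=n)
    values = np.empty(n)
    values[scar_mask] = np.clip(scar_val * jitter[scar_mask], *scar_band)
    values[border_mask] = np.clip(border_val * jitter[border_mask], *border_band)
    normal_mask = ~(scar_mask | border_mask)
    values[normal_mask] = np.clip(normal_val * jitter[normal_mask], *normal_band)
    return GroundTruthFlowMap(
        grid=grid,
        true_mbf=values,
        scar_mask=scar_mask,
        border_mask=border_mask,
        scar_band=scar_band,
    )


def random_phantom_spec(
    seed: int,
    grid: PolarGrid | None = None,
    profile: str | None = None,
    **overrides: Any,
) -> PhantomSpec:
    """A randomized phantom patient under the default study conditions.

    Scar wedges span 80-130 degrees (roughly 21-34 %LV) at a uniform random
    location; the three rest scans use both infusion profiles (the first two
    in random order, the third drawn at random), unless ``profile`` pins one.
    """
    rng = np.random.default_rng(seed)
    grid = grid or PolarGrid()
    center = float(rng.uniform(0.0, 360.0))
    extent = float(rng.uniform(80.0, 130.0))
    flow_map = make_flow_map(grid, rng, center, extent)
    if profile is None:
        first_two = ["bolus_50", "slow_20"]
        rng.shuffle(first_two)
        profiles = tuple(first_two + [str(rng.choice(["bolus_50", "slow_20"]))])
    else:
        profiles = (profile,) * 3
    defaults: dict[str, Any] = dict(
        flow_map=flow_map,
        aif=AifParams(profile=profiles[0]),
        scan_profiles=profiles,
        rng_seed=seed,
    )
    defaults.update(overrides)
    if "n_rest_scans" in overrides:
        n = overrides["n_rest_scans"]
        defaults["scan_profiles"] = (profiles * n)[:n] if profile is None else (profile,) * n
    return PhantomSpec(**defaults)


# ---------------------------------------------------------------------------
# forward model and simulation
# ---------------------------------------------------------------------------

def forward_tissue_tac(
    aif: TimeActivityCurve,
    mbf: float,
    k2_per_min: float,
    pv_recovery: float = 1.0,
    spillover: float = 0.0,
    schedule: FramingSchedule | None = None,
    extraction: RenkinCrone = DEFAULT_EXTRACTION,
) -> TimeActivityCurve:
    """Measured myocardial TAC for a single region.

    ``C_t = K1 (C_a (x) exp(-k2 t))`` with ``K1 = mbf * E(mbf)``; the
    measured curve is ``pv_recovery * C_t + spillover * C_a``, frame-averaged.
    """
    if schedule is not None and schedule.frames != aif.schedule.frames:
        from .framing import AlignmentError

        raise AlignmentError("AIF schedule does not match the requested schedule")
    sched = aif.schedule
    k1_per_s = extraction.k1(mbf) / 60.0
    conv = exp_conv_frame_avg(sched.durations, aif.values, k2_per_min / 60.0)
    measured = pv_recovery * k1_per_s * conv + spillover * aif.values
    return TimeActivityCurve(
        schedule=sched,
        values=measured,
        region_label=f"tissue[mbf={mbf:g}]",
        noisy=aif.noisy,
    )


def _noise_sigma(values: np.ndarray, durations: np.ndarray, level: float) -> np.ndarray:
    # variance proportional to (concentration / frame duration): the count
    # statistics of a frame-averaged, decay-corrected measurement
    return level * np.sqrt(np.maximum(values, 1.0) / durations)


def simulate_phantom(spec: PhantomSpec) -> list[PhantomStudy]:
    """Simulate the full rest protocol: one study per consecutive rest scan.

    Each scan gets a fresh, reproducible noise realization derived from
    ``(rng_seed, scan_index)``; the ground-truth flow map is shared.  Scans
    named in the artifact plan are corrupted after simulation.
    """
    studies: list[PhantomStudy] = []
    grid = spec.flow_map.grid
    spill = spec.spillover_per_sector()
    durations = spec.schedule.durations
    area = grid.area_fraction
    for scan in range(spec.n_rest_scans):
        rng = np.random.default_rng([int(spec.rng_seed) & 0x7FFFFFFF, scan])
        profile = (
            spec.scan_profiles[scan] if spec.scan_profiles else spec.aif.profile
        )
        aif_params = replace(spec.aif, profile=profile)
        blood_true = generate_aif(aif_params, spec.schedule, seed=rng)
        flow_scale = (
            float(np.exp(rng.normal(0.0, spec.flow_jitter_sd)))
            if spec.flow_jitter_sd > 0
            else 1.0
        )
        k1_per_s = DEFAULT_EXTRACTION.k1(spec.flow_map.true_mbf * flow_scale) / 60.0
        conv = exp_conv_frame_avg(
            durations, blood_true.values, spec.k2_per_min / 60.0
        )
        tissue = (
            spec.pv_recovery * k1_per_s[:, None] * conv[None, :]
            + spill[:, None] * blood_true.values[None, :]
        )
        mean_tissue = np.average(tissue, weights=area, axis=0)

        noisy = spec.noise_level > 0
        if noisy:
            tissue = tissue + rng.normal(
                0.0, _noise_sigma(tissue, durations[None, :], spec.noise_level)
            )
        blood: dict[str, TimeActivityCurve] = {}
        for name, bias in spec.input_locations.items():
            vals = bias.scale * blood_true.values + bias.contamination * mean_tissue
            if noisy:
                vals = vals + rng.normal(
                    0.0, _noise_sigma(vals, durations, spec.noise_level)
                )
            blood[name] = TimeActivityCurve(
                schedule=spec.schedule,
                values=vals,
                region_label=f"blood[{name}]",
                noisy=noisy,
            )
        study = PhantomStudy(
            schedule=spec.schedule,
            blood=blood,
            tissue=tissue,
            flow_map=spec.flow_map,
            spec=spec,
            scan_index=scan,
            profile=profile,
            flow_scale=flow_scale,
            noisy=noisy,
        )
        for scan_idx, kind, params in spec.artifact_plan:
            if scan_idx == scan:
                study = inject_artifact(study, kind, **params)
        studies.append(study)
    return studies


# ---------------------------------------------------------------------------
# artifact injection (one kind per quality-screen check)
# ---------------------------------------------------------------------------

def _staircase_lookup(schedule: FramingSchedule, values: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Value of the frame staircase at times t (0 outside the scan)."""
    starts = schedule.starts
    idx = np.searchsorted(starts, t, side="right") - 1
    out = np.where(
        (t >= 0) & (t < schedule.total_duration_s) & (idx >= 0),
        values[np.clip(idx, 0, len(values) - 1)],
        0.0,
    )
    return out


def _map_blood(study: PhantomStudy, fn) -> dict[str, TimeActivityCurve]:
    return {
        name: tac.with_values(fn(tac.values), noisy=True)
        for name, tac in study.blood.items()
    }


def _rotate_rings(grid: PolarGrid, tissue_col: np.ndarray, shift_sectors: float) -> np.ndarray:
    """Rotate one frame's sector values by a fractional number of sectors."""
    out = tissue_col.copy()
    n = grid.n_angular
    idx = np.arange(n)
    src = (idx - shift_sectors) % n
    lo = np.floor(src).astype(int) % n
    hi = (lo + 1) % n
    w = src - np.floor(src)
    for r in range(3):
        ring = tissue_col[r * n : (r + 1) * n]
        out[r * n : (r + 1) * n] = (1 - w) * ring[lo] + w * ring[hi]
    return out


def inject_artifact(study: PhantomStudy, kind: str, **params: Any) -> PhantomStudy:
    """Return a corrupted copy of the study (the input is left untouched)."""
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}; choose from {ARTIFACT_KINDS}")
    schedule = study.schedule
    blood = dict(study.blood)
    tissue = study.tissue.copy()

    if kind == "frame_duration":
        index = int(params.get("index", 29))
        new_duration = float(params.get("new_duration_s", 12.0))
        frames = list(schedule.frames)
        t = frames[index][0]
        frames[index] = (t, new_duration)
        for i in range(index + 1, len(frames)):
            t = frames[i - 1][0] + frames[i - 1][1]
            frames[i] = (t, frames[i][1])
        schedule = FramingSchedule(tuple(frames))
        blood = {
            name: TimeActivityCurve(
                schedule, tac.values, tac.region_label, tac.decay_corrected, True
            )
            for name, tac in blood.items()
        }
    elif kind == "saturation":
        frac = float(params.get("ceiling_fraction", 0.8))
        blood = _map_blood(
            study, lambda v: np.minimum(v, frac * float(np.max(v)))
        )
    elif kind == "blood_peak":
        delay = float(params.get("delay_s", 120.0))
        mids = schedule.mids
        blood = _map_blood(
            study, lambda v: np.interp(mids - delay, mids, v, left=0.0)
        )
    elif kind == "peak_width":
        # time stretch about the peak: max value and peak time preserved,
        # FWHM multiplied by the stretch factor.  The late tail (beyond
        # ``keep_tail_after_s``) is left untouched so the corruption is
        # confined to the peak region.
        stretch = float(params.get("stretch", 2.8))
        keep_after = float(params.get("keep_tail_after_s", 180.0))
        mids = schedule.mids

        def _widen(v: np.ndarray) -> np.ndarray:
            tp = mids[int(np.argmax(v))]
            stretched = np.interp(tp + (mids - tp) / stretch, mids, v)
            return np.where(mids <= keep_after, stretched, v)

        blood = _map_blood(study, _widen)
    elif kind == "flat_tail":
        t_start = float(params.get("t_start_s", 140.0))
        level = float(params.get("level_fraction", 0.35))
        sel = schedule.starts >= t_start - 1e-9

        def _flatten(v: np.ndarray) -> np.ndarray:
            out = v.copy()
            out[sel] = level * float(np.max(v))
            return out

        blood = _map_blood(study, _flatten)
    elif kind == "gradual_motion":
        total = float(params.get("total_shift_sectors", 3.0))
        n_fr = schedule.n_frames
        for i in range(n_fr):
            shift = total * i / (n_fr - 1)
            tissue[:, i] = _rotate_rings(study.grid, tissue[:, i], shift)
    elif kind == "abrupt_motion":
        at_s = float(params.get("at_s", 130.0))
        shift = float(params.get("shift_sectors", 2.0))
        for i, (start, _) in enumerate(schedule.frames):
            if start >= at_s - 1e-9:
                tissue[:, i] = _rotate_rings(study.grid, tissue[:, i], shift)
    elif kind == "spillover_excess":
        frac = float(params.get("fraction", 0.7))
        base = study.spec.spillover_per_sector()
        ref = study.blood["la_aorta"].values
        tissue = tissue + (frac - base)[:, None] * ref[None, :]

    return replace(
        study,
        schedule=schedule,
        blood=blood,
        tissue=tissue,
        artifacts=study.artifacts + (kind,),
        noisy=True,
    )
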
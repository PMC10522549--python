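"""Transmural-scar identification: fine-grid ROI and segmental equivalent.

The scar region of interest (ROI-Scar) is the largest contiguous set of fine
sectors at or below the transmural-uptake threshold (50% of maximum relative
uptake).  Its segmental equivalent applies four criteria to the 17-segment
table: Seg-Scar segments are (1) contiguous on the AHA adjacency graph,
(2) covered > 50% by the defect, (3) have rest score >= 2 and (4) relative
uptake < 65% of maximum.  Segments touching the defect but failing a
criterion form the border zone (Seg-Border); the rest are Seg-Norm.

Because segments admix viable border tissue while the ROI hugs the defect,
ROI-mean scar flow is systematically at or below Seg-Scar mean flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segments import PolarGrid, SegmentTable, aha_neighbors

__all__ = [
    "SegScarCriteria",
    "ScarAnalysis",
    "compute_relative_uptake",
    "segment_rest_score",
    "identify_roi_scar",
    "classify_segments",
    "analyze_scar",
]

#: rest-score bins over percent relative uptake (standard 5-point scoring)
_REST_SCORE_BINS = ((70.0, 0), (50.0, 1), (35.0, 2), (10.0, 3), (-1.0, 4))


@dataclass(frozen=True)
class SegScarCriteria:
    require_contiguity: bool = True
    defect_coverage_threshold: float = 0.50   # fraction of segment area
    segment_score_min: int = 2
    ru_max_percent: float = 65.0

    def __post_init__(self) -> None:
        if not 0 < self.defect_coverage_threshold < 1:
            raise ValueError("coverage threshold must lie in (0, 1)")
        if self.segment_score_min < 0 or self.ru_max_percent <= 0:
            raise ValueError("criteria thresholds must be positive")


@dataclass
class ScarAnalysis:
    """ROI-Scar plus the Seg-Scar / Seg-Border / Seg-Norm partition."""

    roi_mask: np.ndarray
    roi_size_pct_lv: float
    roi_mean_rmbf: float
    roi_min_rmbf: float
    roi_mean_ru: float
    seg_scar: tuple[int, ...]
    seg_border: tuple[int, ...]
    seg_norm: tuple[int, ...]
    seg_scar_mean_rmbf: float
    lowest_segment_rmbf: float
    seg_border_mean: float
    seg_norm_mean: float
    whole_heart_rmbf: float
    empty_roi: bool = False
    empty_seg_scar: bool = False
    secondary_defect_pct_lv: float = 0.0

    def __post_init__(self) -> None:
        groups = set(self.seg_scar) | set(self.seg_border) | set(self.seg_norm)
        if groups != set(range(1, 18)) or (
            len(self.seg_scar) + len(self.seg_border) + len(self.seg_norm) != 17
        ):
            raise ValueError("seg groups must partition segments 1..17")
        if not self.empty_roi and self.roi_min_rmbf > self.roi_mean_rmbf + 1e-12:
            raise ValueError("roi_min_rmbf cannot exceed roi_mean_rmbf")


def compute_relative_uptake(values: np.ndarray) -> np.ndarray:
    """Percent relative uptake: 100 * value / max(value)."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("uptake values must be >= 0")
    vmax = values.max() if values.size else 0.0
    if vmax <= 0:
        raise ValueError("all-zero uptake map is degenerate")
    return 100.0 * values / vmax


def segment_rest_score(ru_percent: float) -> int:
    """Severity score 0-4 from percent relative uptake (monotone
    non-increasing in uptake; 0 is normal, 4 is absent uptake)."""
    if not 0 <= ru_percent <= 100:
        raise ValueError("ru_percent must lie in [0, 100]")
    for threshold, score in _REST_SCORE_BINS:
        if ru_percent >= threshold:
            return score
    raise AssertionError("unreachable")


def identify_roi_scar(
    fine_uptake: np.ndarray,
    fine_rmbf: np.ndarray,
    grid: PolarGrid,
    uptake_threshold: float = 50.0,
) -> dict:
    """ROI-Scar: largest contiguous fine-grid component at <= threshold %RU.

    Returns roi mask, size (%LV by sector area), mean/min rMBF inside and
    mean %RU inside; an all-above-threshold map yields a flagged empty ROI.
    Secondary (disjoint) defect components are reported by total size only.
    """
    ru = compute_relative_uptake(fine_uptake)
    defect = ru <= uptake_threshold
    area = grid.area_fraction
    if not defect.any():
        return dict(
            roi_mask=np.zeros(grid.n_sectors, dtype=bool),
            roi_size_pct_lv=0.0,
            roi_mean_rmbf=float("nan"),
            roi_min_rmbf=float("nan"),
            roi_mean_ru=float("nan"),
            empty_roi=True,
            secondary_defect_pct_lv=0.0,
        )
    comps = grid.connected_components(defect)
    # ties on area are broken toward the lower mean %RU (the denser defect)
    if len(comps) > 1:
        top_area = area[comps[0]].sum()
        tied = [c for c in comps if abs(area[c].sum() - top_area) <= 1e-12]
        comps[0] = min(tied, key=lambda c: float(np.mean(ru[c])))
    roi = comps[0]
    mask = np.zeros(grid.n_sectors, dtype=bool)
    mask[roi] = True
    secondary = float(sum(area[c].sum() for c in comps[1:]) * 100.0)
    return dict(
        roi_mask=mask,
        roi_size_pct_lv=float(area[roi].sum() * 100.0),
        roi_mean_rmbf=float(np.average(fine_rmbf[roi], weights=area[roi])),
        roi_min_rmbf=float(np.min(fine_rmbf[roi])),
        roi_mean_ru=float(np.average(ru[roi], weights=area[roi])),
        empty_roi=False,
        secondary_defect_pct_lv=secondary,
    )


def classify_segments(
    seg_table: SegmentTable,
    defect_mask: np.ndarray,
    grid: PolarGrid,
    criteria: SegScarCriteria = SegScarCriteria(),
) -> dict:
    """Seg-Scar / Seg-Border / Seg-Norm partition under the four criteria.

    Criteria 2-4 are evaluated per segment first; Seg-Scar is then the
    maximal contiguous set (largest total candidate component on the AHA
    graph).  Segments intersecting the defect but failing a criterion (or
    falling outside the chosen contiguous set) are Seg-Border.
    """
    coverage = grid.segment_coverage(defect_mask)
    df = seg_table.df
    ru = df["ru_percent"].to_numpy()
    rmbf = df["rmbf"].to_numpy()
    if "rest_score" in df.columns:
        scores = df["rest_score"].to_numpy()
    else:
        scores = np.array([segment_rest_score(r) for r in ru])

    candidate = (
        (coverage > criteria.defect_coverage_threshold)
        & (scores >= criteria.segment_score_min)
        & (ru < criteria.ru_max_percent)
    )
    candidate_ids = {i + 1 for i in range(17) if candidate[i]}

    if criteria.require_contiguity and candidate_ids:
        nbrs = aha_neighbors()
        comps: list[set[int]] = []
        todo = set(candidate_ids)
        while todo:
            start = min(todo)
            comp = {start}
            stack = [start]
            todo.discard(start)
            while stack:
                u = stack.pop()
                for v in nbrs[u] & todo:
                    todo.discard(v)
                    comp.add(v)
                    stack.append(v)
            comps.append(comp)
        seg_scar = max(comps, key=lambda c: (len(c), -min(c)))
    else:
        seg_scar = candidate_ids

    intersecting = {i + 1 for i in range(17) if coverage[i] > 0}
    seg_border = (intersecting - seg_scar) | (candidate_ids - seg_scar)
    seg_norm = set(range(1, 18)) - seg_scar - seg_border

    def _mean(ids: set[int]) -> float:
        if not ids:
            return float("nan")
        return float(np.mean([rmbf[i - 1] for i in ids]))

    return dict(
        seg_scar=tuple(sorted(seg_scar)),
        seg_border=tuple(sorted(seg_border)),
        seg_norm=tuple(sorted(seg_norm)),
        seg_scar_mean_rmbf=_mean(seg_scar),
        lowest_segment_rmbf=(
            float(min(rmbf[i - 1] for i in seg_scar)) if seg_scar else float("nan")
        ),
        seg_border_mean=_mean(seg_border),
        seg_norm_mean=_mean(seg_norm),
        empty_seg_scar=not seg_scar and bool(np.asarray(defect_mask).any()),
    )


def analyze_scar(
    fine_uptake: np.ndarray,
    fine_rmbf: np.ndarray,
    seg_table: SegmentTable,
    grid: PolarGrid,
    uptake_threshold: float = 50.0,
    criteria: SegScarCriteria = SegScarCriteria(),
) -> ScarAnalysis:
    """Full scar analysis of one scan: ROI on the fine grid, then the
    segmental partition driven by the ROI's defect mask."""
    roi = identify_roi_scar(fine_uptake, fine_rmbf, grid, uptake_threshold)
    seg = classify_segments(seg_table, roi["roi_mask"], grid, criteria)
    whole_heart = float(np.average(fine_rmbf, weights=grid.area_fraction))
    return ScarAnalysis(
        roi_mask=roi["roi_mask"],
        roi_size_pct_lv=roi["roi_size_pct_lv"],
        roi_mean_rmbf=roi["roi_mean_rmbf"],
        roi_min_rmbf=roi["roi_min_rmbf"],
        roi_mean_ru=roi["roi_mean_ru"],
        seg_scar=seg["seg_scar"],
        seg_border=seg["seg_border"],
        seg_norm=seg["seg_norm"],
        seg_scar_mean_rmbf=seg["seg_scar_mean_rmbf"],
        lowest_segment_rmbf=seg["lowest_segment_rmbf"],
        seg_border_mean=seg["seg_border_mean"],
        seg_norm_mean=seg["seg_norm_mean"],
        whole_heart_rmbf=whole_heart,
        empty_roi=roi["empty_roi"],
        empty_seg_scar=seg["empty_seg_scar"],
        secondary_defect_pct_lv=roi["secondary_defect_pct_lv"],
    )
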
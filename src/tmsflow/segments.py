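"""AHA 17-segment model and the fine polar sampling grid.

The left ventricle is sampled on a fine polar grid: three rings of 72 angular
sectors (basal, mid-cavity, apical) plus a single apex cap sector, each sector
mapped to exactly one AHA segment.  Ring area weights follow the equal-area
17-segment convention (6/17 basal, 6/17 mid, 4/17 apical, 1/17 apex), so a
sector's area fraction is its ring weight divided by the ring's sector count.

Angles are in degrees, counterclockwise, with the anterior wall centred on
90 degrees (the usual polar-map orientation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["PolarGrid", "SegmentTable", "AHA_ADJACENCY", "aha_neighbors"]

# Circumferential spans (deg) of the basal (1-6) and mid (7-12) segments and
# the four apical segments (13-16); segment 17 is the apex cap.
_BASAL_MID_SPANS = {
    0: (60.0, 120.0),   # anterior
    1: (120.0, 180.0),  # anteroseptal
    2: (180.0, 240.0),  # inferoseptal
    3: (240.0, 300.0),  # inferior
    4: (300.0, 360.0),  # inferolateral
    5: (0.0, 60.0),     # anterolateral
}
_APICAL_SPANS = {
    13: (45.0, 135.0),   # apical anterior
    14: (135.0, 225.0),  # apical septal
    15: (225.0, 315.0),  # apical inferior
    16: (315.0, 405.0),  # apical lateral (wraps)
}

# Edge list of the 17-segment adjacency graph (contiguity for Seg-Scar).
# Ring neighbours, radial neighbours, mid-apical overlaps, apex to 13-16.
AHA_ADJACENCY: tuple[tuple[int, int], ...] = (
    (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 1),
    (7, 8), (8, 9), (9, 10), (10, 11), (11, 12), (12, 7),
    (13, 14), (14, 15), (15, 16), (16, 13),
    (1, 7), (2, 8), (3, 9), (4, 10), (5, 11), (6, 12),
    (7, 13), (8, 13), (12, 13),
    (8, 14), (9, 14),
    (9, 15), (10, 15), (11, 15),
    (11, 16), (12, 16),
    (13, 17), (14, 17), (15, 17), (16, 17),
)


def aha_neighbors() -> dict[int, frozenset[int]]:
    nbrs: dict[int, set[int]] = {i: set() for i in range(1, 18)}
    for a, b in AHA_ADJACENCY:
        nbrs[a].add(b)
        nbrs[b].add(a)
    return {k: frozenset(v) for k, v in nbrs.items()}


def _angle_in(theta: float, lo: float, hi: float) -> bool:
    t = theta % 360.0
    if hi <= 360.0:
        return lo <= t < hi
    return t >= lo or t < hi - 360.0


@dataclass(frozen=True)
class PolarGrid:
    """Fine polar grid: ``n_angular`` sectors per myocardial ring + apex cap."""

    n_angular: int = 72

    @property
    def ring_sizes(self) -> tuple[int, ...]:
        return (self.n_angular, self.n_angular, self.n_angular, 1)

    @property
    def n_sectors(self) -> int:
        return sum(self.ring_sizes)

    @property
    def ring_index(self) -> np.ndarray:
        """Ring of each sector: 0 basal, 1 mid, 2 apical, 3 apex."""
        return np.repeat(np.arange(4), self.ring_sizes)

    @property
    def angle_deg(self) -> np.ndarray:
        """Centre angle of each sector (apex cap gets 0 by convention)."""
        base = (np.arange(self.n_angular) + 0.5) * (360.0 / self.n_angular)
        return np.concatenate([base, base, base, [0.0]])

    @property
    def area_fraction(self) -> np.ndarray:
        """Sector area as a fraction of total LV myocardium (sums to 1)."""
        weights = np.array([6 / 17, 6 / 17, 4 / 17, 1 / 17])
        return np.repeat(weights / np.array(self.ring_sizes), self.ring_sizes)

    @property
    def segment_of(self) -> np.ndarray:
        """AHA segment id (1-17) of every fine sector."""
        seg = np.empty(self.n_sectors, dtype=int)
        angles = self.angle_deg
        rings = self.ring_index
        for i in range(self.n_sectors):
            r, th = rings[i], angles[i]
            if r == 3:
                seg[i] = 17
            elif r == 2:
                for sid, (lo, hi) in _APICAL_SPANS.items():
                    if _angle_in(th, lo, hi):
                        seg[i] = sid
                        break
            else:
                for k, (lo, hi) in _BASAL_MID_SPANS.items():
                    if _angle_in(th, lo, hi):
                        seg[i] = k + 1 + 6 * r
                        break
        return seg

    def neighbor_lists(self) -> list[list[int]]:
        """Sector adjacency: angular neighbours (wrapping), radial neighbours
        at the same angle, apex cap adjacent to every apical-ring sector."""
        n = self.n_angular
        nbrs: list[list[int]] = [[] for _ in range(self.n_sectors)]
        for r in range(3):
            off = r * n
            for j in range(n):
                i = off + j
                nbrs[i].append(off + (j + 1) % n)
                nbrs[i].append(off + (j - 1) % n)
                if r < 2:
                    nbrs[i].append(off + n + j)
                if r > 0:
                    nbrs[i].append(off - n + j)
        apex = 3 * n
        for j in range(n):
            nbrs[2 * n + j].append(apex)
            nbrs[apex].append(2 * n + j)
        return nbrs

    def connected_components(self, mask: np.ndarray) -> list[np.ndarray]:
        """Connected components of a boolean sector mask, largest first
        (ties broken by smallest member index for determinism)."""
        mask = np.asarray(mask, dtype=bool)
        if mask.size != self.n_sectors:
            raise ValueError("mask length does not match grid")
        nbrs = self.neighbor_lists()
        seen = np.zeros(self.n_sectors, dtype=bool)
        comps: list[np.ndarray] = []
        for start in range(self.n_sectors):
            if not mask[start] or seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in nbrs[u]:
                    if mask[v] and not seen[v]:
                        seen[v] = True
                        stack.append(v)
            comps.append(np.array(sorted(comp)))
        area = self.area_fraction
        comps.sort(key=lambda c: (-float(area[c].sum()), int(c[0])))
        return comps

    def wedge_mask(
        self,
        center_deg: float,
        extent_deg: float,
        rings: Iterable[int] = (0, 1, 2),
        include_apex: bool = False,
    ) -> np.ndarray:
        """Boolean mask of the angular wedge ``center +- extent/2`` on the
        given rings (a transmural, full-height wedge by default)."""
        if not 0 < extent_deg <= 360:
            raise ValueError("extent_deg must be in (0, 360]")
        half = extent_deg / 2.0
        diff = (self.angle_deg - center_deg + 180.0) % 360.0 - 180.0
        mask = np.abs(diff) <= half
        ring_ok = np.isin(self.ring_index, list(rings))
        mask &= ring_ok
        mask[-1] = bool(include_apex)
        return mask

    def segment_values(self, sector_values: np.ndarray) -> np.ndarray:
        """Area-weighted mean of a fine-sector field per AHA segment,
        returned as a length-17 array indexed by segment id - 1."""
        sector_values = np.asarray(sector_values, dtype=float)
        seg = self.segment_of
        area = self.area_fraction
        out = np.empty(17)
        for sid in range(1, 18):
            sel = seg == sid
            out[sid - 1] = float(
                np.average(sector_values[sel], weights=area[sel])
            )
        return out

    def segment_coverage(self, mask: np.ndarray) -> np.ndarray:
        """Fraction of each segment's area covered by a fine-sector mask."""
        mask = np.asarray(mask, dtype=bool)
        seg = self.segment_of
        area = self.area_fraction
        out = np.empty(17)
        for sid in range(1, 18):
            sel = seg == sid
            out[sid - 1] = float(area[sel & mask].sum() / area[sel].sum())
        return out


@dataclass
class SegmentTable:
    """Per-segment results on the 17-segment model.

    Backed by a DataFrame with columns ``segment_id`` (1..17), ``rmbf``
    (mL/min/g), ``ru_percent`` (0-100, percent of the maximum segment) and
    optionally ``rest_score`` (0-4).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        required = {"segment_id", "rmbf", "ru_percent"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"SegmentTable missing columns {sorted(missing)}")
        df["segment_id"] = df["segment_id"].astype(int)
        ids = sorted(df["segment_id"].tolist())
        if ids != list(range(1, 18)):
            raise ValueError("SegmentTable needs exactly segments 1..17")
        if (df["rmbf"] < 0).any():
            raise ValueError("rmbf must be >= 0")
        if ((df["ru_percent"] < 0) | (df["ru_percent"] > 100)).any():
            raise ValueError("ru_percent must lie in [0, 100]")
        if "rest_score" in df.columns:
            scores = df["rest_score"].dropna()
            if (~scores.isin([0, 1, 2, 3, 4])).any():
                raise ValueError("rest_score must be in 0..4")
        self.df = df.sort_values("segment_id").reset_index(drop=True)

    @classmethod
    def from_arrays(
        cls,
        rmbf: Sequence[float],
        ru_percent: Sequence[float],
        rest_score: Sequence[int] | None = None,
    ) -> "SegmentTable":
        data = {
            "segment_id": np.arange(1, 18),
            "rmbf": np.asarray(rmbf, dtype=float),
            "ru_percent": np.asarray(ru_percent, dtype=float),
        }
        if rest_score is not None:
            data["rest_score"] = np.asarray(rest_score, dtype=int)
        return cls(pd.DataFrame(data))

    def value(self, segment_id: int, column: str) -> float:
        return float(
            self.df.loc[self.df["segment_id"] == segment_id, column].iloc[0]
        )

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SegmentTable":
        return cls(pd.read_csv(path))
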
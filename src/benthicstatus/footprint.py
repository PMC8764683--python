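"""Trawl footprint and sensitive-biota threshold metrics from SAR grids.

Works on per-cell total swept-area ratio (F, summed across gears) and cell
areas.  The "uniform" footprint treats each cell's swept area as spread
evenly within the cell, so a cell contributes ``area * min(F, 1)``; the
sensitive-biota metrics report the share of regional area above the local
extinction threshold (F > 0.35, where biota with sensitivity 2.86 have
status 0) and below the persistence threshold (F < 0.07, status > 0.8).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "uniform_footprint",
    "area_exceeding",
    "persistence_area",
    "equivalent_threshold",
    "footprint_report",
]

#: Swept-area ratio above which highly sensitive biota have status 0.
F_EXTINCT = 0.35
#: Swept-area ratio below which highly sensitive biota keep status > 0.8.
F_PERSIST = 0.07


def _areas_F(cells: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    a = cells["area_km2"].to_numpy(dtype=float)
    f = cells["f_total"].to_numpy(dtype=float)
    if np.any(a <= 0):
        raise ValueError("cell areas must be positive")
    if np.any(f < 0):
        raise ValueError("swept-area ratio must be non-negative")
    return a, f


def uniform_footprint(cells: pd.DataFrame) -> dict:
    """Uniform trawl footprint: sum of A where F > 1 plus A*F where F < 1.

    Equivalently ``sum(A * min(F, 1))`` (a cell with F exactly 1
    contributes its full area under either branch).  Bounded by the total
    regional area.
    """
    a, f = _areas_F(cells)
    km2 = float(np.sum(a * np.minimum(f, 1.0)))
    return {"km2": km2, "pct": 100.0 * km2 / float(a.sum())}


def area_exceeding(cells: pd.DataFrame, threshold: float = F_EXTINCT) -> float:
    """% of regional area with F strictly above a threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    a, f = _areas_F(cells)
    return float(100.0 * a[f > threshold].sum() / a.sum())


def persistence_area(cells: pd.DataFrame, threshold: float = F_PERSIST) -> float:
    """% of regional area with F strictly below a threshold (untrawled
    cells included)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    a, f = _areas_F(cells)
    return float(100.0 * a[f < threshold].sum() / a.sum())


def equivalent_threshold(cells: pd.DataFrame) -> float:
    """Threshold F defining "trawled" cells whose total area matches the
    uniform footprint.

    The survival curve of cumulative area over descending distinct F values
    is inverted at the uniform-footprint area; between adjacent distinct F
    values the crossing is linearly interpolated, and an exact crossing
    returns the exact F.  Requires some trawled area.
    """
    a, f = _areas_F(cells)
    target = float(np.sum(a * np.minimum(f, 1.0)))
    if target <= 0:
        raise ValueError("no trawled area: equivalent threshold undefined")
    trawled = f > 0
    f_t, a_t = f[trawled], a[trawled]
    f_knots = np.unique(f_t)[::-1]  # distinct F descending
    # cumulative area at each distinct F = total area of cells with F >= it
    cum_at_knot = np.cumsum([a_t[f_t == fk].sum() for fk in f_knots])
    xp = np.concatenate([[0.0], cum_at_knot])
    fp_ = np.concatenate([[f_knots[0]], f_knots])
    return float(np.interp(target, xp, fp_))


def footprint_report(cells: pd.DataFrame, region_id: str = "region") -> dict:
    """Full footprint report for one region."""
    a, f = _areas_F(cells)
    uf = uniform_footprint(cells)
    report = {
        "region_id": region_id,
        "total_area_km2": float(a.sum()),
        "uniform_footprint_km2": uf["km2"],
        "uniform_footprint_pct": uf["pct"],
        "area_pct_F_gt_0.35": area_exceeding(cells),
        "area_pct_F_lt_0.07": persistence_area(cells),
    }
    report["equivalent_threshold_F"] = (
        equivalent_threshold(cells) if uf["km2"] > 0 else float("nan")
    )
    return report
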
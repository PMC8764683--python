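"""Grid-cell status assessment and regional summaries.

Takes a gridded trawl-effort table (swept-area ratio per gear per ~1 km2
cell), a gridded sediment-composition table, a depletion table and a fitted
(or default) recovery slope, and produces per-cell relative benthic status
with a precautionary lower confidence band, the regional mean, the ordered
status-area curve, category breakdowns, habitat and gear decompositions,
and threshold-risk probabilities.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import GearType, ASSESSMENT_GEARS, HABITATS
from .habitat import classify_habitat_vec
from .recovery import GradientSlope, recovery_from_slope

__all__ = [
    "scale_coverage",
    "assess_cells",
    "regional_mean",
    "rbs_area_curve",
    "curve_value_at",
    "category_breakdown",
    "habitat_gear_decomposition",
    "threshold_probability",
    "regional_summary",
]

#: Default interior category boundaries of the six status intervals:
#: {exactly 1, [0.8, 1), [0.6, 0.8), [0.4, 0.6), (0, 0.4), exactly 0}.
DEFAULT_CATEGORY_BOUNDARIES = (0.8, 0.6, 0.4)


def scale_coverage(F: float | np.ndarray, coverage_pct: float | np.ndarray):
    """Scale swept-area ratio up for incomplete effort-data coverage.

    Collated effort data typically cover only part of a fleet's activity;
    scaling by 100/coverage% avoids underestimating trawl intensity
    (assuming the collated data are spatially representative).
    """
    F = np.asarray(F, dtype=float)
    coverage_pct = np.asarray(coverage_pct, dtype=float)
    if np.any((coverage_pct <= 0) | (coverage_pct > 100)):
        raise ValueError("coverage_pct must be in (0, 100]")
    if np.any(F < 0):
        raise ValueError("swept-area ratio F must be non-negative")
    out = F * 100.0 / coverage_pct
    return float(out) if out.ndim == 0 else out


def _slope_arrays(
    slope: GradientSlope, g: np.ndarray, s: np.ndarray, m: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised composition-dependent slope and its SE over cells."""
    b = slope.b0 + slope.b_gravel * g + slope.b_mud * m
    if slope.cov is not None:
        X = np.stack([np.ones_like(g), g, m], axis=1)
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, slope.cov, X))
    elif slope.vertex_se is not None:
        se = (
            g * slope.vertex_se["gravel"]
            + s * slope.vertex_se["sand"]
            + m * slope.vertex_se["mud"]
        )
    else:
        se = np.zeros_like(b)
    return b, se


def _recovery_vec(b: np.ndarray, dF0: float) -> np.ndarray:
    if np.any(b >= 0):
        raise ValueError("gradient slope must be negative at all compositions")
    return dF0 / (-np.expm1(b * dF0 * np.log(10.0)))


def assess_cells(
    effort: pd.DataFrame,
    sediment: pd.DataFrame,
    d_table: pd.DataFrame,
    slope: GradientSlope,
    apply_coverage_scaling: bool = True,
    dF0: float = 1e-9,
) -> pd.DataFrame:
    """Per-cell relative benthic status with uncertainty.

    Parameters
    ----------
    effort : DataFrame
        Long format, one row per cell x gear: ``cell_id, lon, lat,
        area_km2, gear, sar, coverage_pct``.
    sediment : DataFrame
        One row per cell: ``cell_id, gravel_pct, sand_pct, mud_pct``.
    d_table : DataFrame
        Depletion table indexed by (gear, habitat) with column ``d``.
    slope : GradientSlope
        Composition-dependent recovery slope.

    Returns one row per cell with ``rbs_mean`` (mean recovery), ``rbs_lcl``
    and ``rbs_ucl`` (lower/upper-CL recovery; the lower CL is the
    precautionary band for more sensitive biota), total swept-area ratio,
    the habitat class, and one ``term_<gear>`` column per gear holding the
    cell's depletion term F*d/R_mean.  Assessment gears only; cells present
    in only one of the two grids are dropped with a warning.
    """
    for col in ("cell_id", "gear", "sar"):
        if col not in effort.columns:
            raise ValueError(f"effort grid missing column {col!r}")
    for col in ("cell_id", "gravel_pct", "sand_pct", "mud_pct"):
        if col not in sediment.columns:
            raise ValueError(f"sediment grid missing column {col!r}")
    gears_present = sorted({GearType(g) for g in effort["gear"].unique()}, key=lambda g: g.value)
    bad = [g.value for g in gears_present if g not in ASSESSMENT_GEARS]
    if bad:
        raise ValueError(
            f"gear(s) {bad} not admitted to assessments (meta-analysis only)"
        )

    eff = effort.copy()
    eff["gear"] = eff["gear"].map(lambda g: GearType(g).value)
    if apply_coverage_scaling and "coverage_pct" in eff.columns:
        eff["sar"] = scale_coverage(
            eff["sar"].to_numpy(dtype=float),
            eff["coverage_pct"].to_numpy(dtype=float),
        )
    if (eff["sar"] < 0).any():
        raise ValueError("swept-area ratio must be non-negative")

    wide = eff.pivot_table(
        index="cell_id", columns="gear", values="sar", aggfunc="sum", fill_value=0.0
    )
    meta_cols = [c for c in ("lon", "lat", "area_km2") if c in eff.columns]
    cell_meta = eff.drop_duplicates("cell_id").set_index("cell_id")[meta_cols]

    sed = sediment.drop_duplicates("cell_id").set_index("cell_id")
    common = wide.index.intersection(sed.index)
    n_unmatched = (len(wide) - len(common)) + (len(sed) - len(common))
    if n_unmatched:
        warnings.warn(
            f"{n_unmatched} cell(s) present in only one grid; assessing the "
            f"intersection of {len(common)} cells",
            UserWarning,
        )
    if len(common) == 0:
        raise ValueError("effort and sediment grids share no cells")
    wide = wide.loc[common]
    sed = sed.loc[common]

    gpct = sed["gravel_pct"].to_numpy(dtype=float)
    spct = sed["sand_pct"].to_numpy(dtype=float)
    mpct = sed["mud_pct"].to_numpy(dtype=float)
    tot = gpct + spct + mpct
    if np.any(np.abs(tot - 100.0) > 0.1):
        raise ValueError("sediment percentages must sum to 100 +/- 0.1")
    g, s, m = gpct / tot, spct / tot, mpct / tot

    b, b_se = _slope_arrays(slope, g, s, m)
    R_mean = _recovery_vec(b, dF0)
    R_lcl = _recovery_vec(b - 1.96 * b_se, dF0)
    R_ucl = _recovery_vec(b + 1.96 * b_se, dF0)

    out = pd.DataFrame(index=common)
    for col in meta_cols:
        out[col] = cell_meta.loc[common, col]
    if "area_km2" not in out.columns:
        out["area_km2"] = 1.0
    out["gravel_pct"], out["sand_pct"], out["mud_pct"] = gpct, spct, mpct
    out["habitat"] = classify_habitat_vec(gpct, spct, mpct)

    total_mean = np.zeros(len(common))
    total_lcl = np.zeros(len(common))
    total_ucl = np.zeros(len(common))
    f_total = np.zeros(len(common))
    for gear in gears_present:
        F = wide[gear.value].to_numpy(dtype=float) if gear.value in wide else 0.0
        d = (
            g * d_table.loc[(gear.value, "gravel"), "d"]
            + s * d_table.loc[(gear.value, "sand"), "d"]
            + m * d_table.loc[(gear.value, "mud"), "d"]
        )
        term = F * d / R_mean
        out[f"term_{gear.value}"] = term
        total_mean += term
        total_lcl += F * d / R_lcl
        total_ucl += F * d / R_ucl
        f_total += F
    out["f_total"] = f_total
    out["rbs_mean"] = np.where(f_total == 0, 1.0, np.maximum(0.0, 1.0 - total_mean))
    out["rbs_lcl"] = np.where(f_total == 0, 1.0, np.maximum(0.0, 1.0 - total_lcl))
    out["rbs_ucl"] = np.where(f_total == 0, 1.0, np.maximum(0.0, 1.0 - total_ucl))
    out["R_mean"] = R_mean
    out["R_lcl"] = R_lcl
    out.index.name = "cell_id"
    return out.reset_index()


def regional_mean(cells: pd.DataFrame, value_col: str = "rbs_mean") -> dict:
    """Regional mean status, area-weighted (headline) and unweighted."""
    if len(cells) == 0:
        raise ValueError("no cells")
    v = cells[value_col].to_numpy(dtype=float)
    a = cells["area_km2"].to_numpy(dtype=float)
    return {
        "area_weighted": float(np.average(v, weights=a)),
        "simple": float(v.mean()),
    }


def rbs_area_curve(cells: pd.DataFrame, value_col: str = "rbs_mean") -> pd.DataFrame:
    """Ordered status-area curve: cells sorted by status (descending)
    against cumulative percentage of regional area.

    The curve is a right-continuous step function; the area under it (in
    proportion-of-area units) equals the area-weighted regional mean
    exactly.  Lower/upper-CL bands are built by sorting the band values
    independently, which guarantees monotone curves.
    """
    if len(cells) == 0:
        raise ValueError("no cells")
    order = np.argsort(-cells[value_col].to_numpy(dtype=float), kind="stable")
    v = cells[value_col].to_numpy(dtype=float)[order]
    a = cells["area_km2"].to_numpy(dtype=float)[order]
    cum = np.cumsum(a) / a.sum() * 100.0
    return pd.DataFrame({"cum_area_pct": cum, value_col: v, "area_km2": a})


def curve_value_at(curve: pd.DataFrame, area_pct: float, value_col: str) -> float:
    """Value of the step curve at a cumulative-area percentile.

    Returns the status of the cell whose area interval covers ``area_pct``.
    """
    if not 0 < area_pct <= 100:
        raise ValueError("area_pct must be in (0, 100]")
    cum = curve["cum_area_pct"].to_numpy(dtype=float)
    idx = int(np.searchsorted(cum, area_pct, side="left"))
    idx = min(idx, len(cum) - 1)
    return float(curve[value_col].to_numpy(dtype=float)[idx])


def category_breakdown(
    cells: pd.DataFrame,
    boundaries: Sequence[float] = DEFAULT_CATEGORY_BOUNDARIES,
    value_col: str = "rbs_mean",
) -> pd.DataFrame:
    """Percentage of regional area in six status categories.

    Categories (default boundaries 0.8, 0.6, 0.4): exactly 1 (untrawled),
    [0.8, 1), [0.6, 0.8), [0.4, 0.6), (0, 0.4) and exactly 0.  Interior
    intervals are half-open ``[lo, hi)``; the exact-1 and exact-0 classes
    are pulled out first.  Percentages sum to 100.
    """
    b = sorted(set(boundaries), reverse=True)
    if len(b) != 3 or b[0] >= 1 or b[-1] <= 0:
        raise ValueError("need three distinct interior boundaries in (0, 1)")
    v = cells[value_col].to_numpy(dtype=float)
    a = cells["area_km2"].to_numpy(dtype=float)
    total = a.sum()
    edges = [1.0] + list(b) + [0.0]
    labels = ["=1"] + [f"[{lo:g},{hi:g})" for hi, lo in zip(edges[:-1], edges[1:])]
    labels[-1] = f"(0,{edges[-2]:g})"
    labels.append("=0")
    masks = [v == 1.0]
    for hi, lo in zip(edges[:-1], edges[1:]):
        if lo == 0.0:
            masks.append((v > 0.0) & (v < hi) & (v != 1.0))
        else:
            masks.append((v >= lo) & (v < hi))
    # the top interior interval [b0, 1) must exclude the exact-1 class
    masks[1] = masks[1] & (v != 1.0)
    masks.append(v == 0.0)
    pct = [100.0 * a[mk].sum() / total for mk in masks]
    return pd.DataFrame({"category": labels, "area_pct": pct})


def habitat_gear_decomposition(cells: pd.DataFrame) -> dict:
    """Per-habitat mean status and per-gear mean status reduction.

    A cell's per-gear reduction is its depletion term F*d/R; when the sum
    of terms exceeds 1 (status clamped at 0) the terms are rescaled
    proportionally so they total exactly 1.  Regional per-gear reductions
    are area-weighted means and sum to 1 minus the area-weighted mean
    status.
    """
    term_cols = [c for c in cells.columns if c.startswith("term_")]
    a = cells["area_km2"].to_numpy(dtype=float)
    terms = cells[term_cols].to_numpy(dtype=float)
    total = terms.sum(axis=1)
    scale = np.ones_like(total)
    over = total > 1.0
    scale[over] = 1.0 / total[over]
    attributed = terms * scale[:, None]
    gear_reduction = {
        c.removeprefix("term_"): float(np.average(attributed[:, i], weights=a))
        for i, c in enumerate(term_cols)
    }
    by_habitat = {}
    for h in HABITATS:
        sub = cells[cells["habitat"] == h]
        if len(sub):
            by_habitat[h] = {
                "mean_rbs": float(
                    np.average(sub["rbs_mean"], weights=sub["area_km2"])
                ),
                "mean_rbs_lcl": float(
                    np.average(sub["rbs_lcl"], weights=sub["area_km2"])
                ),
                "area_pct": float(100.0 * sub["area_km2"].sum() / a.sum()),
            }
    return {"gear_reduction": gear_reduction, "by_habitat": by_habitat}


def threshold_probability(
    curve_mean: pd.DataFrame,
    curve_lcl: pd.DataFrame,
    curve_ucl: pd.DataFrame,
    rbs_threshold: float = 0.8,
    area_threshold_pct: float = 80.0,
) -> float:
    """Probability that status at an area percentile is below a threshold.

    Reads the mean and 95% confidence-limit curves at the stated
    cumulative-area percentile, treats the band as a normal 95% interval
    with sd = (ucl - lcl)/3.92, and returns P(status < threshold).  A
    degenerate band gives a 0/1 step (0.5 exactly at the threshold).
    """
    mean = curve_value_at(curve_mean, area_threshold_pct, "rbs_mean")
    lcl = curve_value_at(curve_lcl, area_threshold_pct, "rbs_lcl")
    ucl = curve_value_at(curve_ucl, area_threshold_pct, "rbs_ucl")
    sd = (ucl - lcl) / 3.92
    if sd <= 0:
        if mean == rbs_threshold:
            return 0.5
        return float(mean < rbs_threshold)
    return float(norm.cdf((rbs_threshold - mean) / sd))


def regional_summary(
    cells: pd.DataFrame,
    region_id: str = "region",
    boundaries: Sequence[float] = DEFAULT_CATEGORY_BOUNDARIES,
    rbs_threshold: float = 0.8,
    area_threshold_pct: float = 80.0,
) -> dict:
    """Assemble the full regional summary from assessed cells."""
    from . import footprint as fp

    a = cells["area_km2"].to_numpy(dtype=float)
    f = cells["f_total"].to_numpy(dtype=float)
    means = regional_mean(cells)
    means_lcl = regional_mean(cells, "rbs_lcl")
    curve_mean = rbs_area_curve(cells, "rbs_mean")
    curve_lcl = rbs_area_curve(cells, "rbs_lcl")
    curve_ucl = rbs_area_curve(cells, "rbs_ucl")
    decomp = habitat_gear_decomposition(cells)
    fp_cells = cells[["area_km2", "f_total"]]
    return {
        "region_id": region_id,
        "n_cells": int(len(cells)),
        "total_area_km2": float(a.sum()),
        "regional_sar": float(np.average(f, weights=a)),
        "mean_rbs": means["area_weighted"],
        "mean_rbs_simple": means["simple"],
        "mean_rbs_lcl": means_lcl["area_weighted"],
        "untrawled_area_pct": float(100.0 * a[f == 0].sum() / a.sum()),
        "rbs_zero_area_pct": float(
            100.0 * a[cells["rbs_mean"].to_numpy() == 0.0].sum() / a.sum()
        ),
        "categories": category_breakdown(cells, boundaries).to_dict("records"),
        "by_habitat": decomp["by_habitat"],
        "gear_reduction": decomp["gear_reduction"],
        "threshold_probability": threshold_probability(
            curve_mean, curve_lcl, curve_ucl, rbs_threshold, area_threshold_pct
        ),
        "footprint": fp.footprint_report(fp_cells, region_id=region_id),
    }
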
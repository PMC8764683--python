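"""Sediment habitat classification and continuous parameter surfaces.

Grid cells carry gravel/sand/mud percentages.  Cells are classified into
three categorical habitats for reporting ("gravel" if gravel% > 30, else
"sand" if sand% > mud%, else "mud"), while the assessment parameters vary
continuously over the composition simplex: penetration depth and depletion
are fraction-weighted means of the three habitat values, and recovery comes
from the composition-dependent gradient slope.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .core import GearType, HABITATS, ASSESSMENT_GEARS
from .recovery import GradientSlope, recovery_with_cls

__all__ = [
    "classify_habitat",
    "classify_habitat_vec",
    "continuous_d",
    "continuous_pd",
    "continuous_R",
    "param_surface",
    "default_depletion_table",
]


def classify_habitat(gravel_pct: float, sand_pct: float, mud_pct: float) -> str:
    """Categorical habitat from sediment percentages (0-100).

    Rule: "gravel" if gravel% > 30 (strict), else "sand" if sand% > mud%,
    else "mud"; the sand% == mud% tie falls to "mud" through the
    else-branch.
    """
    _check_pct(gravel_pct, sand_pct, mud_pct)
    if gravel_pct > 30.0:
        return "gravel"
    if sand_pct > mud_pct:
        return "sand"
    return "mud"


def classify_habitat_vec(
    gravel_pct: np.ndarray, sand_pct: np.ndarray, mud_pct: np.ndarray
) -> np.ndarray:
    """Vectorised :func:`classify_habitat`."""
    gravel_pct = np.asarray(gravel_pct, dtype=float)
    sand_pct = np.asarray(sand_pct, dtype=float)
    mud_pct = np.asarray(mud_pct, dtype=float)
    out = np.where(
        gravel_pct > 30.0, "gravel", np.where(sand_pct > mud_pct, "sand", "mud")
    )
    return out


def _check_pct(gravel: float, sand: float, mud: float) -> None:
    if min(gravel, sand, mud) < -1e-9:
        raise ValueError("sediment percentages must be non-negative")
    if abs(gravel + sand + mud - 100.0) > 0.1:
        raise ValueError(
            f"sediment percentages must sum to 100 +/- 0.1, "
            f"got {gravel + sand + mud}"
        )


def _fractions(gravel: float, sand: float, mud: float) -> tuple[float, float, float]:
    """Percentages (0-100) to fractions, validated once at ingest."""
    _check_pct(gravel, sand, mud)
    total = gravel + sand + mud
    return gravel / total, sand / total, mud / total


def continuous_d(
    gravel: float, sand: float, mud: float, gear: GearType | str, d_table: pd.DataFrame
) -> float:
    """Fraction-weighted mean depletion for a gear at a composition.

    ``gravel, sand, mud`` are fractions summing to 1.  Linear in the
    fractions, so bounded by the three habitat values and equal to them at
    the simplex vertices.
    """
    gear = GearType(gear)
    return float(
        gravel * d_table.loc[(gear.value, "gravel"), "d"]
        + sand * d_table.loc[(gear.value, "sand"), "d"]
        + mud * d_table.loc[(gear.value, "mud"), "d"]
    )


def continuous_pd(
    gravel: float, sand: float, mud: float, gear: GearType | str, d_table: pd.DataFrame
) -> float:
    """Fraction-weighted mean penetration depth (cm); same logic as
    :func:`continuous_d`."""
    gear = GearType(gear)
    return float(
        gravel * d_table.loc[(gear.value, "gravel"), "pd_cm"]
        + sand * d_table.loc[(gear.value, "sand"), "pd_cm"]
        + mud * d_table.loc[(gear.value, "mud"), "pd_cm"]
    )


def continuous_R(
    gravel: float, sand: float, mud: float, slope: GradientSlope
) -> tuple[float, float]:
    """(R_mean, R_lcl) at a composition, from the gradient slope."""
    r_mean, r_lcl, _ = recovery_with_cls(slope, gravel, sand, mud)
    return r_mean, r_lcl


def param_surface(
    gear: GearType | str,
    d_table: pd.DataFrame,
    slope: GradientSlope,
    step_pct: float = 5.0,
) -> pd.DataFrame:
    """Parameter surface on a ternary composition lattice for one gear.

    Returns a DataFrame with one row per lattice composition (default 5%
    steps) and columns ``gravel_pct, sand_pct, mud_pct, pd_cm, d, R_mean,
    R_lcl, sensitivity, f_crit``.  Vertex rows equal the categorical
    habitat parameters exactly.
    """
    gear = GearType(gear)
    if not (0 < step_pct <= 50):
        raise ValueError("step_pct must be in (0, 50]")
    n = int(round(100.0 / step_pct))
    rows = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            k = n - i - j
            g, s, m = i / n, j / n, k / n
            d = continuous_d(g, s, m, gear, d_table)
            pd_cm = continuous_pd(g, s, m, gear, d_table)
            r_mean, r_lcl = continuous_R(g, s, m, slope)
            rows.append(
                {
                    "gear": gear.value,
                    "gravel_pct": 100 * g,
                    "sand_pct": 100 * s,
                    "mud_pct": 100 * m,
                    "pd_cm": pd_cm,
                    "d": d,
                    "R_mean": r_mean,
                    "R_lcl": r_lcl,
                    "sensitivity": d / r_mean if d > 0 else np.nan,
                    "f_crit": r_mean / d if d > 0 else np.inf,
                }
            )
    return pd.DataFrame(rows)


def default_depletion_table(gears: Iterable[GearType] | None = None) -> pd.DataFrame:
    """Synthetic default depletion/penetration table.

    A labelled stand-in used by examples and by the pipeline when no
    experimental study data are supplied: depletion per pass is lowest for
    otter trawls and highest for towed dredges, lower in sand than in
    gravel or mud, spanning roughly 0.05-0.26; penetration depths increase
    in the same gear order.  Not fitted to data -- run the depletion
    meta-analysis on study records to estimate these from inputs.
    """
    d_vals = {
        GearType.otter_trawl: {"gravel": 0.078, "sand": 0.047, "mud": 0.069},
        GearType.beam_trawl: {"gravel": 0.14, "sand": 0.09, "mud": 0.12},
        GearType.towed_dredge: {"gravel": 0.26, "sand": 0.16, "mud": 0.22},
    }
    pd_vals = {
        GearType.otter_trawl: {"gravel": 1.9, "sand": 2.2, "mud": 2.8},
        GearType.beam_trawl: {"gravel": 2.5, "sand": 3.0, "mud": 3.8},
        GearType.towed_dredge: {"gravel": 4.6, "sand": 5.4, "mud": 6.6},
    }
    if gears is None:
        gears = sorted(ASSESSMENT_GEARS, key=lambda g: g.value)
    rows = []
    for gear in gears:
        for h in HABITATS:
            rows.append(
                {
                    "gear": gear.value,
                    "habitat": h,
                    "d": d_vals[gear][h],
                    "pd_cm": pd_vals[gear][h],
                }
            )
    return pd.DataFrame(rows).set_index(["gear", "habitat"])
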
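"""Equilibrium relative benthic status (RBS) model and scale conversions.

The status of a seabed community under chronic trawling is described by the
equilibrium of a logistic (Schaefer) production model with an additional
mortality term for trawl passes.  With annual swept-area ratio ``F``
(area swept by gear per year / cell area, dimensionless per year), depletion
``d`` (proportion of community abundance removed per trawl pass) and annual
proportional recovery rate ``R`` (per year, at the grid-cell scale), the
equilibrium relative abundance B/K is::

    RBS = 1 - F * d / R    where F < R / d, otherwise RBS = 0

The ratio ``d/R`` is the community's *sensitivity* (years between trawl
passes at which it is locally extirpated) and its reciprocal ``R/d`` is the
critical swept-area ratio ``F_crit`` at which equilibrium status reaches
zero.

Depletion and recovery are measured at two scales: ``d`` and ``r`` apply at
the scale of an individual trawl track, ``D`` and ``R`` at the grid-cell
scale.  Under random trawl placement within a cell ``D = d`` while the
cell-scale recovery is reduced, ``R = r d / (-ln(1 - d))``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GearType",
    "ASSESSMENT_GEARS",
    "HABITATS",
    "GearHabitatParams",
    "Sensitivity",
    "equilibrium_rbs",
    "cumulative_rbs",
    "sensitivity",
    "grid_recovery_from_gear_scale",
]


class GearType(str, enum.Enum):
    """Towed bottom-fishing gear types.

    ``hydraulic_dredge`` appears in the impact/penetration meta-analyses
    only; regional assessments cover otter trawls, beam trawls and towed
    dredges.
    """

    otter_trawl = "otter_trawl"
    beam_trawl = "beam_trawl"
    towed_dredge = "towed_dredge"
    hydraulic_dredge = "hydraulic_dredge"


#: Gear types admitted to grid-cell status assessments.
ASSESSMENT_GEARS: frozenset[GearType] = frozenset(
    {GearType.otter_trawl, GearType.beam_trawl, GearType.towed_dredge}
)

#: Sediment habitat classes, in gravel/sand/mud order used throughout.
HABITATS: tuple[str, str, str] = ("gravel", "sand", "mud")


@dataclass(frozen=True)
class Sensitivity:
    """Sensitivity ``s = d/R`` (years) and critical SAR ``f_crit = R/d``."""

    s: float
    f_crit: float


@dataclass
class GearHabitatParams:
    """Depletion, recovery and penetration-depth parameters for one
    gear x habitat combination, with uncertainty on the natural scale."""

    gear: GearType
    habitat: str
    d: float
    d_se: float = float("nan")
    d_lcl: float = float("nan")
    d_ucl: float = float("nan")
    pd_cm: float = float("nan")
    pd_se: float = float("nan")
    pd_lcl: float = float("nan")
    pd_ucl: float = float("nan")
    R_mean: float = float("nan")
    R_lcl: float = float("nan")
    R_ucl: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.d < 1.0:
            raise ValueError(f"depletion d must be in [0, 1), got {self.d}")
        if math.isfinite(self.pd_cm) and self.pd_cm <= 0:
            raise ValueError(f"penetration depth must be positive, got {self.pd_cm}")


def _check_dR(d: float, R: float) -> None:
    if not (0.0 <= d < 1.0):
        raise ValueError(f"depletion d must be in [0, 1), got {d}")
    if not R > 0.0:
        raise ValueError(f"recovery rate R must be positive, got {R}")


def equilibrium_rbs(F: float, d: float, R: float) -> float:
    """Equilibrium relative benthic status of a grid cell.

    Parameters
    ----------
    F : float
        Annual swept-area ratio of the cell (per year), >= 0.
    d : float
        Depletion per trawl pass, in [0, 1).
    R : float
        Annual proportional recovery rate at the grid-cell scale, > 0.

    Returns
    -------
    float
        Status in [0, 1]; exactly 1 when ``F == 0`` and exactly 0 when
        ``F >= R/d``.
    """
    _check_dR(d, R)
    if not F >= 0.0:
        raise ValueError(f"swept-area ratio F must be non-negative, got {F}")
    if F == 0.0:
        return 1.0
    return max(0.0, 1.0 - F * d / R)


def cumulative_rbs(gear_terms: Iterable[tuple[float, float]], R: float) -> float:
    """Status of a cell trawled by several gears, summing per-gear depletion.

    Each element of ``gear_terms`` is ``(F_g, d_g)`` for one gear; the
    recovery rate ``R`` is a property of the habitat and therefore shared.
    The per-gear depletion terms ``F_g * d_g / R`` add, and the total is
    clamped at 1 (status 0).
    """
    total = 0.0
    any_effort = False
    for F, d in gear_terms:
        _check_dR(d, R)
        if not F >= 0.0:
            raise ValueError(f"swept-area ratio F must be non-negative, got {F}")
        if F > 0.0:
            any_effort = True
            total += F * d / R
    if not any_effort:
        return 1.0
    return max(0.0, 1.0 - total)


def sensitivity(d: float, R: float) -> Sensitivity:
    """Sensitivity ``d/R`` and critical swept-area ratio ``R/d``.

    ``d = 0`` is rejected: it implies an infinite critical SAR, which is
    not represented.
    """
    _check_dR(d, R)
    if d == 0.0:
        raise ValueError("sensitivity undefined for d = 0 (F_crit infinite)")
    return Sensitivity(s=d / R, f_crit=R / d)


def grid_recovery_from_gear_scale(r: float, d: float) -> float:
    """Convert track-scale recovery ``r`` to cell-scale ``R``.

    Under random trawl placement within a cell, overlapping passes make
    cell-scale recovery slower than track-scale recovery::

        R = r * d / (-ln(1 - d))

    so ``R < r`` for all ``d`` in (0, 1) and ``R -> r`` as ``d -> 0``.
    """
    if not r > 0.0:
        raise ValueError(f"gear-scale recovery r must be positive, got {r}")
    if not (0.0 < d < 1.0):
        raise ValueError(f"depletion d must be in (0, 1), got {d}")
    return r * d / (-math.log1p(-d))


def equilibrium_rbs_vec(
    F: np.ndarray | Sequence[float],
    d: np.ndarray | Sequence[float],
    R: np.ndarray | Sequence[float],
) -> np.ndarray:
    """Vectorised :func:`equilibrium_rbs` (used on cell grids).

    Broadcasting follows numpy rules; exactness at F = 0 is preserved by
    masking rather than relying on floating-point cancellation.
    """
    F = np.asarray(F, dtype=float)
    d = np.asarray(d, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(F < 0):
        raise ValueError("swept-area ratio F must be non-negative")
    if np.any((d < 0) | (d >= 1)):
        raise ValueError("depletion d must be in [0, 1)")
    if np.any(R <= 0):
        raise ValueError("recovery rate R must be positive")
    out = np.maximum(0.0, 1.0 - F * d / R)
    return np.where(F == 0.0, 1.0, out)
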
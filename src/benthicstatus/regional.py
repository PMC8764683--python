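"""Cross-region relationships: status vs regional SAR and vs stock
exploitation.

Regional swept-area ratio (total annual swept area / total regional area)
is a strong driver of regional mean status; a monotone bounded fit with a
prediction interval allows preliminary status prediction for regions that
lack high-resolution spatial effort data.  Mean status also declines
linearly with the stock-exploitation ratio f/f_MSY, linking seabed state to
fishery sustainability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SarRbsFit", "fit_sar_rbs", "fit_fmsy_rbs"]

#: Clip bound applied to mean status before the logit transform.
LOGIT_CLIP = 1e-4


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SarRbsFit:
    """Logit-log fit of regional mean status on regional SAR.

    ``logit(mean_rbs) ~ a + c * log10(regional_sar)`` on regions with
    positive SAR; zero-SAR regions are pinned at status 1 and excluded.
    The logit link keeps predictions in (0, 1) and, with a negative slope,
    monotone decreasing in SAR.
    """

    intercept: float
    slope: float
    result: object = None
    meta: dict = field(default_factory=dict)

    def predict(self, regional_sar, alpha: float = 0.05) -> pd.DataFrame:
        """Predicted status with 95% prediction interval at given SAR(s).

        Zero SAR predicts status 1 with a degenerate interval.
        """
        import statsmodels.api as sm

        sar = np.atleast_1d(np.asarray(regional_sar, dtype=float))
        if np.any(sar < 0):
            raise ValueError("regional SAR must be non-negative")
        out = pd.DataFrame(
            {"regional_sar": sar, "mean": 1.0, "pi_low": 1.0, "pi_high": 1.0}
        )
        pos = sar > 0
        if pos.any():
            X = sm.add_constant(np.log10(sar[pos]), has_constant="add")
            frame = self.result.get_prediction(X).summary_frame(alpha=alpha)
            out.loc[pos, "mean"] = _expit(frame["mean"].to_numpy())
            out.loc[pos, "pi_low"] = _expit(frame["obs_ci_lower"].to_numpy())
            out.loc[pos, "pi_high"] = _expit(frame["obs_ci_upper"].to_numpy())
        return out


def fit_sar_rbs(points: pd.DataFrame) -> SarRbsFit:
    """Fit the regional status vs regional SAR relationship.

    ``points`` needs columns ``regional_sar`` and ``mean_rbs``.  At least
    four regions with positive SAR are required; status values are clipped
    to [1e-4, 1 - 1e-4] before the logit (clip constant recorded in the fit
    metadata).
    """
    import statsmodels.api as sm

    for col in ("regional_sar", "mean_rbs"):
        if col not in points.columns:
            raise ValueError(f"region points missing column {col!r}")
    usable = points[points["regional_sar"] > 0]
    if len(usable) < 4:
        raise ValueError("need at least 4 regions with positive SAR")
    rbs = np.clip(
        usable["mean_rbs"].to_numpy(dtype=float), LOGIT_CLIP, 1.0 - LOGIT_CLIP
    )
    y = _logit(rbs)
    X = sm.add_constant(np.log10(usable["regional_sar"].to_numpy(dtype=float)))
    fit = sm.OLS(y, X).fit()
    return SarRbsFit(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        result=fit,
        meta={
            "n_regions": int(len(usable)),
            "n_excluded_zero_sar": int(len(points) - len(usable)),
            "logit_clip": LOGIT_CLIP,
            "r_squared": float(fit.rsquared),
        },
    )


def fit_fmsy_rbs(
    stock_points: pd.DataFrame, regional_points: pd.DataFrame
) -> dict:
    """OLS fits of mean status on f/f_MSY for stocks and regional means.

    Both frames need columns ``f_over_fmsy`` and ``mean_rbs``.  Returns a
    dict with per-fit slope, intercept, R-squared and two-sided p-value of
    the slope.
    """
    import statsmodels.api as sm

    def one(points: pd.DataFrame, label: str) -> dict:
        if len(points) < 3:
            raise ValueError(f"need at least 3 points for the {label} fit")
        y = points["mean_rbs"].to_numpy(dtype=float)
        X = sm.add_constant(points["f_over_fmsy"].to_numpy(dtype=float))
        fit = sm.OLS(y, X).fit()
        return {
            "slope": float(fit.params[1]),
            "intercept": float(fit.params[0]),
            "r_squared": float(fit.rsquared),
            "p_value": float(fit.pvalues[1]),
            "n": int(len(points)),
        }

    return {
        "stocks": one(stock_points, "all-stocks"),
        "regions": one(regional_points, "regional-means"),
    }
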
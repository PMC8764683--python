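"""Depletion-rate estimation from experimental trawl-impact studies.

Stage 1 of the assessment pipeline.  Three linked analyses:

1. A linear mixed-effects model of log response ratios (lnRR) of community
   abundance against time since experimental trawling gives, per gear type,
   the immediate impact ``i`` (the intercept at time 0); depletion per pass
   is its back-transform ``d = 1 - exp(i)``.
2. A log-linear model of gear-component penetration depths (doors, sweeps,
   ground gear, whole gear) with sediment habitat as a factor gives
   component mean penetration depths, aggregated to whole-gear
   gear x habitat depths using component width proportions.
3. A regression of gear-mean depletion on log gear-mean penetration depth
   transfers depletion estimates to every gear x habitat combination via
   its penetration depth.

Uncertainty is propagated by Monte Carlo: 2,000 samples of the impact
intercepts and of the component penetration depths are drawn from their
fitted normal distributions, aggregated with the same weights as the means,
used to fit 2,000 depletion-vs-log(depth) regressions, and each regression
predicts depletion at that replicate's gear x habitat depth.  Quantiles of
the prediction distribution give approximate standard errors and 95%
confidence limits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GearType, HABITATS

__all__ = [
    "fit_impact_model",
    "PDModelFit",
    "fit_pd_model",
    "aggregate_whole_gear_pd",
    "sample_pd_uncertainty",
    "weighted_gear_mean_pd",
    "DlogPDRegression",
    "fit_d_vs_logpd",
    "mc_propagate_depletion",
]

PD_COMPONENTS = ("doors", "sweeps", "ground_gear", "whole_gear")


# ---------------------------------------------------------------------------
# 1. Impact model: lnRR vs time -> immediate impact i and depletion d per gear


def fit_impact_model(
    records: pd.DataFrame, n_samples: int = 2000, seed: int | None = None
) -> pd.DataFrame:
    """Per-gear immediate impact and depletion from impact-study records.

    Model: lnRR ~ gear-specific intercept + gear-specific slope on
    log10(days_after + 1), with a random intercept per study.  The gear
    intercept is the immediate log-scale impact ``i``; depletion is
    ``d = 1 - exp(i)``.  Natural-scale SE and 95% CLs of d are obtained by
    sampling the intercept's normal distribution and back-transforming.

    Returns a DataFrame indexed by gear with columns
    ``i, i_se, d, d_se, d_lcl, d_ucl, n_records, n_studies``.
    """
    import statsmodels.formula.api as smf

    required = {"study_id", "gear", "days_after", "lnRR"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"impact records missing columns: {sorted(missing)}")
    data = records.copy()
    data["gear"] = data["gear"].map(lambda g: GearType(g).value)
    for gear, grp in data.groupby("gear"):
        if grp["study_id"].nunique() < 2:
            raise ValueError(
                f"singular fit: gear {gear!r} has fewer than 2 studies"
            )
        if grp["days_after"].min() > 30:
            raise ValueError(
                f"gear {gear!r} has no record near time 0 (min days_after "
                f"{grp['days_after'].min():g}); intercept not identifiable"
            )
    data["log_t"] = np.log10(data["days_after"].astype(float) + 1.0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "lnRR ~ 0 + C(gear) + C(gear):log_t", data, groups=data["study_id"]
        )
        result = model.fit(reml=True)

    rng = np.random.default_rng(seed)
    rows = {}
    for gear, grp in data.groupby("gear"):
        name = f"C(gear)[{gear}]"
        i = float(result.fe_params[name])
        i_se = float(result.bse_fe[name])
        if not math.isfinite(i_se):
            i_se = 0.0
        d = 1.0 - math.exp(i)
        if i > 0:
            warnings.warn(
                f"gear {gear!r}: positive impact intercept {i:.4f} implies "
                "negative depletion; truncating d at 0",
                UserWarning,
            )
            d = 0.0
        samples = 1.0 - np.exp(rng.normal(i, i_se, size=n_samples))
        rows[gear] = {
            "i": i,
            "i_se": i_se,
            "d": d,
            "d_se": float(np.std(samples, ddof=1)),
            "d_lcl": float(np.quantile(samples, 0.025)),
            "d_ucl": float(np.quantile(samples, 0.975)),
            "n_records": int(len(grp)),
            "n_studies": int(grp["study_id"].nunique()),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gear"
    return out


# ---------------------------------------------------------------------------
# 2. Penetration-depth model and whole-gear aggregation


@dataclass
class PDModelFit:
    """Fitted log-linear penetration-depth model.

    ``table`` has one row per estimable gear x component x habitat cell with
    the fitted mean of log(PD), its SE (NaN when the model has no residual
    degrees of freedom) and the back-transformed mean in cm.  ``width_props``
    maps (gear, component) to the proportion of total gear width.
    """

    table: pd.DataFrame
    width_props: dict[tuple[str, str], float]
    meta: dict = field(default_factory=dict)


def fit_pd_model(records: pd.DataFrame) -> PDModelFit:
    """Fit log(PD) ~ gear-component factor + habitat factor (additive).

    Records carry per-record component width proportions; the fit returns
    cell means for every combination of an observed gear-component with an
    observed habitat.  A combination whose gear-component was never observed
    is not estimable and is absent from the result.
    """
    import statsmodels.formula.api as smf

    required = {"study_id", "gear", "component", "habitat", "pd_cm", "width_prop"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"pd records missing columns: {sorted(missing)}")
    if (records["pd_cm"] <= 0).any():
        raise ValueError("penetration depths must be positive")
    bad = set(records["component"]) - set(PD_COMPONENTS)
    if bad:
        raise ValueError(f"unknown gear components: {sorted(bad)}")
    data = records.copy()
    data["gear"] = data["gear"].map(lambda g: GearType(g).value)
    data["gc"] = data["gear"] + ":" + data["component"]
    data["log_pd"] = np.log(data["pd_cm"].astype(float))

    habitats_seen = [h for h in HABITATS if h in set(data["habitat"])]
    if not habitats_seen:
        raise ValueError("no recognised habitat levels in pd records")

    single_habitat = len(habitats_seen) == 1
    formula = "log_pd ~ 0 + C(gc)" + ("" if single_habitat else " + C(habitat)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.ols(formula, data).fit()

    # width proportions: mean of per-record values (allows record-level
    # overrides of published widths)
    width_props = (
        data.groupby(["gear", "component"])["width_prop"].mean().to_dict()
    )

    rows = []
    gcs = sorted(set(data["gc"]))
    for gc in gcs:
        gear, component = gc.split(":", 1)
        for habitat in habitats_seen:
            newdata = pd.DataFrame({"gc": [gc], "habitat": [habitat]})
            with warnings.catch_warnings():
                # zero residual df (single record) yields NaN variances,
                # which are flagged below rather than warned about
                warnings.simplefilter("ignore", RuntimeWarning)
                pred = fit.get_prediction(newdata)
            log_mean = float(pred.predicted_mean[0])
            log_se = float(np.sqrt(pred.var_pred_mean[0]))
            if fit.df_resid <= 0 or not math.isfinite(log_se):
                log_se = float("nan")  # flagged: no residual df
            rows.append(
                {
                    "gear": gear,
                    "component": component,
                    "habitat": habitat,
                    "log_mean": log_mean,
                    "log_se": log_se,
                    "pd_cm": math.exp(log_mean),
                }
            )
    table = pd.DataFrame(rows)
    return PDModelFit(
        table=table,
        width_props={k: float(v) for k, v in width_props.items()},
        meta={
            "n_records": int(len(data)),
            "n_studies": int(data["study_id"].nunique()),
            "habitats": habitats_seen,
            "df_resid": float(fit.df_resid),
        },
    )


def aggregate_whole_gear_pd(
    component_pds: pd.DataFrame,
    width_props: dict[tuple[str, str], float],
) -> pd.DataFrame:
    """Whole-gear penetration depth per gear x habitat.

    ``PD_gear = sum_component width_prop * PD_component``; width proportions
    per gear may sum to less than 1 (the remaining width does not penetrate
    and contributes zero).  A 'whole_gear' component is a direct measurement
    of the full gear and enters with its own width proportion.
    """
    _check_width_props(width_props)
    df = component_pds.copy()
    df["w"] = [
        width_props[(g, c)] for g, c in zip(df["gear"], df["component"])
    ]
    df["wpd"] = df["w"] * df["pd_cm"]
    out = df.groupby(["gear", "habitat"])["wpd"].sum().rename("pd_cm").reset_index()
    if (out["pd_cm"] <= 0).any():
        warnings.warn(
            "aggregated whole-gear penetration depth is zero for some "
            "gear/habitat; below positivity bound",
            UserWarning,
        )
    return out.set_index(["gear", "habitat"])


def _check_width_props(width_props: dict[tuple[str, str], float]) -> None:
    by_gear: dict[str, float] = {}
    for (gear, _), w in width_props.items():
        if w < 0:
            raise ValueError("width proportions must be non-negative")
        by_gear[gear] = by_gear.get(gear, 0.0) + w
    for gear, total in by_gear.items():
        if total > 1.0 + 1e-9:
            raise ValueError(
                f"width proportions for gear {gear!r} sum to {total:.6f} > 1"
            )


def sample_pd_uncertainty(
    pd_fit: PDModelFit,
    n_samples: int = 2000,
    seed: int | None = None,
) -> tuple[dict[tuple[str, str], np.ndarray], pd.DataFrame]:
    """Monte Carlo whole-gear penetration-depth uncertainty.

    Draws ``n_samples`` from the normal distribution of each component's
    log-scale mean (SD = its SE), back-transforms, and aggregates to
    whole-gear gear x habitat depths with the same width weighting as the
    means.  Returns the per-(gear, habitat) sample arrays and a summary
    DataFrame with ``pd_cm`` (point estimate), ``pd_se`` (sample SD) and
    ``pd_lcl``/``pd_ucl`` (2.5/97.5% quantiles).
    """
    rng = np.random.default_rng(seed)
    tbl = pd_fit.table
    samples: dict[tuple[str, str], np.ndarray] = {}
    # one normal draw stream per component cell, aggregated per gear x habitat
    for (gear, habitat), grp in tbl.groupby(["gear", "habitat"]):
        agg = np.zeros(n_samples)
        for _, row in grp.iterrows():
            se = row["log_se"]
            if not math.isfinite(se):
                se = 0.0
            draws = np.exp(rng.normal(row["log_mean"], se, size=n_samples))
            agg += pd_fit.width_props[(gear, row["component"])] * draws
        samples[(gear, habitat)] = agg
    point = aggregate_whole_gear_pd(tbl, pd_fit.width_props)
    rows = []
    for (gear, habitat), arr in samples.items():
        rows.append(
            {
                "gear": gear,
                "habitat": habitat,
                "pd_cm": float(point.loc[(gear, habitat), "pd_cm"]),
                "pd_se": float(np.std(arr, ddof=1)),
                "pd_lcl": float(np.quantile(arr, 0.025)),
                "pd_ucl": float(np.quantile(arr, 0.975)),
            }
        )
    summary = pd.DataFrame(rows).set_index(["gear", "habitat"])
    return samples, summary


def weighted_gear_mean_pd(
    gearhab_pd: pd.DataFrame, freqs: pd.DataFrame
) -> pd.Series:
    """Gear-mean penetration depth weighted by habitat study frequencies.

    ``gearhab_pd`` is indexed by (gear, habitat) with column ``pd_cm``;
    ``freqs`` is indexed by gear with one column per habitat holding the
    number of experimental studies in that habitat.  The weighting makes
    the gear-mean depth comparable with the gear-mean depletion estimated
    from the same mixture of habitats.
    """
    out = {}
    for gear in gearhab_pd.index.get_level_values("gear").unique():
        if gear not in freqs.index:
            raise ValueError(f"no habitat study frequencies for gear {gear!r}")
        w = freqs.loc[gear]
        total = float(sum(w.get(h, 0.0) for h in HABITATS))
        if total <= 0:
            raise ValueError(f"all habitat frequencies zero for gear {gear!r}")
        acc = 0.0
        for h in HABITATS:
            wh = float(w.get(h, 0.0))
            if wh > 0:
                acc += wh * float(gearhab_pd.loc[(gear, h), "pd_cm"])
        out[gear] = acc / total
    return pd.Series(out, name="pd_cm")


# ---------------------------------------------------------------------------
# 3. Depletion vs log(penetration depth) regression and MC propagation


@dataclass
class DlogPDRegression:
    """OLS of gear-mean depletion on natural-log gear-mean penetration depth."""

    intercept: float
    slope: float
    r_squared: float
    result: object = None

    def predict(self, pd_cm: float | np.ndarray) -> np.ndarray:
        """Predicted depletion at penetration depth(s), clipped to [0, 0.999]."""
        pd_cm = np.asarray(pd_cm, dtype=float)
        if np.any(pd_cm <= 0):
            raise ValueError("penetration depth must be positive")
        pred = self.intercept + self.slope * np.log(pd_cm)
        return np.clip(pred, 0.0, 0.999)

    def prediction_interval(
        self, pd_cm: float | np.ndarray, alpha: float = 0.05
    ) -> pd.DataFrame:
        """Mean prediction with OLS prediction interval (unclipped)."""
        import statsmodels.api as sm

        x = np.log(np.atleast_1d(np.asarray(pd_cm, dtype=float)))
        X = sm.add_constant(x, has_constant="add")
        pred = self.result.get_prediction(X)
        frame = pred.summary_frame(alpha=alpha)
        frame.index = np.atleast_1d(pd_cm)
        return frame


def fit_d_vs_logpd(
    gear_mean_d: pd.Series, gear_mean_pd: pd.Series, weights: pd.Series | None = None
) -> DlogPDRegression:
    """Regression of gear-mean depletion on log gear-mean penetration depth.

    Unweighted by default; pass ``weights`` (e.g. inverse-variance) for a
    WLS sensitivity fit.
    """
    import statsmodels.api as sm

    gears = [g for g in gear_mean_d.index if g in gear_mean_pd.index]
    if len(gears) < 3:
        raise ValueError("need at least 3 gear means to fit the regression")
    y = gear_mean_d.loc[gears].to_numpy(dtype=float)
    pdv = gear_mean_pd.loc[gears].to_numpy(dtype=float)
    if np.any(pdv <= 0):
        raise ValueError("gear-mean penetration depths must be positive")
    X = sm.add_constant(np.log(pdv))
    if weights is not None:
        fit = sm.WLS(y, X, weights=weights.loc[gears].to_numpy(dtype=float)).fit()
    else:
        fit = sm.OLS(y, X).fit()
    return DlogPDRegression(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        r_squared=float(fit.rsquared),
        result=fit,
    )


def mc_propagate_depletion(
    impact: pd.DataFrame,
    pd_samples: dict[tuple[str, str], np.ndarray],
    freqs: pd.DataFrame,
    n_samples: int = 2000,
    seed: int | None = None,
    max_failure_rate: float = 0.01,
) -> pd.DataFrame:
    """Monte Carlo propagation of depletion uncertainty to gear x habitat.

    Per replicate: sample each gear's impact intercept, back-transform to
    depletion; sample each gear's mean penetration depth by drawing a
    habitat in proportion to the study frequencies and taking that
    habitat's sampled depth; fit the depletion-vs-log(depth) regression
    across gears; predict depletion at the replicate's sampled
    gear x habitat depths.  Summaries over replicates give ``d_se`` (SD)
    and ``d_lcl``/``d_ucl`` (2.5/97.5% quantiles) per gear x habitat.

    Replicates with a degenerate regression (zero spread in log depth) are
    dropped and counted; more than ``max_failure_rate`` failures aborts.
    """
    rng = np.random.default_rng(seed)
    gears = list(impact.index)
    if len(gears) < 3:
        raise ValueError("need at least 3 gears for the propagation")
    habitats_by_gear = {
        g: [h for h in HABITATS if (g, h) in pd_samples] for g in gears
    }
    for g, hs in habitats_by_gear.items():
        if not hs:
            raise ValueError(f"no penetration-depth samples for gear {g!r}")
        n_avail = len(next(iter(pd_samples.values())))
        if n_avail < n_samples:
            raise ValueError(
                f"pd sample arrays hold {n_avail} draws < n_samples={n_samples}"
            )

    # sampled gear-mean d: back-transformed normal draws of the intercept
    d_mat = np.empty((n_samples, len(gears)))
    for j, g in enumerate(gears):
        draws = rng.normal(impact.loc[g, "i"], impact.loc[g, "i_se"], n_samples)
        d_mat[:, j] = 1.0 - np.exp(draws)

    # sampled gear-mean PD: habitat chosen per replicate by study frequency
    pd_mean_mat = np.empty((n_samples, len(gears)))
    for j, g in enumerate(gears):
        hs = habitats_by_gear[g]
        w = np.array([float(freqs.loc[g].get(h, 0.0)) for h in hs])
        if w.sum() <= 0:
            raise ValueError(f"all habitat frequencies zero for gear {g!r}")
        choice = rng.choice(len(hs), size=n_samples, p=w / w.sum())
        stacked = np.stack([pd_samples[(g, h)][:n_samples] for h in hs], axis=1)
        pd_mean_mat[:, j] = stacked[np.arange(n_samples), choice]

    x = np.log(pd_mean_mat)  # (n, G)
    y = d_mat
    xbar = x.mean(axis=1, keepdims=True)
    ybar = y.mean(axis=1, keepdims=True)
    sxx = ((x - xbar) ** 2).sum(axis=1)
    sxy = ((x - xbar) * (y - ybar)).sum(axis=1)
    ok = sxx > 1e-12
    n_failed = int((~ok).sum())
    if n_failed > max_failure_rate * n_samples:
        raise RuntimeError(
            f"{n_failed}/{n_samples} Monte Carlo regressions degenerate"
        )
    slope = np.where(ok, sxy / np.where(ok, sxx, 1.0), np.nan)
    intercept = ybar[:, 0] - slope * xbar[:, 0]

    rows = []
    for g in gears:
        for h in habitats_by_gear[g]:
            target = np.log(pd_samples[(g, h)][:n_samples])
            pred = np.clip(intercept + slope * target, 0.0, 0.999)[ok]
            rows.append(
                {
                    "gear": g,
                    "habitat": h,
                    "d_se": float(np.std(pred, ddof=1)),
                    "d_lcl": float(np.quantile(pred, 0.025)),
                    "d_ucl": float(np.quantile(pred, 0.975)),
                    "n_effective": int(ok.sum()),
                    "n_failed": n_failed,
                }
            )
    return pd.DataFrame(rows).set_index(["gear", "habitat"])
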
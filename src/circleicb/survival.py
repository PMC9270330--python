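"""Survival stratification of classifier calls.

Kaplan–Meier curves, the two-group log-rank test, and Cox proportional
hazards with covariates (Efron tie handling), backed by lifelines.  The ICB
validation use case stratifies overall survival by CIRCLE responder /
non-responder status with tumor type as the Cox covariate; both the
dichotomized classification and the continuous score can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .association import build_logistic_design


@dataclass
class KmCurve:
    """Product-limit survival estimate: step values at distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


def kaplan_meier(time, event, ci: float = 0.95) -> KmCurve:
    """Kaplan–Meier estimator over the distinct event times.

    ``time`` must be positive; ``event`` is True for an observed death and
    False for right censoring.  CI bands use the log(-log) transform.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if np.any(time <= 0) or not np.all(np.isfinite(time)):
        raise ValueError("survival times must be finite and positive")
    km = KaplanMeierFitter(alpha=1 - ci)
    km.fit(time, event_observed=event)
    table = km.event_table
    event_times = table.index[table["observed"] > 0].to_numpy(dtype=float)
    surv = km.survival_function_at_times(event_times).to_numpy()
    at_risk = table.loc[table["observed"] > 0, "at_risk"].to_numpy(dtype=int)
    ci_df = km.confidence_interval_survival_function_
    lo = np.interp(event_times, ci_df.index.to_numpy(), ci_df.iloc[:, 0].to_numpy())
    hi = np.interp(event_times, ci_df.index.to_numpy(), ci_df.iloc[:, 1].to_numpy())
    return KmCurve(times=event_times, survival=surv, at_risk=at_risk,
                   ci_low=lo, ci_high=hi)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(levels)}")
    if event.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    a = group == levels[0]
    res = _ll_logrank(time[a], time[~a], event_observed_A=event[a],
                      event_observed_B=event[~a])
    return float(res.test_statistic), float(res.p_value)


def cox_ph(
    data: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    categorical: tuple[str, ...] = ("tumor_type",),
) -> pd.DataFrame:
    """Cox proportional-hazards fit with Efron tie handling.

    Every column of ``data`` other than time/event enters the model;
    columns named in ``categorical`` are reference-coded against their most
    frequent level.  Returns a per-covariate table with coefficient,
    HR = e^coef, its 95% CI and the two-sided Wald p.  A monotone likelihood
    (perfectly separating covariate) is reported as an infinite-HR sentinel
    row rather than raised.
    """
    if data[event_col].sum() == 0:
        raise ValueError("Cox regression needs at least one event")
    design = pd.DataFrame({
        "time": data[duration_col].astype(float),
        "event": data[event_col].astype(bool).astype(int),
    }, index=data.index)
    covariate_cols = [c for c in data.columns if c not in (duration_col, event_col)]
    encoded = build_logistic_design(data[covariate_cols], categorical=categorical)
    design = pd.concat([design, encoded], axis=1)

    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col="time", event_col="event")
    except Exception as err:  # monotone likelihood / collinearity
        return pd.DataFrame({
            "coef": np.nan, "hr": np.inf, "ci_low": np.nan,
            "ci_high": np.nan, "p": np.nan,
            "note": f"fit failed: {type(err).__name__}",
        }, index=pd.Index(encoded.columns, name="covariate"))

    summary = cph.summary
    return pd.DataFrame({
        "coef": summary["coef"],
        "hr": summary["exp(coef)"],
        "ci_low": summary["exp(coef) lower 95%"],
        "ci_high": summary["exp(coef) upper 95%"],
        "p": summary["p"],
    }).rename_axis("covariate")
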
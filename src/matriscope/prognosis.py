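"""Prognostic value of landmark genes within their subtypes.

For each (subtype, landmark gene), patients are split at the subtype mean
expression (boundary values go to the high group), the split is tested
with the two-group log-rank test, and a Cox proportional-hazards model on
{split, age} asks whether the effect holds with age as covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _lifelines_logrank


def stratify_by_mean(values) -> np.ndarray | None:
    """High/low split at the mean; value exactly at the mean is high.

    Returns None (gene skipped) when either group ends with < 2 samples.
    """
    v = np.asarray(values, float)
    high = v >= v.mean()
    if high.sum() < 2 or (~high).sum() < 2:
        return None
    return high


def logrank_test(groups, time, event) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value."""
    groups = np.asarray(groups).astype(bool)
    time = np.asarray(time, float)
    event = np.asarray(event).astype(int)
    if event[groups].sum() < 1 or event[~groups].sum() < 1:
        raise ValueError("both groups need at least one event")
    res = _lifelines_logrank(
        time[groups], time[~groups], event[groups], event[~groups]
    )
    return float(res.test_statistic), float(res.p_value)


def cox_age_adjusted(
    groups, time, event, age
) -> tuple[float, float, float]:
    """Cox PH fit (Efron ties) of {group, age}: (HR_group, p_group, beta_age).

    Collinear covariates produce a convergence warning, not a crash."""
    df = pd.DataFrame(
        {
            "time": np.asarray(time, float),
            "event": np.asarray(event).astype(int),
            "group": np.asarray(groups).astype(float),
            "age": np.asarray(age, float),
        }
    )
    if df["age"].std() == 0:
        raise ValueError("age is constant; cannot adjust for it")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # collinear / ill-conditioned design
        warnings.warn(
            f"Cox fit ill-conditioned ({exc}); refitting with a small ridge "
            "penalty"
        )
        cph = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["group"]))
    p = float(cph.summary.loc["group", "p"])
    beta_age = float(cph.params_["age"])
    return hr, p, beta_age


@dataclass
class PrognosticResult:
    subtype: str
    gene: str
    n_high: int
    n_low: int
    logrank_stat: float
    logrank_p: float
    cox_hr: float
    cox_p: float
    direction: str  # "unfavorable" (high expression = worse) or "favorable"
    prognostic: bool
    age_independent: bool


def prognostic_scan(
    landmarks: dict[str, set[str]],
    expression: pd.DataFrame,
    survival: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One row per eligible (subtype, landmark gene).

    ``survival`` is indexed by sample with columns subtype, time, event,
    age.  A gene is prognostic when the log-rank p < alpha; it is
    additionally age independent when the Cox group term stays below
    alpha with age in the model.
    """
    rows = []
    for subtype in sorted(landmarks):
        samples = survival.index[survival["subtype"] == subtype]
        if len(samples) == 0:
            continue
        sub = survival.loc[samples]
        if sub["event"].sum() < 2:
            continue
        for gene in sorted(landmarks[subtype]):
            if gene not in expression.index:
                continue
            v = expression.loc[gene, samples].to_numpy(float)
            high = stratify_by_mean(v)
            if high is None:
                continue
            t = sub["time"].to_numpy(float)
            e = sub["event"].to_numpy(int)
            if e[high].sum() < 1 or e[~high].sum() < 1:
                continue
            stat, p = logrank_test(high, t, e)
            try:
                hr, cox_p, _ = cox_age_adjusted(
                    high, t, e, sub["age"].to_numpy(float)
                )
            except Exception:
                continue
            rows.append(
                PrognosticResult(
                    subtype=subtype,
                    gene=gene,
                    n_high=int(high.sum()),
                    n_low=int((~high).sum()),
                    logrank_stat=stat,
                    logrank_p=p,
                    cox_hr=hr,
                    cox_p=cox_p,
                    direction="unfavorable" if hr > 1 else "favorable",
                    prognostic=bool(p < alpha),
                    age_independent=bool(p < alpha and cox_p < alpha),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
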
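"""Survival endpoints and risk-model comparison.

Kaplan-Meier/log-rank and Cox proportional hazards go through lifelines
(Efron tie handling).  Time-dependent discrimination is the IPCW
cumulative-case / dynamic-control AUC(t), weighting cases by the inverse
censoring-distribution KM evaluated just before the event time (Uno-style).
Model comparison uses the continuous net reclassification improvement with
KM-based handling of censoring before the horizon.

Records of patients who died of causes unrelated to the cancer are excluded
before any estimator runs (`records_from_clinical`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import fisher_exact as _fisher_exact
from scipy.stats import kruskal as _kruskal

__all__ = [
    "records_from_clinical",
    "km_logrank",
    "cox_fit",
    "time_dependent_auc",
    "nri_compare",
    "fisher_exact",
    "kruskal_wallis",
]

DAYS_PER_YEAR = 365.25


def records_from_clinical(clin: pd.DataFrame, extra: pd.DataFrame | None = None) -> pd.DataFrame:
    """Survival records: joins covariates, applies the exclusion rules.

    Drops records with ``death_unrelated == 1`` and requires time > 0
    (zero-day follow-ups are excluded).  ``extra`` (indexed by sample_id) adds
    columns such as subtype labels or risk scores; samples missing from
    ``extra`` are dropped.
    """
    df = clin.copy()
    if df.index.name != "sample_id":
        df = df.set_index("sample_id", drop=False)
    df = df[df["death_unrelated"] == 0]
    df = df[df["os_days"] > 0]
    rec = df[["os_days", "event", "age", "sex", "site", "stage_group"]].copy()
    rec = rec.rename(columns={"os_days": "time"})
    if extra is not None:
        rec = rec.join(extra, how="inner")
    return rec


def km_logrank(records: pd.DataFrame, group_col: str) -> dict:
    """Per-group KM medians plus the log-rank test.

    Median = first time the KM curve drops to <= 0.5 (NaN if never reached).
    """
    groups = sorted(records[group_col].dropna().unique())
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    medians = {}
    curves = {}
    for g in groups:
        sub = records[records[group_col] == g]
        if sub.empty:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        medians[g] = float(kmf.median_survival_time_)
        curves[g] = kmf.survival_function_
    res = multivariate_logrank_test(records["time"], records[group_col], records["event"])
    return {
        "groups": groups,
        "medians": medians,
        "chi2": float(res.test_statistic),
        "p": float(res.p_value),
        "curves": curves,
    }


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    references: dict[str, str] | None = None,
    ties: str = "efron",
) -> pd.DataFrame:
    """Cox proportional-hazards fit; returns a forest-plot-ready table.

    Categorical covariates expand to dummies against the stated reference
    level (default: lexicographically first).  Output columns: term, hr,
    ci_low, ci_high, p; ``attrs['log_likelihood']`` carries the model LL.
    """
    references = references or {}
    design = pd.DataFrame(index=records.index)
    for cov in covariates:
        col = records[cov]
        if col.nunique(dropna=True) < 2:
            raise ValueError(f"covariate {cov!r} is constant")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique())
            ref = references.get(cov, levels[0])
            if ref not in levels:
                raise ValueError(f"reference {ref!r} not a level of {cov!r}")
            for lev in levels:
                if lev != ref:
                    design[f"{cov}[{lev}]"] = (col == lev).astype(float)
        else:
            design[cov] = col.astype(float)
    df = design.assign(time=records["time"], event=records["event"]).dropna()
    n_events = int(df["event"].sum())
    if n_events < design.shape[1]:
        raise ValueError(f"{n_events} events for {design.shape[1]} parameters")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summ = cph.summary
    out = pd.DataFrame(
        {
            "term": summ.index,
            "hr": summ["exp(coef)"].values,
            "ci_low": summ["exp(coef) lower 95%"].values,
            "ci_high": summ["exp(coef) upper 95%"].values,
            "p": summ["p"].values,
        }
    ).reset_index(drop=True)
    out.attrs["log_likelihood"] = float(cph.log_likelihood_)
    out.attrs["linear_predictor"] = cph.predict_partial_hazard(df).apply(np.log)
    return out


def _censor_km(time: np.ndarray, event: np.ndarray):
    """KM of the censoring distribution; returns a step-function evaluator G(t)."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, 1 - event)
    times = kmf.survival_function_.index.values
    surv = kmf.survival_function_.iloc[:, 0].values

    def G(t: np.ndarray, left: bool = False) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if left:
            idx = np.searchsorted(times, t, side="left") - 1
        else:
            idx = np.searchsorted(times, t, side="right") - 1
        return np.where(idx < 0, 1.0, surv[np.clip(idx, 0, len(surv) - 1)])

    return G


def time_dependent_auc(
    records: pd.DataFrame,
    risk: pd.Series,
    horizons,
) -> dict[float, float]:
    """IPCW cumulative/dynamic AUC(t) at each horizon (same units as time).

    Cases at t: events with time <= t, weighted 1/G(time-); controls: time > t.
    Risk ties count 1/2.  Horizons with no prior events or no controls give
    NaN.
    """
    rec = records.join(risk.rename("_risk"), how="inner")
    time = rec["time"].values.astype(float)
    event = rec["event"].values.astype(int)
    score = rec["_risk"].values.astype(float)
    G = _censor_km(time, event)
    out: dict[float, float] = {}
    for t in horizons:
        cases = (time <= t) & (event == 1)
        controls = time > t
        if not cases.any() or not controls.any():
            out[float(t)] = float("nan")
            continue
        w = np.zeros(len(time))
        gv = G(time[cases], left=True)
        w[cases] = np.where(gv > 0, 1.0 / gv, 0.0)
        sc, scw = score[cases], w[cases]
        sn = score[controls]
        conc = (sc[:, None] > sn[None, :]).astype(float) + 0.5 * (sc[:, None] == sn[None, :])
        num = (scw[:, None] * conc).sum()
        den = scw.sum() * len(sn)
        out[float(t)] = float(num / den) if den > 0 else float("nan")
    return out


def nri_compare(
    records: pd.DataFrame,
    standard_risk: pd.Series,
    new_risk: pd.Series,
    horizon: float,
) -> dict:
    """Continuous NRI of a new risk model against a standard one.

    Movement up/down = new risk above/below standard.  Event probabilities at
    the horizon within the up/down groups come from KM curves, which handles
    censoring before the horizon; with no censoring this reduces to plain
    counting.  Total NRI = event NRI + non-event NRI; swapping the models
    negates it.
    """
    rec = records.join(standard_risk.rename("_std"), how="inner").join(
        new_risk.rename("_new"), how="inner"
    )
    if horizon > rec["time"].max():
        raise ValueError("horizon beyond last follow-up")
    time = rec["time"].values.astype(float)
    event = rec["event"].values.astype(int)
    up = rec["_new"].values > rec["_std"].values
    down = rec["_new"].values < rec["_std"].values

    def p_event(mask: np.ndarray) -> float:
        if not mask.any():
            return 0.0
        kmf = KaplanMeierFitter().fit(time[mask], event[mask])
        return float(1.0 - kmf.predict(horizon))

    pe = p_event(np.ones(len(time), dtype=bool))
    if pe in (0.0, 1.0):
        raise ValueError("horizon has no events or no survivors")
    p_up, p_down = up.mean(), down.mean()
    pe_up, pe_down = p_event(up), p_event(down)
    nri_event = (p_up * pe_up - p_down * pe_down) / pe
    nri_nonevent = (p_down * (1 - pe_down) - p_up * (1 - pe_up)) / (1 - pe)
    return {
        "nri": float(nri_event + nri_nonevent),
        "nri_event": float(nri_event),
        "nri_nonevent": float(nri_nonevent),
        "horizon": float(horizon),
        "p_up": float(p_up),
        "p_down": float(p_down),
    }


def fisher_exact(table) -> dict:
    """Two-sided Fisher exact test on a 2x2 contingency table."""
    odds, p = _fisher_exact(np.asarray(table))
    return {"odds_ratio": float(odds), "p": float(p)}


def kruskal_wallis(values, groups) -> dict:
    """Kruskal-Wallis rank-sum test of a continuous variable across groups."""
    values = np.asarray(values)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    stat, p = _kruskal(*samples)
    return {"statistic": float(stat), "p": float(p)}
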
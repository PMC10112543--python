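"""Age-at-onset analysis of the polygenic score by quintile.

Cases contribute their age at onset as an event time (age at analysis
when onset is unrecorded); controls contribute right-censored
observations at their age at analysis — a prevalent-cohort
simplification. Subjects with onset at or before age 18 are excluded
(adult-onset disease). Kaplan-Meier curves are stratified by PRS
quintile; Cox proportional-hazards fits use quintile indicators with
the lowest quintile as reference and Efron handling of tied times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

from .evaluate import _align, assign_quintiles
from .prs import PRSVector

logger = logging.getLogger(__name__)

ADULT_ONSET_MIN = 18.0


@dataclass
class QuintileHazard:
    quintile: int
    hazard_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float


def build_survival(
    cohort: pd.DataFrame,
    prs: PRSVector,
    quintiles: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble (time, event, quintile) survival records.

    Cases use age at onset when available, else age at analysis; the
    event indicator is the case status. Controls are censored at age at
    analysis. Onsets <= 18 are excluded. ``quintiles`` overrides the
    default assignment from the PRS empirical distribution.
    """
    df = _align(prs, cohort).copy()
    if quintiles is not None:
        df["quintile"] = np.asarray(quintiles)
    else:
        df["quintile"] = assign_quintiles(df["prs"].to_numpy(dtype=float))
    onset = df["age_at_onset"] if "age_at_onset" in df.columns else pd.Series(np.nan, index=df.index)
    time = np.where((df["status"] == 1) & onset.notna(), onset, df["age"])
    df["time"] = time
    df["event"] = df["status"].astype(int)
    n0 = len(df)
    df = df[df["time"].notna()]
    dropped_missing = n0 - len(df)
    if dropped_missing:
        logger.warning("%d subjects dropped: no usable age/onset", dropped_missing)
    juvenile = (df["event"] == 1) & (df["time"] <= ADULT_ONSET_MIN)
    if juvenile.any():
        logger.info("excluding %d subjects with onset <= %g", int(juvenile.sum()), ADULT_ONSET_MIN)
    df = df[~juvenile]
    return df.reset_index(drop=True)


def km_estimate(records: pd.DataFrame, strata: str = "quintile") -> pd.DataFrame:
    """Product-limit survival per stratum.

    Returns a long table (stratum, time, n_risk, n_event, survival);
    empty strata are omitted with a warning.
    """
    if records["event"].sum() == 0:
        logger.warning("no events in input; survival is identically 1")
    frames = []
    for label, grp in records.groupby(strata, sort=True):
        if len(grp) == 0:
            logger.warning("stratum %s empty; omitted", label)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], event_observed=grp["event"])
        ev = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        frames.append(
            pd.DataFrame(
                {
                    "stratum": label,
                    "time": ev.index.to_numpy(),
                    "n_risk": ev["at_risk"].to_numpy(),
                    "n_event": ev["observed"].to_numpy(),
                    "survival": surv.reindex(ev.index).to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["stratum", "time", "n_risk", "n_event", "survival"]
    )


def cox_quintile(
    records: pd.DataFrame,
    covariates: list[str] | None = None,
    cases_only: bool = False,
    level: float = 0.95,
) -> list[QuintileHazard]:
    """Cox PH fit with quintile indicators (reference = quintile 1).

    ``cases_only`` restricts to event = 1 subjects, in which case every
    observation is an event (onset-age analysis among the diagnosed).
    Ties are handled by the Efron approximation.
    """
    covariates = covariates or []
    df = records.copy()
    if cases_only:
        df = df[df["event"] == 1].copy()
    used = df["quintile"].unique()
    if (df.groupby("quintile")["event"].sum() > 0).sum() < 2:
        raise ValueError("need events in at least two quintiles")
    cols = {"time": df["time"].to_numpy(dtype=float), "event": df["event"].to_numpy(dtype=int)}
    for k in range(2, 6):
        cols[f"q{k}"] = (df["quintile"] == k).astype(float).to_numpy()
    data = pd.DataFrame(cols)
    for c in covariates:
        if df[c].dtype == object or isinstance(df[c].dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(df[c], prefix=c, drop_first=True)
            for col in dummies.columns:
                data[col] = dummies[col].to_numpy(dtype=float)
        else:
            data[c] = df[c].to_numpy(dtype=float)
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col="time", event_col="event")
    except Exception as exc:
        raise ValueError(f"Cox fit failed (possibly monotone likelihood): {exc}") from exc
    from scipy.stats import norm

    zq = norm.isf((1.0 - level) / 2.0)
    out = [QuintileHazard(quintile=1, hazard_ratio=1.0, ci_low=1.0, ci_high=1.0, pvalue=1.0)]
    for k in range(2, 6):
        name = f"q{k}"
        if name not in cph.params_.index or k not in used:
            continue
        b = float(cph.params_[name])
        se = float(cph.standard_errors_[name])
        out.append(
            QuintileHazard(
                quintile=k,
                hazard_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - zq * se)),
                ci_high=float(np.exp(b + zq * se)),
                pvalue=float(cph.summary.loc[name, "p"]),
            )
        )
    return out
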
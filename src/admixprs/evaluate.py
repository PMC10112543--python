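"""Case-control evaluation statistics for polygenic scores.

Covers the reporting block of a PRS study: logistic association with
covariates, Nagelkerke pseudo-R² increments, the liability-scale
variance transformation for ascertained case-control samples, ROC/AUC
with DeLong confidence intervals and paired AUC comparison,
classification metrics at the Youden operating point, per-quintile odds
ratios, and the risk-allele frequency sign test between populations.

Liability-scale R² (case-control ascertainment correction)
----------------------------------------------------------
With population prevalence K, sample case fraction P, liability
threshold t = Phi^-1(1 - K) and normal ordinate z = phi(t):

    C     = K^2 (1-K)^2 / (z^2 P (1-P))
    theta = m (P-K)/(1-K) * (m (P-K)/(1-K) - t),   m = z / K
    R2_l  = C R2_o / (1 + C theta R2_o)

The theta term vanishes when P = K (no ascertainment), where the
transform reduces to R2_o * K(1-K) / z^2 * K(1-K)/(P(1-P)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .prs import PRSVector

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    """Logistic PRS association with pseudo-R² and optional liability R²."""

    beta: float
    se: float
    pvalue: float
    nagelkerke_r2: float
    n: int
    r2_observed: float
    liability_r2: float | None = None
    converged: bool = True


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    threshold: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    balanced_accuracy: float | None = None


@dataclass
class QuintileEffect:
    quintile: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_cases: int
    n_controls: int


def _align(prs: PRSVector, cohort: pd.DataFrame) -> pd.DataFrame:
    df = cohort.copy()
    lookup = pd.Series(prs.score, index=prs.sample_ids)
    df = df[df["sample_id"].isin(lookup.index)].copy()
    df["prs"] = lookup.loc[df["sample_id"]].to_numpy()
    return df


def nagelkerke_r2(ll_full: float, ll_reduced: float, n: int) -> float:
    """Nagelkerke pseudo-R² of a model against a reduced (baseline) model."""
    cox_snell = 1.0 - np.exp(-2.0 * (ll_full - ll_reduced) / n)
    max_r2 = 1.0 - np.exp(2.0 * ll_reduced / n)
    if max_r2 <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_r2, 0.0, 1.0))


def _fit_logit(y: np.ndarray, X: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        res = model.fit(disp=0, maxiter=200)
    return res


def _design(df: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for c in covariates:
        if df[c].dtype == object or isinstance(df[c].dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(df[c], prefix=c, drop_first=True)
            cols.extend(dummies[col].to_numpy(dtype=float) for col in dummies.columns)
        else:
            cols.append(df[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def logistic_assoc(
    prs: PRSVector,
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    prevalence_k: float | None = None,
) -> AssociationResult:
    """Maximum-likelihood logistic fit of status ~ PRS + covariates.

    The Nagelkerke pseudo-R² is the increment of the full model over the
    covariate-only model. The observed-scale R² feeding the liability
    transform is the squared point-biserial correlation between case
    status and the score (a linear-probability R²); when
    ``prevalence_k`` is supplied the Lee et al. ascertainment transform
    converts it to the liability scale.
    """
    covariates = covariates or []
    df = _align(prs, cohort).dropna(subset=["status", "prs"] + covariates)
    y = df["status"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both case and control classes required")
    X_cov = _design(df, covariates)
    X_full = np.column_stack([X_cov[:, :1], df["prs"].to_numpy(dtype=float), X_cov[:, 1:]])
    try:
        res_full = _fit_logit(y, X_full)
        res_cov = _fit_logit(y, X_cov)
        converged = bool(res_full.mle_retvals.get("converged", True))
    except Exception as exc:
        logger.warning("logistic fit failed: %s", exc)
        return AssociationResult(
            beta=np.nan, se=np.nan, pvalue=np.nan, nagelkerke_r2=np.nan,
            n=len(df), r2_observed=np.nan, converged=False,
        )
    n = len(df)
    nag = nagelkerke_r2(res_full.llf, res_cov.llf, n)
    prs_vals = df["prs"].to_numpy(dtype=float)
    if prs_vals.std() == 0:
        r2_obs = 0.0
    else:
        r2_obs = float(np.corrcoef(prs_vals, y)[0, 1] ** 2)
    liab = liability_r2(r2_obs, prevalence_k, float(y.mean())) if prevalence_k else None
    return AssociationResult(
        beta=float(res_full.params[1]),
        se=float(res_full.bse[1]),
        pvalue=float(res_full.pvalues[1]),
        nagelkerke_r2=nag,
        n=n,
        r2_observed=r2_obs,
        liability_r2=liab,
        converged=converged,
    )


def liability_r2(r2_observed: float, K: float, P: float) -> float:
    """Convert observed-scale R² to the liability scale (see module docs)."""
    if not 0.0 < K < 1.0 or not 0.0 < P < 1.0:
        raise ValueError("K and P must lie strictly inside (0, 1)")
    if not 0.0 <= r2_observed < 1.0:
        raise ValueError("r2_observed must lie in [0, 1)")
    t = sps.norm.isf(K)
    z = sps.norm.pdf(t)
    m = z / K
    c = K**2 * (1.0 - K) ** 2 / (z**2 * P * (1.0 - P))
    theta = m * (P - K) / (1.0 - K) * (m * (P - K) / (1.0 - K) - t)
    return float(c * r2_observed / (1.0 + c * theta * r2_observed))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the Mann-Whitney formulation: P(case > control) + P(tie)/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes required for AUC")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m < 2 or n < 2:
        raise ValueError("DeLong requires at least 2 samples per class")
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (all_ranks[:m] - pos_ranks) / n          # structural components, cases
    v10 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # structural components, controls
    return auc, v01, v10


def delong_ci(
    scores: np.ndarray, labels: np.ndarray, level: float = 0.95
) -> tuple[float, float, float]:
    """AUC with a DeLong normal-approximation CI truncated to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    auc, v01, v10 = _delong_components(scores, labels)
    var = v01.var(ddof=1) / v01.size + v10.var(ddof=1) / v10.size
    if var <= 0:
        logger.warning("degenerate DeLong variance (perfect separation); CI collapses")
        return float(auc), float(auc), float(auc)
    zq = sps.norm.isf((1.0 - level) / 2.0)
    half = zq * np.sqrt(var)
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def delong_paired_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> float:
    """Two-sided p-value for AUC_a = AUC_b on the same samples (paired DeLong)."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired scores must cover the same samples")
    auc_a, v01_a, v10_a = _delong_components(scores_a, labels)
    auc_b, v01_b, v10_b = _delong_components(scores_b, labels)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    var = (
        s01[0, 0] / v01_a.size + s10[0, 0] / v10_a.size
        + s01[1, 1] / v01_a.size + s10[1, 1] / v10_a.size
        - 2 * (s01[0, 1] / v01_a.size + s10[0, 1] / v10_a.size)
    )
    diff = auc_a - auc_b
    if var <= 0:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def confusion_metrics(scores: np.ndarray, labels: np.ndarray, level: float = 0.95) -> ROCResult:
    """Classification metrics at the Youden's J optimal operating point.

    The threshold maximizing sensitivity + specificity − 1 on the
    empirical ROC is chosen (ties: the highest such threshold, i.e. the
    most specific operating point).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos_n = int((labels == 1).sum())
    neg_n = int((labels == 0).sum())
    if pos_n == 0 or neg_n == 0:
        raise ValueError("both classes required")
    thresholds = np.unique(scores)[::-1]
    best = None
    for t in thresholds:
        pred = scores >= t
        sens = float((pred & (labels == 1)).sum() / pos_n)
        spec = float((~pred & (labels == 0)).sum() / neg_n)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    _, t, sens, spec = best
    pred = scores >= t
    acc = float((pred == (labels == 1)).mean())
    auc, lo, hi = delong_ci(scores, labels, level=level) if min(pos_n, neg_n) >= 2 else (
        roc_auc(scores, labels),) * 3
    return ROCResult(
        auc=auc, ci_low=lo, ci_high=hi, threshold=float(t),
        sensitivity=sens, specificity=spec, accuracy=acc,
        balanced_accuracy=(sens + spec) / 2.0,
    )


def assign_quintiles(scores: np.ndarray) -> np.ndarray:
    """Quintile labels 1-5 from the empirical distribution; ties go low."""
    scores = np.asarray(scores, dtype=float)
    bounds = np.quantile(scores, [0.2, 0.4, 0.6, 0.8])
    return np.searchsorted(bounds, scores, side="left") + 1


def quintile_effects(
    prs: PRSVector,
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    level: float = 0.95,
) -> list[QuintileEffect]:
    """Per-quintile odds ratios (reference = lowest quintile), Wald CIs.

    Quintile boundaries come from the full analyzed sample's empirical
    PRS distribution, cases and controls jointly.
    """
    covariates = covariates or []
    df = _align(prs, cohort).dropna(subset=["status", "prs"] + covariates)
    y = df["status"].to_numpy(dtype=float)
    q = assign_quintiles(df["prs"].to_numpy(dtype=float))
    X_cov = _design(df, covariates)
    indicators = np.column_stack([(q == k).astype(float) for k in range(2, 6)])
    cells = pd.crosstab(q, y)
    X = np.column_stack([X_cov[:, :1], indicators, X_cov[:, 1:]])
    res = _fit_logit(y, X)
    zq = sps.norm.isf((1.0 - level) / 2.0)
    out = [
        QuintileEffect(
            quintile=1, odds_ratio=1.0, ci_low=1.0, ci_high=1.0, pvalue=1.0,
            n_cases=int(cells.loc[1, 1.0]) if 1 in cells.index and 1.0 in cells.columns else 0,
            n_controls=int(cells.loc[1, 0.0]) if 1 in cells.index and 0.0 in cells.columns else 0,
        )
    ]
    for k in range(2, 6):
        b = float(res.params[k - 1])
        se = float(res.bse[k - 1])
        n_cases = int(cells.loc[k, 1.0]) if k in cells.index and 1.0 in cells.columns else 0
        n_ctrl = int(cells.loc[k, 0.0]) if k in cells.index and 0.0 in cells.columns else 0
        if n_cases == 0 or n_ctrl == 0:
            logger.warning("quintile %d has an empty case or control cell", k)
        out.append(
            QuintileEffect(
                quintile=k,
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - zq * se)),
                ci_high=float(np.exp(b + zq * se)),
                pvalue=float(res.pvalues[k - 1]),
                n_cases=n_cases,
                n_controls=n_ctrl,
            )
        )
    return out


def risk_allele_freq_contrast(
    betas: np.ndarray, freqs_pop_a: np.ndarray, freqs_pop_b: np.ndarray
) -> tuple[tuple[int, int], float, float]:
    """Sign test: is the risk-increasing allele rarer in population A?

    ``freqs_pop_*`` are effect-allele frequencies aligned to ``betas``.
    The risk allele is the effect allele when beta > 0, the other allele
    otherwise. Returns ((n_lower, n_higher), chi-square, p) from a 1-df
    test against a 50:50 split; equal-frequency variants are excluded.
    """
    betas = np.asarray(betas, dtype=float)
    fa = np.asarray(freqs_pop_a, dtype=float)
    fb = np.asarray(freqs_pop_b, dtype=float)
    risk_a = np.where(betas > 0, fa, 1.0 - fa)
    risk_b = np.where(betas > 0, fb, 1.0 - fb)
    usable = (betas != 0) & np.isfinite(risk_a) & np.isfinite(risk_b) & (risk_a != risk_b)
    if not usable.any():
        raise ValueError("no usable variants for the frequency contrast")
    n_lower = int((risk_a[usable] < risk_b[usable]).sum())
    n_higher = int(usable.sum()) - n_lower
    total = n_lower + n_higher
    chi2 = (n_lower - n_higher) ** 2 / total
    p = float(sps.chi2.sf(chi2, df=1))
    return (n_lower, n_higher), float(chi2), p
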
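"""Synthetic admixed case-control cohorts with known ground truth.

The generator stands in for restricted cohort data so that every
analysis stage has a parameter-recovery test. It emulates:

* K-way admixed genotypes: Balding-Nichols population frequencies
  around a shared ancestral frequency (drift parameterized by FST),
  per-sample ancestry proportions q ~ Dirichlet(alpha), and per-copy,
  per-variant ancestry draws (unlinked admixture; optional template-copy
  LD blocks).
* A liability-threshold phenotype: a sparse set of causal variants
  with effects on the standardized-genotype scale, Gaussian
  environment, disease when liability exceeds the prevalence quantile,
  and case/control ascertainment to a configured ratio.
* Discovery summary statistics estimated with noise in a single
  ancestry (European-style discovery), which produces the downstream
  portability gradient: variants rare or monomorphic in the discovery
  population are noisily estimated, fail significance, or are omitted.
* A diagnosis-age channel: a Weibull baseline hazard scaled by the
  true-score quintile, with administrative censoring at age at
  analysis. This proportional-hazards channel is deliberately separate
  from the liability channel so the Cox estimand equals the configured
  log hazard ratio exactly (see docs/methods.md).
* A phased focal-SNP window in which one ancestral A-haplotype is
  shared by all populations while two population-specific G-haplotypes
  share a configurable fraction of their derived alleles, and disease
  risk flows only through the focal allele.

All randomness derives from ``SimConfig.seed``; every output is
reproducible bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenotypeSet, SummaryStatRecord, write_cohort as write_cohort_tsv, write_summary_stats, write_vcf

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort generator."""

    n_pops: int = 3
    fst: tuple[float, ...] = (0.15, 0.15, 0.15)
    n_samples: int = 2000
    n_variants: int = 5000
    n_causal: int = 100
    h2: float = 0.3
    prevalence: float = 0.1
    case_control_ratio: float = 1.0
    dirichlet_alpha: tuple[float, ...] = (0.4, 1.0, 1.6)
    discovery_n: int = 100_000
    discovery_pop: int = 1
    focal_window_sites: int = 52
    focal_risk_or: float = 1.3
    focal_g_freq: float = 0.25
    focal_mutation_rate: float = 0.002
    hap_share_target: float = 0.14
    onset_top_log_hr: float = float(np.log(2.3))
    onset_weibull_shape: float = 5.0
    onset_weibull_scale: float = 72.0
    age_min: float = 45.0
    age_max: float = 85.0
    n_sites: int = 3
    variant_spacing_bp: int = 50_000
    n_chromosomes: int = 22
    ld_block_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if len(self.fst) != self.n_pops or len(self.dirichlet_alpha) != self.n_pops:
            raise ValueError("fst and dirichlet_alpha must have n_pops entries")
        if any(not 0.0 < f < 1.0 for f in self.fst):
            raise ValueError("fst entries must lie in (0, 1)")
        if not 0 <= self.discovery_pop < self.n_pops:
            raise ValueError("discovery_pop out of range")
        if self.focal_window_sites < 10:
            raise ValueError("focal window needs at least 10 sites")


@dataclass
class TruthTable:
    """Generator ground truth for the ascertained cohort."""

    q: np.ndarray                    # n × K ancestry proportions
    true_score: np.ndarray           # n, genetic liability component
    liability: np.ndarray            # n
    beta_std: np.ndarray             # M, standardized-scale effects (0 = null)
    beta_allele: np.ndarray          # M, per-allele effects
    causal_idx: np.ndarray
    pop_freqs: np.ndarray            # K × M
    global_freq: np.ndarray          # M, Dirichlet-mean-weighted frequency
    geno_sd: np.ndarray              # M, standardizing SD sqrt(2 p (1-p))
    pool_prevalence: float
    true_top_quintile_or: float


@dataclass
class CohortBundle:
    config: SimConfig
    genotypes: GenotypeSet
    cohort: pd.DataFrame
    sumstats: list[SummaryStatRecord]
    truth: TruthTable


def _variant_table(cfg: SimConfig) -> pd.DataFrame:
    m = cfg.n_variants
    per_chrom = int(np.ceil(m / cfg.n_chromosomes))
    idx = np.arange(m)
    chrom = (idx // per_chrom + 1).astype(str)
    pos = (idx % per_chrom) * cfg.variant_spacing_bp + 10_000
    return pd.DataFrame(
        {
            "variant_id": [f"var{i:06d}" for i in idx],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
        }
    )


def simulate_frequencies(cfg: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Balding-Nichols population × variant allele frequencies.

    Ancestral frequencies are Uniform(0.05, 0.95); each population's
    frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral p,
    with F the population's drift (FST) parameter.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    p_anc = rng.uniform(0.05, 0.95, size=cfg.n_variants)
    freqs = np.empty((cfg.n_pops, cfg.n_variants))
    for k, F in enumerate(cfg.fst):
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        freqs[k] = rng.beta(a, b)
    return np.clip(freqs, 1e-4, 1.0 - 1e-4)


def _draw_q(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.dirichlet(cfg.dirichlet_alpha, size=n)


def _draw_haploid(
    rng: np.random.Generator, q: np.ndarray, freqs: np.ndarray
) -> np.ndarray:
    """One haploid allele per (sample, variant): ancestry ~ Cat(q), allele ~ Bern(p)."""
    n = q.shape[0]
    m = freqs.shape[1]
    cum = np.cumsum(q, axis=1)
    u = rng.random((n, m))
    anc = (u[:, :, None] > cum[:, None, :]).sum(axis=2)
    p = freqs[anc, np.arange(m)[None, :]]
    return (rng.random((n, m)) < p).astype(np.int8)


def _draw_block_diploid(
    cfg: SimConfig,
    rng: np.random.Generator,
    q: np.ndarray,
    freqs: np.ndarray,
    n_founders: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Both haploid copies with founder-template LD blocks.

    Per block a small pool of founder haplotypes is drawn from the
    across-population mean frequency; each population weights the
    founders differently (so blocks are also ancestry-informative) and
    every chromosome copies its founder with a 1% per-site mutation
    rate. The shared founder pool is what creates within-block LD.
    """
    n = q.shape[0]
    m = freqs.shape[1]
    bs = cfg.ld_block_size
    h0 = np.empty((n, m), dtype=np.int8)
    h1 = np.empty((n, m), dtype=np.int8)
    cum = np.cumsum(q, axis=1)
    for start in range(0, m, bs):
        stop = min(start + bs, m)
        width = stop - start
        p_block = freqs[:, start:stop].mean(axis=0)
        founders = (rng.random((n_founders, width)) < p_block[None, :]).astype(np.int8)
        # population-specific founder frequencies
        founder_w = rng.dirichlet(np.ones(n_founders), size=cfg.n_pops)
        founder_cum = np.cumsum(founder_w, axis=1)
        for out in (h0, h1):
            anc = (rng.random(n)[:, None] > cum).sum(axis=1)
            pick = (rng.random(n)[:, None] > founder_cum[anc]).sum(axis=1)
            hap = founders[pick].copy()
            mut = rng.random((n, width)) < 0.01
            hap[mut] = 1 - hap[mut]
            out[:, start:stop] = hap
    return h0, h1


def simulate_genotypes(
    cfg: SimConfig,
    freqs: np.ndarray,
    rng: np.random.Generator | None = None,
    n: int | None = None,
    phased: bool = False,
) -> tuple[GenotypeSet, np.ndarray]:
    """Admixed genotypes: returns (GenotypeSet, true q matrix)."""
    rng = rng or np.random.default_rng(cfg.seed)
    n = n or cfg.n_samples
    q = _draw_q(cfg, rng, n)
    if cfg.ld_block_size > 1:
        h0, h1 = _draw_block_diploid(cfg, rng, q, freqs)
    else:
        h0 = _draw_haploid(rng, q, freqs)
        h1 = _draw_haploid(rng, q, freqs)
    dosage = (h0 + h1).astype(float)
    gs = GenotypeSet(
        sample_ids=[f"S{i:05d}" for i in range(n)],
        variants=_variant_table(cfg).iloc[: freqs.shape[1]].reset_index(drop=True),
        dosage=dosage,
        phased=np.stack([h0, h1], axis=2) if phased else None,
    )
    return gs, q


def _global_freq(cfg: SimConfig, freqs: np.ndarray) -> np.ndarray:
    alpha = np.asarray(cfg.dirichlet_alpha, dtype=float)
    w = alpha / alpha.sum()
    return w @ freqs


def _true_top_quintile_or(
    pool_g: np.ndarray, pool_prob: np.ndarray, case_frac: float
) -> float:
    """Large-sample logistic estimand of the top-vs-bottom quintile contrast.

    Quintile boundaries are taken on the case/control mixture matching
    the ascertained design (weight case_frac on the case-conditional
    score distribution); the odds ratio is the quintile-membership OR
    P(top|case)P(bottom|control) / (P(bottom|case)P(top|control)).
    """
    pbar = pool_prob.mean()
    w = case_frac * pool_prob / pbar + (1.0 - case_frac) * (1.0 - pool_prob) / (1.0 - pbar)
    order = np.argsort(pool_g)
    g_sorted = pool_g[order]
    w_sorted = w[order]
    cw = np.cumsum(w_sorted) / w_sorted.sum()
    b_low = g_sorted[np.searchsorted(cw, 0.2)]
    b_high = g_sorted[np.searchsorted(cw, 0.8)]
    top = pool_g > b_high
    bottom = pool_g <= b_low
    p_top_case = pool_prob[top].sum() / pool_prob.sum()
    p_bot_case = pool_prob[bottom].sum() / pool_prob.sum()
    ctrl = 1.0 - pool_prob
    p_top_ctrl = ctrl[top].sum() / ctrl.sum()
    p_bot_ctrl = ctrl[bottom].sum() / ctrl.sum()
    return float((p_top_case * p_bot_ctrl) / (p_bot_case * p_top_ctrl))


def simulate_phenotypes(
    cfg: SimConfig,
    genotypes: GenotypeSet,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Liability-threshold phenotypes for an existing genotype set.

    Draws sparse causal effects on the standardized-genotype scale,
    forms liability = genetic score + N(0, 1-h²), declares cases above
    the prevalence quantile, and subsamples to the configured
    case:control ratio. Returns (cohort table, true score, causal
    effect vector over all variants). Raises when the realized cases
    cannot satisfy the ratio (increase n or prevalence).
    """
    rng = rng or np.random.default_rng(cfg.seed + 4)
    m = genotypes.n_variants
    n_causal = min(cfg.n_causal, m)
    causal_idx = np.sort(rng.choice(m, size=n_causal, replace=False))
    beta_std = np.zeros(m)
    if n_causal > 0:
        beta_std[causal_idx] = rng.normal(0.0, np.sqrt(cfg.h2 / max(n_causal, 1)), n_causal)
    f = genotypes.alt_freq
    f = np.clip(f, 1e-3, 1 - 1e-3)
    sd = np.sqrt(2.0 * f * (1.0 - f))
    x_std = (genotypes.dosage - 2.0 * f) / sd
    g = x_std @ beta_std
    liab = g + rng.normal(0.0, np.sqrt(max(1.0 - cfg.h2, 1e-12)), size=len(g))
    status = (liab > sps.norm.isf(cfg.prevalence)).astype(int)

    n_cases = int(status.sum())
    want_cases = int(
        round(len(g) * cfg.case_control_ratio / (1.0 + cfg.case_control_ratio))
    )
    take_cases = min(n_cases, want_cases)
    if take_cases == 0:
        raise ValueError("no cases generated: increase n_samples or prevalence")
    want_ctrls = int(round(take_cases / cfg.case_control_ratio))
    cases = np.flatnonzero(status == 1)[:take_cases]
    ctrls = np.flatnonzero(status == 0)[:want_ctrls]
    keep = np.sort(np.concatenate([cases, ctrls]))
    cohort = pd.DataFrame(
        {
            "sample_id": [genotypes.sample_ids[i] for i in keep],
            "status": status[keep],
            "sex": rng.integers(0, 2, size=keep.size),
            "age": np.round(rng.uniform(cfg.age_min, cfg.age_max, size=keep.size), 1),
            "site": rng.choice([f"site{k+1}" for k in range(cfg.n_sites)], size=keep.size),
        }
    )
    return cohort, g[keep], beta_std


def simulate_cohort(cfg: SimConfig, max_pool_factor: int = 60) -> CohortBundle:
    """Full generator: frequencies, ascertained cohort, truth, discovery stats.

    Cases and controls are ascertained from an internal simulant pool to
    the configured ratio with final size ``n_samples``. Only causal-variant
    genotypes are drawn for the pool; the remaining variants are filled
    in for the ascertained subjects (ancestry is drawn independently per
    variant, so this is distributionally exact).
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = simulate_frequencies(cfg, rng)
    gfreq = _global_freq(cfg, freqs)
    geno_sd = np.sqrt(2.0 * gfreq * (1.0 - gfreq))

    causal_idx = np.sort(rng.choice(cfg.n_variants, size=cfg.n_causal, replace=False))
    beta_std = np.zeros(cfg.n_variants)
    if cfg.n_causal > 0:
        beta_std[causal_idx] = rng.normal(
            0.0, np.sqrt(cfg.h2 / cfg.n_causal), size=cfg.n_causal
        )
    beta_allele = beta_std / geno_sd

    n_cases_target = int(round(cfg.n_samples * cfg.case_control_ratio / (1.0 + cfg.case_control_ratio)))
    n_ctrl_target = cfg.n_samples - n_cases_target
    thresh = sps.norm.isf(cfg.prevalence)
    env_sd = np.sqrt(max(1.0 - cfg.h2, 1e-12))

    kept_q: list[np.ndarray] = []
    kept_causal: list[np.ndarray] = []
    kept_g: list[np.ndarray] = []
    kept_liab: list[np.ndarray] = []
    kept_status: list[np.ndarray] = []
    pool_g: list[np.ndarray] = []
    pool_prob: list[np.ndarray] = []
    n_cases = n_ctrls = 0
    pool_total = 0
    chunk = max(2000, cfg.n_samples)
    causal_freqs = freqs[:, causal_idx]
    sub_sd = geno_sd[causal_idx]
    sub_mean = 2.0 * gfreq[causal_idx]
    sub_beta = beta_std[causal_idx]
    while (n_cases < n_cases_target or n_ctrls < n_ctrl_target):
        if pool_total > max_pool_factor * cfg.n_samples:
            raise ValueError(
                "insufficient cases generated: increase n_samples, prevalence or pool factor"
            )
        q = _draw_q(cfg, rng, chunk)
        x = (_draw_haploid(rng, q, causal_freqs) + _draw_haploid(rng, q, causal_freqs)).astype(float)
        g = ((x - sub_mean) / sub_sd) @ sub_beta
        liab = g + rng.normal(0.0, env_sd, size=chunk)
        status = (liab > thresh).astype(int)
        pool_total += chunk
        pool_g.append(g)
        pool_prob.append(sps.norm.sf((thresh - g) / env_sd))
        take_case = np.flatnonzero(status == 1)[: max(0, n_cases_target - n_cases)]
        take_ctrl = np.flatnonzero(status == 0)[: max(0, n_ctrl_target - n_ctrls)]
        take = np.concatenate([take_case, take_ctrl])
        n_cases += take_case.size
        n_ctrls += take_ctrl.size
        kept_q.append(q[take])
        kept_causal.append(x[take])
        kept_g.append(g[take])
        kept_liab.append(liab[take])
        kept_status.append(status[take])

    q = np.concatenate(kept_q)
    x_causal = np.concatenate(kept_causal)
    true_score = np.concatenate(kept_g)
    liability = np.concatenate(kept_liab)
    status = np.concatenate(kept_status)
    pool_g_all = np.concatenate(pool_g)
    pool_prob_all = np.concatenate(pool_prob)

    # deterministic shuffle so cases and controls interleave
    perm = rng.permutation(cfg.n_samples)
    q, x_causal = q[perm], x_causal[perm]
    true_score, liability, status = true_score[perm], liability[perm], status[perm]

    # fill the non-causal genotype columns for the ascertained subjects
    noncausal_idx = np.setdiff1d(np.arange(cfg.n_variants), causal_idx)
    dosage = np.empty((cfg.n_samples, cfg.n_variants))
    dosage[:, causal_idx] = x_causal
    nc_freqs = freqs[:, noncausal_idx]
    dosage[:, noncausal_idx] = (
        _draw_haploid(rng, q, nc_freqs) + _draw_haploid(rng, q, nc_freqs)
    ).astype(float)

    genotypes = GenotypeSet(
        sample_ids=[f"S{i:05d}" for i in range(cfg.n_samples)],
        variants=_variant_table(cfg),
        dosage=dosage,
    )

    case_frac = n_cases_target / cfg.n_samples
    truth = TruthTable(
        q=q,
        true_score=true_score,
        liability=liability,
        beta_std=beta_std,
        beta_allele=beta_allele,
        causal_idx=causal_idx,
        pop_freqs=freqs,
        global_freq=gfreq,
        geno_sd=geno_sd,
        pool_prevalence=float(pool_prob_all.mean()),
        true_top_quintile_or=_true_top_quintile_or(pool_g_all, pool_prob_all, case_frac),
    )

    cohort = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "status": status,
            "sex": rng.integers(0, 2, size=cfg.n_samples),
            "age": np.round(rng.uniform(cfg.age_min, cfg.age_max, size=cfg.n_samples), 1),
            "site": rng.choice([f"site{k+1}" for k in range(cfg.n_sites)], size=cfg.n_samples),
        }
    )
    cohort["age_at_onset"] = np.nan
    is_case = cohort["status"].to_numpy() == 1
    if is_case.any():
        onset = _truncated_onset(
            cfg, rng, true_score[is_case], cohort.loc[is_case, "age"].to_numpy()
        )
        cohort.loc[is_case, "age_at_onset"] = onset

    sumstats = simulate_discovery_stats(cfg, freqs, truth, rng=rng)
    return CohortBundle(config=cfg, genotypes=genotypes, cohort=cohort, sumstats=sumstats, truth=truth)


def simulate_discovery_stats(
    cfg: SimConfig,
    freqs: np.ndarray,
    truth: TruthTable,
    rng: np.random.Generator | None = None,
) -> list[SummaryStatRecord]:
    """Noisy single-ancestry discovery GWAS over all variants.

    beta_hat_j = beta_j + N(0, se_j^2) with
    se_j = 1 / sqrt(2 p_dj (1 - p_dj) discovery_n), p_dj the discovery
    population's frequency; p-values from the Wald statistic. Variants
    effectively monomorphic in the discovery population are omitted.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    p_d = freqs[cfg.discovery_pop]
    variants = _variant_table(cfg)
    min_f = 1.0 / (2.0 * cfg.discovery_n)
    records: list[SummaryStatRecord] = []
    se = 1.0 / np.sqrt(2.0 * p_d * (1.0 - p_d) * cfg.discovery_n)
    beta_hat = truth.beta_allele + rng.normal(0.0, 1.0, size=cfg.n_variants) * se
    z = beta_hat / se
    pvals = np.clip(2.0 * sps.norm.sf(np.abs(z)), 1e-300, 1.0)
    for j in range(cfg.n_variants):
        if p_d[j] < min_f or p_d[j] > 1.0 - min_f:
            logger.info("variant %s monomorphic in discovery: omitted", variants["variant_id"][j])
            continue
        records.append(
            SummaryStatRecord(
                variant_id=variants["variant_id"][j],
                chrom=variants["chrom"][j],
                pos=int(variants["pos"][j]),
                effect_allele=variants["alt"][j],
                other_allele=variants["ref"][j],
                beta=float(beta_hat[j]),
                se=float(se[j]),
                pvalue=float(pvals[j]),
                eaf=float(p_d[j]),
            )
        )
    return records


def _truncated_onset(
    cfg: SimConfig, rng: np.random.Generator, score: np.ndarray, age: np.ndarray
) -> np.ndarray:
    """Onset ages for diagnosed cases, conditioned to (18, age]."""
    from .evaluate import assign_quintiles

    quint = assign_quintiles(score)
    eta = cfg.onset_top_log_hr * (quint - 1) / 4.0
    k, lam = cfg.onset_weibull_shape, cfg.onset_weibull_scale
    onset = np.empty_like(age, dtype=float)
    for i in range(onset.size):
        for _ in range(200):
            u = rng.random()
            t = lam * (-np.log(u) / np.exp(eta[i])) ** (1.0 / k)
            if 18.0 < t <= age[i]:
                onset[i] = t
                break
        else:
            onset[i] = max(19.0, age[i] - 1.0)
    return np.round(onset, 1)


def simulate_onset(
    cfg: SimConfig,
    cohort: pd.DataFrame,
    true_score: np.ndarray,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Diagnosis-age channel: Weibull hazard scaled by score quintile.

    Every subject receives a latent onset age
    t = lambda * (-log U / exp(eta_q))^(1/shape) with
    eta_q = top_log_hr * (q - 1)/4 for true-score quintile q, resampled
    while <= 18, then administratively censored at age at analysis:
    event = (t <= age), time = min(t, age). Returns survival records
    (sample_id, time, event, quintile) ready for Cox/KM analysis.
    """
    from .evaluate import assign_quintiles

    rng = rng or np.random.default_rng(cfg.seed + 2)
    n = len(cohort)
    quint = assign_quintiles(np.asarray(true_score, dtype=float))
    eta = cfg.onset_top_log_hr * (quint - 1) / 4.0
    k, lam = cfg.onset_weibull_shape, cfg.onset_weibull_scale
    t = np.empty(n)
    pending = np.ones(n, dtype=bool)
    while pending.any():
        u = rng.random(pending.sum())
        draw = lam * (-np.log(u) / np.exp(eta[pending])) ** (1.0 / k)
        t[pending] = draw
        pending = t <= 18.0
    age = cohort["age"].to_numpy(dtype=float)
    event = (t <= age).astype(int)
    time = np.minimum(t, age)
    out = pd.DataFrame(
        {
            "sample_id": cohort["sample_id"].to_numpy(),
            "time": time,
            "event": event,
            "quintile": quint,
        }
    )
    for c in ("sex", "site", "age"):
        if c in cohort.columns:
            out[c] = cohort[c].to_numpy()
    return out


@dataclass
class FocalHaplotypeTruth:
    focal_variant_id: str
    focal_index: int
    hap_ancestral: str
    hap_g_discovery: str
    hap_g_target: str
    realized_share: float
    hap_labels: np.ndarray  # (n, 2) template index per chromosome copy


def _derived_site_sets(cfg: SimConfig) -> tuple[int, set[int], set[int], float]:
    """Site sets for the two G-haplotypes achieving the sharing target."""
    L = cfg.focal_window_sites
    focal = L // 2
    s = max(2, round(0.31 * L))
    share = cfg.hap_share_target
    o = max(1, round(share * 2 * s / (1.0 + share)))
    o = min(o, s)
    while (o - 1) + 2 * (s - o) > L - 1:
        s -= 1
        o = min(o, s)
    others = [i for i in range(L) if i != focal]
    shared = {focal} | set(others[: o - 1])
    priv_e = set(others[o - 1 : o - 1 + (s - o)])
    priv_t = set(others[o - 1 + (s - o) : o - 1 + 2 * (s - o)])
    realized = o / (2 * s - o)
    if abs(realized - share) > 0.01:
        logger.warning(
            "sharing target %.3f not achievable at %d sites; using %.3f", share, L, realized
        )
    return focal, shared | priv_e, shared | priv_t, realized


def simulate_focal_haplotypes(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeSet, pd.DataFrame, FocalHaplotypeTruth]:
    """Phased focal-SNP window with ancestry-specific risk backgrounds.

    One ancestral A-haplotype is common everywhere; a discovery-type and
    a target-type G-haplotype (both carrying the focal risk allele)
    segregate at ``focal_g_freq`` in their home populations and are rare
    elsewhere. Their derived-allele sets overlap at the configured
    sharing fraction. Disease risk is assigned ONLY through the focal
    allele count at ``focal_risk_or`` per allele, which makes the
    conditional likelihood-ratio test a designed null. A per-site
    mutation rate adds a rare haplotype tail. Recombination is off.
    """
    rng = rng or np.random.default_rng(cfg.seed + 3)
    L = cfg.focal_window_sites
    n = cfg.n_samples
    focal, set_e, set_t, realized = _derived_site_sets(cfg)

    templates = np.zeros((3, L), dtype=np.int8)  # 0 = ancestral A-hap
    templates[1, sorted(set_e)] = 1              # discovery-type G-hap
    templates[2, sorted(set_t)] = 1              # target-type G-hap

    # template frequencies per population: G-haps are home-population specific
    g = cfg.focal_g_freq
    hap_freq = np.full((cfg.n_pops, 3), 0.0)
    hap_freq[:, 1] = 0.02
    hap_freq[:, 2] = 0.02
    hap_freq[cfg.discovery_pop, 1] = g
    target_pop = (cfg.discovery_pop + 1) % cfg.n_pops
    hap_freq[target_pop, 2] = g
    hap_freq[:, 0] = 1.0 - hap_freq[:, 1:].sum(axis=1)

    alpha = np.asarray(cfg.dirichlet_alpha, dtype=float)
    pop = rng.choice(cfg.n_pops, size=n, p=alpha / alpha.sum())
    labels = np.empty((n, 2), dtype=np.int8)
    hap = np.empty((n, L, 2), dtype=np.int8)
    for c in range(2):
        u = rng.random(n)
        cum = np.cumsum(hap_freq[pop], axis=1)
        lab = (u[:, None] > cum).sum(axis=1)
        labels[:, c] = lab
        h = templates[lab].copy()
        mut = rng.random((n, L)) < cfg.focal_mutation_rate
        h[mut] = 1 - h[mut]
        hap[:, :, c] = h

    dosage = hap.sum(axis=2).astype(float)
    pos0 = 89_700_000  # rs356182-scale coordinates on chromosome 4
    variants = pd.DataFrame(
        {
            "variant_id": [f"snca{i:03d}" for i in range(L)],
            "chrom": "4",
            "pos": pos0 + np.arange(L) * 650,
            "ref": "A",
            "alt": "G",
        }
    )
    variants.loc[focal, "variant_id"] = "rs_focal"
    genotypes = GenotypeSet(
        sample_ids=[f"S{i:05d}" for i in range(n)],
        variants=variants,
        dosage=dosage,
        phased=hap,
    )

    g_focal = dosage[:, focal]
    logit = np.log(0.4 / 0.6) + np.log(cfg.focal_risk_or) * (g_focal - g_focal.mean())
    p_case = 1.0 / (1.0 + np.exp(-logit))
    status = (rng.random(n) < p_case).astype(int)
    cohort = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "status": status,
            "sex": rng.integers(0, 2, size=n),
            "age": np.round(rng.uniform(cfg.age_min, cfg.age_max, size=n), 1),
            "site": rng.choice([f"site{k+1}" for k in range(cfg.n_sites)], size=n),
        }
    )
    truth = FocalHaplotypeTruth(
        focal_variant_id="rs_focal",
        focal_index=focal,
        hap_ancestral="".join(map(str, templates[0])),
        hap_g_discovery="".join(map(str, templates[1])),
        hap_g_target="".join(map(str, templates[2])),
        realized_share=realized,
        hap_labels=labels,
    )
    return genotypes, cohort, truth


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text files re-readable by the IO module."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "sumstats": out / "sumstats.tsv",
        "cohort": out / "cohort.tsv",
        "truth": out / "truth.tsv",
    }
    write_vcf(bundle.genotypes, paths["vcf"])
    write_summary_stats(bundle.sumstats, paths["sumstats"])
    write_cohort_tsv(bundle.cohort, paths["cohort"])
    truth_df = pd.DataFrame(
        {
            "sample_id": bundle.genotypes.sample_ids,
            "true_score": bundle.truth.true_score,
            "liability": bundle.truth.liability,
        }
    )
    for k in range(bundle.truth.q.shape[1]):
        truth_df[f"q{k+1}"] = bundle.truth.q[:, k]
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    return paths
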
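"""Population-structure tools: genotype PCA, PC-space clustering,
supervised admixture proportions, and PRS-by-ancestry statistics.

Admixture proportions are estimated per sample by maximizing the
binomial log-likelihood

    L(q_i) = sum_j [ d_ij log(pi_ij) + (2 - d_ij) log(1 - pi_ij) ],
    pi_ij = sum_k q_ik p_kj,

with the reference population frequencies p fixed (supervised
projection). The EM update with responsibilities
a_ijk = q_ik p_kj / pi_ij (alt allele) and
b_ijk = q_ik (1 - p_kj) / (1 - pi_ij) (ref allele) is

    q_ik <- sum_j [ d_ij a_ijk + (2 - d_ij) b_ijk ] / (2 M),

which keeps q on the simplex and never decreases the likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .io import GenotypeSet
from .prs import PRSVector

logger = logging.getLogger(__name__)


@dataclass
class PCProjection:
    """Sample coordinates on the top genotype principal components."""

    sample_ids: list[str]
    coords: np.ndarray
    explained_variance_ratio: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords, columns=[f"PC{i+1}" for i in range(self.coords.shape[1])]
        )
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass
class AncestryModel:
    """Reference allele frequencies and per-sample ancestry proportions."""

    populations: list[str]
    sample_ids: list[str]
    ref_freqs: np.ndarray  # populations × variants
    q: np.ndarray  # samples × populations
    log_likelihood: np.ndarray | None = None  # per-iteration trace

    def __post_init__(self) -> None:
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("ancestry proportions must sum to 1 per sample")
        if (self.q < -1e-12).any() or (self.q > 1 + 1e-12).any():
            raise ValueError("ancestry proportions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.q, columns=self.populations)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def genotype_pca(genotypes: GenotypeSet, n_pcs: int = 10) -> PCProjection:
    """PCA of mean-imputed, frequency-standardized genotypes.

    Each variant is centered by 2f and scaled by sqrt(2f(1-f)) (the
    binomial SD under Hardy-Weinberg); monomorphic variants are dropped
    with a log entry. Components come from the SVD of the standardized
    matrix, so they are orthogonal on the training samples.
    """
    n = genotypes.n_samples
    if n < n_pcs + 1:
        raise ValueError("need at least n_pcs + 1 samples")
    d = genotypes.dosage.astype(float)
    f = np.nanmean(d, axis=0) / 2.0
    poly = (f > 0) & (f < 1)
    if (~poly).any():
        logger.info("dropping %d monomorphic variants from PCA", int((~poly).sum()))
    d = d[:, poly]
    f = f[poly]
    nan_mask = np.isnan(d)
    if nan_mask.any():
        d = np.where(nan_mask, (2.0 * f)[None, :], d)
    x = (d - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    x -= x.mean(axis=0)  # exact centering after imputation
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_pcs, s.size)
    coords = u[:, :k] * s[:k]
    total_var = float((s**2).sum())
    evr = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return PCProjection(
        sample_ids=list(genotypes.sample_ids),
        coords=coords,
        explained_variance_ratio=evr,
    )


def pc_kmeans(projection: PCProjection, k: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """K-means on the retained PCs; labels relabeled by descending size."""
    if k < 2:
        raise ValueError("k must be at least 2")
    n = projection.coords.shape[0]
    if k > n:
        raise ValueError("k cannot exceed the number of samples")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(projection.coords)
    sizes = np.bincount(raw, minlength=k)
    # stable relabeling: by descending size, ties by original label
    order = np.lexsort((np.arange(k), -sizes))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[raw]


def supervised_admixture(
    genotypes: GenotypeSet,
    ref_freqs: pd.DataFrame | np.ndarray,
    populations: list[str] | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> AncestryModel:
    """Per-sample admixture proportions against fixed reference frequencies.

    ``ref_freqs`` is either a populations × variants array aligned to
    the genotype set's variant order, or a DataFrame keyed by variant_id
    with one column per population. Frequencies are clipped to
    [0.001, 0.999] to keep the log-likelihood finite. If all reference
    populations are identical the likelihood is flat; a uniform q is
    returned with a degeneracy warning.
    """
    if isinstance(ref_freqs, pd.DataFrame):
        pops = populations or [c for c in ref_freqs.columns if c != "variant_id"]
        merged = genotypes.variants[["variant_id"]].merge(
            ref_freqs, on="variant_id", how="inner"
        )
        if len(merged) == 0:
            raise ValueError("no overlapping variants between genotypes and reference")
        keep = genotypes.variants["variant_id"].isin(merged["variant_id"]).to_numpy()
        d = genotypes.dosage[:, keep]
        p = merged[pops].to_numpy().T
    else:
        p = np.asarray(ref_freqs, dtype=float)
        pops = populations or [f"pop{k+1}" for k in range(p.shape[0])]
        if p.shape[1] != genotypes.n_variants:
            raise ValueError("ref_freqs must align to the genotype variants")
        d = genotypes.dosage
    K = p.shape[0]
    p = np.clip(p, 0.001, 0.999)
    d = np.asarray(d, dtype=float)
    missing = np.isnan(d)
    d = np.where(missing, 0.0, d)
    alt = d
    ref = np.where(missing, 0.0, 2.0 - d)  # missing sites contribute nothing

    n = alt.shape[0]
    if np.allclose(p, p[0][None, :], atol=1e-12):
        logger.warning("reference populations are identical: ancestry not identifiable")
        q = np.full((n, K), 1.0 / K)
        return AncestryModel(
            populations=pops, sample_ids=list(genotypes.sample_ids),
            ref_freqs=p, q=q, log_likelihood=None,
        )

    q = np.full((n, K), 1.0 / K)
    ll_trace: list[float] = []
    weight = (alt + ref).sum(axis=1, keepdims=True)  # 2 * observed sites
    for _ in range(max_iter):
        pi = np.clip(q @ p, 1e-12, 1.0 - 1e-12)  # n × M
        ll = float((alt * np.log(pi) + ref * np.log1p(-pi)).sum())
        ll_trace.append(ll)
        # responsibilities folded into the q update
        alt_term = (alt / pi) @ p.T           # n × K
        ref_term = (ref / (1.0 - pi)) @ (1.0 - p).T
        q_new = q * (alt_term + ref_term) / weight
        q_new /= q_new.sum(axis=1, keepdims=True)
        if len(ll_trace) > 1 and ll_trace[-1] - ll_trace[-2] < tol:
            q = q_new
            break
        q = q_new
    return AncestryModel(
        populations=pops,
        sample_ids=list(genotypes.sample_ids),
        ref_freqs=p,
        q=q,
        log_likelihood=np.asarray(ll_trace),
    )


def prs_ancestry_correlation(
    prs: PRSVector, model: AncestryModel
) -> pd.DataFrame:
    """Pearson correlation of the PRS with each ancestry proportion."""
    if list(prs.sample_ids) != list(model.sample_ids):
        lookup = {s: i for i, s in enumerate(model.sample_ids)}
        idx = [lookup[s] for s in prs.sample_ids]
        q = model.q[idx]
    else:
        q = model.q
    rows = []
    for k, pop in enumerate(model.populations):
        col = q[:, k]
        if col.std() == 0:
            rows.append({"population": pop, "r": np.nan, "pvalue": np.nan})
            continue
        r, p = sps.pearsonr(prs.score, col)
        rows.append({"population": pop, "r": float(r), "pvalue": float(p)})
    return pd.DataFrame(rows, columns=["population", "r", "pvalue"])


def compare_prs_distributions(
    prs_by_group: dict[str, np.ndarray], reference: str
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum of each group's PRS vs the reference."""
    if reference not in prs_by_group:
        raise ValueError(f"reference group {reference!r} missing")
    ref_scores = np.asarray(prs_by_group[reference], dtype=float)
    rows = []
    for group, values in prs_by_group.items():
        if group == reference:
            continue
        values = np.asarray(values, dtype=float)
        if values.size < 2 or ref_scores.size < 2:
            logger.warning("group %s too small; skipped", group)
            continue
        stat, p = sps.mannwhitneyu(values, ref_scores, alternative="two-sided")
        rows.append({"group": group, "W": float(stat), "pvalue": float(p)})
    return pd.DataFrame(rows, columns=["group", "W", "pvalue"])
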
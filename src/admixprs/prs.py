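"""LD clumping, pruning+thresholding model search, and polygenic scoring.

The polygenic risk score of subject i is PRS_i = sum_j beta_j * d_ij,
the dosage-weighted sum of harmonized log-odds effects. Clumping is the
PLINK/PRSice greedy rule: walk variants in order of ascending discovery
p-value, take each unassigned variant as an index, and absorb every
unassigned variant on the same chromosome within the window whose
dosage r² with the index exceeds the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeSet, HarmonizedStats

logger = logging.getLogger(__name__)


@dataclass
class ClumpResult:
    """Index variants and their absorbed members (a partition of the input)."""

    index_variants: list[str]
    members: dict[str, list[str]]
    r2_threshold: float
    window_kb: float

    @property
    def n_assigned(self) -> int:
        return len(self.index_variants) + sum(len(v) for v in self.members.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"index_variant": iv, "members": ",".join(self.members.get(iv, []))}
            for iv in self.index_variants
        ]
        return pd.DataFrame(rows, columns=["index_variant", "members"])


@dataclass
class PRSVector:
    """Per-subject polygenic score with provenance."""

    sample_ids: list[str]
    score: np.ndarray
    n_variants: int
    p_threshold: float | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        if len(self.score) != len(self.sample_ids):
            raise ValueError("score length must match sample_ids")
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")

    def standardize(self) -> "PRSVector":
        sd = self.score.std(ddof=0)
        if sd == 0:
            raise ValueError("cannot standardize a constant score")
        return PRSVector(
            sample_ids=list(self.sample_ids),
            score=(self.score - self.score.mean()) / sd,
            n_variants=self.n_variants,
            p_threshold=self.p_threshold,
            standardized=True,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "score": self.score})


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Returns NaN when either vector is constant (the pair is then treated
    as unlinked by :func:`clump`). Missing entries are dropped pairwise.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump(
    stats: HarmonizedStats,
    genotypes: GenotypeSet,
    r2: float = 0.1,
    window_kb: float = 250.0,
) -> ClumpResult:
    """Greedy p-value-ordered LD clumping.

    Ties in p are broken by (chrom, pos). The result partitions the
    harmonized variants into index variants and clump members; the
    partition property is asserted on every run.
    """
    m = len(stats)
    chrom = genotypes.variants["chrom"].to_numpy()[stats.col]
    pos = genotypes.variants["pos"].to_numpy()[stats.col].astype(np.int64)
    order = sorted(range(m), key=lambda k: (stats.pvalue[k], chrom[k], pos[k]))

    assigned = np.zeros(m, dtype=bool)
    index_variants: list[str] = []
    members: dict[str, list[str]] = {}
    window_bp = window_kb * 1000.0
    for k in order:
        if assigned[k]:
            continue
        assigned[k] = True
        vid = stats.variant_ids[k]
        index_variants.append(vid)
        members[vid] = []
        near = np.flatnonzero(
            ~assigned & (chrom == chrom[k]) & (np.abs(pos - pos[k]) <= window_bp)
        )
        if near.size == 0:
            continue
        d_index = genotypes.dosage[:, stats.col[k]]
        for q in near:
            r2_val = ld_r2(d_index, genotypes.dosage[:, stats.col[q]])
            if np.isfinite(r2_val) and r2_val > r2:
                assigned[q] = True
                members[vid].append(stats.variant_ids[q])
    result = ClumpResult(
        index_variants=index_variants, members=members, r2_threshold=r2, window_kb=window_kb
    )
    assert result.n_assigned == m, "clump output must partition the input"
    return result


def score(
    genotypes: GenotypeSet,
    stats: HarmonizedStats,
    standardize: bool = False,
    p_threshold: float | None = None,
    missing: str = "mean",
) -> PRSVector:
    """Per-subject weighted allele-dosage sum.

    Missing dosages are mean-imputed per variant (``missing='mean'``,
    the default) or the variant is dropped for every subject
    (``missing='drop'`` drops variants with any missing dosage).
    """
    if len(stats) == 0:
        raise ValueError("no usable variants to score")
    d = stats.aligned_dosage(genotypes)
    beta = stats.beta.copy()
    if missing == "mean":
        col_mean = np.nanmean(d, axis=0)
        nan_mask = np.isnan(d)
        if nan_mask.any():
            d = np.where(nan_mask, col_mean[None, :], d)
    elif missing == "drop":
        keep = ~np.isnan(d).any(axis=0)
        if not keep.any():
            raise ValueError("no usable variants to score after dropping missing")
        d, beta = d[:, keep], beta[keep]
    else:
        raise ValueError("missing must be 'mean' or 'drop'")
    raw = d @ beta
    prs = PRSVector(
        sample_ids=list(genotypes.sample_ids),
        score=raw,
        n_variants=int(beta.size),
        p_threshold=p_threshold,
        standardized=False,
    )
    return prs.standardize() if standardize else prs


def prune_and_threshold(
    stats: HarmonizedStats,
    genotypes: GenotypeSet,
    cohort: pd.DataFrame,
    threshold_grid: tuple[float, ...],
    covariates: list[str] | None = None,
    r2: float = 0.1,
    window_kb: float = 250.0,
) -> tuple[float, PRSVector, pd.DataFrame]:
    """Pruning+thresholding model search over a p-value grid.

    For each cutoff: clump the sub-threshold variants, score the index
    variants, fit status ~ PRS + covariates, and record the Nagelkerke
    pseudo-R² increment over the covariate-only model. Returns the
    cutoff maximizing the increment, its score vector, and the full
    per-threshold fit table. Deterministic given its inputs.
    """
    from .evaluate import logistic_assoc  # local import avoids a cycle

    if len(threshold_grid) == 0:
        raise ValueError("threshold grid must be nonempty")
    covariates = covariates or []
    rows = []
    best: tuple[float, float, PRSVector] | None = None
    for cutoff in threshold_grid:
        sub = stats.subset(stats.pvalue <= cutoff)
        if len(sub) == 0:
            rows.append({"p_threshold": cutoff, "n_variants": 0, "nagelkerke_increment": np.nan})
            continue
        clumped = clump(sub, genotypes, r2=r2, window_kb=window_kb)
        keep_ids = set(clumped.index_variants)
        idx_mask = np.array([vid in keep_ids for vid in sub.variant_ids])
        prs = score(genotypes, sub.subset(idx_mask), p_threshold=cutoff)
        try:
            assoc = logistic_assoc(prs, cohort, covariates)
        except Exception as exc:
            logger.warning("cutoff %g skipped: logistic fit failed (%s)", cutoff, exc)
            rows.append(
                {"p_threshold": cutoff, "n_variants": prs.n_variants,
                 "nagelkerke_increment": np.nan}
            )
            continue
        inc = assoc.nagelkerke_r2
        rows.append(
            {"p_threshold": cutoff, "n_variants": prs.n_variants, "nagelkerke_increment": inc}
        )
        if best is None or inc > best[1]:
            best = (cutoff, inc, prs)
    table = pd.DataFrame(rows, columns=["p_threshold", "n_variants", "nagelkerke_increment"])
    if best is None:
        raise ValueError("no threshold in the grid produced a scoreable model")
    return best[0], best[2], table
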
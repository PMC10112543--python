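"""Pairwise kinship, unrelated-subset selection and MAF filtering.

Kinship uses the KING-robust between-family moment estimator, which is
robust to population structure because it never touches allele
frequencies: for a sample pair (i, j) with hard-call genotypes over the
sites where both are observed,

    phi_ij = (N_Aa,Aa - 2 * N_AA,aa) / (N_Aa(i) + N_Aa(j))

where N_Aa,Aa counts double-heterozygous sites, N_AA,aa counts
opposite-homozygous sites, and N_Aa(i) counts sites heterozygous in
sample i. Duplicates give 0.5, parent-offspring pairs 0.25 in
expectation, and unrelated pairs 0. The conventional degree cutoffs are
0.354 / 0.177 / 0.0884 / 0.0442 for duplicate / 1st / 2nd / 3rd degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeSet

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    """Symmetric kinship coefficients; diagonal fixed at 0.5 by convention."""

    sample_ids: list[str]
    phi: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.phi.shape != (n, n):
            raise ValueError("phi must be square over sample_ids")

    def pairs_above(self, threshold: float) -> list[tuple[str, str, float]]:
        out = []
        n = len(self.sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isfinite(self.phi[i, j]) and self.phi[i, j] > threshold:
                    out.append((self.sample_ids[i], self.sample_ids[j], float(self.phi[i, j])))
        return out

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        n = len(self.sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "id1": self.sample_ids[i],
                        "id2": self.sample_ids[j],
                        "phi": self.phi[i, j],
                    }
                )
        pd.DataFrame(rows, columns=["id1", "id2", "phi"]).to_csv(path, sep="\t", index=False)


def king_kinship(genotypes: GenotypeSet, min_sites: int = 100) -> KinshipMatrix:
    """KING-robust between-family kinship for every sample pair.

    Dosages are rounded to hard calls. Pairs sharing fewer than
    ``min_sites`` non-missing sites get phi = NaN with a log entry.
    """
    g = np.round(genotypes.dosage)
    observed = np.isfinite(g)
    gz = np.where(observed, g, -1)

    het = (gz == 1).astype(np.float64)
    hom_ref = (gz == 0).astype(np.float64)
    hom_alt = (gz == 2).astype(np.float64)
    obs = observed.astype(np.float64)

    n_hethet = het @ het.T
    n_opp = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    # heterozygote counts restricted to the pair's shared observed sites
    n_het_i = het @ obs.T
    n_het_j = obs @ het.T
    shared = obs @ obs.T

    denom = n_het_i + n_het_j
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n_hethet - 2.0 * n_opp) / denom
    phi[denom == 0] = np.nan
    low = shared < min_sites
    if low.any():
        n_low = int(np.triu(low, 1).sum())
        if n_low:
            logger.warning("%d pairs below %d shared sites: phi set missing", n_low, min_sites)
    phi[low] = np.nan
    np.fill_diagonal(phi, 0.5)
    return KinshipMatrix(sample_ids=list(genotypes.sample_ids), phi=phi)


def unrelated_subset(kinship: KinshipMatrix, threshold: float = 0.0884) -> list[str]:
    """Greedy unrelated-subset selection.

    Repeatedly removes the sample with the most remaining relationships
    above ``threshold`` (ties broken by sample id order), until no pair
    exceeds the threshold. The output is verified against that property
    before returning.
    """
    ids = kinship.sample_ids
    n = len(ids)
    related = np.isfinite(kinship.phi) & (kinship.phi > threshold)
    np.fill_diagonal(related, False)
    active = np.ones(n, dtype=bool)
    order = np.argsort(np.array(ids, dtype=object))  # lexicographic tie-break
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    while True:
        degree = (related & active[None, :] & active[:, None]).sum(axis=1)
        degree[~active] = 0
        if degree.max() == 0:
            break
        top = degree.max()
        candidates = np.flatnonzero(degree == top)
        drop = candidates[np.argmin(rank[candidates])]
        active[drop] = False
    kept = [ids[i] for i in range(n) if active[i]]
    # post-hoc verification of the defining property
    idx = np.flatnonzero(active)
    assert not related[np.ix_(idx, idx)].any(), "unrelated subset violates threshold"
    return kept


def maf_filter(genotypes: GenotypeSet, maf_min: float = 0.05) -> GenotypeSet:
    """Drop variants with minor-allele frequency below ``maf_min`` (inclusive keep)."""
    keep = np.flatnonzero(genotypes.maf >= maf_min - 1e-12)  # inclusive bound
    logger.info("MAF filter kept %d / %d variants", keep.size, genotypes.n_variants)
    return genotypes.subset_variants(keep)
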
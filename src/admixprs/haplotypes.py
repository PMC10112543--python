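"""Focal-SNP haplotype analysis.

Given phased genotypes over a window around a focal risk variant
(rs356182-style), this module: estimates D'-confidence-interval
haplotype blocks (Gabriel/Haploview rule), enumerates window haplotypes
and categorizes them by their focal-SNP allele, tests each common
haplotype for case-control association with covariate adjustment and
Bonferroni correction, applies the conditioning likelihood-ratio test
(does the haplotype add signal beyond the focal genotype?), computes
the derived-allele sharing fraction between haplotypes, and builds a
statistical-parsimony (TCS-style) minimum-spanning haplotype network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .evaluate import _design, _fit_logit
from .io import GenotypeSet

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeBlock:
    chrom: str
    start: int
    end: int
    variant_ids: list[str]

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)


@dataclass
class HaplotypeAllele:
    """One distinct window haplotype with per-sample copy counts."""

    label: str
    alleles: str  # '0' = ref, '1' = alt, one character per window site
    frequency: float
    focal_allele: str  # the base carried at the focal site
    copies: np.ndarray  # per-sample 0/1/2


@dataclass
class HaplotypeTable:
    """Common haplotypes plus the pooled rare bin (excluded from testing)."""

    haplotypes: list[HaplotypeAllele]
    rare_frequency: float
    rare_copies: np.ndarray
    focal_variant_id: str
    n_chromosomes: int

    def __post_init__(self) -> None:
        total = sum(h.frequency for h in self.haplotypes) + self.rare_frequency
        if abs(total - 1.0) > 1e-6:
            raise ValueError("haplotype frequencies must sum to 1")
        copies = self.rare_copies.copy()
        for h in self.haplotypes:
            copies = copies + h.copies
        if not np.all(copies == 2):
            raise ValueError("per-sample haplotype copies must sum to 2")


@dataclass
class HapAssociationResult:
    label: str
    focal_allele: str
    beta: float
    se: float
    pvalue: float
    p_adjusted: float
    frequency: float
    lrt_p: float | None = None
    lrt_defined: bool = True


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph
    connection_limit: int

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"hap_a": a, "hap_b": b, "distance": d["distance"]}
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["hap_a", "hap_b", "distance"])

    def write_gml(self, path) -> None:
        nx.write_gml(self.graph, str(path))


# ---------------------------------------------------------------------------
# D' confidence intervals and Gabriel blocks


def dprime_ci(
    hap_counts: np.ndarray, level: float = 0.90, grid: int = 201
) -> tuple[float, float, float]:
    """|D'| point estimate with likelihood-grid confidence bounds.

    ``hap_counts`` is a 2x2 table of phased two-site haplotype counts
    (rows: site-1 alleles, columns: site-2 alleles). The CI follows the
    Haploview convention: the multinomial likelihood is evaluated on a
    grid of |D'| in [0, 1] (frequencies held at their MLEs), normalized,
    and equal-tail bounds taken from its cumulative distribution.
    Monomorphic sites give (nan, nan, nan).
    """
    c = np.asarray(hap_counts, dtype=float)
    n = c.sum()
    if n == 0:
        return (float("nan"),) * 3
    pA = (c[0, 0] + c[0, 1]) / n
    pB = (c[0, 0] + c[1, 0]) / n
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return (float("nan"),) * 3
    d = c[0, 0] / n - pA * pB
    if d >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax <= 0:
        return (float("nan"),) * 3
    dprime = abs(d) / dmax
    sign = 1.0 if d >= 0 else -1.0

    grid_vals = np.linspace(0.0, 1.0, grid)
    eps = 1e-12
    loglik = np.empty(grid)
    for i, g in enumerate(grid_vals):
        dd = sign * g * dmax
        p11 = pA * pB + dd
        p12 = pA * (1 - pB) - dd
        p21 = (1 - pA) * pB - dd
        p22 = (1 - pA) * (1 - pB) + dd
        probs = np.clip(np.array([p11, p12, p21, p22]), eps, 1.0)
        loglik[i] = (c.ravel() * np.log(probs)).sum()
    lik = np.exp(loglik - loglik.max())
    cdf = np.cumsum(lik) / lik.sum()
    alpha = (1.0 - level) / 2.0
    lo = float(grid_vals[np.searchsorted(cdf, alpha)])
    hi = float(grid_vals[min(np.searchsorted(cdf, 1.0 - alpha), grid - 1)])
    return float(min(dprime, 1.0)), lo, hi


def _haplotype_matrix(genotypes: GenotypeSet) -> np.ndarray:
    """(2n, m) matrix of 0/1 alleles, one row per chromosome copy."""
    if genotypes.phased is None:
        raise ValueError("phased haplotypes required")
    ph = genotypes.phased
    return np.concatenate([ph[:, :, 0], ph[:, :, 1]], axis=0)


def _pair_counts(h: np.ndarray, i: int, j: int) -> np.ndarray:
    a = h[:, i]
    b = h[:, j]
    return np.array(
        [
            [((a == 0) & (b == 0)).sum(), ((a == 0) & (b == 1)).sum()],
            [((a == 1) & (b == 0)).sum(), ((a == 1) & (b == 1)).sum()],
        ],
        dtype=float,
    )


def classify_pair(
    lo: float,
    hi: float,
    strong_low: float = 0.70,
    strong_high: float = 0.98,
    recomb_high: float = 0.90,
) -> str:
    """Gabriel pair class from D' CI bounds: strong / recomb / uninformative."""
    if not np.isfinite(lo) or not np.isfinite(hi):
        return "uninformative"
    if lo >= strong_low and hi >= strong_high:
        return "strong"
    if hi < recomb_high:
        return "recomb"
    return "uninformative"


def gabriel_blocks(
    genotypes: GenotypeSet,
    maf_min: float = 0.05,
    strong_low: float = 0.70,
    strong_high: float = 0.98,
    recomb_high: float = 0.90,
    informative_frac: float = 0.95,
    ci_level: float = 0.90,
) -> list[HaplotypeBlock]:
    """D'-CI haplotype blocks (Gabriel-style, Haploview default cutoffs).

    Site pairs are classified strong-LD / recombination / uninformative
    from their D' confidence bounds; every maximal run of sites in which
    at least ``informative_frac`` of informative pairs are strong-LD
    becomes a block, chosen non-overlapping largest-first.
    """
    maf_ok = np.flatnonzero(genotypes.maf >= maf_min)
    if maf_ok.size < 2:
        return []
    gs = genotypes.subset_variants(maf_ok)
    h = _haplotype_matrix(gs)
    m = gs.n_variants
    classes = np.empty((m, m), dtype=object)
    for i in range(m):
        for j in range(i + 1, m):
            _, lo, hi = dprime_ci(_pair_counts(h, i, j), level=ci_level)
            classes[i, j] = classify_pair(lo, hi, strong_low, strong_high, recomb_high)

    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            pair_classes = [classes[a, b] for a in range(i, j + 1) for b in range(a + 1, j + 1)]
            n_strong = sum(c == "strong" for c in pair_classes)
            n_inform = sum(c != "uninformative" for c in pair_classes)
            if n_inform == 0:
                continue
            if n_strong / n_inform >= informative_frac:
                candidates.append((j - i + 1, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken = np.zeros(m, dtype=bool)
    blocks: list[HaplotypeBlock] = []
    for _, i, j in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        sub = gs.variants.iloc[i : j + 1]
        blocks.append(
            HaplotypeBlock(
                chrom=str(sub["chrom"].iloc[0]),
                start=int(sub["pos"].iloc[0]),
                end=int(sub["pos"].iloc[-1]),
                variant_ids=sub["variant_id"].tolist(),
            )
        )
    blocks.sort(key=lambda b: b.start)
    return blocks


# ---------------------------------------------------------------------------
# Haplotype enumeration and association


def enumerate_haplotypes(
    genotypes: GenotypeSet, focal_variant_id: str, freq_min: float = 0.01
) -> HaplotypeTable:
    """Count distinct phased haplotypes over the window.

    Haplotypes at frequency strictly above ``freq_min`` are labelled
    hap1, hap2, ... by descending frequency; the rest are pooled into a
    rare bin that is excluded from association testing. The focal allele
    of each haplotype is read from the focal site's column.
    """
    vindex = genotypes.variant_index()
    if focal_variant_id not in vindex:
        raise ValueError(f"focal variant {focal_variant_id} absent from window")
    focal_col = vindex[focal_variant_id]
    h = _haplotype_matrix(genotypes)
    n = genotypes.n_samples
    two_n = 2 * n
    strings = ["".join(map(str, row)) for row in h]
    counts: dict[str, int] = {}
    for s in strings:
        counts[s] = counts.get(s, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))

    ref = genotypes.variants["ref"].iloc[focal_col]
    alt = genotypes.variants["alt"].iloc[focal_col]
    hap_of_chrom = pd.Series(strings)
    haplotypes: list[HaplotypeAllele] = []
    rare_copies = np.zeros(n, dtype=int)
    rare_freq = 0.0
    rank = 0
    for s, cnt in ordered:
        freq = cnt / two_n
        member = (hap_of_chrom == s).to_numpy()
        copies = member[:n].astype(int) + member[n:].astype(int)
        if freq > freq_min:
            rank += 1
            haplotypes.append(
                HaplotypeAllele(
                    label=f"hap{rank}",
                    alleles=s,
                    frequency=freq,
                    focal_allele=alt if s[focal_col] == "1" else ref,
                    copies=copies,
                )
            )
        else:
            rare_freq += freq
            rare_copies += copies
    return HaplotypeTable(
        haplotypes=haplotypes,
        rare_frequency=rare_freq,
        rare_copies=rare_copies,
        focal_variant_id=focal_variant_id,
        n_chromosomes=two_n,
    )


def haplotype_assoc(
    hap: HaplotypeAllele,
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    n_tested: int = 1,
) -> HapAssociationResult:
    """Covariate-adjusted logistic association of haplotype copy count.

    ``p_adjusted`` is the Bonferroni correction for the number of
    haplotypes tested in the cohort.
    """
    covariates = covariates or []
    keep = cohort[["status"] + covariates].notna().all(axis=1).to_numpy()
    df = cohort.loc[keep].reset_index(drop=True)
    copies = np.asarray(hap.copies)[keep]
    y = df["status"].to_numpy(dtype=float)
    if np.std(copies) == 0:
        logger.warning("haplotype %s has zero-variance copy counts", hap.label)
        return HapAssociationResult(
            label=hap.label, focal_allele=hap.focal_allele, beta=np.nan, se=np.nan,
            pvalue=np.nan, p_adjusted=np.nan, frequency=hap.frequency,
        )
    X_cov = _design(df, covariates)
    X = np.column_stack([X_cov[:, :1], np.asarray(copies, dtype=float), X_cov[:, 1:]])
    res = _fit_logit(y, X)
    p = float(res.pvalues[1])
    return HapAssociationResult(
        label=hap.label,
        focal_allele=hap.focal_allele,
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        pvalue=p,
        p_adjusted=min(1.0, p * n_tested),
        frequency=hap.frequency,
    )


def conditional_lrt(
    hap: HaplotypeAllele,
    focal_dosage: np.ndarray,
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
) -> tuple[float | None, bool]:
    """1-df LRT: does the haplotype improve on covariates + focal genotype?

    Returns (p, defined). The test is undefined when the haplotype's
    copy counts are collinear with the focal dosage.
    """
    covariates = covariates or []
    keep = cohort[["status"] + covariates].notna().all(axis=1).to_numpy()
    df = cohort.loc[keep].reset_index(drop=True)
    y = df["status"].to_numpy(dtype=float)
    copies = np.asarray(hap.copies, dtype=float)[keep]
    focal = np.asarray(focal_dosage, dtype=float)[keep]
    if np.std(copies) == 0 or np.std(focal) == 0:
        return None, False
    if abs(np.corrcoef(copies, focal)[0, 1]) > 1.0 - 1e-10:
        logger.warning("haplotype %s collinear with focal genotype; LRT undefined", hap.label)
        return None, False
    X_cov = _design(df, covariates)
    X_reduced = np.column_stack([X_cov[:, :1], focal, X_cov[:, 1:]])
    X_full = np.column_stack([X_cov[:, :1], focal, copies, X_cov[:, 1:]])
    res_red = _fit_logit(y, X_reduced)
    res_full = _fit_logit(y, X_full)
    lrt = max(0.0, 2.0 * (res_full.llf - res_red.llf))
    return float(sps.chi2.sf(lrt, df=1)), True


def screen_and_condition(
    table: HaplotypeTable,
    focal_dosage: np.ndarray,
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    screen_alpha: float = 0.05,
) -> list[HapAssociationResult]:
    """Association screen, then the conditional LRT for nominal hits.

    Every common haplotype is tested for association (Bonferroni over
    the tested count); haplotypes with unadjusted p below
    ``screen_alpha`` proceed to the conditional LRT against the focal
    genotype.
    """
    n_tested = len(table.haplotypes)
    results = [
        haplotype_assoc(h, cohort, covariates, n_tested=n_tested) for h in table.haplotypes
    ]
    for hap, res in zip(table.haplotypes, results):
        if np.isfinite(res.pvalue) and res.pvalue < screen_alpha:
            res.lrt_p, res.lrt_defined = conditional_lrt(hap, focal_dosage, cohort, covariates)
    return results


# ---------------------------------------------------------------------------
# Sharing metric, parsimony network, direction concordance


def haplotype_sharing(hap_a: str, hap_b: str, ancestral: str) -> int:
    """Percent of derived alleles shared by two haplotypes.

    Derived alleles are sites where a haplotype differs from the
    ancestral/reference haplotype; the statistic is the Jaccard overlap
    |A ∩ B| / |A ∪ B| of the two derived-allele site sets, reported to
    the nearest percent.
    """
    if not len(hap_a) == len(hap_b) == len(ancestral):
        raise ValueError("haplotypes must cover the same window")
    derived_a = {i for i, (x, r) in enumerate(zip(hap_a, ancestral)) if x != r}
    derived_b = {i for i, (x, r) in enumerate(zip(hap_b, ancestral)) if x != r}
    union = derived_a | derived_b
    if not union:
        return 100  # identical to the ancestral background on every site
    return round(100.0 * len(derived_a & derived_b) / len(union))


def parsimony_connection_limit(n_sites: int, prob: float = 0.95) -> int:
    """Maximum parsimony steps with non-homoplasy probability >= ``prob``.

    Approximates the statistical-parsimony criterion by the probability
    that j mutations strike j distinct sites out of ``n_sites``
    (product_{i<j} (1 - i/n_sites)); the limit is the largest j keeping
    that probability at or above ``prob``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be positive")
    j = 1
    p = 1.0
    while j < n_sites:
        p_next = p * (1.0 - j / n_sites)
        if p_next < prob:
            break
        p = p_next
        j += 1
    return j


def parsimony_network(
    haplotypes: list[HaplotypeAllele] | list[tuple[str, str]],
    connection_limit: int | None = None,
) -> HaplotypeNetwork:
    """Minimum-spanning haplotype network under a parsimony step limit.

    Edges are pairwise Hamming distances; the network keeps, per
    distance class, every edge that joins components that were distinct
    before that class was processed (so all ties with the MST-entering
    weight are retained), and no edge longer than the connection limit.
    Haplotypes that cannot be connected within the limit are returned as
    separate components with a warning.
    """
    if haplotypes and isinstance(haplotypes[0], HaplotypeAllele):
        items = [(h.label, h.alleles) for h in haplotypes]
        freqs = {h.label: h.frequency for h in haplotypes}
    else:
        items = list(haplotypes)
        freqs = {label: None for label, _ in items}
    if len(items) < 2:
        raise ValueError("need at least two haplotypes")
    seqs = [s for _, s in items]
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate haplotype sequences: collapse them first")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("haplotypes must have equal length")
    if connection_limit is None:
        connection_limit = parsimony_connection_limit(length)

    arr = np.array([[int(c) for c in s] for s in seqs])
    dist = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)

    g = nx.Graph()
    for label, s in items:
        g.add_node(label, sequence=s, frequency=freqs[label])
    edges = [
        (int(dist[i, j]), items[i][0], items[j][0])
        for i in range(len(items))
        for j in range(i + 1, len(items))
        if dist[i, j] <= connection_limit
    ]
    edges.sort()
    # union-find with per-distance-class freezing
    parent = {label: label for label, _ in items}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    k = 0
    while k < len(edges):
        w = edges[k][0]
        cls = []
        while k < len(edges) and edges[k][0] == w:
            cls.append(edges[k])
            k += 1
        frozen = {label: find(label) for label, _ in items}
        added = []
        for w_, a, b in cls:
            if frozen[a] != frozen[b]:
                g.add_edge(a, b, distance=w_)
                added.append((a, b))
        for a, b in added:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    net = HaplotypeNetwork(graph=g, connection_limit=int(connection_limit))
    if net.n_components > 1:
        logger.warning(
            "haplotype network split into %d components under limit %d",
            net.n_components, connection_limit,
        )
    return net


def direction_concordance(
    results: list[HapAssociationResult], risk_allele: str
) -> float:
    """Percent of tested haplotypes whose effect sign matches expectation.

    A haplotype carrying the focal risk allele is expected to have a
    positive log-odds effect, any other focal allele a negative one.
    Haplotypes with beta exactly 0 count as discordant (logged).
    """
    tested = [r for r in results if np.isfinite(r.beta)]
    if not tested:
        raise ValueError("no tested haplotypes with an estimated beta")
    n_conc = 0
    for r in tested:
        if r.beta == 0:
            logger.warning("haplotype %s has beta exactly 0: counted discordant", r.label)
            continue
        expected_positive = r.focal_allele == risk_allele
        if (r.beta > 0) == expected_positive:
            n_conc += 1
    return 100.0 * n_conc / len(tested)
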
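"""D' confidence intervals, Gabriel blocks, haplotype enumeration and
association, sharing metric, parsimony network and direction concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from admixprs.haplotypes import (
    HapAssociationResult,
    HaplotypeAllele,
    classify_pair,
    conditional_lrt,
    direction_concordance,
    dprime_ci,
    enumerate_haplotypes,
    gabriel_blocks,
    haplotype_assoc,
    haplotype_sharing,
    parsimony_connection_limit,
    parsimony_network,
)

from conftest import make_genotypes


def _phased_set(h0, h1, **kw):
    h0 = np.asarray(h0, dtype=np.int8)
    h1 = np.asarray(h1, dtype=np.int8)
    return make_genotypes(
        (h0 + h1).astype(float), phased=np.stack([h0, h1], axis=2), **kw
    )


class TestDprimeCi:
    def test_complete_coupling(self):
        counts = np.array([[100, 0], [0, 100]])
        d, lo, hi = dprime_ci(counts)
        assert d == pytest.approx(1.0)
        assert lo > 0.9

    def test_hand_computed_table(self):
        # 40/10/10/40: pA=pB=0.5, p11=0.4, D=0.15, Dmax=0.25 -> D'=0.6
        d, lo, hi = dprime_ci(np.array([[40, 10], [10, 40]]))
        assert d == pytest.approx(0.6)
        assert lo <= d <= hi

    def test_equilibrium_low_ci(self, rng):
        low_bounds = []
        for _ in range(20):
            a = rng.integers(0, 2, 500)
            b = rng.integers(0, 2, 500)
            counts = np.array(
                [[np.sum((a == 0) & (b == 0)), np.sum((a == 0) & (b == 1))],
                 [np.sum((a == 1) & (b == 0)), np.sum((a == 1) & (b == 1))]]
            )
            _, lo, _ = dprime_ci(counts)
            low_bounds.append(lo)
        assert np.median(low_bounds) < 0.7

    def test_monomorphic_site_undefined(self):
        assert np.all(np.isnan(dprime_ci(np.array([[50, 50], [0, 0]]))))

    def test_negative_coupling_symmetric(self):
        d_pos, *_ = dprime_ci(np.array([[40, 10], [10, 40]]))
        d_neg, *_ = dprime_ci(np.array([[10, 40], [40, 10]]))
        assert d_pos == pytest.approx(d_neg)


def _template_window(rng, n=150, m=5, mut=0.01):
    """Near-perfect LD: chromosomes copy one of two complementary templates."""
    t = np.array([[0] * m, [1] * m], dtype=np.int8)
    haps = []
    for _ in range(2):
        pick = rng.integers(0, 2, n)
        h = t[pick].copy()
        flip = rng.random((n, m)) < mut
        h[flip] = 1 - h[flip]
        haps.append(h)
    return _phased_set(haps[0], haps[1], positions=1000 * (np.arange(m) + 1))


class TestGabrielBlocks:
    def test_single_block_under_strong_ld(self, rng):
        gs = _template_window(rng)
        blocks = gabriel_blocks(gs)
        assert len(blocks) == 1
        assert blocks[0].variant_ids == [f"v{j+1}" for j in range(5)]

    def test_independent_sites_give_no_blocks(self, rng):
        h0 = rng.integers(0, 2, size=(200, 6)).astype(np.int8)
        h1 = rng.integers(0, 2, size=(200, 6)).astype(np.int8)
        gs = _phased_set(h0, h1, positions=1000 * (np.arange(6) + 1))
        assert gabriel_blocks(gs) == []

    def test_sample_order_invariance(self, rng):
        gs = _template_window(rng, n=80)
        perm = rng.permutation(80)
        shuffled = make_genotypes(
            gs.dosage[perm], phased=gs.phased[perm],
            positions=gs.variants["pos"].tolist(),
        )
        a = gabriel_blocks(gs)
        b = gabriel_blocks(shuffled)
        assert [blk.variant_ids for blk in a] == [blk.variant_ids for blk in b]

    def test_allele_relabel_invariance(self, rng):
        gs = _template_window(rng, n=80)
        flipped_phased = gs.phased.copy()
        flipped_phased[:, 2, :] = 1 - flipped_phased[:, 2, :]
        flipped = make_genotypes(
            flipped_phased.sum(axis=2).astype(float),
            phased=flipped_phased, positions=gs.variants["pos"].tolist(),
        )
        a = gabriel_blocks(gs)
        b = gabriel_blocks(flipped)
        assert [blk.variant_ids for blk in a] == [blk.variant_ids for blk in b]


def _oracle_blocks(gs, **params):
    """Naive reimplementation: classify all pairs, scan all intervals,
    keep qualifying intervals largest-first without overlap."""
    from admixprs.haplotypes import _haplotype_matrix, _pair_counts

    maf_ok = np.flatnonzero(gs.maf >= params.get("maf_min", 0.05))
    sub = gs.subset_variants(maf_ok)
    h = _haplotype_matrix(sub)
    m = sub.n_variants
    cls = {}
    for i, j in itertools.combinations(range(m), 2):
        _, lo, hi = dprime_ci(_pair_counts(h, i, j))
        cls[(i, j)] = classify_pair(lo, hi)
    chosen = []
    cand = []
    for i, j in itertools.combinations(range(m), 2):
        pairs = [cls[(a, b)] for a, b in itertools.combinations(range(i, j + 1), 2)]
        informative = [c for c in pairs if c != "uninformative"]
        if informative and sum(c == "strong" for c in informative) / len(informative) >= 0.95:
            cand.append((i, j))
    cand.sort(key=lambda ij: (-(ij[1] - ij[0]), ij[0]))
    used = set()
    for i, j in cand:
        if used & set(range(i, j + 1)):
            continue
        used |= set(range(i, j + 1))
        chosen.append(sub.variants["variant_id"].iloc[i : j + 1].tolist())
    return sorted(chosen, key=lambda ids: ids[0])


class TestGabrielOracle:
    def test_matches_brute_force_on_random_windows(self, rng):
        for _ in range(10):
            m = int(rng.integers(4, 9))
            gs = _template_window(rng, n=100, m=m, mut=float(rng.uniform(0.01, 0.3)))
            got = sorted(
                [b.variant_ids for b in gabriel_blocks(gs)], key=lambda ids: ids[0]
            )
            assert got == _oracle_blocks(gs)


class TestEnumerateHaplotypes:
    def _four_chromosomes(self):
        # 2 samples = 4 chromosomes; strings 3:1
        h0 = np.array([[0, 0, 0], [0, 0, 0]], dtype=np.int8)
        h1 = np.array([[0, 0, 0], [1, 0, 1]], dtype=np.int8)
        return _phased_set(h0, h1)

    def test_counting_frequencies(self):
        table = enumerate_haplotypes(self._four_chromosomes(), "v2", freq_min=0.0)
        assert [h.frequency for h in table.haplotypes] == [0.75, 0.25]
        assert table.haplotypes[0].alleles == "000"

    def test_rare_haplotypes_pooled(self, rng):
        n = 300
        h0 = np.zeros((n, 4), dtype=np.int8)
        h1 = np.zeros((n, 4), dtype=np.int8)
        h1[:2] = [1, 1, 0, 0]  # frequency 2/600 = 0.0033 < 0.01
        gs = _phased_set(h0, h1)
        table = enumerate_haplotypes(gs, "v1", freq_min=0.01)
        assert len(table.haplotypes) == 1
        assert table.rare_frequency == pytest.approx(2 / 600)

    def test_copy_counts_sum_to_two(self, rng):
        h0 = rng.integers(0, 2, size=(50, 6)).astype(np.int8)
        h1 = rng.integers(0, 2, size=(50, 6)).astype(np.int8)
        gs = _phased_set(h0, h1)
        table = enumerate_haplotypes(gs, "v3", freq_min=0.0)
        total = table.rare_copies + sum(h.copies for h in table.haplotypes)
        np.testing.assert_array_equal(total, 2)

    def test_frequencies_sum_to_one(self, rng):
        h0 = rng.integers(0, 2, size=(40, 5)).astype(np.int8)
        h1 = rng.integers(0, 2, size=(40, 5)).astype(np.int8)
        table = enumerate_haplotypes(_phased_set(h0, h1), "v1", freq_min=0.02)
        assert sum(h.frequency for h in table.haplotypes) + table.rare_frequency == pytest.approx(1.0)

    def test_focal_absent_errors(self):
        with pytest.raises(ValueError, match="focal"):
            enumerate_haplotypes(self._four_chromosomes(), "nope")

    def test_focal_allele_read_from_column(self):
        table = enumerate_haplotypes(self._four_chromosomes(), "v1", freq_min=0.0)
        by_string = {h.alleles: h.focal_allele for h in table.haplotypes}
        assert by_string["000"] == "A" and by_string["101"] == "G"


class TestHaplotypeAssoc:
    def test_bonferroni_arithmetic(self):
        res = HapAssociationResult(
            label="h", focal_allele="G", beta=0.1, se=0.05,
            pvalue=0.01, p_adjusted=min(1.0, 0.01 * 11), frequency=0.1,
        )
        assert res.p_adjusted == pytest.approx(0.11)

    def test_risk_haplotype_detected(self, rng):
        n = 800
        copies = rng.binomial(2, 0.3, n)
        p = 1 / (1 + np.exp(-(-0.5 + 0.5 * copies)))
        cohort = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(n)],
             "status": (rng.random(n) < p).astype(int)}
        )
        hap = HaplotypeAllele("hap1", "111", 0.3, "G", copies)
        res = haplotype_assoc(hap, cohort, n_tested=3)
        assert res.pvalue < 1e-4
        assert res.p_adjusted == pytest.approx(min(1.0, res.pvalue * 3))

    def test_zero_variance_flagged(self):
        cohort = pd.DataFrame({"sample_id": ["a", "b"], "status": [0, 1]})
        hap = HaplotypeAllele("hap1", "11", 0.5, "G", np.array([1, 1]))
        res = haplotype_assoc(hap, cohort)
        assert np.isnan(res.beta)


class TestConditionalLrt:
    def test_perfect_collinearity_undefined(self, rng):
        n = 100
        copies = rng.binomial(2, 0.3, n)
        cohort = pd.DataFrame(
            {"sample_id": range(n), "status": rng.integers(0, 2, n)}
        )
        hap = HaplotypeAllele("hap1", "11", 0.3, "G", copies)
        p, defined = conditional_lrt(hap, copies.astype(float), cohort)
        assert not defined and p is None

    def test_private_risk_variant_detected(self, rng):
        """Risk carried by a non-focal variant private to the haplotype is
        seen by the LRT even after conditioning on the focal genotype."""
        n = 2000
        hap_copies = rng.binomial(2, 0.25, n)
        focal = np.clip(hap_copies + rng.binomial(2, 0.15, n), 0, 2)  # focal also on other background
        p = 1 / (1 + np.exp(-(-0.6 + 0.5 * hap_copies)))
        cohort = pd.DataFrame(
            {"sample_id": range(n), "status": (rng.random(n) < p).astype(int)}
        )
        hap = HaplotypeAllele("hap1", "11", 0.25, "G", hap_copies)
        p_lrt, defined = conditional_lrt(hap, focal.astype(float), cohort)
        assert defined and p_lrt < 0.05


class TestSharing:
    def test_identical_haplotypes(self):
        assert haplotype_sharing("0110", "0110", "0000") == 100

    def test_disjoint_derived_sets(self):
        assert haplotype_sharing("1100", "0011", "0000") == 0

    def test_hand_jaccard(self):
        # derived sets {1,2,3,4} and {3,4,5,6}: 2 shared of 6 -> 33%
        a = "0111100"
        b = "0001111"
        anc = "0000000"
        assert haplotype_sharing(a, b, anc) == 33

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            haplotype_sharing("01", "011", "000")


class TestParsimonyNetwork:
    def _hap(self, label, s):
        return (label, s)

    def test_triangle_keeps_two_short_edges(self):
        haps = [("a", "0000"), ("b", "0001"), ("c", "0011")]
        net = parsimony_network(haps, connection_limit=5)
        edges = {tuple(sorted(e)) for e in net.graph.edges}
        assert edges == {("a", "b"), ("b", "c")}

    def test_duplicate_sequences_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            parsimony_network([("a", "01"), ("b", "01")])

    def test_ties_at_entering_weight_retained(self):
        # square: four haplotypes each 1 step from two neighbors
        haps = [("a", "00"), ("b", "01"), ("c", "11"), ("d", "10")]
        net = parsimony_network(haps, connection_limit=2)
        assert net.graph.number_of_edges() == 4  # all distance-1 edges kept

    def test_matches_exhaustive_msn_on_hand_instance(self):
        haps = [
            ("h1", "000000"), ("h2", "000001"), ("h3", "000011"),
            ("h4", "011000"), ("h5", "011001"), ("h6", "110011"),
        ]
        seqs = dict(haps)
        dist = {
            (a, b): sum(x != y for x, y in zip(seqs[a], seqs[b]))
            for a, b in itertools.combinations(seqs, 2)
        }
        # oracle: iterative weight classes over an explicit component partition
        comps = {h: {h} for h in seqs}
        expected = set()
        for w in sorted(set(dist.values())):
            cls = [e for e, d in dist.items() if d == w]
            snapshot = {h: frozenset(c) for h, c in comps.items()}
            for a, b in cls:
                if snapshot[a] != snapshot[b]:
                    expected.add(tuple(sorted((a, b))))
            for a, b in cls:
                if comps[a] is not comps[b]:
                    merged = comps[a] | comps[b]
                    for h in merged:
                        comps[h] = merged
        net = parsimony_network(haps, connection_limit=10)
        got = {tuple(sorted(e)) for e in net.graph.edges}
        assert got == expected

    def test_disconnection_under_limit_warns(self, caplog):
        haps = [("a", "000000"), ("b", "111111")]
        net = parsimony_network(haps, connection_limit=2)
        assert net.n_components == 2
        assert any("components" in r.message for r in caplog.records)

    def test_connection_limit_monotone_in_length(self):
        limits = [parsimony_connection_limit(m) for m in (20, 60, 200, 1000)]
        assert limits == sorted(limits)
        assert all(l >= 1 for l in limits)


class TestDirectionConcordance:
    def _res(self, label, focal, beta):
        return HapAssociationResult(
            label=label, focal_allele=focal, beta=beta, se=0.1,
            pvalue=0.5, p_adjusted=1.0, frequency=0.1,
        )

    def test_fully_concordant(self):
        results = [self._res("h1", "G", 0.4), self._res("h2", "A", -0.2)]
        assert direction_concordance(results, "G") == 100.0

    def test_seven_of_eight(self):
        results = [self._res(f"g{i}", "G", 0.1) for i in range(7)]
        results.append(self._res("bad", "G", -0.1))
        assert direction_concordance(results, "G") == pytest.approx(87.5)

    def test_independent_signs_near_half(self, rng):
        rates = []
        for _ in range(200):
            results = [
                self._res(f"h{i}", rng.choice(["A", "G"]), rng.normal())
                for i in range(8)
            ]
            rates.append(direction_concordance(results, "G"))
        assert abs(np.mean(rates) - 50.0) < 5.0
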
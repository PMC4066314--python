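"""Map bins, linkage p-values, group construction, ordering, map statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from jamkit import linkage as lk
from jamkit import simulate as sim


def brute_force_linkage_p(a, b):
    """Enumerate all per-parent call outcomes: P(matches >= m) at p=1/2."""
    ok = (a >= 0) & (b >= 0)
    n = 2 * int(ok.sum())
    best = 1.0
    for r in range(4):
        ar = a[ok] ^ r
        m = int(((ar >> 1) == (b[ok] >> 1)).sum() + ((ar & 1) == (b[ok] & 1)).sum())
        tail = sum(math.comb(n, i) for i in range(m, n + 1)) / 2**n
        best = min(best, tail)
    return best


class TestLinkagePvalue:
    def test_length_one_identical(self):
        # one offspring: n = 2 calls, both match -> 1 - (C(2,0)+C(2,1))/4
        assert lk.linkage_pvalue(np.array([0]), np.array([0])) == pytest.approx(0.25)

    def test_four_offspring_one_mismatch(self):
        a = np.zeros(4, dtype=int)
        b = a.copy()
        b[0] = 1  # one paternal-allele mismatch: m = 7 of n = 8
        assert lk.linkage_pvalue(a, b) == pytest.approx(9 / 256)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, 12)
        base = lk.linkage_pvalue(a, a)
        for r in range(4):
            assert lk.linkage_pvalue(a, a ^ r) == pytest.approx(base)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.integers(0, 4, 10), rng.integers(0, 4, 10)
        assert lk.linkage_pvalue(a, b) == pytest.approx(lk.linkage_pvalue(b, a))

    def test_matches_brute_force_enumeration(self):
        """Exact tail enumeration over all outcomes for n <= 12 calls."""
        rng = np.random.default_rng(2)
        for trial in range(30):
            n_off = int(rng.integers(1, 7))  # up to 12 per-parent calls
            a = rng.integers(0, 4, n_off)
            b = rng.integers(0, 4, n_off)
            assert lk.linkage_pvalue(a, b) == pytest.approx(
                brute_force_linkage_p(a, b), rel=1e-12
            )

    def test_missing_dropped_pairwise(self):
        a = np.array([0, 1, -1, 2])
        b = np.array([0, -1, 3, 2])
        # only positions 0 and 3 compared -> n = 4
        assert lk.linkage_pvalue(a, b) == pytest.approx(
            brute_force_linkage_p(a, b)
        )

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError):
            lk.linkage_pvalue(np.array([-1, 0]), np.array([1, -1]))

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(3)
        pats = [rng.integers(0, 4, 8) for _ in range(6)]
        P = lk._pairwise_pvalues(pats)
        for i in range(6):
            for j in range(i + 1, 6):
                assert P[i, j] == pytest.approx(lk.linkage_pvalue(pats[i], pats[j]))


class TestMapBins:
    def _markers(self, rows):
        return pd.DataFrame(
            [
                {
                    "marker_id": f"m{i}",
                    "pattern": np.array(p),
                    "n_snps": s,
                    "mean_phase_prob": q,
                }
                for i, (p, s, q) in enumerate(rows)
            ]
        )

    def test_three_marker_support(self):
        pat = [0, 1, 2, 3, 0]
        mk = self._markers([(pat, 5, 0.5)] * 3)
        assert len(lk.define_map_bins(mk)) == 1

    def test_single_marker_many_snps(self):
        mk = self._markers([([0, 1, 2, 3, 0], 25, 0.95)])
        bins = lk.define_map_bins(mk)
        assert len(bins) == 1 and bins[0].best_n_snps == 25

    def test_two_small_markers_fail_both(self):
        mk = self._markers([([0, 1, 2, 3, 0], 10, 0.95)] * 2)
        assert lk.define_map_bins(mk) == []

    def test_relabeled_patterns_collapse(self):
        pat = np.array([0, 1, 2, 3, 0])
        mk = self._markers(
            [(pat, 5, 0.5), (pat ^ 2, 5, 0.5), (pat ^ 3, 5, 0.5)]
        )
        bins = lk.define_map_bins(mk)
        assert len(bins) == 1 and bins[0].n_markers == 3


def patterns_from_cross(n_off, n_markers, length, rate, seed, n_chrom=1):
    rng = np.random.default_rng(seed)
    frames = []
    for chrom in range(n_chrom):
        hs = sim.simulate_haplotypes(100, 0.0, 0.0, seed=chrom)
        hs.length = length
        ct = sim.simulate_cross(hs, n_off, rate, rate * 0.6, seed=seed + chrom)
        pos = np.sort(rng.choice(length, n_markers, replace=False))
        for mi, p in enumerate(pos):
            pat = np.array([ct.true_genotype(j, int(p)) for j in range(n_off)])
            frames.append(
                {
                    "marker_id": f"c{chrom}m{mi}",
                    "pattern": pat,
                    "n_snps": 25,
                    "mean_phase_prob": 0.99,
                    "chrom": chrom,
                    "pos": int(p),
                }
            )
    return pd.DataFrame(frames)


class TestGroupsAndOrdering:
    def test_three_chromosomes_recovered(self):
        mk = patterns_from_cross(34, 50, 30_000_000, 1.28, seed=5, n_chrom=3)
        gmap = lk.build_genetic_map(mk, min_support=1)
        assert gmap.n_groups == 3
        for members in gmap.groups:
            chroms = {
                mk[mk.marker_id.isin(gmap.bins[b].marker_ids)]["chrom"].iloc[0]
                for b in members
            }
            assert len(chroms) == 1

    def test_order_matches_truth(self):
        from scipy.stats import kendalltau

        mk = patterns_from_cross(34, 200, 40_000_000, 1.28, seed=9)
        gmap = lk.build_genetic_map(mk, min_support=1)
        members = gmap.groups[0]
        pos = [
            mk[mk.marker_id.isin(gmap.bins[b].marker_ids)]["pos"].mean()
            for b in members
        ]
        tau = abs(kendalltau(np.arange(len(pos)), pos).statistic)
        assert tau >= 0.9

    def test_cluster_matches_union_find(self):
        rng = np.random.default_rng(4)
        pats = [rng.integers(0, 4, 30) for _ in range(20)]
        bins = [
            lk.MapBin(id=i, pattern=p, marker_ids=[f"m{i}"], n_markers=1,
                      best_n_snps=20, best_mean_phase_prob=1.0)
            for i, p in enumerate(pats)
        ]
        p1 = 1e-3
        P = lk._pairwise_pvalues(pats)
        groups = lk.cluster_linkage_groups(bins, p1, P)
        # union-find oracle
        parent = list(range(20))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(20):
            for j in range(i + 1, 20):
                if P[i, j] < p1:
                    parent[find(i)] = find(j)
        oracle = {}
        for i in range(20):
            oracle.setdefault(find(i), set()).add(i)
        assert sorted(map(sorted, groups)) == sorted(
            sorted(s) for s in oracle.values()
        )

    def test_articulation_barbell(self):
        """A bridge bin joining two dense cliques is removed."""
        # explicit p-value matrix: bins 0-4 a clique, 5-9 a clique, bin 10
        # strongly linked into both; no direct clique-to-clique linkage
        B = 11
        P = np.ones((B, B))
        strong = 1e-12
        for grp in (range(0, 5), range(5, 10)):
            for i in grp:
                for j in grp:
                    if i != j:
                        P[i, j] = strong
        for i in range(10):
            P[10, i] = P[i, 10] = strong
        np.fill_diagonal(P, 0.0)
        bins = [
            lk.MapBin(id=i, pattern=np.zeros(30, dtype=int), marker_ids=[f"b{i}"],
                      n_markers=1, best_n_snps=20, best_mean_phase_prob=1.0)
            for i in range(B)
        ]
        removed, groups = lk.filter_articulation_bins(
            bins, threshold_pairs=((1e-10, 1e-6),), pvalues=P
        )
        assert removed == [10]
        assert len(groups) == 2

    def test_articulation_matches_networkx_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(8)
        pats = [rng.integers(0, 4, 26) for _ in range(15)]
        bins = [
            lk.MapBin(id=i, pattern=p, marker_ids=[f"m{i}"], n_markers=1,
                      best_n_snps=20, best_mean_phase_prob=1.0)
            for i, p in enumerate(pats)
        ]
        P = lk._pairwise_pvalues(pats)
        p1, p2 = 1e-4, 1e-2
        removed, _ = lk.filter_articulation_bins(bins, ((p1, p2),), P)
        G1 = nx.Graph(np.triu(P < p1, 1))
        G2 = nx.Graph(np.triu(P < p2, 1))
        oracle = set()
        for comp in nx.connected_components(G1):
            oracle |= set(nx.articulation_points(G2.subgraph(comp)))
        assert set(removed) == oracle

    def test_biconnected_untouched(self):
        mk = patterns_from_cross(30, 10, 5_000_000, 1.28, seed=13)
        pats = [np.asarray(p) for p in mk["pattern"]]
        bins = [
            lk.MapBin(id=i, pattern=p, marker_ids=[f"m{i}"], n_markers=1,
                      best_n_snps=20, best_mean_phase_prob=1.0)
            for i, p in enumerate(pats)
        ]
        removed, _ = lk.filter_articulation_bins(bins, ((1e-10, 1e-6),))
        # tightly linked markers form a near-clique: no articulation points
        assert removed == []

    def test_harmonize_recovers_scrambled_labels(self):
        mk = patterns_from_cross(34, 20, 20_000_000, 1.28, seed=15)
        rng = np.random.default_rng(0)
        pats = [np.asarray(p) ^ rng.integers(0, 4) for p in mk["pattern"]]
        bins = [
            lk.MapBin(id=i, pattern=p.copy(), marker_ids=[f"m{i}"], n_markers=1,
                      best_n_snps=20, best_mean_phase_prob=1.0)
            for i, p in enumerate(pats)
        ]
        lk.harmonize_labels(bins, list(range(len(bins))))
        # after harmonization every pair agrees under the identity relabeling
        # at least as well as under any other
        for i in range(len(bins)):
            for j in range(i + 1, len(bins)):
                a, b = bins[i].pattern, bins[j].pattern
                m_id = ((a >> 1) == (b >> 1)).sum() + ((a & 1) == (b & 1)).sum()
                best = max(
                    (((a ^ r) >> 1) == (b >> 1)).sum()
                    + (((a ^ r) & 1) == (b & 1)).sum()
                    for r in range(4)
                )
                assert m_id >= best * 0.75  # global consistency, not pairwise max

    def test_harmonize_identity_when_consistent(self):
        mk = patterns_from_cross(20, 10, 10_000_000, 1.28, seed=17)
        bins = [
            lk.MapBin(id=i, pattern=np.asarray(p).copy(), marker_ids=[f"m{i}"],
                      n_markers=1, best_n_snps=20, best_mean_phase_prob=1.0)
            for i, p in enumerate(mk["pattern"])
        ]
        applied = lk.harmonize_labels(bins, list(range(len(bins))))
        assert all(r == 0 for r in applied.values())


class TestAnchoring:
    def test_identical_pattern_anchors(self):
        rng = np.random.default_rng(5)
        pats = [rng.integers(0, 4, 34) for _ in range(10)]
        bins = [
            lk.MapBin(id=i, pattern=p, marker_ids=[f"m{i}"], n_markers=1,
                      best_n_snps=20, best_mean_phase_prob=1.0)
            for i, p in enumerate(pats)
        ]
        bid, p = lk.anchor_marker(pats[3], bins)
        assert bid == 3
        assert p < 1e-6  # n = 68 identical calls

    def test_relabeled_pattern_anchors_same_bin(self):
        rng = np.random.default_rng(6)
        pats = [rng.integers(0, 4, 34) for _ in range(10)]
        bins = [
            lk.MapBin(id=i, pattern=p, marker_ids=[f"m{i}"], n_markers=1,
                      best_n_snps=20, best_mean_phase_prob=1.0)
            for i, p in enumerate(pats)
        ]
        bid, _ = lk.anchor_marker(pats[3] ^ 2, bins)
        assert bid == 3

    def test_random_pattern_unplaced(self):
        rng = np.random.default_rng(7)
        bins = [
            lk.MapBin(id=i, pattern=rng.integers(0, 4, 34), marker_ids=[f"m{i}"],
                      n_markers=1, best_n_snps=20, best_mean_phase_prob=1.0)
            for i in range(100)
        ]
        unplaced = 0
        for _ in range(20):
            bid, _ = lk.anchor_marker(rng.integers(0, 4, 34), bins)
            unplaced += bid is None
        assert unplaced >= 19


class TestMapStatistics:
    def test_haldane_values(self):
        assert lk.haldane_distance(0.0) == 0.0
        assert lk.haldane_distance(0.25) == pytest.approx(0.3466, abs=1e-4)
        assert lk.haldane_distance(0.001) == pytest.approx(0.001, rel=0.01)

    def test_haldane_roundtrip(self):
        for r in (0.0, 0.1, 0.25, 0.4, 0.49):
            assert lk.haldane_inverse(lk.haldane_distance(r)) == pytest.approx(
                r, abs=1e-12
            )

    def test_haldane_domain(self):
        with pytest.raises(ValueError):
            lk.haldane_distance(0.5)

    def test_watterson_reference_value(self):
        assert lk.watterson_theta(0.0076, 4) == pytest.approx(0.0042, abs=5e-5)
        assert lk.watterson_theta(0.0076, 4, finite_sites=False) == pytest.approx(
            0.0076 / (11 / 6)
        )

    def test_watterson_two_haplotypes_identity(self):
        x = 0.003
        assert lk.watterson_theta(x, 2, finite_sites=False) == pytest.approx(x)

    def test_watterson_unbiased_on_simulation(self):
        theta = 0.005
        dens = np.mean(
            [
                sim.simulate_haplotypes(100_000, theta, 0.0085, seed=s).snp_density
                for s in range(10)
            ]
        )
        assert lk.watterson_theta(dens, 4) == pytest.approx(theta, rel=0.05)

    def test_segregation_distortion(self):
        balanced = np.array([0, 3] * 17)  # 17:17 both parents
        assert lk.segregation_distortion(balanced) == 1.0
        skewed = np.array([0] * 30 + [2] * 4)  # 30:4 maternal
        assert lk.segregation_distortion(skewed) < 0.001

    def test_distortion_type_one_error(self):
        rng = np.random.default_rng(9)
        alpha = 0.05
        hits = sum(
            lk.segregation_distortion(rng.integers(0, 4, 34)) < alpha
            for _ in range(400)
        )
        # Bonferroni x2 over two exact binomial tests: at most ~5% flagged
        assert hits / 400 <= 0.07

    def test_local_rate_flat_profile(self):
        mk = patterns_from_cross(34, 40, 40_000_000, 1.28, seed=19)
        gmap = lk.build_genetic_map(mk, min_support=1)
        members = gmap.groups[0]
        ordered = [gmap.bins[b] for b in members]
        rates = lk.local_recombination_rate(ordered, bp_per_marker=1_000_000)
        assert np.isfinite(rates).all()
        assert (rates >= 0).all()

    def test_zero_recombination_rate_zero(self):
        pats = [np.full(20, 0), np.full(20, 0), np.full(20, 3)]
        bins = [
            lk.MapBin(id=i, pattern=p, marker_ids=[f"m{i}"], n_markers=1,
                      best_n_snps=20, best_mean_phase_prob=1.0)
            for i, p in enumerate(pats[:2])
        ]
        rates = lk.local_recombination_rate(bins, bp_per_marker=1e6)
        assert np.allclose(rates, 0.0)

    def test_correlate_tracks(self):
        x = np.arange(10.0)
        r, r2, p = lk.correlate_bin_tracks(x, x)
        assert r == pytest.approx(1.0)
        # hand-computed 5-point example
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([2.0, 1, 4, 3, 6])
        r, r2, _ = lk.correlate_bin_tracks(a, b)
        num = ((a - a.mean()) * (b - b.mean())).sum()
        den = math.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        assert r == pytest.approx(num / den)
        with pytest.raises(ValueError):
            lk.correlate_bin_tracks(np.ones(5), b)

    def test_independent_tracks_r2_near_zero(self):
        rng = np.random.default_rng(10)
        r2s = [
            lk.correlate_bin_tracks(rng.normal(size=200), rng.normal(size=200))[1]
            for _ in range(20)
        ]
        assert np.mean(r2s) < 0.02
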
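"""Macro-synteny and WGD analyses: RBH, enrichment, paralogons, Ks mixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from jamkit import comparative as cp


def hit_frame(rows):
    return pd.DataFrame(rows, columns=["query", "subject", "evalue", "score"])


class TestRBH:
    def test_mutual_best_pair(self):
        ab = hit_frame([("A", "X", 1e-20, 200.0)])
        ba = hit_frame([("X", "A", 1e-20, 200.0)])
        out = cp.reciprocal_best_hits(ab, ba)
        assert out.to_dict("records") == [{"marker": "A", "gene": "X"}]

    def test_asymmetric_best_no_pair(self):
        ab = hit_frame([("A", "X", 1e-20, 200.0)])
        ba = hit_frame([("X", "B", 1e-30, 300.0), ("X", "A", 1e-20, 200.0)])
        assert len(cp.reciprocal_best_hits(ab, ba)) == 0

    def test_evalue_threshold(self):
        ab = hit_frame([("A", "X", 1e-3, 200.0)])
        ba = hit_frame([("X", "A", 1e-20, 200.0)])
        assert len(cp.reciprocal_best_hits(ab, ba, evalue_threshold=1e-5)) == 0

    def test_matches_double_argmax_oracle(self):
        rng = np.random.default_rng(0)
        queries = [f"q{i}" for i in range(12)]
        subjects = [f"s{i}" for i in range(10)]
        rows_ab, rows_ba = [], []
        score = {}
        for q in queries:
            for s in subjects:
                if rng.random() < 0.4:
                    sc = float(rng.integers(50, 500))
                    score[(q, s)] = sc
                    rows_ab.append((q, s, 1e-10, sc))
                    rows_ba.append((s, q, 1e-10, sc))
        out = cp.reciprocal_best_hits(hit_frame(rows_ab), hit_frame(rows_ba))
        got = {(r.marker, r.gene) for r in out.itertuples()}
        # oracle: symmetric double argmax
        oracle = set()
        for q in queries:
            qs = {s: sc for (qq, s), sc in score.items() if qq == q}
            if not qs:
                continue
            s_best = max(sorted(qs), key=lambda s: qs[s])
            sq = {qq: sc for (qq, s), sc in score.items() if s == s_best}
            q_best = max(sorted(sq), key=lambda q2: sq[q2])
            if q_best == q:
                oracle.add((q, s_best))
        assert got == oracle

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cp.reciprocal_best_hits(hit_frame([]), hit_frame([("a", "b", 0, 1)]))


class TestAlgEnrichment:
    def test_extreme_bin(self):
        orth = pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(100)],
                "gene": [f"g{i}" for i in range(100)],
                "map_index": list(range(100)),
            }
        )
        alg = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(100)],
                "alg": ["ALG7"] * 50 + ["ALG1"] * 50,
            }
        )
        out = cp.alg_enrichment(orth, alg, bin_size=50)
        top = out[(out.bin == 0) & (out.alg == "ALG7")].iloc[0]
        assert top.significant and top.p < 1e-10

    def test_fisher_equals_hypergeometric(self):
        """Exhaustive small 2x2 tables: one-sided Fisher = hypergeom tail."""
        for n in range(2, 16):
            for k_bin in range(1, n):
                for k_alg in range(1, n):
                    for k in range(max(0, k_bin + k_alg - n), min(k_bin, k_alg) + 1):
                        table = [
                            [k, k_bin - k],
                            [k_alg - k, n - k_bin - k_alg + k],
                        ]
                        p_f = stats.fisher_exact(table, alternative="greater").pvalue
                        p_h = stats.hypergeom.sf(k - 1, n, k_alg, k_bin)
                        assert p_f == pytest.approx(p_h, rel=1e-9, abs=1e-12)

    def test_bonferroni_factor(self):
        rng = np.random.default_rng(1)
        n = 3000
        orth = pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(n)],
                "gene": [f"g{i}" for i in range(n)],
                "map_index": rng.permutation(n),
            }
        )
        alg = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(n)],
             "alg": rng.choice([f"ALG{j}" for j in range(18)], n)}
        )
        out = cp.alg_enrichment(orth, alg, bin_size=1000)
        assert out.attrs["n_tests"] == 3 * 18
        # random assignment: nothing significant after correction
        assert not out.significant.any()


def make_best_hits(rows):
    return pd.DataFrame(rows, columns=["marker", "gene", "group", "index"])


class TestParalogPairs:
    def test_pair_enumeration(self):
        bh = make_best_hits(
            [("a", "g1", 0, 1), ("b", "g1", 0, 5), ("c", "g1", 1, 2)]
        )
        pairs, summary = cp.paralog_pairs(bh)
        assert len(pairs) == 3  # C(3,2)
        assert summary["n_tandem"] == 1

    def test_gene_cap_excludes(self):
        bh = make_best_hits([(f"m{i}", "g1", 0, i) for i in range(6)])
        pairs, _ = cp.paralog_pairs(bh, max_markers_per_gene=5)
        assert pairs == []

    def test_tandem_classification(self):
        bh = make_best_hits([("a", "g1", 2, 1), ("b", "g1", 2, 9)])
        pairs, summary = cp.paralog_pairs(bh)
        assert pairs[0].tandem
        assert summary["same_group_fraction"] == 1.0


def brute_force_clusters(pairs, max_gap, mp):
    """O(n^2) chaining oracle over inter-chromosomal pairs."""
    inter = [p for p in pairs if not p.tandem]
    norm = []
    for p in inter:
        if p.group_a < p.group_b:
            norm.append((p.group_a, p.group_b, p.index_a, p.index_b, p.gene))
        else:
            norm.append((p.group_b, p.group_a, p.index_b, p.index_a, p.gene))
    clusters = []
    used = [False] * len(norm)
    for i in range(len(norm)):
        if used[i]:
            continue
        comp = [i]
        used[i] = True
        frontier = [i]
        while frontier:
            x = frontier.pop()
            for j in range(len(norm)):
                if used[j]:
                    continue
                if (
                    norm[x][0] == norm[j][0]
                    and norm[x][1] == norm[j][1]
                    and abs(norm[x][2] - norm[j][2]) <= max_gap
                    and abs(norm[x][3] - norm[j][3]) <= max_gap
                ):
                    used[j] = True
                    comp.append(j)
                    frontier.append(j)
        genes = {norm[j][4] for j in comp}
        if len(genes) >= mp:
            clusters.append(frozenset(comp))
    return clusters


def random_pairs(rng, n, n_groups=4, span=1000):
    pairs = []
    for i in range(n):
        ga, gb = rng.choice(n_groups, 2, replace=False)
        pairs.append(
            cp.ParalogPair(
                marker_a=f"a{i}", marker_b=f"b{i}", gene=f"g{rng.integers(n // 2)}",
                group_a=int(ga), group_b=int(gb),
                index_a=int(rng.integers(span)), index_b=int(rng.integers(span)),
            )
        )
    return pairs


class TestMaxGapClusters:
    def test_toy_six_pairs(self):
        pairs = [
            cp.ParalogPair(f"a{i}", f"b{i}", f"g{i}", 0, 1, i * 5, 100 + i * 5)
            for i in range(6)
        ]
        assert len(cp.max_gap_clusters(pairs, max_gap=10, mp=6)) == 1
        assert len(cp.max_gap_clusters(pairs, max_gap=10, mp=7)) == 0

    def test_single_pair_below_mp(self):
        pairs = [cp.ParalogPair("a", "b", "g", 0, 1, 5, 9)]
        assert cp.max_gap_clusters(pairs, max_gap=100, mp=2) == []

    def test_shared_gene_counts_once_toward_mp(self):
        pairs = [
            cp.ParalogPair(f"a{i}", f"b{i}", "same_gene", 0, 1, i, 100 + i)
            for i in range(6)
        ]
        assert cp.max_gap_clusters(pairs, max_gap=10, mp=2) == []

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            pairs = random_pairs(rng, int(rng.integers(5, 60)))
            max_gap = int(rng.integers(10, 400))
            mp = int(rng.integers(2, 6))
            got = cp.max_gap_clusters(pairs, max_gap, mp)
            oracle = brute_force_clusters(pairs, max_gap, mp)
            got_sets = {
                frozenset(frozenset((p.marker_a, p.marker_b)) for p in cl.pairs) for cl in got
            }
            inter = [p for p in pairs if not p.tandem]
            norm_pairs = []
            for p in inter:
                norm_pairs.append(p)
            oracle_sets = {
                frozenset(
                    frozenset((norm_pairs[j].marker_a, norm_pairs[j].marker_b))
                    for j in comp
                )
                for comp in oracle
            }
            assert got_sets == oracle_sets

    def test_footprint_merging(self):
        c1 = cp.MaxGapCluster([], 0, 1, (0, 100), (50, 120))
        c2 = cp.MaxGapCluster([], 0, 2, (80, 200), (0, 40))
        merged = cp.merged_footprints([c1, c2])
        assert (0, 0, 200) in merged
        assert cp.footprint_coverage([c1, c2]) == 201 + 71 + 41


class TestPermutationNull:
    def _clustered_hits(self, rng):
        """Planted paralogon: genes duplicated between groups 0 and 1 in a
        tight index window, plus random background."""
        rows = []
        for i in range(8):
            rows.append((f"p{i}a", f"pg{i}", 0, 10 + i * 3))
            rows.append((f"p{i}b", f"pg{i}", 1, 500 + i * 3))
        for i in range(120):
            rows.append((f"r{i}", f"rg{rng.integers(80)}", int(rng.integers(4)),
                         int(rng.integers(1000))))
        return make_best_hits(rows)

    def test_planted_structure_significant(self):
        rng = np.random.default_rng(5)
        bh = self._clustered_hits(rng)
        out = cp.permutation_null(bh, n_perm=200, max_gap=30, mp=6, seed=1)
        assert out["observed_clusters"] >= 1
        assert out["p_empirical"] <= 1 / 200
        assert out["observed_clusters"] > out["null_mean"]

    def test_null_preserves_marker_universe(self):
        rng = np.random.default_rng(6)
        bh = self._clustered_hits(rng)
        # permuting the observed data itself: observed should sit inside null
        perm = bh.copy()
        g = perm["gene"].to_numpy()
        perm["gene"] = g[rng.permutation(len(g))]
        out = cp.permutation_null(perm, n_perm=100, max_gap=30, mp=4, seed=2)
        assert out["p_empirical"] > 0.05

    def test_exclude_tandem_variant_runs(self):
        rng = np.random.default_rng(7)
        bh = self._clustered_hits(rng)
        out = cp.permutation_null(
            bh, n_perm=50, exclude_tandem=True, max_gap=30, mp=6, seed=3
        )
        assert out["exclude_tandem"] is True


class TestSameAlgExcess:
    def test_all_pairs_same_alg(self):
        pairs = [
            cp.ParalogPair(f"a{i}", f"b{i}", f"g{i}", 0, 1, i, i) for i in range(5)
        ]
        segs = [(0, 0, 100, "ALG1"), (1, 0, 100, "ALG1")]
        out = cp.same_alg_excess(pairs, segs)
        assert out["observed_same_alg"] == 5

    def test_different_alg_zero(self):
        pairs = [cp.ParalogPair("a", "b", "g", 0, 1, 5, 5)]
        segs = [(0, 0, 100, "ALG1"), (1, 0, 100, "ALG2")]
        assert cp.same_alg_excess(pairs, segs)["observed_same_alg"] == 0


class TestParalogonGraph:
    def test_triangle_coefficient_one(self):
        clusters = [
            cp.MaxGapCluster([], 0, 1, (0, 10), (0, 10)),
            cp.MaxGapCluster([], 1, 2, (0, 10), (0, 10)),
            cp.MaxGapCluster([], 0, 2, (0, 10), (0, 10)),
        ]
        out = cp.paralogon_graph_clustering(clusters, n_random=200, seed=0)
        assert out["clustering_coefficient"] == pytest.approx(1.0)

    def test_er_null_mean_near_edge_probability(self):
        import networkx as nx

        rng = np.random.default_rng(1)
        vals = [
            nx.average_clustering(nx.fast_gnp_random_graph(30, 0.3, seed=int(s)))
            for s in rng.integers(0, 10**6, 200)
        ]
        assert np.mean(vals) == pytest.approx(0.3, abs=0.03)

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            cp.paralogon_graph_clustering(
                [cp.MaxGapCluster([], 0, 1, (0, 5), (0, 5))]
            )


class TestKsMixture:
    def test_recovers_reference_two_component_model(self):
        rng = np.random.default_rng(0)
        n = 500
        comp = rng.random(n) < 0.55
        ks = np.where(comp, rng.normal(0.70, 0.14, n), rng.normal(1.45, 0.45, n))
        fits, best = cp.ks_mixture(ks, seed=1)
        assert best.n_components == 2
        assert best.means[0] == pytest.approx(0.70, abs=0.1)
        assert best.means[1] == pytest.approx(1.45, abs=0.1)

    def test_single_gaussian_selects_one(self):
        rng = np.random.default_rng(2)
        ks = rng.normal(1.0, 0.2, 400).clip(0, 2.5)
        _, best = cp.ks_mixture(ks, components=(1, 2, 3), seed=3)
        assert best.n_components == 1

    def test_bic_aic_algebra(self):
        rng = np.random.default_rng(4)
        ks = rng.normal(1.0, 0.3, 300).clip(0, 2.5)
        fits, _ = cp.ks_mixture(ks, components=(2,), seed=5)
        f = fits[0]
        assert f.k_params == 5
        assert f.bic - f.aic == pytest.approx(f.k_params * (np.log(f.n) - 2))
        assert f.bic == pytest.approx(-2 * f.log_likelihood + 5 * np.log(f.n))

    def test_component_count_recovery_well_separated(self):
        """BIC picks the true count for well-separated mixtures."""
        rng = np.random.default_rng(6)
        hits = 0
        for t in range(6):
            comp = rng.random(500) < 0.5
            x = np.where(comp, rng.normal(0.4, 0.08, 500), rng.normal(1.6, 0.12, 500))
            _, best = cp.ks_mixture(x, components=(1, 2, 3), seed=t)
            hits += best.n_components == 2
        assert hits >= 5

    def test_range_restriction(self):
        rng = np.random.default_rng(7)
        ks = np.concatenate([rng.normal(1.0, 0.2, 100), np.full(50, 5.0)])
        fits, _ = cp.ks_mixture(ks, components=(1,), seed=8)
        assert fits[0].n == (ks <= 2.5).sum()

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            cp.ks_mixture(np.linspace(0, 2, 10))
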
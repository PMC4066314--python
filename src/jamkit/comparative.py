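"""Macro-synteny and whole-genome-duplication analyses on mapped markers.

Mapped markers are tied to out-group genes by reciprocal-best-hit
orthology; bins of the map are tested for enrichment in ancestral
linkage group (ALG) content by Fisher's exact test with Bonferroni
correction.  Pairs of mapped markers sharing a best-hit out-group gene
are candidate paralogs: same-chromosome pairs are classed as tandem;
inter-chromosomal pairs are chained into max-gap clusters ("paralogons")
whose significance is assessed against permutations of gene identities,
optionally excluding tandem-involved genes.  The paralogon overlap graph
is compared with Erdos-Renyi nulls via its clustering coefficient, and
the age distribution of paralog pairs is modeled by univariate Gaussian
mixtures on Ks in [0, 2.5] selected by BIC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# reciprocal best hits


def reciprocal_best_hits(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    evalue_threshold: float = 1e-5,
) -> pd.DataFrame:
    """Mutual best-scoring pairs from two directed hit tables.

    Tables need columns query, subject, evalue, score.  Best hit per query
    is the maximum score (ties broken by lower e-value, then subject id
    for determinism); a pair (a, x) is RBH when a's best hit is x and x's
    best hit is a, and both directions pass the e-value threshold.
    """
    for df in (hits_ab, hits_ba):
        if df.empty:
            raise ValueError("empty hit table")

    def best(df):
        df = df[df["evalue"] <= evalue_threshold]
        df = df.sort_values(
            ["query", "score", "evalue", "subject"],
            ascending=[True, False, True, True],
        )
        return df.drop_duplicates("query", keep="first").set_index("query")["subject"]

    ab = best(hits_ab)
    ba = best(hits_ba)
    rows = []
    for q, s in ab.items():
        if ba.get(s) == q:
            rows.append({"marker": q, "gene": s})
    out = pd.DataFrame(rows, columns=["marker", "gene"])
    return out


# ---------------------------------------------------------------------------
# ALG enrichment


def alg_enrichment(
    orthologs: pd.DataFrame,
    alg_map: pd.DataFrame,
    bin_size: int = 1000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher's exact enrichment of ALG content per map bin.

    `orthologs` columns: marker, gene, map_index (position along the
    concatenated ordered map in markers); `alg_map` columns: gene, alg.
    The map is divided into non-overlapping bins of `bin_size` markers;
    each (bin, ALG) 2x2 table (in-bin & in-ALG vs not) is tested and
    Bonferroni-corrected over bins x ALGs tests.
    """
    df = orthologs.merge(alg_map, on="gene", how="inner")
    if df.empty:
        raise ValueError("no orthologs with ALG assignments")
    df = df.copy()
    df["bin"] = (df["map_index"] // bin_size).astype(int)
    algs = sorted(df["alg"].unique())
    bins = sorted(df["bin"].unique())
    n_tests = len(bins) * len(algs)
    total = len(df)
    rows = []
    for b in bins:
        in_bin = df["bin"] == b
        nb = int(in_bin.sum())
        if nb == 0:
            continue
        for alg in algs:
            in_alg = df["alg"] == alg
            k = int((in_bin & in_alg).sum())
            table = [
                [k, nb - k],
                [int(in_alg.sum()) - k, total - nb - int(in_alg.sum()) + k],
            ]
            p = stats.fisher_exact(table, alternative="greater").pvalue
            rows.append(
                {
                    "bin": b,
                    "alg": alg,
                    "in_bin_in_alg": k,
                    "p": float(p),
                    "p_bonferroni": float(min(1.0, p * n_tests)),
                    "significant": bool(p * n_tests < alpha),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = n_tests
    return out


# ---------------------------------------------------------------------------
# paralog pairs


@dataclass
class ParalogPair:
    marker_a: str
    marker_b: str
    gene: str
    group_a: int
    group_b: int
    index_a: int  # order index within the linkage group
    index_b: int

    @property
    def tandem(self) -> bool:
        return self.group_a == self.group_b


def paralog_pairs(
    best_hits: pd.DataFrame, max_markers_per_gene: int = 5
) -> tuple[list[ParalogPair], dict]:
    """Pairs of mapped markers sharing a best-hit out-group gene.

    `best_hits` columns: marker, gene, group, index (map position).  Genes
    hit by more than `max_markers_per_gene` markers are excluded (they are
    likely repeats rather than genes).  Same-group pairs are classed
    tandem; the summary reports the same-group fraction and the mean
    within-group squared position correlation.
    """
    pairs: list[ParalogPair] = []
    for gene, sub in best_hits.groupby("gene"):
        if len(sub) > max_markers_per_gene or len(sub) < 2:
            continue
        recs = sub.to_dict("records")
        for r1, r2 in itertools.combinations(recs, 2):
            if r1["marker"] == r2["marker"]:
                continue
            pairs.append(
                ParalogPair(
                    marker_a=r1["marker"],
                    marker_b=r2["marker"],
                    gene=gene,
                    group_a=int(r1["group"]),
                    group_b=int(r2["group"]),
                    index_a=int(r1["index"]),
                    index_b=int(r2["index"]),
                )
            )
    tandem = [p for p in pairs if p.tandem]
    summary = {
        "n_pairs": len(pairs),
        "n_tandem": len(tandem),
        "same_group_fraction": len(tandem) / len(pairs) if pairs else np.nan,
    }
    r2s = []
    if tandem:
        td = pd.DataFrame(
            {"g": [p.group_a for p in tandem], "x": [p.index_a for p in tandem],
             "y": [p.index_b for p in tandem]}
        )
        for g, sub in td.groupby("g"):
            if len(sub) >= 3 and sub["x"].nunique() > 1 and sub["y"].nunique() > 1:
                r, _ = stats.pearsonr(sub["x"], sub["y"])
                r2s.append(r * r)
    summary["tandem_position_r2_mean"] = float(np.mean(r2s)) if r2s else np.nan
    return pairs, summary


# ---------------------------------------------------------------------------
# max-gap clusters


@dataclass
class MaxGapCluster:
    """A chained set of inter-chromosomal paralog pairs: a paralogon."""

    pairs: list[ParalogPair]
    group_a: int
    group_b: int
    footprint_a: tuple[int, int]  # inclusive marker-index interval
    footprint_b: tuple[int, int]

    @property
    def n_independent(self) -> int:
        return len({p.gene for p in self.pairs})

    @property
    def span(self) -> int:
        return (self.footprint_a[1] - self.footprint_a[0] + 1) + (
            self.footprint_b[1] - self.footprint_b[0] + 1
        )


def max_gap_clusters(
    pairs: list[ParalogPair], max_gap: int = 300, mp: int = 6
) -> list[MaxGapCluster]:
    """Transitive max-gap chaining of inter-chromosomal paralog pairs.

    Two pairs belong to the same cluster when they relate the same
    (oriented) pair of linkage groups and lie within `max_gap` markers in
    both footprints; clusters are kept when they contain at least `mp`
    independent pairs (pairs seeded by distinct out-group genes count once).
    """
    inter = []
    for p in pairs:
        if p.tandem:
            continue
        # orient each pair so group_a < group_b for a stable footprint side
        if (p.group_a, p.index_a) <= (p.group_b, p.index_b) and p.group_a < p.group_b:
            inter.append(p)
        else:
            inter.append(
                ParalogPair(
                    marker_a=p.marker_b, marker_b=p.marker_a, gene=p.gene,
                    group_a=p.group_b, group_b=p.group_a,
                    index_a=p.index_b, index_b=p.index_a,
                )
            )
    clusters: list[MaxGapCluster] = []
    keyfn = lambda p: (p.group_a, p.group_b)
    for (ga, gb), grp in itertools.groupby(sorted(inter, key=keyfn), key=keyfn):
        members = list(grp)
        n = len(members)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if (
                    abs(members[i].index_a - members[j].index_a) <= max_gap
                    and abs(members[i].index_b - members[j].index_b) <= max_gap
                ):
                    parent[find(i)] = find(j)
        comp: dict[int, list[ParalogPair]] = {}
        for i in range(n):
            comp.setdefault(find(i), []).append(members[i])
        for mem in comp.values():
            cl = MaxGapCluster(
                pairs=mem,
                group_a=ga,
                group_b=gb,
                footprint_a=(min(p.index_a for p in mem), max(p.index_a for p in mem)),
                footprint_b=(min(p.index_b for p in mem), max(p.index_b for p in mem)),
            )
            if cl.n_independent >= mp:
                clusters.append(cl)
    return clusters


def merged_footprints(clusters: list[MaxGapCluster]) -> list[tuple[int, int, int]]:
    """Non-redundant union of cluster footprints: (group, start, end)."""
    by_group: dict[int, list[tuple[int, int]]] = {}
    for cl in clusters:
        by_group.setdefault(cl.group_a, []).append(cl.footprint_a)
        by_group.setdefault(cl.group_b, []).append(cl.footprint_b)
    merged = []
    for g, ivals in by_group.items():
        ivals.sort()
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                merged.append((g, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((g, cur_s, cur_e))
    return merged


def footprint_coverage(clusters: list[MaxGapCluster]) -> int:
    """Markers covered by the merged, non-redundant paralogon footprints."""
    return sum(e - s + 1 for _, s, e in merged_footprints(clusters))


# ---------------------------------------------------------------------------
# permutation nulls


def _tandem_genes(pairs: list[ParalogPair]) -> set[str]:
    return {p.gene for p in pairs if p.tandem}


def permutation_null(
    best_hits: pd.DataFrame,
    n_perm: int = 1000,
    exclude_tandem: bool = False,
    max_gap: int = 300,
    mp: int = 6,
    max_markers_per_gene: int = 5,
    seed: int | None = None,
) -> dict:
    """Null distribution of paralogon counts under permuted gene identities.

    Gene labels are shuffled over the mapped markers (preserving per-gene
    marker counts and the marker universe); with `exclude_tandem`, genes
    that have tandem (same-group) duplicates in the observed data are
    removed before permuting.  Returns observed vs null mean/sd/max and
    the empirical p-value of the observed cluster count.
    """
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives a coarse empirical p-value")
    rng = np.random.default_rng(seed)
    obs_pairs, _ = paralog_pairs(best_hits, max_markers_per_gene)
    universe = best_hits
    if exclude_tandem:
        bad = _tandem_genes(obs_pairs)
        universe = best_hits[~best_hits["gene"].isin(bad)].reset_index(drop=True)
    obs_universe_pairs, _ = paralog_pairs(universe, max_markers_per_gene)
    obs_clusters = max_gap_clusters(obs_universe_pairs, max_gap, mp)
    obs_count = len(obs_clusters)
    obs_cov = footprint_coverage(obs_clusters) if obs_clusters else 0

    counts = np.empty(n_perm, dtype=int)
    covs = np.empty(n_perm, dtype=int)
    genes = universe["gene"].to_numpy()
    for t in range(n_perm):
        perm = universe.copy()
        perm["gene"] = genes[rng.permutation(len(genes))]
        ppairs, _ = paralog_pairs(perm, max_markers_per_gene)
        pcl = max_gap_clusters(ppairs, max_gap, mp)
        counts[t] = len(pcl)
        covs[t] = footprint_coverage(pcl) if pcl else 0
    return {
        "observed_clusters": obs_count,
        "observed_coverage": obs_cov,
        "null_mean": float(counts.mean()),
        "null_sd": float(counts.std(ddof=1)) if n_perm > 1 else 0.0,
        "null_max": int(counts.max()),
        "null_coverage_mean": float(covs.mean()),
        "p_empirical": float((1 + (counts >= obs_count).sum()) / (n_perm + 1)),
        "n_perm": n_perm,
        "exclude_tandem": exclude_tandem,
    }


def same_alg_excess(
    pairs: list[ParalogPair],
    segment_alg: dict[tuple[int, int, int], str] | list[tuple[int, int, int, str]],
    best_hits: pd.DataFrame | None = None,
    n_perm: int = 1000,
    max_markers_per_gene: int = 5,
    seed: int | None = None,
) -> dict:
    """Observed vs permuted counts of inter-chromosomal pairs within one ALG.

    `segment_alg` assigns ALG labels to map segments as (group, start,
    end, alg) records; pairs whose two footprint positions fall in
    segments of the same ALG are counted.  Passing `best_hits` enables the
    permutation null (gene identities shuffled as in `permutation_null`).
    """
    if not isinstance(segment_alg, dict):
        segs = list(segment_alg)
    else:
        segs = [(g, s, e, a) for (g, s, e), a in segment_alg.items()]

    def label(group: int, index: int) -> str | None:
        for g, s, e, a in segs:
            if g == group and s <= index <= e:
                return a
        return None

    def count_same(pp: list[ParalogPair]) -> int:
        c = 0
        for p in pp:
            if p.tandem:
                continue
            la, lb = label(p.group_a, p.index_a), label(p.group_b, p.index_b)
            if la is not None and la == lb:
                c += 1
        return c

    out = {"observed_same_alg": count_same(pairs)}
    if best_hits is not None:
        rng = np.random.default_rng(seed)
        genes = best_hits["gene"].to_numpy()
        counts = np.empty(n_perm, dtype=int)
        for t in range(n_perm):
            perm = best_hits.copy()
            perm["gene"] = genes[rng.permutation(len(genes))]
            ppairs, _ = paralog_pairs(perm, max_markers_per_gene)
            counts[t] = count_same(ppairs)
        out.update(
            null_mean=float(counts.mean()),
            null_sd=float(counts.std(ddof=1)) if n_perm > 1 else 0.0,
            p_empirical=float(
                (1 + (counts >= out["observed_same_alg"]).sum()) / (n_perm + 1)
            ),
        )
    return out


# ---------------------------------------------------------------------------
# paralogon graph clustering


def paralogon_graph_clustering(
    clusters: list[MaxGapCluster], n_random: int = 10_000, seed: int | None = None
) -> dict:
    """Average clustering coefficient of the paralogon graph vs ER nulls.

    Nodes are merged non-redundant footprint regions; an edge joins two
    nodes when a max-gap cluster connects them.  Triangles (a-b, b-c, a-c)
    indicate successive duplication rounds; the observed coefficient is
    compared with Erdos-Renyi graphs of the same node count and edge
    probability.
    """
    footprints = merged_footprints(clusters)
    if len(footprints) < 3:
        raise ValueError("need at least 3 footprint nodes")

    def node_of(group: int, ival: tuple[int, int]) -> int:
        for i, (g, s, e) in enumerate(footprints):
            if g == group and s <= ival[0] and ival[1] <= e:
                return i
        raise RuntimeError("footprint not found")

    G = nx.Graph()
    G.add_nodes_from(range(len(footprints)))
    for cl in clusters:
        G.add_edge(node_of(cl.group_a, cl.footprint_a), node_of(cl.group_b, cl.footprint_b))
    cc = nx.average_clustering(G)
    n = G.number_of_nodes()
    p_edge = G.number_of_edges() / (n * (n - 1) / 2)
    rng = np.random.default_rng(seed)
    null = np.empty(n_random)
    for t in range(n_random):
        H = nx.fast_gnp_random_graph(n, p_edge, seed=int(rng.integers(2**31 - 1)))
        null[t] = nx.average_clustering(H)
    return {
        "clustering_coefficient": float(cc),
        "n_nodes": n,
        "edge_probability": float(p_edge),
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)),
        "p_empirical": float((1 + (null >= cc).sum()) / (n_random + 1)),
    }


# ---------------------------------------------------------------------------
# Ks mixture dating


@dataclass
class KsMixtureFit:
    n_components: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    bic: float
    aic: float
    n: int
    fit_range: tuple[float, float]
    degenerate: bool = False

    @property
    def k_params(self) -> int:
        return 3 * self.n_components - 1

    def summary_row(self) -> dict:
        return {
            "components": self.n_components,
            "k": self.k_params,
            "lnL": self.log_likelihood,
            "BIC": self.bic,
            "AIC": self.aic,
            "mixture": " ; ".join(
                f"{m:.2f} ± {s:.2f}" for m, s in zip(self.means, self.sds)
            ),
        }


def ks_mixture(
    ks_values,
    components=(1, 2, 3, 4),
    fit_range: tuple[float, float] = (0.0, 2.5),
    seed: int | None = None,
) -> tuple[list[KsMixtureFit], KsMixtureFit]:
    """Univariate Gaussian mixtures on Ks, best model by minimum BIC.

    Values outside `fit_range` are discarded (the Ks estimator saturates
    above ~2.5).  BIC = -2 lnL + k ln N and AIC = -2 lnL + 2k with
    k = 3c - 1 free parameters for c components.  Degenerate fits
    (vanishing component variance) are retried with jitter and flagged.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(ks_values, dtype=float)
    x = x[(x >= fit_range[0]) & (x <= fit_range[1])]
    if x.size < 20:
        raise ValueError("need at least 20 Ks values in the fit range")
    X = x.reshape(-1, 1)
    fits = []
    for c in components:
        degenerate = False
        gm = GaussianMixture(
            n_components=c,
            covariance_type="full",
            n_init=10,
            tol=1e-6,
            max_iter=2000,
            reg_covar=1e-6,
            random_state=seed,
        ).fit(X)
        sds = np.sqrt(gm.covariances_.ravel())
        if (sds < 1e-3).any():
            degenerate = True
            gm = GaussianMixture(
                n_components=c,
                covariance_type="full",
                n_init=10,
                tol=1e-6,
                max_iter=2000,
                reg_covar=1e-4,
                random_state=None if seed is None else seed + 1,
            ).fit(X + np.random.default_rng(seed).normal(0, 1e-3, X.shape))
            sds = np.sqrt(gm.covariances_.ravel())
        order = np.argsort(gm.means_.ravel())
        lnL = float(gm.score(X) * x.size)
        k = 3 * c - 1
        fits.append(
            KsMixtureFit(
                n_components=c,
                means=gm.means_.ravel()[order],
                sds=sds[order],
                weights=gm.weights_.ravel()[order],
                log_likelihood=lnL,
                bic=float(-2 * lnL + k * np.log(x.size)),
                aic=float(-2 * lnL + 2 * k),
                n=int(x.size),
                fit_range=fit_range,
                degenerate=degenerate,
            )
        )
    best = min(fits, key=lambda f: f.bic)
    return fits, best


def ks_table(fits: list[KsMixtureFit]) -> pd.DataFrame:
    """Model-comparison table: N(components), k, lnL, BIC, AIC, mixture."""
    return pd.DataFrame([f.summary_row() for f in fits])
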
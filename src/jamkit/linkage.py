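"""Map bins, linkage groups, marker ordering and map statistics.

Markers sharing an offspring segregation pattern (up to relabeling of the
parental chromosomes) collapse into *map bins* — loci uninterrupted by
recombination in the cross.  Pairwise linkage between bins is the minimum
over the four parental relabelings of the upper binomial tail of the
match count at p=1/2; bins cluster into linkage groups by single-linkage
at a stringent threshold, spurious bins are removed as articulation
points of a looser-threshold graph, per-group chromosome labels are
harmonized along a minimum spanning tree, and bins are ordered by
average-linkage hierarchical clustering on cosine distances between
recombination-distance profiles with deterministic subtree rotations.
Additional markers are anchored to their best bin below a placement
threshold.  Population-genetic summaries (Watterson theta, Haldane map
distances, local recombination rates, segregation distortion) live here
too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

RELABELINGS = (0, 1, 2, 3)  # bit1: swap a<->b (maternal), bit0: swap c<->d

MISSING = -1


def relabel_pattern(pattern: np.ndarray, r: int) -> np.ndarray:
    out = pattern.copy()
    called = out >= 0
    out[called] = out[called] ^ r
    return out


def canonical_pattern(pattern: np.ndarray) -> tuple:
    return min(tuple(relabel_pattern(pattern, r)) for r in RELABELINGS)


# ---------------------------------------------------------------------------
# linkage p-value


def linkage_pvalue(pattern_a: np.ndarray, pattern_b: np.ndarray) -> float:
    """Min over parental relabelings of the binomial upper tail of matches.

    p_ab = min_r P(X >= m_r), X ~ Binomial(n, 1/2), where m_r is the
    number of matching genotypes under relabeling r and n the number of
    samples called in both patterns.  Relabeling-invariant in either
    argument; p=1 only when every relabeling matches at most chance level.
    """
    a = np.asarray(pattern_a)
    b = np.asarray(pattern_b)
    if a.shape != b.shape:
        raise ValueError("patterns must have equal length")
    ok = (a >= 0) & (b >= 0)
    if not ok.any():
        raise ValueError("no pairwise-complete samples")
    n = 2 * int(ok.sum())  # each offspring contributes one call per parent
    best = 1.0
    for r in RELABELINGS:
        ar = a[ok] ^ r
        m = int(((ar >> 1) == (b[ok] >> 1)).sum() + ((ar & 1) == (b[ok] & 1)).sum())
        best = min(best, float(stats.binom.sf(m - 1, n, 0.5)))
    return best


def _pairwise_pvalues(patterns: list[np.ndarray]) -> np.ndarray:
    """Dense symmetric matrix of linkage p-values (diagonal 0)."""
    B = len(patterns)
    # precompute binomial tails up to max n (two calls per offspring)
    n_max = 2 * max(p.size for p in patterns)
    tail = np.ones((n_max + 1, n_max + 2))
    for n in range(1, n_max + 1):
        tail[n, : n + 1] = stats.binom.sf(np.arange(n + 1) - 1, n, 0.5)
    P = np.zeros((B, B))
    mat = np.stack(patterns)
    called = mat >= 0
    for i in range(B):
        ok = called[i] & called
        n = 2 * ok.sum(axis=1)
        best = np.ones(B)
        for r in RELABELINGS:
            ar = mat[i] ^ r
            m = ((((ar >> 1) == (mat >> 1)) & ok).sum(axis=1)
                 + (((ar & 1) == (mat & 1)) & ok).sum(axis=1))
            t = np.where(n > 0, tail[n, np.minimum(m, n)], 1.0)
            best = np.minimum(best, t)
        P[i] = best
    np.fill_diagonal(P, 0.0)
    return np.minimum(P, P.T)


# ---------------------------------------------------------------------------
# map bins


@dataclass
class MapBin:
    id: int
    pattern: np.ndarray  # canonical genotype codes per offspring, -1 missing
    marker_ids: list[str]
    n_markers: int
    best_n_snps: int
    best_mean_phase_prob: float
    linkage_group: int | None = None
    order_index: int | None = None

    @property
    def marker_count(self) -> int:
        """Physical-size proxy: number of markers carrying this pattern."""
        return self.n_markers


def define_map_bins(
    markers: pd.DataFrame,
    min_support: int = 3,
    min_snps: int = 20,
    min_mean_phase_prob: float = 0.9,
    min_called_fraction: float = 0.8,
) -> list[MapBin]:
    """Collapse marker patterns into qualified map bins.

    `markers` needs columns marker_id, pattern (int array), n_snps,
    mean_phase_prob.  A unique pattern becomes a bin when (1) at least
    `min_support` markers carry it independently, or (2) some carrier has
    at least `min_snps` SNPs with mean inferred-phase probability above
    `min_mean_phase_prob`.  Patterns are compared up to parental
    relabeling; sparsely called patterns are dropped.
    """
    groups: dict[tuple, list[int]] = {}
    for idx, row in markers.iterrows():
        pat = np.asarray(row["pattern"])
        if (pat >= 0).mean() < min_called_fraction:
            continue
        groups.setdefault(canonical_pattern(pat), []).append(idx)
    bins: list[MapBin] = []
    for pat, idxs in groups.items():
        sub = markers.loc[idxs]
        crit1 = len(idxs) >= min_support
        crit2 = (
            (sub["n_snps"] >= min_snps)
            & (sub["mean_phase_prob"] > min_mean_phase_prob)
        ).any()
        if not (crit1 or crit2):
            continue
        bins.append(
            MapBin(
                id=len(bins),
                pattern=np.array(pat),
                marker_ids=list(sub["marker_id"]),
                n_markers=len(idxs),
                best_n_snps=int(sub["n_snps"].max()),
                best_mean_phase_prob=float(sub["mean_phase_prob"].max()),
            )
        )
    return bins


# ---------------------------------------------------------------------------
# linkage groups


def cluster_linkage_groups(
    bins: list[MapBin], p1: float = 1e-10, pvalues: np.ndarray | None = None
) -> list[list[int]]:
    """Single-linkage partition: connected components of {p_ab < p1}."""
    if pvalues is None:
        pvalues = _pairwise_pvalues([b.pattern for b in bins])
    G = nx.Graph()
    G.add_nodes_from(range(len(bins)))
    ii, jj = np.nonzero(np.triu(pvalues < p1, k=1))
    G.add_edges_from(zip(ii.tolist(), jj.tolist()))
    groups = [sorted(c) for c in nx.connected_components(G)]
    groups.sort(key=len, reverse=True)
    for gi, members in enumerate(groups):
        for m in members:
            bins[m].linkage_group = gi
    return groups


def filter_articulation_bins(
    bins: list[MapBin],
    threshold_pairs: tuple[tuple[float, float], ...] = (
        (1e-10, 1e-6),
        (1e-12, 1e-8),
        (1e-14, 1e-10),
    ),
    pvalues: np.ndarray | None = None,
) -> tuple[list[int], list[list[int]]]:
    """Remove bins that alone bridge otherwise-separate linkage groups.

    For each (p1, p2) pair with p2 > p1, bins that are articulation points
    of the looser p2-graph restricted to a strict p1-component are flagged
    (they merge what would otherwise be two partitions, indicating an
    inconsistent or error-ridden pattern).  Pairs are applied in sequence;
    returns (removed bin ids, final partition over surviving bins).
    """
    if pvalues is None:
        pvalues = _pairwise_pvalues([b.pattern for b in bins])
    removed: list[int] = []
    active = set(range(len(bins)))
    for p1, p2 in threshold_pairs:
        if not p2 > p1:
            raise ValueError("each pair needs p2 > p1")
        idx = sorted(active)
        sub = pvalues[np.ix_(idx, idx)]
        G1 = nx.Graph()
        G1.add_nodes_from(range(len(idx)))
        ii, jj = np.nonzero(np.triu(sub < p1, k=1))
        G1.add_edges_from(zip(ii.tolist(), jj.tolist()))
        G2 = nx.Graph()
        G2.add_nodes_from(range(len(idx)))
        ii, jj = np.nonzero(np.triu(sub < p2, k=1))
        G2.add_edges_from(zip(ii.tolist(), jj.tolist()))
        for comp in nx.connected_components(G1):
            H = G2.subgraph(comp)
            for art in nx.articulation_points(H):
                removed.append(idx[art])
        active -= set(removed)
    survivors = sorted(active)
    sub = pvalues[np.ix_(survivors, survivors)]
    sub_bins = [bins[i] for i in survivors]
    groups_local = cluster_linkage_groups(sub_bins, threshold_pairs[0][0], sub)
    groups = [[survivors[i] for i in g] for g in groups_local]
    return sorted(set(removed)), groups


# ---------------------------------------------------------------------------
# label harmonization and ordering


def harmonize_labels(
    bins: list[MapBin], members: list[int], pvalues: np.ndarray | None = None
) -> dict[int, int]:
    """Consistent parental chromosome labels along the group's MST.

    Builds the minimum spanning tree of the linkage-p-value graph and, in
    a traversal from an arbitrary root, relabels each bin with the r
    maximizing the match count along the traversed edge.  Returns the
    relabeling applied per bin (patterns are updated in place).
    """
    if len(members) == 1:
        return {members[0]: 0}
    pats = {m: bins[m].pattern for m in members}
    if pvalues is None:
        P = _pairwise_pvalues([pats[m] for m in members])
    else:
        P = pvalues[np.ix_(members, members)]
    G = nx.Graph()
    local = {m: i for i, m in enumerate(members)}
    for i, mi in enumerate(members):
        for j in range(i + 1, len(members)):
            G.add_edge(mi, members[j], weight=P[i, local[members[j]]])
    T = nx.minimum_spanning_tree(G)
    root = members[0]
    applied = {root: 0}
    for parent, child in nx.bfs_edges(T, root):
        pa, pc = pats[parent], pats[child]
        ok = (pa >= 0) & (pc >= 0)
        best_r, best_m = 0, -1
        for r in RELABELINGS:
            m = int(((pc[ok] ^ r) == pa[ok]).sum())
            if m > best_m:
                best_m, best_r = m, r
        pats[child] = relabel_pattern(pc, best_r)
        bins[child].pattern = pats[child]
        applied[child] = best_r
    return applied


def recombination_fraction_matrix(
    bins: list[MapBin], members: list[int], parent: str | None = None
) -> np.ndarray:
    """Pairwise recombination fractions between harmonized bins.

    With `parent` "maternal" or "paternal", only that parent's meiosis is
    compared (genotype bit 1 or 0); otherwise both alleles are compared
    and averaged.
    """
    mat = np.stack([bins[m].pattern for m in members])
    called = mat >= 0
    B = len(members)
    R = np.zeros((B, B))
    for i in range(B):
        ok = called[i] & called
        n = ok.sum(axis=1).astype(float)
        n[n == 0] = np.nan
        if parent == "maternal":
            diff = ((mat[i] >> 1) != (mat >> 1)) & ok
            R[i] = diff.sum(axis=1) / n
        elif parent == "paternal":
            diff = ((mat[i] & 1) != (mat & 1)) & ok
            R[i] = diff.sum(axis=1) / n
        else:
            dm = ((mat[i] >> 1) != (mat >> 1)) & ok
            dp = ((mat[i] & 1) != (mat & 1)) & ok
            R[i] = (dm.sum(axis=1) + dp.sum(axis=1)) / (2 * n)
    np.fill_diagonal(R, 0.0)
    return np.nan_to_num(np.minimum(R, R.T), nan=0.5)


def order_markers(
    bins: list[MapBin], members: list[int], harmonize: bool = True
) -> list[int]:
    """Order a linkage group's bins along the chromosome.

    Bins are clustered by average-linkage hierarchical clustering on the
    cosine distance between rows of the recombination-fraction matrix, and
    the binary tree is flattened by an in-order traversal after
    deterministic subtree rotations: inside the root's right subtree a
    node's children are swapped unless its left child is closer (in mean
    recombination distance) to the root's left-subtree markers, and
    mirror-image for the left subtree.  Returns bin ids in map order.
    """
    if len(members) < 2:
        return list(members)
    if harmonize:
        harmonize_labels(bins, members)
    R = recombination_fraction_matrix(bins, members)
    if len(members) == 2:
        return list(members)
    with np.errstate(invalid="ignore"):
        D = squareform(_cosine_distance_matrix(R), checks=False)
    Z = hierarchy.linkage(D, method="average")
    tree = hierarchy.to_tree(Z)

    def leaves(node) -> list[int]:
        return node.pre_order(lambda leaf: leaf.id)

    def mean_dist(ids_a, ids_b) -> float:
        return float(R[np.ix_(ids_a, ids_b)].mean())

    if tree.is_leaf():
        return [members[tree.id]]
    left_ref = leaves(tree.left)
    right_ref = leaves(tree.right)

    def rotate(node, ref_ids, ref_left: bool):
        """Orient every subtree so its ref-closer child faces the reference."""
        if node.is_leaf():
            return
        la, lb = leaves(node.left), leaves(node.right)
        d_left = mean_dist(la, ref_ids)
        d_right = mean_dist(lb, ref_ids)
        if (ref_left and d_right < d_left) or (not ref_left and d_left < d_right):
            node.left, node.right = node.right, node.left
        rotate(node.left, ref_ids, ref_left)
        rotate(node.right, ref_ids, ref_left)

    rotate(tree.right, left_ref, ref_left=True)
    rotate(tree.left, right_ref, ref_left=False)
    order = leaves(tree)
    for pos, li in enumerate(order):
        bins[members[li]].order_index = pos
    return [members[i] for i in order]


def _cosine_distance_matrix(R: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(R, axis=1)
    norms[norms == 0] = 1.0
    C = (R @ R.T) / np.outer(norms, norms)
    D = 1.0 - np.clip(C, -1.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


# ---------------------------------------------------------------------------
# anchoring


def anchor_marker(
    pattern: np.ndarray, bins: list[MapBin], threshold: float = 1e-6
) -> tuple[int | None, float]:
    """Anchor a marker to the bin minimizing p_ab, if below threshold."""
    best_bin, best_p = None, 1.0
    for b in bins:
        p = linkage_pvalue(pattern, b.pattern)
        if p < best_p:
            best_bin, best_p = b.id, p
    if best_p < threshold:
        return best_bin, best_p
    return None, best_p


# ---------------------------------------------------------------------------
# map statistics


def haldane_distance(r: float) -> float:
    """Haldane map distance -1/2 ln(1-2r), in Morgans."""
    if not 0.0 <= r < 0.5:
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    return -0.5 * math.log1p(-2.0 * r)


def haldane_inverse(d: float) -> float:
    return 0.5 * (1.0 - math.exp(-2.0 * d))


def local_recombination_rate(
    ordered_bins: list[MapBin],
    window: int = 10,
    bp_per_marker: float = 32_000.0,
    parent: str | None = None,
) -> np.ndarray:
    """cM/Mb per bin by regression of map distance on physical distance.

    Cumulative Haldane distance (from adjacent-bin recombination
    fractions) is regressed on cumulative physical position (marker-count
    proxy scaled by `bp_per_marker`) over up to `window` bins each side,
    truncated near the group ends.
    """
    B = len(ordered_bins)
    if B < 2:
        raise ValueError("need at least 2 ordered bins")
    pats = [b.pattern for b in ordered_bins]
    cum_map = np.zeros(B)
    for i in range(1, B):
        a, b = pats[i - 1], pats[i]
        ok = (a >= 0) & (b >= 0)
        if parent == "maternal":
            r = float((((a >> 1) != (b >> 1)) & ok).sum() / max(1, ok.sum()))
        elif parent == "paternal":
            r = float((((a & 1) != (b & 1)) & ok).sum() / max(1, ok.sum()))
        else:
            rm = (((a >> 1) != (b >> 1)) & ok).sum()
            rp = (((a & 1) != (b & 1)) & ok).sum()
            r = float((rm + rp) / max(1, 2 * ok.sum()))
        cum_map[i] = cum_map[i - 1] + haldane_distance(min(r, 0.499))
    phys = np.cumsum([b.marker_count for b in ordered_bins]).astype(float)
    phys *= bp_per_marker / 1e6  # Mb
    rates = np.empty(B)
    for i in range(B):
        lo, hi = max(0, i - window), min(B, i + window + 1)
        x, y = phys[lo:hi], cum_map[lo:hi]
        if np.ptp(x) == 0:
            rates[i] = 0.0
            continue
        slope = np.polyfit(x, y, 1)[0]  # Morgans per Mb
        rates[i] = max(0.0, slope * 100.0)  # cM/Mb
    return rates


def segregation_distortion(pattern: np.ndarray) -> float:
    """Exact binomial test of 1:1 transmission for each parent.

    Returns min(maternal p, paternal p) with a Bonferroni factor of 2,
    capped at 1.
    """
    pat = pattern[pattern >= 0]
    if pat.size == 0:
        raise ValueError("no called genotypes")
    n = pat.size
    p_m = stats.binomtest(int((pat >> 1).sum()), n, 0.5).pvalue
    p_p = stats.binomtest(int((pat & 1).sum()), n, 0.5).pvalue
    return float(min(1.0, 2.0 * min(p_m, p_p)))


def watterson_theta(
    snp_density: float, n_haplotypes: int, finite_sites: bool = True
) -> float:
    """Theta from segregating-site density over n haplotypes.

    Theta = density / sum_{i=1}^{n-1} 1/i; with `finite_sites` the observed
    density is first corrected for unseen recurrent hits via the Poisson
    relation (true per-site mutation density = -ln(1 - observed)).  A
    density of 0.76% over 4 haplotypes gives 0.0042 with the correction.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    if not 0.0 <= snp_density < 1.0:
        raise ValueError("density must lie in [0, 1)")
    dens = -math.log1p(-snp_density) if finite_sites else snp_density
    a_n = sum(1.0 / i for i in range(1, n_haplotypes))
    return dens / a_n


def correlate_bin_tracks(track_x, track_y) -> tuple[float, float, float]:
    """Pearson correlation between two per-bin tracks: (r, r^2, p)."""
    x = np.asarray(track_x, dtype=float)
    y = np.asarray(track_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("tracks must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant track")
    r, p = stats.pearsonr(x, y)
    return float(r), float(r * r), float(p)


# ---------------------------------------------------------------------------
# assembled genetic map


@dataclass
class GeneticMap:
    bins: list[MapBin]
    groups: list[list[int]]  # ordered bin ids per linkage group
    removed_bins: list[int] = field(default_factory=list)
    anchors: pd.DataFrame | None = None

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, members in enumerate(self.groups):
            for oi, b in enumerate(members):
                rows.append(
                    {
                        "linkage_group": gi,
                        "order_index": oi,
                        "bin": b,
                        "n_markers": self.bins[b].n_markers,
                        "marker_ids": ";".join(self.bins[b].marker_ids),
                    }
                )
        return pd.DataFrame(rows)


def build_genetic_map(
    markers: pd.DataFrame,
    p1: float = 1e-10,
    threshold_pairs=((1e-10, 1e-6), (1e-12, 1e-8), (1e-14, 1e-10)),
    anchor_threshold: float = 1e-6,
    min_group_size: int = 2,
    **bin_kwargs,
) -> GeneticMap:
    """Map bins -> filtered linkage groups -> ordered map, with anchoring.

    `markers` as for `define_map_bins`; markers not used to build bins can
    be anchored afterwards via `anchor_marker`.  Singleton groups are
    reported but not ordered.
    """
    bins = define_map_bins(markers, **bin_kwargs)
    if not bins:
        raise ValueError("no qualified map bins")
    P = _pairwise_pvalues([b.pattern for b in bins])
    removed, groups = filter_articulation_bins(bins, threshold_pairs, P)
    ordered_groups = []
    for members in groups:
        if len(members) < min_group_size:
            continue
        ordered_groups.append(order_markers(bins, members))
    ordered_groups.sort(key=len, reverse=True)
    for gi, members in enumerate(ordered_groups):
        for oi, b in enumerate(members):
            bins[b].linkage_group = gi
            bins[b].order_index = oi
    return GeneticMap(bins=bins, groups=ordered_groups, removed_bins=removed)
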
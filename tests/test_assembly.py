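"""k-mer graph construction, robust edges, contigs, scaffolds, consensus."""

import re

import numpy as np
import pytest

from jamkit import assembly as asm
from jamkit import kmers as km
from jamkit import simulate as sim
from jamkit import snpmers as sm
from jamkit._kcode import decode_bases, revcomp_str


def toy_edge(a, ea, b, eb, dist, support):
    return asm.Edge(a=(a, ea), b=(b, eb), distance=dist, support=support)


class TestRobustRule:
    def _graph(self, edges):
        g = asm.KmerGraph(nodeset=None, edges=edges)
        g.nodeset = type("NS", (), {"__len__": lambda self: 10})()
        return g

    def test_supermajority(self):
        # supports {5,1}: 5 >= 2+1 and 5 >= 2*1 -> robust
        e1 = toy_edge(0, asm.DOWN, 1, asm.UP, 10, 5)
        e2 = toy_edge(0, asm.DOWN, 2, asm.UP, 12, 1)
        asm.mark_robust_edges(self._graph([e1, e2]))
        assert e1.robust_from_a and not e2.robust_from_a

    def test_sum_rule_fails(self):
        # {3,2}: 3 < 2+2 -> nothing robust
        e1 = toy_edge(0, asm.DOWN, 1, asm.UP, 10, 3)
        e2 = toy_edge(0, asm.DOWN, 2, asm.UP, 12, 2)
        asm.mark_robust_edges(self._graph([e1, e2]))
        assert not e1.robust_from_a and not e2.robust_from_a

    def test_single_edge_boundary(self):
        # lone edge: support 2 passes (2 >= 2+0, 2 >= 0), support 1 fails
        e2 = toy_edge(0, asm.DOWN, 1, asm.UP, 10, 2)
        asm.mark_robust_edges(self._graph([e2]))
        assert e2.robust_from_a and e2.robust_from_b
        e1 = toy_edge(0, asm.DOWN, 1, asm.UP, 10, 1)
        asm.mark_robust_edges(self._graph([e1]))
        assert not e1.robust_from_a

    def test_at_most_one_robust_per_end(self):
        rng = np.random.default_rng(0)
        edges = [
            toy_edge(0, asm.DOWN, i, asm.UP, 10 + i, int(rng.integers(1, 20)))
            for i in range(1, 6)
        ]
        asm.mark_robust_edges(self._graph(edges))
        assert sum(e.robust_from_a for e in edges) <= 1


def build_toy_pipeline(hs, coverage=25.0, error_rate=0.0, seed=5):
    genomes = {
        "mother": [(hs.haplotypes[0], hs.haplotypes[1])],
        "father": [(hs.haplotypes[2], hs.haplotypes[3])],
    }
    reads = sim.simulate_reads(
        genomes, {s: coverage for s in genomes}, error_rate=error_rate, seed=seed
    )
    spec = km.KmerSpec(k=23)
    table = km.filter_kmers(km.count_kmers(reads, spec))
    sel = sm.select_nodes(sm.classify_kmers(table))
    nodeset = asm.build_node_set(sel, table)
    hits = [
        asm.scan_sample(sr.seqs, sr.quals, nodeset, spec, name)
        for name, sr in reads.samples.items()
    ]
    graph = asm.build_kmer_graph(nodeset, hits)
    asm.mark_robust_edges(graph)
    contigs = asm.extract_contigs(graph)
    return reads, spec, nodeset, hits, graph, contigs


@pytest.fixture(scope="module")
def toy_assembly():
    hs = sim.simulate_haplotypes(30_000, 0.006, 0.005, seed=17)
    return hs, *build_toy_pipeline(hs)


class TestGraphAndContigs:
    def test_edges_have_positive_distance_and_support(self, toy_assembly):
        *_, graph, contigs = toy_assembly
        assert len(graph.edges) > 0
        assert all(e.distance > 0 and e.support > 0 for e in graph.edges)

    def test_component_count_matches_union_find(self, toy_assembly):
        *_, graph, contigs = toy_assembly
        parent = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        nodes_in_mr = set()
        for e in graph.usable_edges():
            if e.mutually_robust:
                a, b = e.a[0], e.b[0]
                nodes_in_mr.update((a, b))
                parent[find(a)] = find(b)
        n_comp = len({find(x) for x in nodes_in_mr})
        multi = [c for c in contigs if len(c) > 1]
        assert len(multi) == n_comp

    def test_nodes_disjoint_across_contigs(self, toy_assembly):
        *_, contigs = toy_assembly
        seen = set()
        for c in contigs:
            for n in c.node_ids():
                assert n not in seen
                seen.add(n)

    def test_conflict_rule_suppresses_ends(self):
        """Same node pair at two distances poisons both ends."""
        ns = type("NS", (), {"k": 23, "__len__": lambda self: 4})()
        h = asm.SampleHits(
            sample="s",
            read=np.array([0, 0, 1, 1]),
            pos=np.array([0, 7, 0, 9]),
            node=np.array([0, 1, 0, 1]),
            strand=np.array([True, True, True, True]),
            is_hi=np.zeros(4, dtype=bool),
        )
        g = asm.build_kmer_graph(ns, [h])
        assert (0, asm.DOWN) in g.conflicted_ends
        assert (1, asm.UP) in g.conflicted_ends
        assert g.usable_edges() == []

    def test_consensus_matches_haplotype_outside_snps(self, toy_assembly):
        edlib = pytest.importorskip("edlib")
        hs, reads, spec, nodeset, hits, graph, contigs = toy_assembly
        src = decode_bases(hs.haplotypes[0])
        n_snp = len(hs.snp_truth)
        linear = [c for c in contigs if c.status == "linear"]
        big = sorted(linear, key=lambda c: -c.length)[:5]
        for c in big:
            cons = re.sub("[RYMKWS]", "N", asm.contig_consensus(c, nodeset, reads=reads))
            eq = [("N", b) for b in "ACGT"]
            best = min(
                edlib.align(s, src, mode="HW", task="distance", additionalEqualities=eq)[
                    "editDistance"
                ]
                for s in (cons, revcomp_str(cons))
            )
            # mismatches only at SNP sites where another haplotype's allele won
            assert best <= n_snp * (c.length / hs.length) * 1.5 + 2

    def test_isolated_snp_recovery(self, toy_assembly):
        """Most well-separated true SNPs land in contigs via SNPmer nodes."""
        hs, reads, spec, nodeset, hits, graph, contigs = toy_assembly
        pos = hs.snp_truth["pos"].to_numpy()
        iso = np.ones(pos.size, dtype=bool)
        iso[1:] &= np.diff(pos) >= 22
        iso[:-1] &= np.diff(pos) >= 22
        iso &= hs.snp_truth["biallelic"].to_numpy()
        # SNPmer nodes inside multi-node contigs
        in_contig = {
            n
            for c in contigs
            if c.status == "linear"
            for n in c.node_ids()
            if nodeset.nodes[n].kind == "snpmer"
        }
        total_snpmer_nodes = sum(1 for n in nodeset.nodes if n.kind == "snpmer")
        assert total_snpmer_nodes > 0
        assert len(in_contig) / total_snpmer_nodes >= 0.8


class TestTemplatesAndScaffolds:
    def test_template_links_recover_order(self, toy_assembly):
        hs, reads, spec, nodeset, hits, graph, contigs = toy_assembly
        links = asm.map_templates(contigs, hits, nodeset)
        assert len(links) > 0
        scaffolds = asm.scaffold_contigs(contigs, links, min_links=2)
        # order within scaffolds should follow the genome: check via node
        # positions of the underlying contigs
        from jamkit.pipeline import kmer_position_index

        index = kmer_position_index([hs], 23)
        by_id = {c.id: c for c in contigs}
        for s in scaffolds:
            if len(s.contigs) < 3:
                continue
            mids = []
            for cid, orient, _ in s.contigs:
                locs = [
                    index[n.code_lo][1]
                    for n in (nodeset.nodes[i] for i in by_id[cid].node_ids())
                    if n.code_lo in index
                ]
                if locs:
                    mids.append(np.median(locs))
            diffs = np.diff(mids)
            assert (diffs > 0).all() or (diffs < 0).all()

    def test_orientation_tie_drops_pair(self):
        contigs = [
            asm.Contig(id=0, nodes=[(0, 1, 0)], status="linear", length=23),
            asm.Contig(id=1, nodes=[(1, 1, 0)], status="linear", length=23),
        ]
        links = [
            asm.TemplateLink(0, 1, 1, 1, 10.0),
            asm.TemplateLink(0, 1, 1, -1, 10.0),
        ]
        scaffolds = asm.scaffold_contigs(contigs, links, min_links=1)
        assert all(len(s.contigs) == 1 for s in scaffolds)

    def test_max_span_caps_chains(self, toy_assembly):
        hs, reads, spec, nodeset, hits, graph, contigs = toy_assembly
        links = asm.map_templates(contigs, hits, nodeset)
        capped = asm.scaffold_contigs(contigs, links, min_links=2, max_span=2000)
        by_id = {c.id: c for c in contigs}
        for s in capped:
            span = sum(by_id[cid].length for cid, _, _ in s.contigs) + sum(
                g for _, _, g in s.contigs
            )
            assert span <= 2000 + max(by_id[c].length for c, _, _ in s.contigs)

    def test_scaffold_gap_rendering(self):
        contigs = [
            asm.Contig(id=0, nodes=[(0, 1, 0)], status="linear", length=23),
            asm.Contig(id=1, nodes=[(1, 1, 0)], status="linear", length=23),
        ]
        ns = asm.NodeSet(
            k=23,
            nodes=[asm.Node(kind="unique", code_lo=0), asm.Node(kind="unique", code_lo=1)],
            member_codes=np.array([0, 1], dtype=np.uint64),
            member_node=np.array([0, 1]),
            member_flip=np.zeros(2, bool),
            member_is_hi=np.zeros(2, bool),
        )
        s = asm.Scaffold(id=0, contigs=[(0, 1, 0), (1, 1, 5)])
        cons = asm.consensus(s, contigs, ns, reads=None)
        assert "N" * 5 in cons and len(cons) == 23 + 5 + 23


class TestStats:
    def test_hand_example(self):
        st = asm.assembly_stats([1, 2, 3, 4, 10])
        assert st["n50_span"] == 10
        assert st["total_span"] == 20 and st["count"] == 5

    def test_single(self):
        assert asm.assembly_stats([42])["n50_span"] == 42

    def test_permutation_invariant(self):
        a = asm.assembly_stats([5, 1, 9, 3, 3])
        b = asm.assembly_stats([9, 3, 5, 3, 1])
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            asm.assembly_stats([])
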
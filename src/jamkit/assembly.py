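"""k-mer graph assembly: contigs, template links, scaffolds, consensus.

Nodes of the graph are the selected tags — unpaired unique k-mers and
SNPmer pairs (both alleles of a pair share one node).  Two nodes are
connected when their k-mers appear consecutively in at least one read
(intervening non-node k-mers skipped); each edge stores the relative
orientation, start-to-start distance and supporting-read count.  An edge
is *robust* at a node end when its support is at least two plus the sum
of all competing edges' support and at least twice the runner-up;
contigs are the connected components of the mutually robust subgraph.
Contigs are then linked by read-pair templates and chained greedily into
scaffolds with consistent order and orientation (a deliberately simple
stand-in for a full scaffolder, sharing its contract), and consensus
sequences are emitted with single-read gap patching.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._kcode import INVALID, canonical_codes, decode_kmer, kmer_codes, revcomp_str
from .kmers import KmerSpec, KmerTable
from .snpmers import NodeSelection

UP, DOWN = 0, 1  # node ends: upstream / downstream in the node's own frame

_IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("AC"): "M",
    frozenset("GT"): "K", frozenset("AT"): "W", frozenset("CG"): "S",
}
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# node set


@dataclass
class Node:
    kind: str  # "unique" | "snpmer"
    code_lo: int
    code_hi: int | None = None
    sub_position: int | None = None
    rc_partner: bool = False
    count_lo: int = 0
    count_hi: int = 0

    def sequence(self, k: int, ambiguity: bool = True) -> str:
        """Node tag sequence in the node frame (the lo member's canonical).

        SNPmer nodes emit the better-supported allele's base at the SNP;
        ties emit the IUPAC ambiguity code when `ambiguity` is set.
        """
        seq = decode_kmer(self.code_lo, k)
        if self.kind != "snpmer":
            return seq
        p = self.sub_position - 1
        lo_base = seq[p]
        hi_seq = decode_kmer(self.code_hi, k)
        if self.rc_partner:
            hi_seq = revcomp_str(hi_seq)
        hi_base = hi_seq[p]
        if self.count_hi > self.count_lo:
            best = hi_base
        elif self.count_lo > self.count_hi:
            best = lo_base
        else:
            best = (
                _IUPAC.get(frozenset((lo_base, hi_base)), lo_base)
                if ambiguity
                else lo_base
            )
        return seq[:p] + best + seq[p + 1 :]

    def alleles(self, k: int) -> tuple[str, str] | None:
        if self.kind != "snpmer":
            return None
        p = self.sub_position - 1
        lo = decode_kmer(self.code_lo, k)[p]
        hi_seq = decode_kmer(self.code_hi, k)
        if self.rc_partner:
            hi_seq = revcomp_str(hi_seq)
        return lo, hi_seq[p]


@dataclass
class NodeSet:
    """Selected tags indexed for O(log n) k-mer lookup during read scans."""

    k: int
    nodes: list[Node]
    member_codes: np.ndarray  # sorted canonical codes of all member k-mers
    member_node: np.ndarray
    member_flip: np.ndarray  # member canonical frame is RC of the node frame
    member_is_hi: np.ndarray

    def __len__(self) -> int:
        return len(self.nodes)


def build_node_set(selection: NodeSelection, table: KmerTable | None = None) -> NodeSet:
    k = selection.classified.table.k
    if table is None:
        table = selection.classified.table
    nodes: list[Node] = []
    codes, node_ids, flips, is_hi = [], [], [], []
    for pair in selection.selected_pairs:
        i = len(nodes)
        nodes.append(
            Node(
                kind="snpmer",
                code_lo=pair.kmer_lo,
                code_hi=pair.kmer_hi,
                sub_position=pair.sub_position,
                rc_partner=pair.rc_partner,
            )
        )
        codes += [pair.kmer_lo, pair.kmer_hi]
        node_ids += [i, i]
        flips += [False, pair.rc_partner]
        is_hi += [False, True]
    for code in selection.selected_unique:
        i = len(nodes)
        nodes.append(Node(kind="unique", code_lo=int(code)))
        codes.append(int(code))
        node_ids.append(i)
        flips.append(False)
        is_hi.append(False)
    order = np.argsort(codes)
    member_codes = np.asarray(codes, dtype=np.uint64)[order]
    ns = NodeSet(
        k=k,
        nodes=nodes,
        member_codes=member_codes,
        member_node=np.asarray(node_ids, dtype=np.int64)[order],
        member_flip=np.asarray(flips, dtype=bool)[order],
        member_is_hi=np.asarray(is_hi, dtype=bool)[order],
    )
    # allele support from the table, for consensus major-allele calls
    idx = np.searchsorted(table.kmers, member_codes)
    ok = (idx < len(table.kmers)) & (table.kmers[np.clip(idx, 0, len(table.kmers) - 1)] == member_codes)
    for m in np.flatnonzero(ok):
        node = ns.nodes[int(ns.member_node[m])]
        cnt = int(table.counts[idx[m]])
        if ns.member_is_hi[m]:
            node.count_hi = cnt
        else:
            node.count_lo = cnt
    return ns


# ---------------------------------------------------------------------------
# read scanning


@dataclass
class SampleHits:
    """Node k-mer hits of one sample's reads, in read order."""

    sample: str
    read: np.ndarray  # read row index within the sample
    pos: np.ndarray  # k-mer start offset within the read
    node: np.ndarray
    strand: np.ndarray  # True: read frame matches node frame
    is_hi: np.ndarray


def scan_sample(
    seqs: np.ndarray, quals: np.ndarray, nodeset: NodeSet, spec: KmerSpec, sample: str
) -> SampleHits:
    """Find node-member k-mer hits in a sample's fixed-length reads."""
    n_reads, read_len = seqs.shape
    codes = np.where(quals >= spec.hard_quality, seqs, INVALID)
    sep = np.full((n_reads, 1), INVALID, dtype=np.uint8)
    flat = np.concatenate([codes, sep], axis=1).ravel()
    kcodes, valid = kmer_codes(flat, spec.k)
    canon, fwd = canonical_codes(kcodes, spec.k)
    mc = nodeset.member_codes
    idx = np.searchsorted(mc, canon)
    idx[idx >= mc.size] = max(0, mc.size - 1)
    hit = valid & (mc.size > 0)
    if mc.size:
        hit &= mc[idx] == canon
    flat_pos = np.flatnonzero(hit)
    stride = read_len + 1
    read = flat_pos // stride
    pos = flat_pos % stride
    m = idx[hit]
    return SampleHits(
        sample=sample,
        read=read,
        pos=pos,
        node=nodeset.member_node[m],
        strand=fwd[hit] ^ nodeset.member_flip[m],
        is_hi=nodeset.member_is_hi[m],
    )


# ---------------------------------------------------------------------------
# graph


@dataclass
class EdgeRep:
    """One witness read for an edge, for gap patching."""

    sample: str
    read: int
    pos_a: int
    pos_b: int
    a_first: bool  # witness traverses endpoint a before b


@dataclass
class Edge:
    a: tuple[int, int]  # (node, end)
    b: tuple[int, int]
    distance: int  # start-to-start offset along the witness read
    support: int = 0
    rep: EdgeRep | None = None
    robust_from_a: bool = False
    robust_from_b: bool = False

    @property
    def mutually_robust(self) -> bool:
        return self.robust_from_a and self.robust_from_b

    def other(self, end: tuple[int, int]) -> tuple[int, int]:
        return self.b if end == self.a else self.a


@dataclass
class KmerGraph:
    nodeset: NodeSet
    edges: list[Edge]
    conflicted_ends: set[tuple[int, int]] = field(default_factory=set)

    def usable_edges(self):
        return [
            e
            for e in self.edges
            if e.a not in self.conflicted_ends and e.b not in self.conflicted_ends
        ]


def build_kmer_graph(nodeset: NodeSet, hits: list[SampleHits]) -> KmerGraph:
    """Assemble edges from consecutive node hits within reads.

    Conflicting observations — the same node pair seen at different
    distances or relative orientations — poison all edges at the involved
    node ends ("ignored in contigging").
    """
    packed_all: list[np.ndarray] = []
    rep_all: list[np.ndarray] = []  # columns: sample_idx, read, pu, pv, swap
    sample_names: list[str] = []
    for si, sh in enumerate(hits):
        sample_names.append(sh.sample)
        if sh.node.size < 2:
            continue
        same = sh.read[1:] == sh.read[:-1]
        u, v = sh.node[:-1][same], sh.node[1:][same]
        su, sv = sh.strand[:-1][same], sh.strand[1:][same]
        pu, pv = sh.pos[:-1][same], sh.pos[1:][same]
        rd = sh.read[1:][same]
        keep = u != v  # self-adjacency (tandem or allele re-hit) is not usable
        u, v, su, sv, pu, pv, rd = (x[keep] for x in (u, v, su, sv, pu, pv, rd))
        eu = np.where(su, DOWN, UP)
        ev = np.where(sv, UP, DOWN)
        dist = (pv - pu).astype(np.uint64)
        a_code = (u * 2 + eu).astype(np.uint64)
        b_code = (v * 2 + ev).astype(np.uint64)
        swap = a_code > b_code
        lo = np.where(swap, b_code, a_code)
        hi = np.where(swap, a_code, b_code)
        # pack (lo, hi, dist) into one uint64: node-end codes < 2^23, dist < 2^16
        packed = (lo << np.uint64(39)) | (hi << np.uint64(16)) | dist
        packed_all.append(packed)
        rep_all.append(
            np.column_stack(
                [np.full(u.size, si), rd, pu, pv, swap.astype(np.int64)]
            )
        )

    edges: list[Edge] = []
    by_pair: dict[tuple[int, int], list[Edge]] = defaultdict(list)
    if packed_all:
        packed = np.concatenate(packed_all)
        reps = np.concatenate(rep_all)
        uniq, first, cnt = np.unique(packed, return_index=True, return_counts=True)
        mask16 = np.uint64(0xFFFF)
        mask23 = np.uint64((1 << 23) - 1)
        for key, fi, c in zip(uniq, first, cnt):
            dist = int(key & mask16)
            b_code = int((key >> np.uint64(16)) & mask23)
            a_code = int(key >> np.uint64(39))
            si, rd, pu, pv, swap = (int(x) for x in reps[fi])
            e = Edge(
                a=(a_code // 2, a_code % 2),
                b=(b_code // 2, b_code % 2),
                distance=dist,
                support=int(c),
                rep=EdgeRep(
                    sample=sample_names[si],
                    read=rd,
                    pos_a=pu,
                    pos_b=pv,
                    a_first=not swap,
                ),
            )
            edges.append(e)
            by_pair[(e.a[0], e.b[0])].append(e)

    conflicted: set[tuple[int, int]] = set()
    for pair_edges in by_pair.values():
        combos = {(e.a[1], e.b[1]) for e in pair_edges}
        if len(combos) > 1:  # orientation conflict
            for e in pair_edges:
                conflicted.add(e.a)
                conflicted.add(e.b)
            continue
        if len({e.distance for e in pair_edges}) > 1:  # distance conflict
            for e in pair_edges:
                conflicted.add(e.a)
                conflicted.add(e.b)
    return KmerGraph(nodeset=nodeset, edges=edges, conflicted_ends=conflicted)


def mark_robust_edges(graph: KmerGraph) -> KmerGraph:
    """Flag the supermajority edge (if any) at every node end.

    An edge is robust at an end when its support s1 satisfies both
    s1 >= 2 + sum(other supports) and s1 >= 2 * (next-best support).
    """
    incident: dict[tuple[int, int], list[Edge]] = defaultdict(list)
    for e in graph.usable_edges():
        incident[e.a].append(e)
        incident[e.b].append(e)
    for end, elist in incident.items():
        elist.sort(key=lambda e: -e.support)
        s1 = elist[0].support
        rest = sum(e.support for e in elist[1:])
        s2 = elist[1].support if len(elist) > 1 else 0
        if s1 >= 2 + rest and s1 >= 2 * s2:
            best = elist[0]
            if end == best.a:
                best.robust_from_a = True
            else:
                best.robust_from_b = True
    return graph


# ---------------------------------------------------------------------------
# contigs


@dataclass
class Contig:
    id: int
    nodes: list[tuple[int, int, int]]  # (node_id, orientation ±1, offset bp)
    status: str  # linear | singleton | circular
    edges: list[Edge] = field(default_factory=list)  # between consecutive nodes
    length: int = 0  # tag span in bp (last offset + k)

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def span(self) -> int:
        # offsets are starts in contig coordinates; add k via consensus length
        return self.nodes[-1][2] - self.nodes[0][2]

    def node_ids(self) -> list[int]:
        return [n for n, _, _ in self.nodes]


def extract_contigs(graph: KmerGraph) -> list[Contig]:
    """Chains of the mutually robust subgraph.

    Linear chains become contigs; cycles are flagged circular and isolated
    nodes singleton (both reported, both excluded downstream).
    """
    mr: dict[tuple[int, int], Edge] = {}
    for e in graph.usable_edges():
        if e.mutually_robust:
            mr[e.a] = e
            mr[e.b] = e
    n_nodes = len(graph.nodeset)
    visited = np.zeros(n_nodes, dtype=bool)
    contigs: list[Contig] = []

    def walk_right(start: int, orient0: int):
        """Follow mutually robust edges rightward from (start, orient0)."""
        out: list[tuple[int, int, int]] = []
        out_edges: list[Edge] = []
        node, orient, off = start, orient0, 0
        while True:
            exit_end = DOWN if orient == 1 else UP
            e = mr.get((node, exit_end))
            if e is None:
                return out, out_edges, False
            nnode, nend = e.other((node, exit_end))
            if nnode == start:
                out_edges.append(e)
                return out, out_edges, True  # closed a cycle
            if visited[nnode]:
                return out, out_edges, False
            visited[nnode] = True
            orient = 1 if nend == UP else -1
            off += e.distance
            out.append((nnode, orient, off))
            out_edges.append(e)
            node = nnode

    for start in range(n_nodes):
        if visited[start]:
            continue
        visited[start] = True
        right, r_edges, circular = walk_right(start, 1)
        if circular:
            chain = [(start, 1, 0)] + right
            edges = r_edges
        else:
            left, l_edges, _ = walk_right(start, -1)
            # the leftward walk ran in the flipped frame; restore
            chain = (
                [(n, -o, -off) for n, o, off in reversed(left)]
                + [(start, 1, 0)]
                + right
            )
            edges = list(reversed(l_edges)) + r_edges
        base = min(off for _, _, off in chain)
        chain = [(n, o, off - base) for n, o, off in chain]
        status = (
            "circular" if circular else ("singleton" if len(chain) == 1 else "linear")
        )
        contigs.append(
            Contig(
                id=len(contigs),
                nodes=chain,
                status=status,
                edges=edges,
                length=chain[-1][2] + graph.nodeset.k,
            )
        )
    return contigs


def _contig_consensus(
    contig: Contig, nodeset: NodeSet, reads=None, fill_gaps: bool = True
) -> str:
    """Phase-1 consensus (node tags joined by Ns) with phase-2 read patching."""
    k = nodeset.k
    parts: list[str] = []
    prev_end = None  # contig coordinate where emitted sequence currently ends
    for i, (node_id, orient, off) in enumerate(contig.nodes):
        seq = nodeset.nodes[node_id].sequence(k)
        if orient == -1:
            seq = revcomp_str(seq)
        if i == 0:
            parts.append(seq)
            prev_end = off + k
            continue
        gap = off - prev_end
        if gap < 0:
            # overlapping tags: trim the overlap from the incoming tag
            seq = seq[-gap:]
            gap = 0
        elif gap > 0:
            patch = None
            if fill_gaps and reads is not None:
                patch = _patch_from_read(contig.edges[i - 1], contig, i, nodeset, reads)
            parts.append(patch if patch is not None else "N" * gap)
        parts.append(seq)
        prev_end = off + k
    return "".join(parts)


def _patch_from_read(edge: Edge, contig: Contig, i: int, nodeset: NodeSet, reads) -> str | None:
    """Fill the gap before contig node i from the edge's witness read."""
    rep = edge.rep
    if rep is None:
        return None
    sr = reads.samples.get(rep.sample) if hasattr(reads, "samples") else None
    if sr is None:
        return None
    from ._kcode import decode_bases

    k = nodeset.k
    seq = decode_bases(sr.seqs[rep.read])
    lo, hi = sorted((rep.pos_a, rep.pos_b))
    frag = seq[lo + k : hi]
    if not frag:
        return None
    # orientation: the witness traverses the two nodes in read order; the
    # contig stores them left-to-right.  If the earlier-in-read node is the
    # right-hand one in the contig, the patch must be reverse complemented.
    prev_node, prev_orient, _ = contig.nodes[i - 1]
    # which endpoint of the edge belongs to prev_node?
    a_is_prev = edge.a[0] == prev_node
    first_in_read_is_a = rep.a_first
    prev_first_in_read = a_is_prev == first_in_read_is_a
    return frag if prev_first_in_read else revcomp_str(frag)


# ---------------------------------------------------------------------------
# templates and scaffolds


@dataclass
class TemplateLink:
    contig_a: int
    orient_a: int  # +1: a's downstream (right) side faces the gap
    contig_b: int
    orient_b: int
    gap: float


def map_templates(
    contigs: list[Contig],
    hits: list[SampleHits],
    nodeset: NodeSet,
    insert_mean: float = 300.0,
    read_len: int = 100,
) -> list[TemplateLink]:
    """Derive inter-contig links from read-pair templates.

    A read end is assigned to the contig with which it shares the most
    node k-mers (ties discard the template) provided the hit span reaches
    k; a template links two different contigs via its two mates.  Mate
    pairing assumes the interleaved layout row 2i / 2i+1.
    """
    node_contig = np.full(len(nodeset), -1, dtype=np.int64)
    node_orient = np.zeros(len(nodeset), dtype=np.int8)
    node_offset = np.zeros(len(nodeset), dtype=np.int64)
    contig_len: dict[int, int] = {}
    for c in contigs:
        if c.status != "linear":
            continue
        for nid, orient, off in c.nodes:
            node_contig[nid] = c.id
            node_orient[nid] = orient
            node_offset[nid] = off
        contig_len[c.id] = c.nodes[-1][2] + nodeset.k

    links: list[TemplateLink] = []
    k = nodeset.k
    for sh in hits:
        if sh.node.size == 0:
            continue
        cid = node_contig[sh.node]
        ok = cid >= 0
        read, pos, node, strand, cid = (
            sh.read[ok], sh.pos[ok], sh.node[ok], sh.strand[ok], cid[ok]
        )
        # per (read, contig) hit counts and spans
        assign: dict[int, tuple[int, int, int] | None] = {}
        # best (count, contig) per read with tie discard, plus span and a hit
        order = np.lexsort((cid, read))
        read, pos, node, strand, cid = (
            x[order] for x in (read, pos, node, strand, cid)
        )
        boundaries = np.flatnonzero(
            np.diff(read) | np.diff(cid).astype(bool)
        )
        starts = np.concatenate(([0], boundaries + 1))
        ends = np.concatenate((boundaries + 1, [read.size]))
        per_read: dict[int, list[tuple[int, int, int]]] = defaultdict(list)
        for s, e in zip(starts, ends):
            r = int(read[s])
            span = int(pos[e - 1] - pos[s]) + k
            per_read[r].append((int(cid[s]), e - s, s))
            if span < k:  # unreachable under the inclusive convention; kept
                per_read[r].pop()
        for r, lst in per_read.items():
            lst.sort(key=lambda t: -t[1])
            if len(lst) > 1 and lst[0][1] == lst[1][1]:
                assign[r] = None
            else:
                assign[r] = lst[0]
        # pair mates
        for r, rec in assign.items():
            if r % 2 or rec is None:
                continue
            mate = assign.get(r + 1)
            if mate is None:
                continue
            ca, _, sa = rec
            cb, _, sb = mate
            if ca == cb:
                continue
            # fragment frame: mate1 forward, mate2 reverse-complemented
            def frame(s_idx, flip):
                d_read = (
                    1
                    if bool(strand[s_idx]) == (node_orient[node[s_idx]] > 0)
                    else -1
                )
                if flip:
                    d_read = -d_read
                return d_read, int(node_offset[node[s_idx]])
            da, pa = frame(sa, flip=False)
            db, pb = frame(sb, flip=True)
            la, lb = contig_len[ca], contig_len[cb]
            # distance from the hit to the gap-facing side of each contig
            tail_a = (la - pa) if da == 1 else (pa + k)
            tail_b = (pb + k) if db == 1 else (lb - pb)
            gap = insert_mean - tail_a - tail_b
            links.append(
                TemplateLink(
                    contig_a=ca, orient_a=da, contig_b=cb, orient_b=db, gap=gap
                )
            )
    return links


@dataclass
class Scaffold:
    id: int
    contigs: list[tuple[int, int, int]]  # (contig_id, orientation, gap before)


def scaffold_contigs(
    contigs: list[Contig],
    links: list[TemplateLink],
    min_links: int = 2,
    max_span: int | None = None,
) -> list[Scaffold]:
    """Greedy consistent chaining of contigs by template support.

    Links are grouped by contig pair; the majority orientation wins (an
    exact tie drops the pair); groups are applied in decreasing support
    order, accepted only when both contigs' facing ends are still free and
    the contigs lie in different chains.  `max_span` caps the chained
    span in bp: markers must stay small relative to a chromosome so the
    no-recombination-within-marker assumption holds downstream.
    """
    grouped: dict[tuple[int, int], dict[tuple[int, int], list[float]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for ln in links:
        a, da, b, db = ln.contig_a, ln.orient_a, ln.contig_b, ln.orient_b
        if a > b:  # normalize: reverse the chain
            a, da, b, db = b, -db, a, -da
        grouped[(a, b)][(da, db)].append(ln.gap)

    candidates = []
    for (a, b), combos in grouped.items():
        best = sorted(combos.items(), key=lambda kv: -len(kv[1]))
        if len(best) > 1 and len(best[0][1]) == len(best[1][1]):
            continue  # irreconcilable orientation tie
        (da, db), gaps = best[0]
        if len(gaps) < min_links:
            continue
        candidates.append((len(gaps), a, da, b, db, float(np.mean(gaps))))
    candidates.sort(key=lambda t: -t[0])

    # a chain is (members: list[(cid, orient)], gaps: list[float] between them)
    linear_ids = [c.id for c in contigs if c.status == "linear"]
    chains: dict[int, tuple[list[tuple[int, int]], list[float]]] = {
        cid: ([(cid, 1)], []) for cid in linear_ids
    }
    chain_of = {cid: cid for cid in linear_ids}

    def flipped(chain):
        members, gaps = chain
        return [(c, -o) for c, o in reversed(members)], list(reversed(gaps))

    length_of = {c.id: c.length for c in contigs}

    def chain_span(chain):
        members, gaps = chain
        return sum(length_of[c] for c, _ in members) + sum(max(1.0, g) for g in gaps)

    for support, a, da, b, db, gap in candidates:
        ra, rb = chain_of.get(a), chain_of.get(b)
        if ra is None or rb is None or ra == rb:
            continue
        ca, cb = chains[ra], chains[rb]
        if max_span is not None and (
            chain_span(ca) + chain_span(cb) + max(1.0, gap) > max_span
        ):
            continue
        oa = dict(ca[0])[a]
        ob = dict(cb[0])[b]
        # the link wants: a (orient da), gap, then b (orient db)
        if oa * da < 0:
            ca = flipped(ca)
        if ca[0][-1][0] != a:
            continue  # a's gap-facing end is already occupied
        if ob * db < 0:
            cb = flipped(cb)
        if cb[0][0][0] != b:
            continue
        merged = (ca[0] + cb[0], ca[1] + [max(1.0, gap)] + cb[1])
        del chains[ra], chains[rb]
        chains[ra] = merged
        for c, _ in merged[0]:
            chain_of[c] = ra

    scaffolds = []
    for sid, (members, gaps) in enumerate(chains.values()):
        entry = [(members[0][0], members[0][1], 0)]
        for (c, o), g in zip(members[1:], gaps):
            entry.append((c, o, int(round(g))))
        scaffolds.append(Scaffold(id=sid, contigs=entry))
    return scaffolds


def consensus(
    scaffold: Scaffold,
    contigs: list[Contig],
    nodeset: NodeSet,
    reads=None,
    fill_gaps: bool = True,
) -> str:
    """Scaffold consensus: oriented contig consensi joined by N gaps."""
    by_id = {c.id: c for c in contigs}
    parts = []
    for i, (cid, orient, gap) in enumerate(scaffold.contigs):
        seq = _contig_consensus(by_id[cid], nodeset, reads=reads, fill_gaps=fill_gaps)
        if orient == -1:
            seq = revcomp_str(seq)
        if i > 0:
            parts.append("N" * max(1, gap))
        parts.append(seq)
    return "".join(parts)


def contig_consensus(
    contig: Contig, nodeset: NodeSet, reads=None, fill_gaps: bool = True
) -> str:
    return _contig_consensus(contig, nodeset, reads=reads, fill_gaps=fill_gaps)


def write_fasta(
    path,
    scaffolds: list[Scaffold],
    contigs: list[Contig],
    nodeset: NodeSet,
    reads=None,
) -> None:
    """Scaffold consensus sequences as FASTA; headers carry node and SNP counts."""
    by_id = {c.id: c for c in contigs}
    with open(path, "w") as fh:
        for s in scaffolds:
            nodes = [n for cid, _, _ in s.contigs for n in by_id[cid].node_ids()]
            n_snps = sum(1 for n in nodes if nodeset.nodes[n].kind == "snpmer")
            seq = consensus(s, contigs, nodeset, reads=reads)
            fh.write(
                f">scaffold_{s.id} nodes={len(nodes)} snps={n_snps} len={len(seq)}\n"
            )
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# stats


def assembly_stats(lengths) -> dict[str, float]:
    """count / total span / mean span / N50 (span-weighted median length)."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("no lengths")
    total = int(arr.sum())
    cum = np.cumsum(arr)
    n50 = int(arr[np.searchsorted(cum, total / 2)])
    return {
        "count": int(arr.size),
        "total_span": total,
        "mean_span": float(total / arr.size),
        "n50_span": n50,
    }
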
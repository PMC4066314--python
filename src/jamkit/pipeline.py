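"""End-to-end orchestration: reads -> k-mer profile -> markers -> genetic map.

Thin glue over the stage modules, for running the whole mapping protocol
on a read set in one call.  Also houses truth-evaluation helpers used to
score a run against a simulated cross.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assembly as asm
from . import genotyping as gt
from . import kmers as km
from . import linkage as lk
from . import snpmers as sm


@dataclass
class JamRun:
    """All artifacts of a pipeline run."""

    spec: km.KmerSpec
    table: km.KmerTable
    classified: sm.ClassifiedKmers
    selection: sm.NodeSelection
    nodeset: asm.NodeSet
    contigs: list[asm.Contig]
    scaffolds: list[asm.Scaffold]
    markers: list[gt.MarkerCounts]
    results: list[gt.GenotypeResult]
    marker_table: pd.DataFrame
    genetic_map: lk.GeneticMap | None
    hits: list[asm.SampleHits] = field(repr=False, default_factory=list)

    def scaffold_consensus(self, reads=None) -> dict[str, str]:
        return {
            f"scaffold_{s.id}": asm.consensus(s, self.contigs, self.nodeset, reads=reads)
            for s in self.scaffolds
        }


def run_jam(
    reads,
    mother: str = "mother",
    father: str = "father",
    spec: km.KmerSpec | None = None,
    run_groups: dict[str, str] | None = None,
    min_kmer_count: int = 3,
    slice_id: int = 0,
    min_links: int = 2,
    max_marker_span: int | None = 4000,
    min_snps_map: int = 18,
    epsilon: float = 0.01,
    restarts: int = 5,
    seed: int | None = None,
    build_map: bool = True,
    map_kwargs: dict | None = None,
) -> JamRun:
    """Run the full joint assembly and mapping protocol.

    `reads` is a `simulate.ReadSet` or a mapping sample -> FASTQ path;
    the two parent sample names must be given.  Markers with at least
    `min_snps_map` SNPs and high-confidence genotypes feed the map.
    """
    if spec is None:
        spec = km.KmerSpec(k=23)
    table = km.filter_kmers(
        km.count_kmers(reads, spec, run_groups=run_groups), min_total=min_kmer_count
    )
    classified = sm.classify_kmers(table)
    selection = sm.select_nodes(classified, slice_id=slice_id)
    nodeset = asm.build_node_set(selection, table)

    from .simulate import ReadSet

    if not isinstance(reads, ReadSet):
        raise TypeError("run_jam needs a ReadSet; load FASTQ via simulate.load_readset")
    sample_names = list(reads.samples.keys())
    offspring = [s for s in sample_names if s not in (mother, father)]
    ordered_samples = [mother, father] + offspring

    hits = [
        asm.scan_sample(reads.samples[s].seqs, reads.samples[s].quals, nodeset, spec, s)
        for s in ordered_samples
    ]
    graph = asm.build_kmer_graph(nodeset, hits)
    asm.mark_robust_edges(graph)
    contigs = asm.extract_contigs(graph)
    links = asm.map_templates(
        contigs, hits, nodeset, insert_mean=getattr(reads, "insert_mean", 300.0)
    )
    scaffolds = asm.scaffold_contigs(
        contigs, links, min_links=min_links, max_span=max_marker_span
    )

    markers = extract_marker_counts(scaffolds, contigs, nodeset, hits, ordered_samples)
    results = []
    rows = []
    rng = np.random.default_rng(seed)
    for mc in markers:
        if mc.n_sites < 1:
            continue
        res = gt.em_genotype(
            mc,
            epsilon=epsilon,
            restarts=restarts,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        results.append(res)
        rows.append(
            {
                "marker_id": mc.marker_id,
                "pattern": res.pattern(),
                "n_snps": mc.n_sites,
                "mean_phase_prob": res.mean_phase_prob,
                "high_confidence": res.high_confidence,
                "mean_confidence": float(res.confidence[2:].mean()),
            }
        )
    marker_table = pd.DataFrame(rows)

    genetic_map = None
    if build_map and len(marker_table):
        usable = marker_table[
            (marker_table["n_snps"] >= min_snps_map) & marker_table["high_confidence"]
        ].reset_index(drop=True)
        if len(usable):
            genetic_map = lk.build_genetic_map(usable, **(map_kwargs or {}))
    return JamRun(
        spec=spec,
        table=table,
        classified=classified,
        selection=selection,
        nodeset=nodeset,
        contigs=contigs,
        scaffolds=scaffolds,
        markers=markers,
        results=results,
        marker_table=marker_table,
        genetic_map=genetic_map,
        hits=hits,
    )


def extract_marker_counts(
    scaffolds: list[asm.Scaffold],
    contigs: list[asm.Contig],
    nodeset: asm.NodeSet,
    hits: list[asm.SampleHits],
    samples: list[str],
) -> list[gt.MarkerCounts]:
    """Per-scaffold SNP-site allele counts from node k-mer hits.

    Every SNPmer node inside a scaffold is a site; a sample's lo/hi counts
    at the site are its read k-mer hits on the two alleles.
    """
    n_nodes = len(nodeset)
    n_samples = len(samples)
    counts = np.zeros((n_nodes, n_samples, 2), dtype=np.int32)
    sample_idx = {s: i for i, s in enumerate(samples)}
    for sh in hits:
        j = sample_idx[sh.sample]
        np.add.at(counts, (sh.node, j, sh.is_hi.astype(np.int8)), 1)

    by_id = {c.id: c for c in contigs}
    k = nodeset.k
    out: list[gt.MarkerCounts] = []
    for s in scaffolds:
        site_nodes = []
        for cid, orient, _gap in s.contigs:
            cnodes = by_id[cid].node_ids()
            if orient == -1:
                cnodes = cnodes[::-1]
            site_nodes += [n for n in cnodes if nodeset.nodes[n].kind == "snpmer"]
        if not site_nodes:
            continue
        alleles = [nodeset.nodes[n].alleles(k) for n in site_nodes]
        idx = np.array(site_nodes)
        out.append(
            gt.MarkerCounts(
                marker_id=f"scaffold_{s.id}",
                samples=samples,
                alleles=alleles,
                n_lo=counts[idx, :, 0],
                n_hi=counts[idx, :, 1],
                n_other=np.zeros((idx.size, n_samples), dtype=np.int32),
                site_meta=pd.DataFrame({"node": site_nodes}),
            )
        )
    return out


# ---------------------------------------------------------------------------
# truth evaluation (for simulated crosses)


def kmer_position_index(hap_sets, k: int) -> dict[int, tuple[int, int]]:
    """Canonical k-mer -> (chromosome, position) over all four haplotypes."""
    from ._kcode import canonical_codes, kmer_codes

    index: dict[int, tuple[int, int]] = {}
    for chrom, hs in enumerate(hap_sets):
        for hap in hs.haplotypes:
            codes, valid = kmer_codes(hap, k)
            canon, _ = canonical_codes(codes, k)
            for pos in np.flatnonzero(valid):
                index.setdefault(int(canon[pos]), (chrom, int(pos)))
    return index


def locate_markers(run: JamRun, hap_sets) -> pd.DataFrame:
    """Median source (chromosome, position) of each marker's node k-mers."""
    index = kmer_position_index(hap_sets, run.spec.k)
    by_id = {c.id: c for c in run.contigs}
    rows = []
    for s in run.scaffolds:
        locs = []
        for cid, _orient, _gap in s.contigs:
            for n in by_id[cid].node_ids():
                node = run.nodeset.nodes[n]
                loc = index.get(node.code_lo)
                if loc is not None:
                    locs.append(loc)
        if not locs:
            continue
        chroms = np.array([c for c, _ in locs])
        chrom = int(np.bincount(chroms).argmax())
        pos = int(np.median([p for c, p in locs if c == chrom]))
        purity = float((chroms == chrom).mean())
        rows.append(
            {
                "marker_id": f"scaffold_{s.id}",
                "chrom": chrom,
                "pos": pos,
                "location_purity": purity,
            }
        )
    return pd.DataFrame(rows)


def true_patterns_at(crosses, locations: pd.DataFrame, n_offspring: int) -> dict[str, np.ndarray]:
    """True offspring genotype codes at each located marker."""
    out = {}
    for _, row in locations.iterrows():
        ct = crosses[int(row["chrom"])]
        out[row["marker_id"]] = np.array(
            [int(ct.true_genotype(j, int(row["pos"]))) for j in range(n_offspring)]
        )
    return out


def genotype_accuracy(
    run: JamRun, crosses, hap_sets, min_confidence: float = 0.0
) -> pd.DataFrame:
    """Per-marker comparison of inferred vs true genotypes (best relabeling)."""
    n_off = len(crosses[0].offspring)
    locs = locate_markers(run, hap_sets)
    truth = true_patterns_at(crosses, locs, n_off)
    rows = []
    for res in run.results:
        t = truth.get(res.marker_id)
        if t is None:
            continue
        pat = res.pattern(min_confidence)
        called = pat >= 0
        best_err, best_r = 1.0, 0
        for r in range(4):
            if called.sum() == 0:
                break
            err = float(((pat[called] ^ r) != t[called]).mean())
            if err < best_err:
                best_err, best_r = err, r
        conf = res.confidence[2:]
        rows.append(
            {
                "marker_id": res.marker_id,
                "n_called": int(called.sum()),
                "error_rate": best_err if called.any() else np.nan,
                "relabeling": best_r,
                "mean_confidence": float(conf[called].mean()) if called.any() else 0.0,
                "high_confidence": res.high_confidence,
            }
        )
    df = pd.DataFrame(rows)
    return df.merge(locs, on="marker_id", how="left")


def call_level_errors(
    run: JamRun, crosses, hap_sets, high_confidence_only: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """(confidence, is_error) arrays over individual offspring calls.

    By default only markers whose restarts agreed (high-confidence, the
    calls the error model is calibrated on) contribute.
    """
    n_off = len(crosses[0].offspring)
    locs = locate_markers(run, hap_sets)
    truth = true_patterns_at(crosses, locs, n_off)
    confs, errs = [], []
    for res in run.results:
        t = truth.get(res.marker_id)
        if t is None:
            continue
        if high_confidence_only and not res.high_confidence:
            continue
        pat = res.pattern()
        called = pat >= 0
        if not called.any():
            continue
        best_r = min(
            range(4), key=lambda r: ((pat[called] ^ r) != t[called]).sum()
        )
        conf = res.confidence[2:]
        confs.extend(conf[called])
        errs.extend((pat[called] ^ best_r) != t[called])
    return np.asarray(confs, dtype=float), np.asarray(errs, dtype=bool)
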
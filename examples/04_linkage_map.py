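"""Run the whole pipeline on a simulated cross and build the genetic map.

Reads -> k-mer table -> SNPmers -> contigs/scaffolds -> EM genotypes ->
map bins -> linkage groups -> ordered map.  The simulated chromosomes are
physically small but genetically long (high cM/Mb), so offspring patterns
recombine as on real chromosomes.
"""

from jamkit import pipeline as pl
from jamkit import simulate as sim

hap_sets, crosses, reads = sim.simulate_cross_readset(
    length=100_000, n_chromosomes=2, n_offspring=34,
    coverage_parents=20, coverage_offspring=5, error_rate=0.002,
    maternal_cM_per_Mb=250, paternal_cM_per_Mb=150, seed=5,
)
run = pl.run_jam(reads, seed=6)

linear = [c for c in run.contigs if c.status == "linear"]
print(f"contigs: {len(linear)}  scaffolds: {len(run.scaffolds)}")
print(f"markers genotyped: {len(run.marker_table)}  "
      f"with >=18 SNPs: {(run.marker_table.n_snps >= 18).sum()}")
gm = run.genetic_map
if gm is not None:
    print(f"linkage groups: {gm.n_groups}  sizes: {[len(g) for g in gm.groups]}")
acc = pl.genotype_accuracy(run, crosses, hap_sets)
good = acc[["marker_id", "error_rate", "high_confidence"]].merge(
    run.marker_table[["marker_id", "n_snps"]], on="marker_id"
)
good = good[(good.n_snps >= 18) & good.high_confidence]
print(f"high-confidence marker genotype error vs truth: "
      f"{good.error_rate.mean():.4f} over {len(good)} markers")
# Two linkage groups should be recovered, one per simulated chromosome,
# and high-confidence marker genotypes should match the cross truth
# almost perfectly.
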
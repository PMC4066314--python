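"""Simulate an outbred cross with sequencing reads and inspect the truth.

Four haplotypes are drawn from the neutral coalescent (theta = 0.012,
rho = 0.0085 per site, the calibration design), paired into two parents,
crossed into 8 offspring, and sequenced at 20X (parents) / 5X (offspring).
"""

import numpy as np

from jamkit import simulate as sim

hap_sets, crosses, reads = sim.simulate_cross_readset(
    length=100_000, theta=0.012, rho=0.0085, n_offspring=8,
    coverage_parents=20, coverage_offspring=5, error_rate=0.002, seed=1,
)
hs = hap_sets[0]
print(f"SNPs on the 100 kb chromosome: {len(hs.snp_truth)}")
print(f"realized SNP density: {1000 * hs.snp_density:.1f} per kb "
      f"(Watterson expectation {1000 * hs.theta * sim.harmonic(4):.1f})")
print(f"singleton fraction: {sim.singleton_fraction(hs):.3f} "
      f"(infinite-sites analytic {sim.expected_singleton_fraction_infinite_sites():.3f})")

ct = crosses[0]
pos = np.array([10_000, 50_000, 90_000])
print("offspring 0 genotypes at 10/50/90 kb:", list(ct.genotype_labels(0, pos)))
n_reads = sum(2 * s.n_pairs for s in reads.samples.values())
print(f"simulated {n_reads} reads across {len(reads.samples)} samples")
# The genotype labels name which maternal (a/b) and paternal (c/d)
# chromosome the offspring inherited at each position; crossovers along
# the chromosome switch one letter at a time.
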
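"""Profile k-mers of a diploid sample set and decompose the spectrum.

The 23-mer frequency spectrum of a polymorphic diploid genome is a
mixture of four Poisson components at depths d, 3d/4, d/2, d/4 —
homozygous loci, major, tied and minor alleles.  The fit estimates the
sequencing depth d, the allele-class fractions, and the genome size.
"""

from jamkit import kmers as km
from jamkit import simulate as sim

hs = sim.simulate_haplotypes(80_000, 0.012, 0.0085, seed=3)
genomes = {
    "mother": [(hs.haplotypes[0], hs.haplotypes[1])],
    "father": [(hs.haplotypes[2], hs.haplotypes[3])],
}
reads = sim.simulate_reads(genomes, {"mother": 20, "father": 20},
                           error_rate=0.002, seed=4)

spec = km.KmerSpec(k=23)
table = km.filter_kmers(km.count_kmers(reads, spec))
fit = km.fit_poisson_mixture(table.histogram())

print(f"distinct filtered 23-mers: {len(table):,}")
print(f"modeled homozygous depth d = {fit.d:.1f}")
for cls, frac in fit.locus_fractions.items():
    print(f"  {cls:<12s} {100 * frac:5.1f}% of modeled loci")
print(f"SNP base fraction estimate: {100 * fit.snp_density_estimate(23):.2f}%")
print(f"genome size estimate: {fit.genome_size_estimate(table.total_occurrences):,.0f} bp"
      f" (true 80,000)")
# d reflects the combined 40X of the two parents minus masking and
# window-edge losses; the bi-allelic locus fractions divided by k give
# the fraction of bases that are SNPs.
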
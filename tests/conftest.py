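import numpy as np
import pytest

from jamkit import genotyping as gt
from jamkit import kmers as km
from jamkit import simulate as sim


@pytest.fixture(scope="session")
def calib_haplotypes():
    """Small haplotype set at the calibration design's rates."""
    return sim.simulate_haplotypes(50_000, 0.012, 0.0085, seed=101)


@pytest.fixture(scope="session")
def diploid_readset(calib_haplotypes):
    """Two deep error-free diploid samples (a,b) and (c,d)."""
    hs = calib_haplotypes
    genomes = {
        "mother": [(hs.haplotypes[0], hs.haplotypes[1])],
        "father": [(hs.haplotypes[2], hs.haplotypes[3])],
    }
    return sim.simulate_reads(
        genomes, {"mother": 25.0, "father": 25.0}, error_rate=0.0, seed=7
    )


@pytest.fixture(scope="session")
def filtered_table(diploid_readset):
    spec = km.KmerSpec(k=23)
    return km.filter_kmers(km.count_kmers(diploid_readset, spec))


def random_marker(rng, n_sites, n_offspring, depth_offspring=2.0, depth_parent=8.0,
                  epsilon=0.01):
    """Marker read counts drawn from a random phase/genotype configuration."""
    phases = [gt._PHASES[rng.integers(gt.N_PHASES)] for _ in range(n_sites)]
    true_g = rng.integers(0, 4, n_offspring)
    samples = ["mother", "father"] + [f"off{j}" for j in range(n_offspring)]
    counts = np.zeros((n_sites, 2 + n_offspring, 4), dtype=int)
    for i, (a, b, c, d) in enumerate(phases):
        for j in range(2 + n_offspring):
            if j == 0:
                alleles = (a, b)
            elif j == 1:
                alleles = (c, d)
            else:
                g = true_g[j - 2]
                alleles = ((a, b)[g >> 1], (c, d)[g & 1])
            depth = rng.poisson(depth_parent if j < 2 else depth_offspring)
            for _ in range(depth):
                base = alleles[rng.integers(2)]
                if rng.random() < epsilon:
                    base = rng.integers(4)
                counts[i, j, base] += 1
    mc = gt.MarkerCounts.from_base_counts(
        "m", samples, [("A", "C")] * n_sites, counts
    )
    return mc, true_g, phases
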
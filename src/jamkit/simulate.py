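"""Synthetic outbred crosses and sequencing reads with known truth.

The generator reproduces the calibration design used to benchmark the
mapping pipeline: four haploid genomes are drawn from a neutral
Wright-Fisher coalescent (population mutation rate theta, population
recombination rate rho, both per site), paired into two outbred diploid
parents (chromosomes a,b maternal and c,d paternal), offspring are formed
by recombinant gametes, and Illumina-like 100 bp paired-end reads on
~300 bp inserts are sampled at the requested fold coverage.

The coalescent is an SMC-like approximation: the chromosome is split into
blocks whose lengths are exponential with rate (rho/2)*(total tree branch
length), and an independent Kingman tree is drawn per block.  This is not
a full ancestral recombination graph, but it reproduces the Watterson
segregating-site density and the n=4 site-frequency spectrum, which is
what the downstream calibration consumes.  Mutations fall as a Poisson
process on tree branches; in finite-sites mode they land on discrete
positions with reuse permitted (recurrent hits can create tri-allelic
sites, which are recorded and flagged).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._kcode import decode_bases

GENOTYPE_LABELS = ("ac", "ad", "bc", "bd")

# harmonic number a_{n-1} for n haplotypes; a_3 = 1 + 1/2 + 1/3
def harmonic(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


# ---------------------------------------------------------------------------
# haplotypes


@dataclass
class HaplotypeSet:
    """Four haplotypes with full SNP truth.

    haplotypes are uint8 base-code arrays (A=0..T=3); `snp_truth` is a
    DataFrame with columns pos, hapA..hapD (bases), n_alleles, biallelic.
    """

    length: int
    haplotypes: list[np.ndarray]
    theta: float
    rho: float
    snp_truth: pd.DataFrame = field(repr=False)

    def sequences(self) -> list[str]:
        return [decode_bases(h) for h in self.haplotypes]

    @property
    def snp_density(self) -> float:
        return len(self.snp_truth) / self.length

    def truth_table(self) -> pd.DataFrame:
        return self.snp_truth.copy()


def _kingman_branches(rng: np.random.Generator, n: int = 4):
    """Sample a Kingman coalescent tree for n lineages.

    Returns (masks, lengths): leaf-set bitmask and branch length for every
    non-root lineage, in coalescent time units of 2N generations.
    """
    masks = [1 << i for i in range(n)]
    born = [0.0] * n
    out_masks: list[int] = []
    out_lens: list[float] = []
    t = 0.0
    while len(masks) > 1:
        m = len(masks)
        t += rng.exponential(2.0 / (m * (m - 1)))
        i, j = rng.choice(m, size=2, replace=False)
        if i > j:
            i, j = j, i
        for idx in (i, j):
            out_masks.append(masks[idx])
            out_lens.append(t - born[idx])
        merged = masks[i] | masks[j]
        masks[i] = merged
        born[i] = t
        del masks[j]
        del born[j]
    return np.array(out_masks), np.array(out_lens)


def simulate_haplotypes(
    length: int,
    theta: float,
    rho: float,
    *,
    finite_sites: bool = True,
    seed: int | None = None,
) -> HaplotypeSet:
    """Draw 4 haplotypes of `length` bp from the neutral coalescent.

    theta and rho are the population mutation and recombination rates per
    site (the calibration design uses 0.012 and 0.0085).  Expected
    segregating-site density is ~theta * (1 + 1/2 + 1/3) before recurrent
    hits.
    """
    length = int(length)
    if length < 1:
        raise ValueError("length must be >= 1")
    if theta < 0 or rho < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    anc = rng.integers(0, 4, size=length, dtype=np.uint8)
    haps = np.tile(anc, (4, 1))

    mut_sites: list[int] = []
    mut_masks: list[int] = []
    # Block lengths use the *expected* tree length 2*a_{n-1}, independent of
    # the realized tree: coupling them to the drawn tree would length-bias
    # genome coverage toward short trees and depress the SNP density.
    expected_tree_len = 2.0 * harmonic(4)
    pos = 0
    while pos < length:
        masks, lens = _kingman_branches(rng)
        total_len = float(lens.sum())
        if rho > 0:
            block = 1 + int(rng.exponential(2.0 / (rho * expected_tree_len)))
        else:
            block = length
        end = min(length, pos + block)
        n_mut = rng.poisson(0.5 * theta * total_len * (end - pos))
        if n_mut:
            sites = pos + rng.integers(0, end - pos, size=n_mut)
            branch = rng.choice(len(lens), size=n_mut, p=lens / total_len)
            mut_sites.extend(int(s) for s in sites)
            mut_masks.extend(int(masks[b]) for b in branch)
        pos = end

    if not finite_sites:
        # infinite-sites mode: force every mutation onto a fresh position
        used: set[int] = set()
        for idx, s in enumerate(mut_sites):
            while s in used:
                s = int(rng.integers(0, length))
            used.add(s)
            mut_sites[idx] = s

    order = rng.permutation(len(mut_sites))
    for idx in order:
        site = mut_sites[idx]
        mask = mut_masks[idx]
        carriers = [h for h in range(4) if mask >> h & 1]
        cur = int(haps[carriers[0], site])
        new = (cur + 1 + int(rng.integers(0, 3))) % 4
        for h in carriers:
            haps[h, site] = new

    seg = (haps != haps[0]).any(axis=0)
    positions = np.flatnonzero(seg)
    cols = haps[:, positions]
    n_alleles = np.array(
        [len(np.unique(cols[:, i])) for i in range(cols.shape[1])], dtype=np.int8
    )
    bases = np.array(list("ACGT"))
    truth = pd.DataFrame(
        {
            "pos": positions,
            "hapA": bases[cols[0]],
            "hapB": bases[cols[1]],
            "hapC": bases[cols[2]],
            "hapD": bases[cols[3]],
            "n_alleles": n_alleles,
        }
    )
    truth["biallelic"] = truth["n_alleles"] == 2
    return HaplotypeSet(
        length=length,
        haplotypes=[haps[i] for i in range(4)],
        theta=theta,
        rho=rho,
        snp_truth=truth,
    )


def singleton_fraction(hs: HaplotypeSet) -> float:
    """Fraction of bi-allelic SNPs whose minor allele sits on one haplotype.

    The infinite-sites expectation for n=4 is (1 + 1/3)/(1 + 1/2 + 1/3)
    = 8/11 ~ 0.727; finite-sites recurrent mutation pushes it slightly
    higher at realistic densities.
    """
    tt = hs.snp_truth
    bi = tt[tt["biallelic"]]
    if len(bi) == 0:
        raise ValueError("haplotype set has no bi-allelic SNPs")
    alleles = bi[["hapA", "hapB", "hapC", "hapD"]].to_numpy()
    first = alleles[:, :1]
    n_first = (alleles == first).sum(axis=1)
    singleton = (n_first == 1) | (n_first == 3)
    return float(singleton.mean())


def expected_singleton_fraction_infinite_sites(n: int = 4) -> float:
    """Analytic unfolded SFS: P(count=i) ~ 1/i; singletons are i in {1, n-1}."""
    weights = [1.0 / i for i in range(1, n)]
    return (weights[0] + weights[-1]) / sum(weights)


# ---------------------------------------------------------------------------
# cross


@dataclass
class Gamete:
    start: int  # which parental haplotype the gamete begins on (0 or 1)
    breakpoints: np.ndarray  # strictly increasing crossover positions

    def hap_index(self, pos: np.ndarray | int) -> np.ndarray | int:
        crossed = np.searchsorted(self.breakpoints, pos, side="right")
        return (self.start + crossed) % 2


@dataclass
class Offspring:
    maternal: Gamete
    paternal: Gamete


@dataclass
class CrossTruth:
    haplotype_set: HaplotypeSet
    offspring: list[Offspring]

    def true_genotype(self, off: int, pos: np.ndarray | int) -> np.ndarray | int:
        """Genotype code at pos: 0=ac, 1=ad, 2=bc, 3=bd."""
        o = self.offspring[off]
        return 2 * o.maternal.hap_index(pos) + o.paternal.hap_index(pos)

    def genotype_labels(self, off: int, pos) -> np.ndarray:
        codes = np.atleast_1d(self.true_genotype(off, pos))
        return np.array(GENOTYPE_LABELS)[codes]

    def offspring_genome(self, off: int) -> tuple[np.ndarray, np.ndarray]:
        """Materialize the diploid genome (maternal, paternal sequences)."""
        hs = self.haplotype_set
        o = self.offspring[off]
        pos = np.arange(hs.length)
        mat = np.where(o.maternal.hap_index(pos) == 0, hs.haplotypes[0], hs.haplotypes[1])
        pat = np.where(o.paternal.hap_index(pos) == 0, hs.haplotypes[2], hs.haplotypes[3])
        return mat.astype(np.uint8), pat.astype(np.uint8)

    def cross_table(self) -> pd.DataFrame:
        rows = []
        for i, o in enumerate(self.offspring):
            for parent, g in (("maternal", o.maternal), ("paternal", o.paternal)):
                rows.append(
                    {
                        "offspring": i,
                        "parent": parent,
                        "start_hap": g.start,
                        "breakpoints": ",".join(str(b) for b in g.breakpoints),
                    }
                )
        return pd.DataFrame(rows)


def simulate_cross(
    hs: HaplotypeSet,
    n_offspring: int,
    maternal_cM_per_Mb: float = 1.28,
    paternal_cM_per_Mb: float = 0.76,
    seed: int | None = None,
) -> CrossTruth:
    """Cross haplotypes (a,b) x (c,d) to produce recombinant offspring.

    Crossover counts per gamete are Poisson with mean rate*length; default
    sex-specific rates follow the study's estimates of 1.28 (maternal) and
    0.76 (paternal) cM/Mb.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    if maternal_cM_per_Mb < 0 or paternal_cM_per_Mb < 0:
        raise ValueError("recombination rates must be non-negative")
    rng = np.random.default_rng(seed)
    length = hs.length
    means = [
        maternal_cM_per_Mb * length / 1e6 / 100.0,
        paternal_cM_per_Mb * length / 1e6 / 100.0,
    ]
    offspring = []
    for _ in range(n_offspring):
        gametes = []
        for mean in means:
            n_xo = rng.poisson(mean)
            bkps = np.unique(rng.integers(1, length, size=n_xo))
            gametes.append(Gamete(start=int(rng.integers(0, 2)), breakpoints=bkps))
        offspring.append(Offspring(maternal=gametes[0], paternal=gametes[1]))
    return CrossTruth(haplotype_set=hs, offspring=offspring)


# ---------------------------------------------------------------------------
# reads


@dataclass
class SampleReads:
    """Paired reads for one sample: 2D uint8 code arrays (n_pairs*2, read_len)."""

    name: str
    seqs: np.ndarray
    quals: np.ndarray  # Phred scores, same shape

    @property
    def n_pairs(self) -> int:
        return self.seqs.shape[0] // 2

    def pair(self, i: int) -> tuple[str, str, str, str]:
        s1 = decode_bases(self.seqs[2 * i])
        s2 = decode_bases(self.seqs[2 * i + 1])
        q1 = (self.quals[2 * i] + 33).tobytes().decode("ascii")
        q2 = (self.quals[2 * i + 1] + 33).tobytes().decode("ascii")
        return s1, q1, s2, q2


@dataclass
class ReadSet:
    samples: dict[str, SampleReads]
    read_len: int
    insert_mean: float
    insert_sd: float
    error_rate: float

    def iter_fastq(self, sample: str):
        """Yield (name, seq, qual) interleaved mate records."""
        sr = self.samples[sample]
        for i in range(sr.n_pairs):
            s1, q1, s2, q2 = sr.pair(i)
            yield f"{sample}:{i}:1", s1, q1
            yield f"{sample}:{i}:2", s2, q2

    def write_fastq(self, out_dir: str | Path, gz: bool = False) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sample in self.samples:
            path = out_dir / (f"{sample}.fastq.gz" if gz else f"{sample}.fastq")
            opener = gzip.open if gz else open
            with opener(path, "wt") as fh:
                for name, seq, qual in self.iter_fastq(sample):
                    fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
            paths[sample] = path
        return paths


def simulate_reads(
    genomes: dict[str, list[tuple[np.ndarray, np.ndarray]]],
    coverages: dict[str, float],
    read_len: int = 100,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    error_rate: float = 0.002,
    low_q_fraction: float = 0.05,
    seed: int | None = None,
) -> ReadSet:
    """Sample paired-end reads from diploid genomes.

    `genomes` maps sample name -> list of (haplotype1, haplotype2) base-code
    arrays, one tuple per chromosome.  Fragments are uniform over
    haplotypes and positions; read 2 is the reverse complement of the
    fragment end.  Substitution errors are applied at `error_rate` on
    average, concentrated on a low-quality (Q15) tier of bases so that the
    q20 masking rule removes most of them, with the remaining bases at Q35.
    """
    for s, c in coverages.items():
        if c <= 0:
            raise ValueError(f"coverage must be positive for sample {s}")
    if read_len > insert_mean:
        raise ValueError("read_len exceeds mean insert length")
    rng = np.random.default_rng(seed)

    # tier error weights: mean error over bases equals error_rate
    p_low_raw, p_high_raw = 10 ** -1.5, 10 ** -3.5
    z = low_q_fraction * p_low_raw + (1 - low_q_fraction) * p_high_raw
    w_low, w_high = p_low_raw / z, p_high_raw / z

    samples = {}
    for name, chroms in genomes.items():
        cov = coverages[name]
        lengths = np.array([c[0].size for c in chroms], dtype=np.int64)
        total = int(lengths.sum())
        n_frag = max(1, int(round(cov * total / (2 * read_len))))
        chrom_idx = rng.choice(len(chroms), size=n_frag, p=lengths / total)
        hap_idx = rng.integers(0, 2, size=n_frag)
        inserts = np.clip(
            np.round(rng.normal(insert_mean, insert_sd, size=n_frag)).astype(np.int64),
            read_len,
            None,
        )
        seqs = np.empty((2 * n_frag, read_len), dtype=np.uint8)
        for ci, (hap_a, hap_b) in enumerate(chroms):
            for hi, hap in enumerate((hap_a, hap_b)):
                sel = np.flatnonzero((chrom_idx == ci) & (hap_idx == hi))
                if sel.size == 0:
                    continue
                ins = np.minimum(inserts[sel], hap.size)
                starts = (rng.random(sel.size) * (hap.size - ins + 1)).astype(np.int64)
                offs = np.arange(read_len)
                r1 = hap[starts[:, None] + offs]
                r2_fwd = hap[(starts + ins - read_len)[:, None] + offs]
                r2 = 3 - r2_fwd[:, ::-1]  # reverse complement
                seqs[2 * sel] = r1
                seqs[2 * sel + 1] = r2
        # qualities and errors: the low-quality (Q15) tier is an exponential
        # run at the 3' end of each read (mean length low_q_fraction*read_len),
        # mimicking the end-of-read quality decay that q20 masking trims;
        # scattering it uniformly would destroy most k-length windows
        n_reads = seqs.shape[0]
        tail = np.minimum(
            read_len,
            np.round(rng.exponential(low_q_fraction * read_len, n_reads)).astype(int),
        )
        low = np.arange(read_len)[None, :] >= (read_len - tail)[:, None]
        quals = np.where(low, 15, 35).astype(np.uint8)
        if error_rate > 0:
            p_err = np.where(low, error_rate * w_low, error_rate * w_high)
            err = rng.random(seqs.shape) < p_err
            shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
            seqs[err] = (seqs[err] + shift) % 4
        samples[name] = SampleReads(name=name, seqs=seqs, quals=quals)
    return ReadSet(
        samples=samples,
        read_len=read_len,
        insert_mean=insert_mean,
        insert_sd=insert_sd,
        error_rate=error_rate,
    )


def load_readset(source: dict[str, str | Path] | str | Path) -> ReadSet:
    """Load per-sample FASTQ into a ReadSet (uniform read length required).

    `source` is a directory of <sample>.fastq[.gz] files or a mapping
    sample -> path.  Mates are assumed interleaved (rows 2i, 2i+1), as
    written by `ReadSet.write_fastq`.
    """
    from ._kcode import encode
    from .kmers import read_fastq

    if isinstance(source, (str, Path)):
        src = Path(source)
        paths = {}
        for p in sorted(src.iterdir()):
            name = p.name
            for suf in (".fastq.gz", ".fq.gz", ".fastq", ".fq"):
                if name.endswith(suf):
                    paths[name[: -len(suf)]] = p
                    break
    else:
        paths = {k: Path(v) for k, v in source.items()}
    samples = {}
    read_len = None
    for sample, path in paths.items():
        seqs, quals = [], []
        for _name, seq, qual in read_fastq(path):
            if read_len is None:
                read_len = len(seq)
            if len(seq) != read_len:
                raise ValueError("load_readset requires uniform read lengths")
            seqs.append(encode(seq))
            quals.append(
                np.frombuffer(qual.encode("ascii"), dtype=np.uint8) - 33
            )
        samples[sample] = SampleReads(
            name=sample,
            seqs=np.vstack(seqs) if seqs else np.empty((0, 0), np.uint8),
            quals=np.vstack(quals) if quals else np.empty((0, 0), np.uint8),
        )
    return ReadSet(
        samples=samples,
        read_len=read_len or 0,
        insert_mean=300.0,
        insert_sd=30.0,
        error_rate=float("nan"),
    )


# ---------------------------------------------------------------------------
# whole-design convenience


def simulate_cross_readset(
    length: int = 200_000,
    theta: float = 0.012,
    rho: float = 0.0085,
    n_offspring: int = 34,
    coverage_parents: float = 20.0,
    coverage_offspring: float = 5.0,
    n_chromosomes: int = 1,
    error_rate: float = 0.002,
    maternal_cM_per_Mb: float = 1.28,
    paternal_cM_per_Mb: float = 0.76,
    seed: int | None = None,
    **read_kwargs,
):
    """Full calibration design: haplotypes -> cross -> reads for all samples.

    Returns (haplotype_sets, cross_truths, read_set).  Parent samples are
    named "mother" and "father"; offspring "off00".."offNN".  With more
    than one chromosome, each gets an independent coalescent and cross.
    """
    rng = np.random.default_rng(seed)
    hap_sets, crosses = [], []
    for _ in range(n_chromosomes):
        hs = simulate_haplotypes(
            length, theta, rho, seed=int(rng.integers(0, 2**31 - 1))
        )
        hap_sets.append(hs)
        crosses.append(
            simulate_cross(
                hs,
                n_offspring,
                maternal_cM_per_Mb=maternal_cM_per_Mb,
                paternal_cM_per_Mb=paternal_cM_per_Mb,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    genomes: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
        "mother": [(hs.haplotypes[0], hs.haplotypes[1]) for hs in hap_sets],
        "father": [(hs.haplotypes[2], hs.haplotypes[3]) for hs in hap_sets],
    }
    for j in range(n_offspring):
        genomes[f"off{j:02d}"] = [ct.offspring_genome(j) for ct in crosses]
    coverages = {name: coverage_offspring for name in genomes}
    coverages["mother"] = coverage_parents
    coverages["father"] = coverage_parents
    reads = simulate_reads(
        genomes,
        coverages,
        error_rate=error_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
        **read_kwargs,
    )
    return hap_sets, crosses, reads


def write_truth(
    out_dir: str | Path,
    hap_sets: list[HaplotypeSet],
    crosses: list[CrossTruth],
    params: dict,
) -> None:
    """TSV truth tables plus a JSON manifest of all parameters."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    snp = pd.concat(
        [hs.truth_table().assign(chrom=i) for i, hs in enumerate(hap_sets)],
        ignore_index=True,
    )
    snp.to_csv(out_dir / "snp_truth.tsv", sep="\t", index=False)
    pd.concat(
        [ct.cross_table().assign(chrom=i) for i, ct in enumerate(crosses)],
        ignore_index=True,
    ).to_csv(out_dir / "cross_truth.tsv", sep="\t", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(params, fh, indent=2, default=str)
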
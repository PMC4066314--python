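"""Quality masking, canonical k-mer counting and frequency-spectrum modeling.

Reads are hard-masked (bases below Phred 20 become N) and soft-masked
(below 30 become lowercase); odd-length k-mers are counted in canonical
form with a per-sample presence bit vector and per-sequencing-run tallies.
The k-mer frequency spectrum of a diploid cross decomposes into four
linked Poisson components: homozygous loci sequenced at the full depth d,
major alleles at 3d/4, tied alleles at d/2 and minor alleles at d/4.
Fitting that mixture yields the depth d, the allele-class weights, a
genome-size estimate (total k-mer occurrences / d) and a SNP-density
estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _kcode
from ._kcode import INVALID, canonical_codes, encode, kmer_codes

MAX_SAMPLES = 64


@dataclass
class KmerSpec:
    """Counting parameters: odd k <= 31, masking thresholds, hash slicing.

    Hash slicing tabulates only k-mers whose canonical integer code is
    congruent to `slice_id` modulo the prime `slice_factor`; the union of
    tables over all slice ids equals the unsliced table exactly.
    """

    k: int = 23
    hard_quality: int = 20
    soft_quality: int = 30
    slice_factor: int | None = None
    slice_id: int | None = None

    def __post_init__(self):
        if self.k % 2 == 0 or not 1 <= self.k <= 31:
            raise ValueError("k must be odd and <= 31")
        if self.slice_factor is not None:
            if not _is_prime(self.slice_factor):
                raise ValueError("slice_factor must be prime")
            if self.slice_id is None or not 0 <= self.slice_id < self.slice_factor:
                raise ValueError("slice_id must lie in [0, slice_factor)")


def _is_prime(n: int) -> bool:
    from sympy import isprime

    return bool(isprime(int(n)))


# ---------------------------------------------------------------------------
# uniqueness bound


def poisson_unique_prob(G: float, k: int) -> float:
    """P(a genomic location has its own unique k-mer) = exp(-2G/4^k).

    Models the genome as G draws from the 4^k/2 canonical odd k-mers, so a
    location collides with ~2G/4^k expected co-occupants.
    """
    if G < 0:
        raise ValueError("G must be non-negative")
    return math.exp(-2.0 * G / 4**k)


def min_k(G: float, R: float) -> int:
    """Smallest k with expected k-mer sharing rate at most R.

    Inverts 1 - exp(-2G/4^k) <= R, i.e. k >= ceil(log4(-2G / ln(1-R))).
    For a mammalian-scale 3 Gb genome at R = 0.1% this gives k = 22.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    if not 0.0 < R < 1.0:
        raise ValueError("R must lie in (0, 1)")
    k = max(1, math.ceil(math.log(-2.0 * G / math.log1p(-R), 4)))
    # guard the float boundary: walk to the true smallest k meeting the bound
    while 1.0 - poisson_unique_prob(G, k) > R:
        k += 1
    while k > 1 and 1.0 - poisson_unique_prob(G, k - 1) <= R:
        k -= 1
    return k


# ---------------------------------------------------------------------------
# masking


@dataclass
class MaskedRead:
    name: str
    seq: str
    qualifies: bool


def _detect_offset(quals: Iterable[str], default: int = 33) -> int:
    for q in quals:
        if any(ord(c) < 64 for c in q):
            return 33
        if any(ord(c) > 74 for c in q):
            return 64
    return default


def mask_read(seq: str, qual: str, spec: KmerSpec, offset: int = 33) -> MaskedRead:
    if len(seq) != len(qual):
        raise ValueError("malformed FASTQ record: sequence/quality length mismatch")
    q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - offset
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    is_base = arr != ord("N")
    soft = (q < spec.soft_quality) & is_base
    arr[soft] += 32  # lowercase
    arr[q < spec.hard_quality] = ord("N")
    masked = arr.tobytes().decode("ascii")
    run = _longest_true_run(arr != ord("N"))
    return MaskedRead(name="", seq=masked, qualifies=run >= spec.k)


def _longest_true_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return int((edges[1::2] - edges[::2]).max())


def mask_and_qualify_reads(
    records: Iterable[tuple[str, str, str]],
    spec: KmerSpec,
    quality_offset: int | str = 33,
) -> Iterator[MaskedRead]:
    """Mask FASTQ records (name, seq, qual) and flag qualifying reads.

    Bases below the hard threshold become N, below the soft threshold
    lowercase; a read qualifies if it retains >= k consecutive non-N bases.
    `quality_offset` may be 33, 64 or "auto" (sniffed from the first
    records; Phred+33 assumed when ambiguous).
    """
    records = iter(records)
    buffered: list[tuple[str, str, str]] = []
    if quality_offset == "auto":
        buffered = [r for _, r in zip(range(50), records)]
        quality_offset = _detect_offset((q for _, _, q in buffered))
    for name, seq, qual in (*buffered, *records):
        mr = mask_read(seq, qual, spec, offset=int(quality_offset))
        mr.name = name
        yield mr


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """(name, seq, qual) triples from a FASTQ file (gzip ok)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    path = Path(path)
    if path.suffix == ".gz":
        import gzip

        with gzip.open(path, "rt") as fh:
            yield from FastqGeneralIterator(fh)
    else:
        with open(path) as fh:
            yield from FastqGeneralIterator(fh)


# ---------------------------------------------------------------------------
# counting


@dataclass
class KmerTable:
    """Canonical k-mers with counts, per-sample presence bits and run tallies."""

    k: int
    kmers: np.ndarray  # sorted uint64 canonical codes
    counts: np.ndarray  # total occurrences
    presence: np.ndarray  # uint64 bitmask over samples
    run_counts: np.ndarray  # (n_kmers, n_runs) occurrences per run group
    samples: list[str]
    run_labels: list[str]

    def __len__(self) -> int:
        return self.kmers.size

    @property
    def total_occurrences(self) -> int:
        return int(self.counts.sum())

    def subset(self, mask: np.ndarray) -> "KmerTable":
        return KmerTable(
            self.k,
            self.kmers[mask],
            self.counts[mask],
            self.presence[mask],
            self.run_counts[mask],
            self.samples,
            self.run_labels,
        )

    def histogram(self) -> np.ndarray:
        """Number of distinct k-mers at each total frequency."""
        return np.bincount(self.counts.astype(np.int64))

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)

    def to_frame(self, max_rows: int | None = None) -> pd.DataFrame:
        n = len(self) if max_rows is None else min(max_rows, len(self))
        return pd.DataFrame(
            {
                "kmer": [_kcode.decode_kmer(int(c), self.k) for c in self.kmers[:n]],
                "count": self.counts[:n],
                "presence": [f"{int(p):x}" for p in self.presence[:n]],
                **{
                    f"run_{lbl}": self.run_counts[:n, i]
                    for i, lbl in enumerate(self.run_labels)
                },
            }
        )

    def write_tsv(self, path: str | Path, max_rows: int | None = None) -> None:
        self.to_frame(max_rows).to_csv(path, sep="\t", index=False)


def _sample_code_stream(source, sample: str, spec: KmerSpec) -> np.ndarray:
    """Concatenated masked base codes for one sample, reads separated by 255."""
    from .simulate import ReadSet

    if isinstance(source, ReadSet):
        sr = source.samples[sample]
        codes = np.where(sr.quals >= spec.hard_quality, sr.seqs, INVALID)
        sep = np.full((codes.shape[0], 1), INVALID, dtype=np.uint8)
        return np.concatenate([codes, sep], axis=1).ravel()
    item = source[sample]
    if isinstance(item, (str, Path)):
        records = read_fastq(item)
    else:
        records = iter(item)
    chunks: list[np.ndarray] = []
    sep = np.array([INVALID], dtype=np.uint8)
    for rec in records:
        seq, qual = rec[-2], rec[-1]
        c = encode(seq)
        q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
        c = np.where(q >= spec.hard_quality, c, INVALID)
        chunks.append(c)
        chunks.append(sep)
    if not chunks:
        return np.empty(0, dtype=np.uint8)
    return np.concatenate(chunks)


def count_kmers(
    reads,
    spec: KmerSpec,
    run_groups: dict[str, str] | None = None,
) -> KmerTable:
    """Tabulate canonical k-mers across samples.

    `reads` is a `simulate.ReadSet` or a mapping sample -> FASTQ path or
    iterable of (name, seq, qual) / (seq, qual) records.  k-mer windows
    containing a hard-masked base are skipped; soft-masked bases count.
    `run_groups` maps each sample to a sequencing-run label (default: all
    samples in one run, which disables the two-run filter downstream).
    """
    from .simulate import ReadSet

    samples = (
        list(reads.samples.keys()) if isinstance(reads, ReadSet) else list(reads.keys())
    )
    if len(samples) > MAX_SAMPLES:
        raise ValueError(f"at most {MAX_SAMPLES} sample libraries supported")
    if run_groups is None:
        run_groups = {s: "1" for s in samples}
    run_labels = sorted(set(run_groups.values()))
    run_of = np.array([run_labels.index(run_groups[s]) for s in samples])

    per_sample: list[tuple[np.ndarray, np.ndarray]] = []
    for s in samples:
        base_codes = _sample_code_stream(reads, s, spec)
        codes, valid = kmer_codes(base_codes, spec.k)
        codes = codes[valid]
        canon, _ = canonical_codes(codes, spec.k)
        if spec.slice_factor is not None:
            canon = canon[
                canon % np.uint64(spec.slice_factor) == np.uint64(spec.slice_id)
            ]
        uniq, cnt = np.unique(canon, return_counts=True)
        per_sample.append((uniq, cnt))

    if per_sample and any(u.size for u, _ in per_sample):
        all_kmers = np.unique(np.concatenate([u for u, _ in per_sample]))
    else:
        all_kmers = np.empty(0, dtype=np.uint64)
    counts = np.zeros(all_kmers.size, dtype=np.int64)
    presence = np.zeros(all_kmers.size, dtype=np.uint64)
    run_counts = np.zeros((all_kmers.size, len(run_labels)), dtype=np.int64)
    for i, (uniq, cnt) in enumerate(per_sample):
        idx = np.searchsorted(all_kmers, uniq)
        counts[idx] += cnt
        presence[idx] |= np.uint64(1 << i)
        run_counts[idx, run_of[i]] += cnt
    return KmerTable(
        k=spec.k,
        kmers=all_kmers,
        counts=counts,
        presence=presence,
        run_counts=run_counts,
        samples=samples,
        run_labels=run_labels,
    )


def filter_kmers(
    table: KmerTable, min_total: int = 3, require_all_runs: bool = True
) -> KmerTable:
    """Drop likely-artifact k-mers.

    Keeps k-mers with at least `min_total` copies overall and (when more
    than one run group is defined) at least one copy in every run group —
    incomplete adapter fragments differ between runs and fail the latter.
    """
    keep = table.counts >= min_total
    if require_all_runs and len(table.run_labels) > 1:
        keep &= (table.run_counts > 0).all(axis=1)
    return table.subset(keep)


# ---------------------------------------------------------------------------
# Poisson mixture decomposition

_COMPONENTS = ("homozygous", "major", "tied", "minor")
_DEPTH_FRACTIONS = (1.0, 0.75, 0.5, 0.25)


@dataclass
class PoissonMixtureFit:
    """Four-component fit to the k-mer frequency spectrum.

    Component means are locked at (d, 3d/4, d/2, d/4); amplitudes are the
    modeled numbers of distinct k-mers of each allele class.  Locus
    accounting: a homozygous locus contributes one k-mer at depth d, a
    major-minor locus one each at 3d/4 and d/4, a tied locus two at d/2.
    """

    d: float
    amplitudes: dict[str, float]
    fit_range: tuple[int, int]
    residual_ss: float
    repeat_tail: float  # observed distinct k-mers above the fit range

    @property
    def component_means(self) -> dict[str, float]:
        return {c: self.d * f for c, f in zip(_COMPONENTS, _DEPTH_FRACTIONS)}

    @property
    def unique_locus_count(self) -> float:
        a = self.amplitudes
        return a["homozygous"] + (a["major"] + a["minor"]) / 2 + a["tied"] / 2

    @property
    def locus_fractions(self) -> dict[str, float]:
        """Fractions of modeled loci: homozygous / major-minor / tied."""
        a = self.amplitudes
        tot = self.unique_locus_count
        return {
            "homozygous": a["homozygous"] / tot,
            "major_minor": (a["major"] + a["minor"]) / 2 / tot,
            "tied": a["tied"] / 2 / tot,
        }

    def snp_density_estimate(self, k: int) -> float:
        """Fraction of bases in unique loci that are SNPs.

        Bi-allelic loci tile each SNP with up to k k-mer windows, so the
        SNP base fraction is the bi-allelic locus share divided by k.
        """
        f = self.locus_fractions
        return (f["major_minor"] + f["tied"]) / k

    def genome_size_estimate(self, total_kmer_occurrences: float) -> float:
        return genome_size_estimate(total_kmer_occurrences, self.d)

    def expected(self, freqs: np.ndarray) -> np.ndarray:
        out = np.zeros(len(freqs), dtype=float)
        for c, f in zip(_COMPONENTS, _DEPTH_FRACTIONS):
            out += self.amplitudes[c] * stats.poisson.pmf(freqs, self.d * f)
        return out


def fit_poisson_mixture(
    histogram: np.ndarray | dict[int, int],
    fit_range: tuple[int, int] = (3, 70),
) -> PoissonMixtureFit:
    """Least-squares fit of the 4-component Poisson mixture to a spectrum.

    `histogram[f]` is the number of distinct k-mers with total frequency f.
    The fitted curve is constrained not to exceed the observed count at any
    frequency in `fit_range` (repeats inflate the observed spectrum, so the
    model must stay below it).  Amplitudes are solved by non-negative least
    squares at each candidate depth d; d is optimized by bounded search
    seeded from the spectrum mode.
    """
    if isinstance(histogram, dict):
        h = np.zeros(max(histogram) + 1, dtype=float)
        for f, c in histogram.items():
            h[f] = c
    else:
        h = np.asarray(histogram, dtype=float)
    lo, hi = fit_range
    hi = min(hi, len(h) - 1)
    if hi < lo:
        raise ValueError("histogram empty on fit range")
    freqs = np.arange(lo, hi + 1)
    obs = h[lo : hi + 1]
    if obs.sum() <= 0:
        raise ValueError("histogram empty on fit range")

    mode = freqs[np.argmax(obs)]

    def solve(d: float) -> tuple[float, np.ndarray]:
        M = np.column_stack([stats.poisson.pmf(freqs, d * f) for f in _DEPTH_FRACTIONS])
        amps = optimize.nnls(M, obs)[0]
        resid = obs - M @ amps
        return float(resid @ resid), amps

    d_lo = max(float(lo) + 0.5, 0.5 * float(mode))
    d_hi = max(2.0 * float(mode), d_lo + 2.0)
    grid = np.linspace(d_lo, d_hi, 60)
    sses = [solve(d)[0] for d in grid]
    d0 = float(grid[int(np.argmin(sses))])
    res = optimize.minimize_scalar(
        lambda d: solve(d)[0],
        bounds=(max(d_lo, d0 - 2.0), min(d_hi, d0 + 2.0)),
        method="bounded",
    )
    d_best = float(res.x)
    sse, amps = solve(d_best)
    if amps.sum() <= 0:
        raise ValueError("degenerate histogram: no mass fit on the range")
    # enforce "fitted curve does not exceed the observed counts" by a uniform
    # amplitude scale (class fractions are scale-invariant).  Where the
    # observed count is zero the model is held below one count, the
    # observable resolution.
    M = np.column_stack(
        [stats.poisson.pmf(freqs, d_best * f) for f in _DEPTH_FRACTIONS]
    )
    fit = M @ amps
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fit > 0, np.maximum(obs, 0.999) / fit, np.inf)
    scale = min(1.0, float(ratio.min()))
    amps = amps * scale
    sse = float(((obs - M @ amps) ** 2).sum())
    return PoissonMixtureFit(
        d=d_best,
        amplitudes=dict(zip(_COMPONENTS, (float(a) for a in amps))),
        fit_range=(lo, hi),
        residual_ss=sse,
        repeat_tail=float(h[hi + 1 :].sum()),
    )


def genome_size_estimate(total_kmer_occurrences: float, d: float) -> float:
    """Genome size = total filtered k-mer occurrences / homozygous depth d."""
    if d <= 0:
        raise ValueError("depth d must be positive")
    return total_kmer_occurrences / d


# ---------------------------------------------------------------------------
# sequence composition


def sequence_composition(sequences, min_len: int = 1000) -> tuple[pd.DataFrame, dict]:
    """Per-sequence GC%, CpG observed/expected and dinucleotide statistics.

    `sequences` is a FASTA path or an iterable of (id, seq).  Returns a
    per-sequence DataFrame plus a summary with the Pearson correlation
    between CpG density and TpG+CpA density across sequences (germ-line
    CpG methylation depletes CpG and creates TpG/CpA in its place).
    """
    if isinstance(sequences, (str, Path)):
        from Bio import SeqIO

        sequences = ((r.id, str(r.seq)) for r in SeqIO.parse(str(sequences), "fasta"))
    dinucs = [a + b for a in "ACGT" for b in "ACGT"]
    rows = []
    for sid, seq in sequences:
        seq = seq.upper()
        if len(seq) < min_len:
            continue
        codes = encode(seq)
        valid = codes != INVALID
        n_valid = int(valid.sum())
        if n_valid == 0:
            continue
        counts = dict(zip("ACGT", np.bincount(codes[valid], minlength=4)))
        # overlapping dinucleotide counts over valid adjacent pairs
        pair_ok = valid[:-1] & valid[1:]
        pair_codes = codes[:-1][pair_ok].astype(np.int16) * 4 + codes[1:][pair_ok]
        di_tally = np.bincount(pair_codes, minlength=16)
        di_counts = {d: int(di_tally[i]) for i, d in enumerate(dinucs)}
        n_di = int(di_tally.sum())
        exp_cpg = counts["C"] * counts["G"] / n_valid
        row = {
            "id": sid,
            "length": len(seq),
            "gc_percent": (counts["G"] + counts["C"]) / n_valid * 100,
            "cpg_oe": di_counts["CG"] / exp_cpg if exp_cpg > 0 else np.nan,
            "cpg_density": di_counts["CG"] / n_di if n_di else np.nan,
            "tpg_cpa_density": (di_counts["TG"] + di_counts["CA"]) / n_di
            if n_di
            else np.nan,
        }
        row.update(
            {f"di_{d}": c / n_di if n_di else np.nan for d, c in di_counts.items()}
        )
        rows.append(row)
    if not rows:
        raise ValueError("no sequences of at least min_len bases")
    df = pd.DataFrame(rows)
    summary = {
        "n_sequences": len(df),
        "gc_mean": float(df["gc_percent"].mean()),
        "gc_sd": float(df["gc_percent"].std()),
    }
    ok = df[["cpg_density", "tpg_cpa_density"]].dropna()
    if len(ok) >= 3 and ok["cpg_density"].nunique() > 1:
        r, p = stats.pearsonr(ok["cpg_density"], ok["tpg_cpa_density"])
        summary["cpg_tpgcpa_r"] = float(r)
        summary["cpg_tpgcpa_p"] = float(p)
    return df, summary
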
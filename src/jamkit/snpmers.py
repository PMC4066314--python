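"""SNPmer identification and node k-mer selection.

A filtered k-mer either has no one-substitution neighbor in the table
(*unique*), exactly one neighbor which itself has no other neighbor
(*partnered* — a "SNPmer pair", the two alleles of an isolated SNP), or
anything else (*ambiguous*).  Neighborhoods are computed in canonical
space: a neighbor relation exists if any orientation combination of the
two k-mers is Hamming-1.

For graph assembly the node set is thinned: SNPmer pairs are kept only
when the substituted position falls in a small, reverse-complement-
symmetric set of positions ({3, 12, 21} for k = 23, a 23/3 = 7.67-fold
reduction), and unpartnered unique k-mers are kept by hash slicing with a
non-Mersenne prime modulus (11 by default — remainders modulo Mersenne
primes mix poorly for base-4 codes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kcode import canonical_codes, decode_kmer
from .kmers import KmerTable, _is_prime

UNIQUE, PARTNERED, AMBIGUOUS = 0, 1, 2
CATEGORY_NAMES = {UNIQUE: "unique", PARTNERED: "partnered", AMBIGUOUS: "ambiguous"}

TRANSITION = "transition"
COMPL_TRANSVERSION = "complementary_transversion"
NONCOMPL_TRANSVERSION = "non_complementary_transversion"


def change_class(base_from: int, base_to: int) -> str:
    """Substitution class for 2-bit base codes (A=0,C=1,G=2,T=3)."""
    if base_from == base_to:
        raise ValueError("not a substitution")
    pair = {base_from, base_to}
    if pair in ({0, 2}, {1, 3}):  # A<->G, C<->T
        return TRANSITION
    if pair in ({0, 3}, {1, 2}):  # A<->T, C<->G
        return COMPL_TRANSVERSION
    return NONCOMPL_TRANSVERSION


@dataclass
class SnpmerPair:
    """Two canonical k-mers differing at exactly one position.

    `sub_position` is 1-based within the canonical form of `kmer_lo`;
    `rc_partner` records whether the partner's canonical form pairs via
    reverse complement rather than in the same sense.
    """

    kmer_lo: int
    kmer_hi: int
    sub_position: int
    change: str
    rc_partner: bool

    def decode(self, k: int) -> tuple[str, str]:
        return decode_kmer(self.kmer_lo, k), decode_kmer(self.kmer_hi, k)


@dataclass
class ClassifiedKmers:
    """Output of `classify_kmers`: per-k-mer categories plus the pair set."""

    table: KmerTable
    categories: np.ndarray  # int8 per table row
    pairs: list[SnpmerPair]
    pair_index: dict[int, int] = field(repr=False, default_factory=dict)

    def counts(self) -> dict[str, int]:
        tally = np.bincount(self.categories, minlength=3)
        return {CATEGORY_NAMES[c]: int(tally[c]) for c in (UNIQUE, PARTNERED, AMBIGUOUS)}

    def pair_frame(self) -> pd.DataFrame:
        k = self.table.k
        return pd.DataFrame(
            [
                {
                    "kmer_lo": decode_kmer(p.kmer_lo, k),
                    "kmer_hi": decode_kmer(p.kmer_hi, k),
                    "sub_position": p.sub_position,
                    "change": p.change,
                    "rc_partner": p.rc_partner,
                }
                for p in self.pairs
            ]
        )


def classify_kmers(table: KmerTable) -> ClassifiedKmers:
    """Partition a filtered table into unique / partnered / ambiguous.

    For every k-mer all 3k one-substitution variants are generated, mapped
    to canonical form and looked up in the table; a k-mer is partnered iff
    it has exactly one neighbor and is that neighbor's only neighbor.
    """
    k = table.k
    kmers = table.kmers
    n = kmers.size
    if n == 0:
        return ClassifiedKmers(
            table=table, categories=np.empty(0, np.int8), pairs=[], pair_index={}
        )
    neighbor_hits = np.zeros(n, dtype=np.int32)
    partner_idx = np.full(n, -1, dtype=np.int64)
    partner_pos = np.zeros(n, dtype=np.int16)
    partner_delta = np.zeros(n, dtype=np.int8)  # packed (old_base, new_base)
    partner_rc = np.zeros(n, dtype=bool)
    self_pairing = np.zeros(n, dtype=bool)
    rows = np.arange(n)

    for pos in range(1, k + 1):
        shift = np.uint64(2 * (k - pos))
        old = (kmers >> shift) & np.uint64(3)
        for delta in (1, 2, 3):
            new = (old + np.uint64(delta)) & np.uint64(3)
            variant = (kmers & ~(np.uint64(3) << shift)) | (new << shift)
            canon, fwd = canonical_codes(variant, k)
            idx = np.searchsorted(kmers, canon)
            idx[idx >= n] = n - 1
            hit = kmers[idx] == canon
            # a k-mer one substitution from its own reverse complement would
            # "pair" with itself; treat as unresolvable rather than partnered
            self_hit = hit & (idx == rows)
            hit &= ~self_hit
            self_pairing |= self_hit
            neighbor_hits += hit
            partner_idx[hit] = idx[hit]
            partner_pos[hit] = pos
            partner_delta[hit] = ((old[hit] << np.uint64(2)) | new[hit]).astype(np.int8)
            partner_rc[hit] = ~fwd[hit]

    mutual = (
        (neighbor_hits == 1)
        & ~self_pairing
        & (neighbor_hits[np.clip(partner_idx, 0, n - 1)] == 1)
        & ~self_pairing[np.clip(partner_idx, 0, n - 1)]
    )
    categories = np.full(n, AMBIGUOUS, dtype=np.int8)
    categories[(neighbor_hits == 0) & ~self_pairing] = UNIQUE
    categories[mutual] = PARTNERED

    pairs: list[SnpmerPair] = []
    pair_index: dict[int, int] = {}
    lo_side = mutual & (kmers < kmers[np.clip(partner_idx, 0, n - 1)])
    for i in np.flatnonzero(lo_side):
        j = int(partner_idx[i])
        d = int(partner_delta[i])
        pair = SnpmerPair(
            kmer_lo=int(kmers[i]),
            kmer_hi=int(kmers[j]),
            sub_position=int(partner_pos[i]),
            change=change_class(d >> 2, d & 3),
            rc_partner=bool(partner_rc[i]),
        )
        pair_index[int(kmers[i])] = len(pairs)
        pair_index[int(kmers[j])] = len(pairs)
        pairs.append(pair)
    return ClassifiedKmers(
        table=table, categories=categories, pairs=pairs, pair_index=pair_index
    )


# ---------------------------------------------------------------------------
# category summary (a SNPmer pair counts as one k-mer)


@dataclass
class KmerCategorySummary:
    unique: int
    partnered: int  # number of SNPmer *pairs*
    ambiguous: int
    k: int

    @property
    def total(self) -> int:
        return self.unique + self.partnered + self.ambiguous

    @property
    def percentages(self) -> dict[str, float]:
        t = self.total
        return {
            "unique": 100.0 * self.unique / t,
            "partnered": 100.0 * self.partnered / t,
            "ambiguous": 100.0 * self.ambiguous / t,
        }

    @property
    def snpmer_share_of_unique_markers(self) -> float:
        """SNPmer pairs as a fraction of putative genomically unique markers."""
        denom = self.unique + self.partnered
        return self.partnered / denom if denom else 0.0

    @property
    def snp_base_fraction(self) -> float:
        """Putative SNP bases per marker base: the SNPmer share divided by k."""
        return self.snpmer_share_of_unique_markers / self.k


def summarize_categories(
    unique: int, partnered_pairs: int, ambiguous: int, k: int = 23
) -> KmerCategorySummary:
    if min(unique, partnered_pairs, ambiguous) < 0:
        raise ValueError("counts must be non-negative")
    if unique + partnered_pairs + ambiguous == 0:
        raise ValueError("zero total")
    return KmerCategorySummary(unique, partnered_pairs, ambiguous, k)


# ---------------------------------------------------------------------------
# node selection


def smallest_non_mersenne_prime_above(x: float) -> int:
    """Least prime > x that is not of the form 2^q - 1 (with 2^q - 1 prime)."""
    if x < 1:
        raise ValueError("x must be >= 1")
    from sympy import isprime, nextprime

    p = nextprime(x)
    while isprime(p) and ((p + 1) & p) == 0:  # p+1 a power of two => Mersenne
        p = nextprime(p)
    return int(p)


def default_snp_positions(k: int, n_positions: int = 3) -> tuple[int, ...]:
    """Evenly spaced, reverse-complement-symmetric substitution positions.

    For k=23 this returns (3, 12, 21): position p maps to k+1-p under
    reverse complement, so the set must be closed under that map for the
    selection to be orientation-independent.
    """
    if n_positions < 1 or n_positions > k - 4:
        raise ValueError("n_positions out of range")
    # spread from position 3 to k-2, avoiding the error-enriched end positions
    pos = tuple(
        int(round(p)) for p in np.linspace(3, k - 2, n_positions)
    )
    if any((k + 1 - p) not in pos for p in pos):
        raise ValueError(f"positions {pos} not reverse-complement symmetric for k={k}")
    return pos


@dataclass
class NodeSelection:
    """Subsampled node set for the k-mer graph, with reduction accounting."""

    classified: ClassifiedKmers
    snp_positions: tuple[int, ...]
    slice_factor: int
    slice_id: int
    selected_pairs: list[SnpmerPair]
    selected_unique: np.ndarray  # canonical codes

    @property
    def snpmer_reduction_factor(self) -> float:
        return self.classified.table.k / len(self.snp_positions)

    @property
    def n_nodes(self) -> int:
        return len(self.selected_pairs) + self.selected_unique.size

    def report(self) -> dict[str, float]:
        counts = self.classified.counts()
        n_pairs = len(self.classified.pairs)
        sel = self.n_nodes
        before = counts["unique"] + n_pairs  # pairs counted once
        return {
            "snpmer_reduction_factor": self.snpmer_reduction_factor,
            "slice_factor": self.slice_factor,
            "nodes_before": before,
            "nodes_after": sel,
            "overall_reduction_factor": before / sel if sel else float("inf"),
        }


def select_nodes(
    classified: ClassifiedKmers,
    snp_positions: tuple[int, ...] | None = None,
    slice_factor: int | None = None,
    slice_id: int = 0,
) -> NodeSelection:
    """Thin the classified table to the assembly node set.

    SNPmer pairs survive iff their substitution position is in
    `snp_positions`; unique k-mers survive iff their canonical code is
    congruent to `slice_id` modulo `slice_factor`.  The default slicing
    factor is the smallest non-Mersenne prime above k/len(positions).
    """
    k = classified.table.k
    if snp_positions is None:
        snp_positions = default_snp_positions(k)
    if slice_factor is None:
        slice_factor = smallest_non_mersenne_prime_above(k / len(snp_positions))
    if not _is_prime(slice_factor):
        raise ValueError("slice_factor must be prime")
    if not 0 <= slice_id < slice_factor:
        raise ValueError("slice_id out of range")
    posset = set(snp_positions)
    selected_pairs = [p for p in classified.pairs if p.sub_position in posset]
    uniq_codes = classified.table.kmers[classified.categories == UNIQUE]
    sel = uniq_codes[uniq_codes % np.uint64(slice_factor) == np.uint64(slice_id)]
    return NodeSelection(
        classified=classified,
        snp_positions=tuple(snp_positions),
        slice_factor=int(slice_factor),
        slice_id=int(slice_id),
        selected_pairs=selected_pairs,
        selected_unique=sel,
    )
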
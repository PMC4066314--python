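"""Joint SNP-phase and offspring-genotype inference for marker scaffolds.

Each marker carries m tightly linked bi-allelic SNPs.  With parental
chromosomes labeled a,b (one parent) and c,d (the other), every offspring
has one of four genotypes {ac, ad, bc, bd} per marker, and every SNP site
has one of 14 phases (assignments of its two alleles to a,b,c,d, minus
the two monomorphic ones).  Read-count likelihoods are binomial for
homozygous site states and trinomial for heterozygous ones;
genotypes are inferred by incremental expectation maximization: samples
are introduced one at a time in random order, phase posteriors are
recomputed, and genotypes re-chosen to maximize the expected
log-likelihood, with five random restarts per marker.  The calibrated
error model maps the per-call confidence score (log-likelihood gap
between best and second-best genotype) to an error probability via a
double stretched exponential.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

GENOTYPES = ("ac", "ad", "bc", "bd")
MOTHER_STATE, FATHER_STATE = 4, 5  # pseudo-genotypes (a,b) and (c,d)
N_PHASES = 14


def enumerate_phases() -> list[tuple[int, int, int, int]]:
    """All 14 bi-allelic phases: allele (0/1) on each of chromosomes a,b,c,d."""
    out = []
    for bits in itertools.product((0, 1), repeat=4):
        if len(set(bits)) == 2:
            out.append(bits)
    return out


_PHASES = enumerate_phases()

# state of (phase, genotype): 0 = hom allele0, 1 = het, 2 = hom allele1
_PHASE_STATE = np.zeros((N_PHASES, 6), dtype=np.int8)
for _pi, (_a, _b, _c, _d) in enumerate(_PHASES):
    for _g, (_mat, _pat) in enumerate(((_a, _c), (_a, _d), (_b, _c), (_b, _d))):
        _PHASE_STATE[_pi, _g] = _mat + _pat
    _PHASE_STATE[_pi, MOTHER_STATE] = _a + _b
    _PHASE_STATE[_pi, FATHER_STATE] = _c + _d


# ---------------------------------------------------------------------------
# likelihoods


def site_likelihood(counts: np.ndarray, state: tuple[int, int] | str, epsilon: float) -> float:
    """Likelihood of per-base read counts under a site state.

    `counts` is length-4 (A,C,G,T); `state` an unordered base pair such as
    "AA" or "AC" (or a tuple of base indexes).  Homozygous states use the
    binomial C(n,m) eps^m (1-eps)^(n-m) with m mismatching reads;
    heterozygous states use the unnormalized trinomial form
    n!/(k! l! m!) (2eps/3)^m (1-2eps/3)^(k+l) — note the absent 1/2 per
    allele-read factor, kept for reference; inference uses the normalized
    variant (see `_site_loglik_table`).
    """
    if isinstance(state, str):
        state = tuple("ACGT".index(b) for b in state.upper())
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("negative counts")
    n = int(counts.sum())
    if n == 0:
        return 1.0
    b1, b2 = state
    if b1 == b2:
        m = n - int(counts[b1])
        return float(
            np.exp(
                gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
                + m * np.log(epsilon)
                + (n - m) * np.log1p(-epsilon)
            )
        )
    k, l = int(counts[b1]), int(counts[b2])
    m = n - k - l
    return float(
        np.exp(
            gammaln(n + 1) - gammaln(k + 1) - gammaln(l + 1) - gammaln(m + 1)
            + m * np.log(2 * epsilon / 3)
            + (k + l) * np.log1p(-2 * epsilon / 3)
        )
    )


def _site_loglik_table(
    n_lo: np.ndarray,
    n_hi: np.ndarray,
    n_other: np.ndarray,
    epsilon: float,
    normalized: bool = True,
) -> np.ndarray:
    """Log-likelihood of (sites x samples) counts under the 3 site states.

    Returns array (m, n_samples, 3): hom-allele0, het, hom-allele1.  With
    `normalized` (the default, used by the EM) each heterozygous allele
    read has probability (1-2eps/3)/2; without it the unnormalized form is
    evaluated, under which the het state dominates every hom state and
    genotype inference degenerates — kept only as the literal value of the
    classic formula (see `site_likelihood`).
    """
    n = n_lo + n_hi + n_other
    log_eps = np.log(epsilon)
    log_1me = np.log1p(-epsilon)
    log_e23 = np.log(2 * epsilon / 3)
    log_1me23 = np.log1p(-2 * epsilon / 3)
    if normalized:
        log_1me23 -= np.log(2.0)
    lg = gammaln
    out = np.empty((*n.shape, 3))
    m0 = n - n_lo
    out[..., 0] = lg(n + 1) - lg(m0 + 1) - lg(n - m0 + 1) + m0 * log_eps + (n - m0) * log_1me
    m2 = n - n_hi
    out[..., 2] = lg(n + 1) - lg(m2 + 1) - lg(n - m2 + 1) + m2 * log_eps + (n - m2) * log_1me
    out[..., 1] = (
        lg(n + 1) - lg(n_lo + 1) - lg(n_hi + 1) - lg(n_other + 1)
        + n_other * log_e23
        + (n_lo + n_hi) * log_1me23
    )
    return out


# ---------------------------------------------------------------------------
# marker data


@dataclass
class MarkerCounts:
    """Per-site, per-sample allele read counts for one marker.

    `alleles[i]` gives the two base letters of site i; counts are split as
    lo/hi (the two alleles) plus other (mismatching bases).  `samples`
    must start with the two parents (mother, father).
    """

    marker_id: str
    samples: list[str]
    alleles: list[tuple[str, str]]
    n_lo: np.ndarray  # (m, n_samples)
    n_hi: np.ndarray
    n_other: np.ndarray
    site_meta: pd.DataFrame | None = None

    @property
    def n_sites(self) -> int:
        return len(self.alleles)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @classmethod
    def from_base_counts(
        cls, marker_id: str, samples: list[str], alleles, base_counts: np.ndarray
    ) -> "MarkerCounts":
        """From a full (m, n_samples, 4) A/C/G/T count array."""
        alleles = [tuple(a) for a in alleles]
        idx_lo = np.array(["ACGT".index(a[0]) for a in alleles])
        idx_hi = np.array(["ACGT".index(a[1]) for a in alleles])
        m = np.arange(len(alleles))
        n_lo = base_counts[m, :, idx_lo]
        n_hi = base_counts[m, :, idx_hi]
        n_other = base_counts.sum(axis=2) - n_lo - n_hi
        return cls(marker_id, list(samples), alleles, n_lo, n_hi, n_other)


@dataclass
class GenotypeResult:
    marker_id: str
    samples: list[str]
    genotypes: np.ndarray  # int codes per sample, -1 for parents / no call
    confidence: np.ndarray  # log-likelihood gap best vs second best
    phase_posterior: np.ndarray  # (m, 14)
    phase_map: list[tuple[int, int, int, int]]
    expected_loglik: float
    consistent_restarts: int
    n_restarts: int
    converged: bool

    @property
    def high_confidence(self) -> bool:
        return self.consistent_restarts >= (self.n_restarts // 2 + 1)

    @property
    def mean_phase_prob(self) -> float:
        return float(self.phase_posterior.max(axis=1).mean())

    def pattern(self, min_confidence: float = 0.0) -> np.ndarray:
        """Offspring genotype codes with low-confidence calls set to -1."""
        pat = self.genotypes[2:].copy()
        pat[self.confidence[2:] <= min_confidence] = -1
        return pat

    def calls_frame(self) -> pd.DataFrame:
        rows = []
        for j, s in enumerate(self.samples):
            g = self.genotypes[j]
            rows.append(
                {
                    "marker": self.marker_id,
                    "sample": s,
                    "genotype": GENOTYPES[g] if g >= 0 else None,
                    "confidence": self.confidence[j],
                }
            )
        return pd.DataFrame(rows)


def _relabel(genos: np.ndarray, r: int) -> np.ndarray:
    """Apply parental relabeling r (bit1: swap a/b, bit0: swap c/d)."""
    out = genos.copy()
    called = out >= 0
    out[called] = out[called] ^ r
    return out


def canonical_genotype_vector(genos: np.ndarray) -> tuple:
    return min(tuple(_relabel(genos, r)) for r in range(4))


def em_genotype(
    marker: MarkerCounts,
    epsilon: float = 0.01,
    restarts: int = 5,
    seed: int | None = None,
    max_sweeps: int = 100,
    tol: float = 1e-6,
) -> GenotypeResult:
    """Incremental EM over phases and genotypes with random restarts.

    The parents anchor the labeling: the first two samples are assigned the
    pseudo-genotypes (a,b) and (c,d); one random offspring starts at (a,c).
    Each iteration updates the phase posteriors, admits one more random
    sample, then re-chooses every included offspring's genotype to maximize
    the expected log likelihood.  Restarts differ in their random admission
    order; a marker is high-confidence when a majority of restarts agree on
    the genotype vector up to parental relabeling.
    """
    if marker.n_sites < 1:
        raise ValueError("marker has no SNPs")
    if not 0.0 < epsilon < 0.25:
        raise ValueError("epsilon must lie in (0, 0.25)")
    ll = _site_loglik_table(marker.n_lo, marker.n_hi, marker.n_other, epsilon)
    m, n = ll.shape[:2]
    offspring = np.arange(2, n)

    best: dict | None = None
    vectors = []
    for r in range(restarts):
        rng = np.random.default_rng(None if seed is None else seed + r)
        geno = np.full(n, -1, dtype=np.int64)
        sample_state = np.empty(n, dtype=np.int64)
        sample_state[0] = MOTHER_STATE
        sample_state[1] = FATHER_STATE
        included = np.zeros(n, dtype=bool)
        included[:2] = True
        first = int(rng.choice(offspring)) if offspring.size else None
        if first is not None:
            geno[first] = 0  # (a, c), without loss of generality
            included[first] = True
        order = [j for j in rng.permutation(offspring) if j != first]
        pending = list(order)
        prev_obj = -np.inf
        converged = False
        for _ in range(max_sweeps):
            sample_state[offspring] = np.where(
                geno[offspring] >= 0, geno[offspring], 0
            )
            sel = np.flatnonzero(included)
            states = _PHASE_STATE[:, sample_state[sel]]  # (14, |sel|)
            lp = np.zeros((m, N_PHASES))
            for p in range(N_PHASES):
                lp[:, p] = np.take_along_axis(
                    ll[:, sel, :], states[p][None, :, None], axis=2
                )[:, :, 0].sum(axis=1)
            post = np.exp(lp - logsumexp(lp, axis=1, keepdims=True))
            if pending:
                j_new = pending.pop(0)
                included[j_new] = True
            # M-step: per offspring, expected score per genotype
            inc_off = [j for j in np.flatnonzero(included) if j >= 2]
            # score[j, g] = sum_i sum_p post[i,p] * ll[i, j, _PHASE_STATE[p, g]]
            wll = np.einsum("ip,ijs->jps", post, ll[:, inc_off, :])  # (|off|, 14, 3)
            scores = np.zeros((len(inc_off), 4))
            for g in range(4):
                scores[:, g] = np.take_along_axis(
                    wll, _PHASE_STATE[:, g][None, :, None], axis=2
                )[:, :, 0].sum(axis=1)
            geno[inc_off] = np.argmax(scores, axis=1)
            # objective: expected log likelihood over included samples
            sample_state[offspring] = np.where(
                geno[offspring] >= 0, geno[offspring], 0
            )
            sel = np.flatnonzero(included)
            states = _PHASE_STATE[:, sample_state[sel]]
            obj = 0.0
            for p in range(N_PHASES):
                obj += float(
                    (
                        post[:, p]
                        * np.take_along_axis(
                            ll[:, sel, :], states[p][None, :, None], axis=2
                        )[:, :, 0].sum(axis=1)
                    ).sum()
                )
            if not pending and abs(obj - prev_obj) < tol:
                converged = True
                break
            prev_obj = obj
        # final confidence scores with the final posterior
        conf = np.zeros(n)
        if offspring.size:
            wll = np.einsum("ip,ijs->jps", post, ll[:, offspring, :])
            scores = np.zeros((offspring.size, 4))
            for g in range(4):
                scores[:, g] = np.take_along_axis(
                    wll, _PHASE_STATE[:, g][None, :, None], axis=2
                )[:, :, 0].sum(axis=1)
            srt = np.sort(scores, axis=1)
            conf[offspring] = srt[:, -1] - srt[:, -2]
        vec = canonical_genotype_vector(geno[2:])
        vectors.append(vec)
        if best is None or obj > best["obj"]:
            best = {
                "obj": obj,
                "geno": geno.copy(),
                "conf": conf,
                "post": post,
                "converged": converged,
                "vec": vec,
            }

    consistent = sum(1 for v in vectors if v == best["vec"])
    no_reads = (marker.n_lo + marker.n_hi + marker.n_other).sum(axis=0) == 0
    genotypes = best["geno"]
    genotypes[:2] = -1
    genotypes[no_reads] = -1
    best["conf"][no_reads] = 0.0
    phase_map = [_PHASES[p] for p in best["post"].argmax(axis=1)]
    return GenotypeResult(
        marker_id=marker.marker_id,
        samples=marker.samples,
        genotypes=genotypes,
        confidence=best["conf"],
        phase_posterior=best["post"],
        phase_map=phase_map,
        expected_loglik=best["obj"],
        consistent_restarts=consistent,
        n_restarts=restarts,
        converged=best["converged"],
    )


def phase_posterior(
    marker: MarkerCounts,
    genotypes: np.ndarray,
    epsilon: float = 0.01,
    include: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior over the 14 phases at each site given genotype assignments.

    `genotypes` holds offspring codes (0..3) aligned with samples[2:];
    parents always contribute through their fixed (a,b) / (c,d) states.
    Sites with no reads get the uniform 1/14.
    """
    ll = _site_loglik_table(marker.n_lo, marker.n_hi, marker.n_other, epsilon)
    n = marker.n_samples
    sample_state = np.empty(n, dtype=np.int64)
    sample_state[0], sample_state[1] = MOTHER_STATE, FATHER_STATE
    sample_state[2:] = genotypes
    if include is None:
        include = np.ones(n, dtype=bool)
    include = include & np.concatenate(([True, True], genotypes >= 0))
    sel = np.flatnonzero(include)
    states = _PHASE_STATE[:, sample_state[sel]]
    m = marker.n_sites
    lp = np.zeros((m, N_PHASES))
    for p in range(N_PHASES):
        lp[:, p] = np.take_along_axis(ll[:, sel, :], states[p][None, :, None], axis=2)[
            :, :, 0
        ].sum(axis=1)
    return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))


# ---------------------------------------------------------------------------
# error model


@dataclass
class ErrorModelFit:
    """Double stretched exponential p(e|s) = a1 exp(-(s/c1)^b1) + a2 exp(-(s/c2)^b2).

    Defaults are a reference fit (a1=0.49, b1=2.08, c1=1.26, a2=5.47,
    b2=0.17, c2=0.16); the alternative parameterization a exp(-s^b / c)
    is available via form="rate".
    """

    a1: float = 0.49
    b1: float = 2.08
    c1: float = 1.26
    a2: float = 5.47
    b2: float = 0.17
    c2: float = 0.16
    form: str = "scale"
    bin_size: int = 10_000
    bins: pd.DataFrame | None = None
    reduced_chi2: float | None = None
    degenerate: bool = False

    def __call__(self, s) -> np.ndarray | float:
        return error_model(s, self)

    def ci_coverage(self) -> float:
        """Fraction of calibration bins whose Beta 95% interval contains the fit."""
        if self.bins is None:
            raise ValueError("no calibration bins stored")
        m = error_model(self.bins["s_mean"].to_numpy(), self)
        lo = self.bins["beta_lo"].to_numpy()
        hi = self.bins["beta_hi"].to_numpy()
        return float(((m >= lo) & (m <= hi)).mean())


def error_model(s, fit: ErrorModelFit | None = None) -> np.ndarray | float:
    """Error probability at confidence score s, clipped to [0, 1]."""
    if fit is None:
        fit = ErrorModelFit()
    s = np.asarray(s, dtype=float)
    if (s < 0).any():
        raise ValueError("confidence scores must be non-negative")
    with np.errstate(divide="ignore"):
        if fit.form == "scale":
            p = fit.a1 * np.exp(-((s / fit.c1) ** fit.b1)) + fit.a2 * np.exp(
                -((s / fit.c2) ** fit.b2)
            )
        elif fit.form == "rate":
            p = fit.a1 * np.exp(-(s**fit.b1) / fit.c1) + fit.a2 * np.exp(
                -(s**fit.b2) / fit.c2
            )
        else:
            raise ValueError("form must be 'scale' or 'rate'")
    out = np.clip(p, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def calibrate_error_model(
    confidence: np.ndarray,
    is_error: np.ndarray,
    bin_size: int = 10_000,
    form: str = "scale",
) -> ErrorModelFit:
    """Minimum-chi-squared fit of the error curve to binned truth calls.

    Calls are sorted by confidence and grouped into bins of `bin_size`;
    each bin contributes ((empirical - model)/sigma)^2 with sigma from the
    Beta(n_e+1, n_c-n_e+1) posterior of the bin's error rate.  95% Beta
    intervals per bin are reported alongside the reduced chi-squared.
    """
    confidence = np.asarray(confidence, dtype=float)
    is_error = np.asarray(is_error, dtype=bool)
    order = np.argsort(confidence)
    confidence, is_error = confidence[order], is_error[order]
    n = confidence.size
    n_bins = max(1, n // bin_size)
    if n_bins < 2:
        raise ValueError("need at least 2 bins; lower bin_size or add calls")
    edges = np.linspace(0, n, n_bins + 1).astype(int)
    rows = []
    for b in range(n_bins):
        sl = slice(edges[b], edges[b + 1])
        nc = edges[b + 1] - edges[b]
        ne = int(is_error[sl].sum())
        lo95, hi95 = stats.beta.ppf((0.025, 0.975), ne + 1, nc - ne + 1)
        # boundary bins get the appropriate one-sided 95% interval
        if ne == 0:
            lo95, hi95 = 0.0, stats.beta.ppf(0.95, 1, nc + 1)
        elif ne == nc:
            lo95, hi95 = stats.beta.ppf(0.05, nc + 1, 1), 1.0
        rows.append(
            {
                "s_mean": float(confidence[sl].mean()),
                "n_calls": nc,
                "n_errors": ne,
                "err_rate": ne / nc,
                "beta_lo": float(lo95),
                "beta_hi": float(hi95),
                "beta_sd": float(stats.beta.std(ne + 1, nc - ne + 1)),
            }
        )
    bins = pd.DataFrame(rows)
    degenerate = bins["n_errors"].sum() == 0

    s = bins["s_mean"].to_numpy()
    y = bins["err_rate"].to_numpy()
    sd = np.maximum(bins["beta_sd"].to_numpy(), 1e-12)

    def model(params):
        a1, b1, c1, a2, b2, c2 = params
        return error_model(
            s, ErrorModelFit(a1=a1, b1=b1, c1=c1, a2=a2, b2=b2, c2=c2, form=form)
        )

    # the cost surface is multi-modal (the curve can be cliff-like when the
    # low and high-confidence regimes separate sharply); multi-start from the
    # reference defaults plus data-driven seeds
    p0 = max(float(y.max()), 1e-3)
    s_med = max(float(np.median(s)), 1e-2)
    s_hi = max(float(s.max()), 1e-1)
    starts = [
        np.array([0.49, 2.08, 1.26, 5.47, 0.17, 0.16]),
        np.array([p0 / 2, 2.0, s_med, p0 / 2, 0.5, s_med / 10]),
        np.array([p0 / 2, 8.0, s_med, p0 / 2, 1.0, s_hi / 2]),
        np.array([p0, 1.0, s_med, p0 / 10, 0.3, s_hi]),
        np.array([p0 / 2, 4.0, s_med / 3, p0 / 2, 4.0, s_med * 3]),
    ]
    bounds = (np.full(6, 1e-6), np.array([10, 30, 10 * s_hi, 10, 30, 10 * s_hi]))
    res = None
    for x0 in starts:
        x0 = np.clip(x0, bounds[0], bounds[1])
        r = optimize.least_squares(
            lambda p: (model(p) - y) / sd, x0, bounds=bounds, max_nfev=20_000
        )
        if res is None or r.cost < res.cost:
            res = r
    a1, b1, c1, a2, b2, c2 = res.x
    dof = max(1, n_bins - 6)
    chi2 = float((res.fun**2).sum() / dof)
    return ErrorModelFit(
        a1=a1, b1=b1, c1=c1, a2=a2, b2=b2, c2=c2,
        form=form, bin_size=bin_size, bins=bins,
        reduced_chi2=chi2, degenerate=degenerate,
    )
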
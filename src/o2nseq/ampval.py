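"""Deep-amplicon validation statistics for candidate low-frequency loci.

For one pileup locus with ``n`` usable bases, ``o`` observed minor-allele
bases and mean per-base error rate ``q``, the minor allele fraction theta is
estimated from the hierarchical posterior

    P(theta | o)  ∝  P(theta) * sum_r  P(r | theta; n) * P(o | r; q)

where ``r`` is the unobserved true minor count, ``P(r | theta; n)`` is
binomial, and ``P(o | r; q)`` convolves Binomial(r, 1 - q) correctly-read
minors with Binomial(n - r, q / 3) majors misread as this minor (a specific
wrong base out of three).  The prior on theta is flat.  Theta is sampled
uniformly 1,000 times from an empirical region ``o/n ± 5*sigma`` (with a
1/n variance floor so o = 0 still yields a nonzero region), weights are
accumulated entirely in log space, and the 95% credible interval is the
2.5/97.5 weighted percentile of the samples.

Candidate loci additionally face a phred-scaled two-sided Fisher strand-bias
filter and the ±2 bp homozygous-neighbor decision rule: a candidate is
positive only when its CI lower bound clears every neighbor's CI upper bound
and its own CI upper bound stays below 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom, fisher_exact


@dataclass
class LocusCounts:
    """Strand-resolved major/minor base counts at one locus."""

    major_forward: int
    major_reverse: int
    minor_forward: int
    minor_reverse: int
    qualities: Sequence[float] | None = None
    mean_q: float | None = None

    @property
    def n(self) -> int:
        return (
            self.major_forward + self.major_reverse + self.minor_forward + self.minor_reverse
        )

    @property
    def o(self) -> int:
        return self.minor_forward + self.minor_reverse

    @property
    def error_rate(self) -> float:
        if self.mean_q is not None:
            return 10 ** (-self.mean_q / 10)
        if self.qualities is not None:
            return phred_to_error(self.qualities)
        raise ValueError("locus has neither qualities nor mean_q")


@dataclass
class MafPosterior:
    theta_samples: np.ndarray
    log_weights: np.ndarray
    ci95: tuple[float, float]
    q: float

    @property
    def weights(self) -> np.ndarray:
        w = np.exp(self.log_weights - self.log_weights.max())
        return w / w.sum()

    @property
    def mean(self) -> float:
        return float(np.sum(self.theta_samples * self.weights))


def phred_to_error(qualities: Sequence[float]) -> float:
    """Mean per-base error probability implied by a list of phred scores."""
    arr = np.asarray(qualities, dtype=float)
    if arr.size == 0:
        raise ValueError("empty quality list")
    return float(np.mean(10 ** (-arr / 10)))


def _log_p_o_given_r(o: int, n: int, q: float, r: np.ndarray) -> np.ndarray:
    """log P(o | r; q) for a vector of true minor counts r.

    Convolution over j = minors read correctly: j ~ Binomial(r, 1-q),
    o - j ~ Binomial(n - r, q/3).
    """
    j = np.arange(o + 1)
    jj = j[None, :]
    rr = r[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_surv = binom.logpmf(jj, rr, 1.0 - q)
        log_err = binom.logpmf(o - jj, n - rr, q / 3.0)
    total = log_surv + log_err
    total = np.where(np.isfinite(total), total, -np.inf)
    return logsumexp(total, axis=1)


def sampling_region(o: int, n: int) -> tuple[float, float]:
    """Empirical theta region o/n ± 5*sigma (1/n variance floor), clipped."""
    o_hat = o / n
    sigma = np.sqrt(max(o_hat, 1.0 / n) * (1.0 - o_hat) / n)
    return max(0.0, o_hat - 5 * sigma), min(1.0, o_hat + 5 * sigma)


def _weighted_quantile(theta: np.ndarray, weights: np.ndarray, probs: Sequence[float]) -> np.ndarray:
    order = np.argsort(theta)
    t, w = theta[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    return np.interp(probs, cum, t)


def maf_posterior(
    counts: LocusCounts,
    n_theta: int = 1000,
    rng: np.random.Generator | None = None,
    r_tail: float = 1e-12,
) -> MafPosterior:
    """Sample the posterior of the minor allele fraction at one locus.

    The marginalisation over the true minor count ``r`` is an exact summation
    truncated where the binomial mass becomes negligible (relative weight
    below ``r_tail``); all accumulation is in log space.
    """
    n, o = counts.n, counts.o
    if n <= 0:
        raise ValueError("total base count must be positive")
    if not 0 <= o <= n:
        raise ValueError("observed minor count outside [0, n]")
    q = counts.error_rate
    if rng is None:
        rng = np.random.default_rng()
    lo, hi = sampling_region(o, n)
    theta = rng.uniform(lo, hi, size=n_theta)

    # r grid: cover the binomial bulk across the whole theta region plus the
    # channel's reach around o, then crop by the relative-weight tail cutoff
    r_hi = n * hi + 10 * np.sqrt(max(n * hi * (1 - hi), 1.0)) + o + 10
    r_max = int(min(n, np.ceil(r_hi)))
    r = np.arange(r_max + 1)
    log_po = _log_p_o_given_r(o, n, q, r)
    keep = log_po > (log_po.max() + np.log(r_tail))
    r, log_po = r[keep], log_po[keep]

    with np.errstate(divide="ignore", invalid="ignore"):
        log_binom = binom.logpmf(r[None, :], n, theta[:, None])
    log_binom = np.where(np.isfinite(log_binom), log_binom, -np.inf)
    log_w = logsumexp(log_binom + log_po[None, :], axis=1)

    weights = np.exp(log_w - logsumexp(log_w))
    ci = _weighted_quantile(theta, weights, [0.025, 0.975])
    return MafPosterior(
        theta_samples=theta,
        log_weights=log_w,
        ci95=(float(ci[0]), float(ci[1])),
        q=q,
    )


@dataclass
class StrandBiasResult:
    evaluated: bool
    phred_p: float | None = None
    passed: bool | None = None
    reason: str = ""


def strand_bias_phred(
    counts: LocusCounts,
    min_depth: int = 500,
    cutoff: float = 60.0,
) -> StrandBiasResult:
    """Phred-scaled two-sided Fisher exact test on the strand 2x2 table.

    Loci below ``min_depth`` total bases are not evaluated; a locus passes
    when the phred-transformed P-value stays below ``cutoff``.
    """
    if counts.n < min_depth:
        return StrandBiasResult(False, reason=f"depth {counts.n} below {min_depth}")
    table = [
        [counts.major_forward, counts.major_reverse],
        [counts.minor_forward, counts.minor_reverse],
    ]
    _, p = fisher_exact(table, alternative="two-sided")
    p = min(max(p, 1e-300), 1.0)
    phred_p = -10.0 * np.log10(p)
    return StrandBiasResult(True, phred_p=float(phred_p), passed=bool(phred_p < cutoff))


@dataclass
class ValidationDecision:
    positive: bool
    reason: str


def neighbor_validate(
    candidate_ci: tuple[float, float],
    neighbor_cis: Sequence[tuple[float, float]],
) -> ValidationDecision:
    """±2 bp homozygous-neighbor rule (strict inequalities)."""
    lo, hi = candidate_ci
    if not neighbor_cis:
        return ValidationDecision(False, "no homozygous neighbors available")
    if hi >= 0.5:
        return ValidationDecision(False, "candidate CI upper bound not under 50%")
    worst = max(upper for _, upper in neighbor_cis)
    if lo > worst:
        return ValidationDecision(True, "candidate lower bound clears all neighbors")
    return ValidationDecision(False, "candidate lower bound within neighbor noise")


def validate_table(
    loci: pd.DataFrame,
    min_depth: int = 500,
    sb_cutoff: float = 60.0,
    n_theta: int = 1000,
    seed: int = 0,
    neighbor_window: int = 2,
) -> pd.DataFrame:
    """Run CI estimation, strand-bias filter and neighbor rule on a locus table.

    Expects columns ``chrom, pos_1based, major_fwd, major_rev, minor_fwd,
    minor_rev, mean_q``; returns a copy with ``ci_low, ci_high, phred_sb,
    decision`` appended.  Every row is treated as a candidate and validated
    against the rows within ``neighbor_window`` bp on the same chromosome.
    """
    rng = np.random.default_rng(seed)
    rows = []
    posteriors: dict[int, MafPosterior | None] = {}
    counts_by_idx: dict[int, LocusCounts] = {}
    for idx, row in loci.iterrows():
        counts = LocusCounts(
            int(row.major_fwd), int(row.major_rev),
            int(row.minor_fwd), int(row.minor_rev),
            mean_q=float(row.mean_q),
        )
        counts_by_idx[idx] = counts
        posteriors[idx] = maf_posterior(counts, n_theta=n_theta, rng=rng) if counts.n > 0 else None
    for idx, row in loci.iterrows():
        post = posteriors[idx]
        if post is None:
            rows.append((np.nan, np.nan, np.nan, "no_data"))
            continue
        sb = strand_bias_phred(counts_by_idx[idx], min_depth=min_depth, cutoff=sb_cutoff)
        if not sb.evaluated:
            rows.append((post.ci95[0], post.ci95[1], np.nan, "not_evaluated"))
            continue
        if not sb.passed:
            rows.append((post.ci95[0], post.ci95[1], sb.phred_p, "strand_bias"))
            continue
        neighbors = [
            posteriors[j].ci95
            for j, other in loci.iterrows()
            if j != idx
            and other.chrom == row.chrom
            and 0 < abs(int(other.pos_1based) - int(row.pos_1based)) <= neighbor_window
            and posteriors[j] is not None
        ]
        decision = neighbor_validate(post.ci95, neighbors)
        rows.append(
            (post.ci95[0], post.ci95[1], sb.phred_p, "positive" if decision.positive else "negative")
        )
    out = loci.copy()
    out[["ci_low", "ci_high", "phred_sb", "decision"]] = pd.DataFrame(rows, index=loci.index)
    return out
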
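"""Maximum pseudo-likelihood estimation of read-to-target Hamming distance.

Each of the ``L - k + 1`` k-mers of a read, compared against one target
(a reference genome, a clade, or a species), either matches an indexed
k-mer at some Hamming distance ``d <= delta`` or misses. Treating k-mers as
independent trials, the sufficient statistic is a histogram ``v[0..delta]``
of match counts plus a miss count ``u``, and the likelihood of a per-base
substitution distance ``D`` is

    L(D) = P_miss(D)^u * prod_d P_match(D; d)^v[d]

with

    P_mutate(D; d, k)  = C(k, d) D^d (1-D)^(k-d)          (binomial pmf)
    P_collide(d, k, h) = C(k-h, d) / C(k, d)              (LSH collision)
    P_match(D; d)      = rho * P_mutate * P_collide
    P_miss(D)          = 1 - sum_{d<=delta} P_match(D; d)

where ``rho`` is the fraction of the target's distinct k-mers retained by
minimizer subsampling. The log-likelihood is concave on (0, 0.5) for the
default (k=29, h=14, delta=4) and is maximized by bounded Brent search.
Counts may be fractional: clade-level histograms are averages of their
children's histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import fminbound
from scipy.special import comb, gammaln

__all__ = [
    "MatchHistogram",
    "DistanceEstimate",
    "NoMatchesError",
    "p_mutate",
    "p_collide",
    "p_match",
    "p_miss",
    "log_likelihood",
    "estimate_distance",
    "filter_distant_refs",
    "check_concavity",
]

D_MIN = 1e-6
D_MAX = 0.5 - 1e-6


class NoMatchesError(ValueError):
    """Raised when a histogram carries no matches at all (unmapped target)."""


@dataclass
class MatchHistogram:
    """Match-count histogram for one target: the likelihood's sufficient statistic.

    v : match counts at Hamming distances 0..delta (fractional for clades).
    u : miss count, ``L - k + 1 - sum(v)``.
    rho : k-mer subsampling rate of the target, in (0, 1].
    L : read length; the number of trials is ``L - k + 1``.
    k : k-mer length.
    """

    v: np.ndarray
    u: float
    rho: float
    L: int
    k: int

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        if np.any(self.v < 0) or self.u < -1e-9:
            raise ValueError("negative counts in histogram")
        if not (0 < self.rho <= 1):
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")
        if abs(self.u + float(self.v.sum()) - self.trials) > 1e-6:
            raise ValueError(
                f"count conservation violated: u + sum(v) = "
                f"{self.u + self.v.sum()} != trials = {self.trials}")

    @property
    def trials(self) -> int:
        return self.L - self.k + 1

    @property
    def n_matches(self) -> float:
        return float(self.v.sum())

    @property
    def delta(self) -> int:
        return len(self.v) - 1

    @classmethod
    def empty(cls, delta: int, rho: float, L: int, k: int) -> "MatchHistogram":
        return cls(v=np.zeros(delta + 1), u=float(L - k + 1), rho=rho, L=L, k=k)

    def min_observed_hd(self) -> int | None:
        """Smallest Hamming distance with a positive match count."""
        nz = np.nonzero(self.v > 0)[0]
        return int(nz[0]) if len(nz) else None


@dataclass(frozen=True)
class DistanceEstimate:
    d_hat: float
    loglik: float
    n_matches: float
    at_bound: bool = False


def p_mutate(D: float, d: int, k: int) -> float:
    """Probability that a k-mer accumulates exactly d substitutions at
    per-base distance D: the Binomial(k, D) pmf."""
    return float(comb(k, d)) * D**d * (1.0 - D) ** (k - d)


def p_collide(d: int, k: int, h: int) -> float:
    """Probability that two k-mers at Hamming distance d share an LSH value
    when h of k positions are sampled: C(k-h, d) / C(k, d)."""
    if d > k - h:
        return 0.0
    return float(comb(k - h, d)) / float(comb(k, d))


def p_match(D: float, d: int, k: int, h: int, rho: float) -> float:
    """Probability of observing a match at Hamming distance d: the k-mer is
    indexed (rho), mutated d times (P_mutate), and found by the LSH
    (P_collide)."""
    return rho * p_mutate(D, d, k) * p_collide(d, k, h)


def p_miss(D: float, k: int, h: int, delta: int, rho: float) -> float:
    """Probability that a query k-mer has no reported match: either it was
    not indexed, or it mutated beyond delta, or the LSH missed it."""
    total = 0.0
    for d in range(delta + 1):
        total += p_match(D, d, k, h, rho)
    return 1.0 - total


def _log_pmatch_terms(D: float, delta: int, k: int, h: int, rho: float) -> np.ndarray:
    """log P_match(D; d) for d = 0..delta, -inf-safe at the boundaries."""
    d = np.arange(delta + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_coef = np.where(
            d <= k - h,
            np.log(rho) + gammaln(k - h + 1) - gammaln(d + 1)
            - gammaln(np.maximum(k - h - d, 0) + 1),
            -np.inf,
        )
        return log_coef + d * np.log(D) + (k - d) * np.log1p(-D)


def log_likelihood(D: float, hist: MatchHistogram, h: int) -> float:
    """Log pseudo-likelihood of distance D given a match histogram.

    ``u * log(P_miss) + sum_d v[d] * log(P_match(d))``; returns -inf (never
    NaN) when a term with positive count has zero probability.
    """
    k, delta, rho = hist.k, hist.delta, hist.rho
    total = 0.0
    if hist.u > 0:
        pm = p_miss(D, k, h, delta, rho)
        if pm <= 0:
            return -np.inf
        total += hist.u * np.log(pm)
    lp = _log_pmatch_terms(D, delta, k, h, rho)
    mask = hist.v > 0
    if np.any(mask & ~np.isfinite(lp)):
        return -np.inf
    total += float(np.dot(hist.v[mask], lp[mask]))
    return total


def estimate_distance(hist: MatchHistogram, h: int) -> DistanceEstimate:
    """Maximize the log pseudo-likelihood over D in [1e-6, 0.5 - 1e-6]
    using bounded Brent search."""
    if hist.n_matches <= 0:
        raise NoMatchesError("histogram has no matches; target is unmapped")
    neg = lambda D: -log_likelihood(D, hist, h)
    d_hat = float(fminbound(neg, D_MIN, D_MAX, xtol=1e-8))
    ll = log_likelihood(d_hat, hist, h)
    at_bound = d_hat <= D_MIN * 1.5 or d_hat >= D_MAX - 1e-6
    return DistanceEstimate(d_hat=d_hat, loglik=ll, n_matches=hist.n_matches,
                            at_bound=at_bound)


def filter_distant_refs(
    histograms: Mapping[str, MatchHistogram], gap: int = 2
) -> dict[str, MatchHistogram]:
    """Drop references whose best (smallest) observed Hamming distance
    exceeds the overall best by more than ``gap``; never drops all."""
    if not histograms:
        return {}
    best = {r: hist.min_observed_hd() for r, hist in histograms.items()}
    observed = [b for b in best.values() if b is not None]
    if not observed:
        return dict(histograms)
    d_min = min(observed)
    kept = {r: hist for r, hist in histograms.items()
            if best[r] is not None and best[r] <= d_min + gap}
    return kept if kept else dict(histograms)


def check_concavity(k: int, h: int, delta: int, rho: float = 0.5,
                    n_grid: int = 200, n_hists: int = 20, seed: int = 0,
                    tol: float = 1e-8, warn: bool = True) -> bool:
    """Numerically verify concavity of the log-likelihood on (0.001, 0.499)
    for randomized histograms under the configured (k, h, delta).

    Emits a warning (when ``warn``) if a positive second difference beyond
    tolerance is found, since the closed-form parameter restrictions are
    configuration-dependent.
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.001, 0.499, n_grid)
    L = 150
    trials = L - k + 1
    ok = True
    for _ in range(n_hists):
        v = rng.uniform(0, 1, delta + 1)
        v *= rng.uniform(0.1, 0.9) * trials / v.sum()
        hist = MatchHistogram(v=v, u=trials - v.sum(), rho=rho, L=L, k=k)
        ll = np.array([log_likelihood(D, hist, h) for D in grid])
        dd = np.diff(ll, 2)
        if np.any(dd > tol * np.maximum(1.0, np.abs(ll[1:-1]))):
            ok = False
            break
    if not ok and warn:
        warnings.warn(
            f"log-likelihood not numerically concave for (k={k}, h={h}, "
            f"delta={delta}); estimates may hit local optima", stacklevel=2)
    return ok
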
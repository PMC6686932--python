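"""Allelic imbalance at heterozygous sites under a beta-binomial null.

Reference/alternate allele counts at heterozygous sites are filtered (>= 10
total counts, >= 1 count per allele, no bases beyond the two genotyped
alleles) and tested against a per-sample null fitted by maximum likelihood:
a beta-binomial with reference-allele ratio pi and intra-class dispersion
rho (alpha = pi (1 - rho) / rho, beta = (1 - pi) (1 - rho) / rho).  rho -> 0
recovers the plain binomial, which is handled analytically.  The per-site
test is two-tailed: twice the smaller exact tail, capped at 1 (a "sum of
outcomes no more likely than observed" alternative is available).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

RHO_BOUNDS = (1e-8, 0.99)
PI_BOUNDS = (1e-4, 1.0 - 1e-4)
DEFAULT_STARTS = ((0.5, 0.01), (0.5, 0.10), (0.35, 0.05), (0.65, 0.05))
#: below this rho the binomial limit is used directly
RHO_BINOMIAL_EPS = 1e-10


@dataclass(frozen=True)
class HetSiteCount:
    chrom: str
    pos: int
    site_id: str
    ref_count: int
    alt_count: int
    other_count: int = 0
    sample: str = ""

    def __post_init__(self) -> None:
        if min(self.ref_count, self.alt_count, self.other_count) < 0:
            raise ValueError(f"{self.site_id}: negative allele counts")

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count


@dataclass
class BetaBinomNull:
    pi: float
    rho: float
    sample: str = ""
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 < self.pi < 1.0):
            raise ValueError("pi must lie in (0, 1)")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")

    @property
    def alpha_beta(self) -> tuple[float, float]:
        if self.rho <= RHO_BINOMIAL_EPS:
            raise ValueError("binomial limit: alpha/beta undefined at rho = 0")
        a = self.pi * (1.0 - self.rho) / self.rho
        b = (1.0 - self.pi) * (1.0 - self.rho) / self.rho
        return a, b


def filter_sites(
    counts: list[HetSiteCount], min_total: int = 10, min_per_allele: int = 1
) -> list[HetSiteCount]:
    """Keep sites with no non-genotyped bases, enough depth and both alleles seen."""
    return [
        c for c in counts
        if c.other_count == 0
        and c.total >= min_total
        and min(c.ref_count, c.alt_count) >= min_per_allele
    ]


def betabinom_logpmf(k: np.ndarray, n: np.ndarray, pi: float, rho: float) -> np.ndarray:
    """Log pmf; exact binomial branch at (numerically) zero dispersion."""
    k = np.asarray(k)
    n = np.asarray(n)
    if rho <= RHO_BINOMIAL_EPS:
        return stats.binom.logpmf(k, n, pi)
    a = pi * (1.0 - rho) / rho
    b = (1.0 - pi) * (1.0 - rho) / rho
    return stats.betabinom.logpmf(k, n, a, b)


def betabinom_loglik(counts: list[tuple[int, int]], pi: float, rho: float) -> float:
    """Sum of log pmf over (ref, total) pairs."""
    if not (0.0 < pi < 1.0):
        raise ValueError("pi must lie in (0, 1)")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    k = np.array([c[0] for c in counts])
    n = np.array([c[1] for c in counts])
    return float(betabinom_logpmf(k, n, pi, rho).sum())


def fit_betabinom_null(
    counts: list[tuple[int, int]],
    sample: str = "",
    starts: tuple[tuple[float, float], ...] = DEFAULT_STARTS,
    bounds: tuple[tuple[float, float], tuple[float, float]] = (PI_BOUNDS, RHO_BOUNDS),
) -> BetaBinomNull:
    """Bounded ML fit of (pi, rho) from multiple starts; best optimum kept.

    Deterministic: L-BFGS-B from each fixed start, the highest final
    log-likelihood wins.  Fewer than 50 sites triggers a warning (the fit is
    then driven by very little information).
    """
    if len(counts) < 50:
        warnings.warn(
            f"fitting a beta-binomial null from only {len(counts)} sites",
            stacklevel=2,
        )
    k = np.array([c[0] for c in counts], dtype=float)
    n = np.array([c[1] for c in counts], dtype=float)

    def nll(theta: np.ndarray) -> float:
        val = betabinom_logpmf(k, n, float(theta[0]), float(theta[1])).sum()
        return -val if np.isfinite(val) else 1e12

    best = None
    for start in starts:
        res = optimize.minimize(nll, np.array(start), method="L-BFGS-B", bounds=bounds)
        if res.success or np.isfinite(res.fun):
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError(
            f"beta-binomial ML fit failed from all starts ({len(counts)} sites)"
        )
    pi_hat, rho_hat = float(best.x[0]), float(best.x[1])
    # check the degenerate binomial boundary explicitly
    ll_hat = -float(best.fun)
    ll_binom = betabinom_logpmf(k, n, pi_hat, 0.0).sum()
    if ll_binom >= ll_hat:
        rho_hat, ll_hat = 0.0, float(ll_binom)
    return BetaBinomNull(pi=pi_hat, rho=rho_hat, sample=sample, loglik=ll_hat)


def two_tailed_test(
    ref: int, total: int, null: BetaBinomNull, method: str = "double"
) -> float:
    """Two-tailed p for ``ref`` successes out of ``total`` under the null.

    ``method='double'`` (default): 2 * min(lower tail, upper tail), capped
    at 1.  ``method='minlike'``: sum of outcome probabilities no greater
    than the observed outcome's.
    """
    if not (0 <= ref <= total) or total < 1:
        raise ValueError("require 0 <= ref <= total, total >= 1")
    k = np.arange(total + 1)
    logpmf = betabinom_logpmf(k, total, null.pi, null.rho)
    pmf = np.exp(logpmf)
    if method == "double":
        lower = pmf[: ref + 1].sum()
        upper = pmf[ref:].sum()
        return float(min(1.0, 2.0 * min(lower, upper)))
    if method == "minlike":
        return float(min(1.0, pmf[pmf <= pmf[ref] * (1 + 1e-10)].sum()))
    raise ValueError(f"unknown method {method!r}")


def _tail_ps(ref: np.ndarray, total: np.ndarray, null: BetaBinomNull) -> np.ndarray:
    """Vectorized doubled-tail p-values."""
    ref = np.asarray(ref)
    total = np.asarray(total)
    if null.rho <= RHO_BINOMIAL_EPS:
        lower = stats.binom.cdf(ref, total, null.pi)
        upper = stats.binom.sf(ref - 1, total, null.pi)
    else:
        a, b = null.alpha_beta
        lower = stats.betabinom.cdf(ref, total, a, b)
        upper = stats.betabinom.sf(ref - 1, total, a, b)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def ase_scan(
    counts: list[HetSiteCount], null: BetaBinomNull, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-site two-tailed tests; rows sorted by p then position.

    Input is expected to be pre-filtered (:func:`filter_sites`).
    """
    if not counts:
        return pd.DataFrame(
            columns=["chrom", "pos", "site_id", "ref_count", "alt_count",
                     "total", "ref_ratio", "p", "nominal"]
        )
    ref = np.array([c.ref_count for c in counts])
    total = np.array([c.total for c in counts])
    p = _tail_ps(ref, total, null)
    df = pd.DataFrame(
        {
            "chrom": [c.chrom for c in counts],
            "pos": [c.pos for c in counts],
            "site_id": [c.site_id for c in counts],
            "ref_count": ref,
            "alt_count": [c.alt_count for c in counts],
            "total": total,
            "ref_ratio": ref / total,
            "p": p,
            "nominal": p < alpha,
        }
    )
    return df.sort_values(["p", "chrom", "pos"], kind="stable").reset_index(drop=True)
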
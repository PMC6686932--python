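"""Aggregate transcription-factor footprint profiling from Tn5 insertions.

For each motif occurrence a window of motif +/- 100 bp is built (dropping
windows that are poorly mappable, blacklisted, or out of bounds), per-base
Tn5 insertion counts are collected into a sites x positions matrix with
minus-strand rows reversed so motif position 1 is always leftmost, sites are
split into bound / unbound by a posterior binding probability (either
supplied externally or estimated by a two-component EM mixture with a
motif-score prior), and the aggregate bound and unbound insertion profiles
are compared through the transposition probability ratio (TPR):

    TPR[pos] = bound_profile[pos] / unbound_profile[pos]

A motif has an aggregate footprint when the mean TPR over motif positions
(mTPR) is below the mean TPR over the flanking positions (fTPR), i.e. when
bound sites show a relative insertion depletion over the motif itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Genome, GenomicInterval
from .motifs import MotifOccurrence

logger = logging.getLogger(__name__)

BOUND_THRESHOLD = 0.99
UNBOUND_THRESHOLD = 0.5


@dataclass(frozen=True)
class MotifWindow:
    occurrence: MotifOccurrence
    window: GenomicInterval
    flank: int = 100

    @property
    def motif_len(self) -> int:
        return len(self.occurrence.interval)


@dataclass
class TranspositionMatrix:
    """Sites x window-positions Tn5 insertion counts, strand-oriented."""

    counts: np.ndarray  # (n_windows, width) int
    windows: list[MotifWindow]
    motif_len: int
    flank: int

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise ValueError("negative insertion counts")
        if self.counts.shape[1] != self.motif_len + 2 * self.flank:
            raise ValueError("matrix width != motif_len + 2*flank")

    @property
    def scores(self) -> np.ndarray:
        return np.array([w.occurrence.score for w in self.windows])

    def motif_columns(self) -> slice:
        return slice(self.flank, self.flank + self.motif_len)


@dataclass
class FootprintResult:
    motif_id: str
    bound_profile: np.ndarray
    unbound_profile: np.ndarray
    tpr: np.ndarray
    mtpr: float
    ftpr: float
    has_footprint: bool
    n_bound: int = 0
    n_unbound: int = 0


def build_windows(
    occs: list[MotifOccurrence],
    genome: Genome,
    flank: int = 100,
    mappability_min: float = 0.90,
) -> list[MotifWindow]:
    """Motif +/- flank windows passing bounds, mappability and blacklist filters."""
    out: list[MotifWindow] = []
    n_oob = 0
    for occ in occs:
        iv = occ.interval
        start, end = iv.start - flank, iv.end + flank
        if start < 0 or iv.chrom not in genome.sizes or end > genome.sizes[iv.chrom]:
            n_oob += 1
            continue
        window = GenomicInterval(iv.chrom, start, end, iv.strand)
        if genome.mappable_fraction(window) < mappability_min:
            continue
        if genome.in_blacklist(window):
            continue
        out.append(MotifWindow(occ, window, flank))
    if n_oob:
        logger.info("dropped %d windows exceeding chromosome bounds", n_oob)
    return out


def transposition_matrix(
    insertions: dict[str, np.ndarray], windows: list[MotifWindow]
) -> TranspositionMatrix:
    """Per-window insertion counts; minus-strand rows are column-reversed."""
    if not windows:
        raise ValueError("no windows")
    motif_len = windows[0].motif_len
    flank = windows[0].flank
    width = motif_len + 2 * flank
    counts = np.zeros((len(windows), width), dtype=np.int64)
    for i, w in enumerate(windows):
        pos = insertions.get(w.window.chrom)
        if pos is None or len(pos) == 0:
            continue
        pos = np.asarray(pos, dtype=np.int64)
        lo = np.searchsorted(pos, w.window.start, side="left")
        hi = np.searchsorted(pos, w.window.end, side="left")
        if hi <= lo:
            continue
        offsets = pos[lo:hi] - w.window.start
        row = np.bincount(offsets, minlength=width)
        if w.occurrence.interval.strand == "-":
            row = row[::-1]
        counts[i] = row
    return TranspositionMatrix(counts, windows, motif_len, flank)


def classify_bound(
    posteriors: np.ndarray,
    bound_thr: float = BOUND_THRESHOLD,
    unbound_thr: float = UNBOUND_THRESHOLD,
) -> np.ndarray:
    """Labels 'bound' (> 0.99), 'unbound' (< 0.5), else 'ambiguous'."""
    posteriors = np.asarray(posteriors, dtype=float)
    if ((posteriors < 0) | (posteriors > 1)).any():
        raise ValueError("posterior probabilities must lie in [0, 1]")
    labels = np.full(posteriors.shape, "ambiguous", dtype=object)
    labels[posteriors > bound_thr] = "bound"
    labels[posteriors < unbound_thr] = "unbound"
    return labels


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35)))


def em_posterior_standin(
    m: TranspositionMatrix,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[np.ndarray, dict]:
    """Posterior bound probabilities from a two-component Poisson mixture.

    The bound component has free per-position rates (it can learn both a
    higher overall insertion rate and a shaped, motif-depleted profile); the
    unbound component has one flat rate.  The prior probability of being
    bound is a logistic function of the standardized motif score, refit each
    M-step by a guarded Newton update (skipped when it would not improve),
    so the EM objective is non-decreasing.  Deterministic: initialization
    splits sites at the median total count.

    Returns (posteriors, info) where info carries convergence diagnostics.
    """
    counts = m.counts.astype(float)
    n, width = counts.shape
    if n < 50:
        raise ValueError("need >= 50 windows for mixture estimation")
    totals = counts.sum(axis=1)
    z = m.scores
    z = (z - z.mean()) / (z.std() + 1e-12)

    # deterministic init: sites above median total count start as bound
    r = np.where(totals > np.median(totals), 0.75, 0.25)
    a, b = 0.0, 0.0

    def component_loglik(lam_b: np.ndarray, lam_u: float) -> tuple[np.ndarray, np.ndarray]:
        ll_b = (counts * np.log(lam_b[None, :]) - lam_b[None, :]).sum(axis=1)
        ll_u = counts.sum(axis=1) * np.log(lam_u) - width * lam_u
        return ll_b, ll_u  # common -log(c!) term cancels in responsibilities

    prev_obj = -np.inf
    converged = False
    ll_b = ll_u = None
    for it in range(max_iter):
        # M-step: component rates from responsibilities
        wsum = r.sum()
        lam_b = np.clip((r[:, None] * counts).sum(axis=0) / max(wsum, 1e-12), 1e-8, None)
        lam_u = float(np.clip(((1 - r) * totals).sum() / (max((1 - r).sum(), 1e-12) * width),
                              1e-8, None))
        # M-step: logistic prior on standardized motif score (guarded Newton)
        for _ in range(5):
            p = _sigmoid(a + b * z)
            grad = np.array([(r - p).sum(), ((r - p) * z).sum()])
            w = np.clip(p * (1 - p), 1e-6, None)
            hess = np.array([[w.sum(), (w * z).sum()], [(w * z).sum(), (w * z * z).sum()]])
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                break
            a_new, b_new = a + step[0], b + step[1]
            obj_old = (r * np.log(_sigmoid(a + b * z) + 1e-300)
                       + (1 - r) * np.log(1 - _sigmoid(a + b * z) + 1e-300)).sum()
            obj_new = (r * np.log(_sigmoid(a_new + b_new * z) + 1e-300)
                       + (1 - r) * np.log(1 - _sigmoid(a_new + b_new * z) + 1e-300)).sum()
            if obj_new >= obj_old:
                a, b = a_new, b_new
            else:
                break
        # E-step
        prior = np.clip(_sigmoid(a + b * z), 1e-12, 1 - 1e-12)
        ll_b, ll_u = component_loglik(lam_b, lam_u)
        log_num = np.log(prior) + ll_b
        log_den = np.logaddexp(log_num, np.log(1 - prior) + ll_u)
        r = np.exp(log_num - log_den)
        obj = log_den.sum()
        if obj - prev_obj < tol and it > 0:
            converged = True
            prev_obj = obj
            break
        prev_obj = obj
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    info = {"converged": converged, "loglik": float(prev_obj),
            "prior_intercept": float(a), "prior_score_coef": float(b)}
    return r, info


def em_loglik_trace(m: TranspositionMatrix, n_iter: int = 25) -> np.ndarray:
    """Objective value after each of the first ``n_iter`` EM iterations."""
    vals = []
    for i in range(1, n_iter + 1):
        _, info = em_posterior_standin(m, max_iter=i, tol=-1.0)
        vals.append(info["loglik"])
    return np.array(vals)


def aggregate_profiles(
    m: TranspositionMatrix,
    labels: np.ndarray,
    top_unbound: int = 10_000,
    smoothing: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate bound and unbound insertion probability profiles.

    Counts are summed per column within each group and normalized to sum to
    one.  Unbound sites are first restricted to the ``top_unbound`` highest
    motif scores.  ``smoothing`` adds a pseudo-count per column per group
    (set 0 to disable) so downstream ratios stay finite.
    """
    labels = np.asarray(labels, dtype=object)
    bound_idx = np.flatnonzero(labels == "bound")
    unbound_idx = np.flatnonzero(labels == "unbound")
    if bound_idx.size == 0:
        raise ValueError("no bound sites")
    if unbound_idx.size == 0:
        raise ValueError("no unbound sites")
    if unbound_idx.size > top_unbound:
        scores = m.scores[unbound_idx]
        keep = np.argsort(-scores, kind="stable")[:top_unbound]
        unbound_idx = unbound_idx[keep]
    bound = m.counts[bound_idx].sum(axis=0).astype(float) + smoothing
    unbound = m.counts[unbound_idx].sum(axis=0).astype(float) + smoothing
    return bound / bound.sum(), unbound / unbound.sum()


def tpr_footprint(
    bound_profile: np.ndarray,
    unbound_profile: np.ndarray,
    motif_len: int,
    flank: int,
    motif_id: str = "",
    n_bound: int = 0,
    n_unbound: int = 0,
) -> FootprintResult:
    """TPR statistic and aggregate-footprint call (mTPR < fTPR)."""
    bound_profile = np.asarray(bound_profile, dtype=float)
    unbound_profile = np.asarray(unbound_profile, dtype=float)
    width = motif_len + 2 * flank
    if bound_profile.shape != (width,) or unbound_profile.shape != (width,):
        raise ValueError("profiles must have length motif_len + 2*flank")
    if (unbound_profile <= 0).any():
        raise ValueError("unbound profile has zero positions; enable smoothing")
    tpr = bound_profile / unbound_profile
    motif_slice = slice(flank, flank + motif_len)
    flank_mask = np.ones(width, dtype=bool)
    flank_mask[motif_slice] = False
    mtpr = float(tpr[motif_slice].mean())
    ftpr = float(tpr[flank_mask].mean())
    return FootprintResult(
        motif_id=motif_id,
        bound_profile=bound_profile,
        unbound_profile=unbound_profile,
        tpr=tpr,
        mtpr=mtpr,
        ftpr=ftpr,
        has_footprint=mtpr < ftpr,
        n_bound=n_bound,
        n_unbound=n_unbound,
    )


def footprint_from_matrix(
    m: TranspositionMatrix,
    posteriors: np.ndarray | None = None,
    top_unbound: int = 10_000,
    smoothing: float = 1.0,
    motif_id: str = "",
) -> FootprintResult:
    """Convenience path: posteriors (EM stand-in if absent) -> labels -> TPR."""
    if posteriors is None:
        posteriors, _ = em_posterior_standin(m)
    labels = classify_bound(posteriors)
    bound, unbound = aggregate_profiles(m, labels, top_unbound, smoothing)
    return tpr_footprint(
        bound, unbound, m.motif_len, m.flank, motif_id=motif_id,
        n_bound=int((labels == "bound").sum()),
        n_unbound=int((labels == "unbound").sum()),
    )
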
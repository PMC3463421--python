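"""Univariate logistic-regression scan, score ranking, and detection statistics.

The scan fits, per SNP, the additive single-marker model
``logit P(D=1) = alpha + gamma X`` with ``X`` the minor-allele count, and
reports the two-sided Wald p-value for ``gamma``.  Because the likelihood
depends on the data only through the 2x3 status-by-genotype table, all SNPs
are fit simultaneously by a vectorized Newton-Raphson on the table counts;
SNPs with (quasi-)complete separation fall back to a likelihood-ratio p-value
and monomorphic SNPs get p = 1.

Detection follows the study's outcome definition: a causal SNP is "detected"
if it ranks within the top k SNPs by a score (k = number of simulated causal
SNPs), with exact ties broken by a seeded random shuffle so that exchangeable
scores give each SNP the same detection chance.  Region detection additionally
credits any SNP whose dosage R^2 with the causal SNP exceeds a threshold
(default 0.85).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, norm

from .gensim import GenotypeMatrix

__all__ = [
    "ScreeningResult",
    "lr_scan",
    "rank_scores",
    "top_k_detection",
    "region_detection",
]

_MAX_SLOPE = 15.0  # |gamma| beyond this is treated as separation


@dataclass
class ScreeningResult:
    """Per-SNP scores for one or more ranking methods.

    ``higher_is_better`` records each method's direction: importance measures
    rank descending, p-values ascending.
    """

    scores: dict[str, np.ndarray] = field(default_factory=dict)
    higher_is_better: dict[str, bool] = field(default_factory=dict)

    def add(self, method: str, values: np.ndarray, higher_is_better: bool) -> None:
        self.scores[method] = np.asarray(values, dtype=float)
        self.higher_is_better[method] = higher_is_better

    @property
    def methods(self) -> list[str]:
        return list(self.scores)


def _status_by_genotype_counts(X: np.ndarray, y: np.ndarray):
    n1 = np.empty((3, X.shape[1]))
    n0 = np.empty((3, X.shape[1]))
    cases = y == 1
    for g in range(3):
        mask = X == g
        n1[g] = mask[cases].sum(axis=0)
        n0[g] = mask[~cases].sum(axis=0)
    return n0, n1


def _loglik(alpha, gamma, n0, n1, x):
    eta = alpha[None, :] + gamma[None, :] * x[:, None]
    # log(sigmoid) computed stably
    log_mu = -np.logaddexp(0.0, -eta)
    log_1m = -np.logaddexp(0.0, eta)
    return np.sum(n1 * log_mu + n0 * log_1m, axis=0)


def lr_scan(G, y) -> np.ndarray:
    """Two-sided Wald p-values for the additive per-SNP logistic slope."""
    X = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)
    y = np.asarray(y)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    p = X.shape[1]
    n0, n1 = _status_by_genotype_counts(X, y)
    ng = n0 + n1
    x = np.arange(3, dtype=float)

    present = ng > 0
    polymorphic = present.sum(axis=0) > 1

    case_frac = np.clip(n1.sum(axis=0) / ng.sum(axis=0), 1e-12, 1 - 1e-12)
    alpha = np.log(case_frac / (1 - case_frac))
    gamma = np.zeros(p)
    se = np.full(p, np.nan)
    converged = np.zeros(p, dtype=bool)

    active = polymorphic.copy()
    for _ in range(60):
        if not np.any(active):
            break
        eta = alpha[None, :] + gamma[None, :] * x[:, None]
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        resid = n1 - ng * mu
        ga = np.sum(resid, axis=0)
        gc = np.sum(x[:, None] * resid, axis=0)
        w = ng * mu * (1 - mu)
        haa = np.sum(w, axis=0)
        hac = np.sum(x[:, None] * w, axis=0)
        hcc = np.sum(x[:, None] ** 2 * w, axis=0)
        det = haa * hcc - hac**2
        ok = active & (det > 1e-12)
        da = np.where(ok, (hcc * ga - hac * gc) / np.where(det > 0, det, 1.0), 0.0)
        dc = np.where(ok, (haa * gc - hac * ga) / np.where(det > 0, det, 1.0), 0.0)
        # damp huge steps to keep the iteration stable under near-separation
        step = np.maximum(np.abs(da), np.abs(dc))
        damp = np.where(step > 5.0, 5.0 / np.where(step > 0, step, 1.0), 1.0)
        alpha = alpha + damp * da * active
        gamma = gamma + damp * dc * active
        newly = active & (np.maximum(np.abs(ga), np.abs(gc)) < 1e-8)
        converged |= newly
        se = np.where(newly & (det > 0), np.sqrt(haa / np.where(det > 0, det, 1.0)), se)
        active &= ~newly
        active &= np.abs(gamma) <= _MAX_SLOPE

    pvals = np.ones(p)
    wald = polymorphic & converged & (np.abs(gamma) <= _MAX_SLOPE) & np.isfinite(se) & (se > 0)
    z = np.zeros(p)
    z[wald] = np.abs(gamma[wald]) / se[wald]
    pvals[wald] = 2 * norm.sf(z[wald])

    # separation / non-convergence fallback: likelihood-ratio test at the
    # (capped) fitted slope against the intercept-only model
    fallback = polymorphic & ~wald
    if np.any(fallback):
        gam_c = np.clip(gamma, -_MAX_SLOPE, _MAX_SLOPE)
        ll1 = _loglik(alpha, gam_c, n0, n1, x)
        mu0 = case_frac
        ll0 = n1.sum(axis=0) * np.log(mu0) + n0.sum(axis=0) * np.log(1 - mu0)
        lrt = np.maximum(2 * (ll1 - ll0), 0.0)
        pvals[fallback] = chi2.sf(lrt[fallback], df=1)
    return pvals


def rank_scores(scores, higher_is_better: bool, tie_seed) -> np.ndarray:
    """0-based ranks (0 = best) with exact ties broken by a seeded shuffle."""
    scores = np.asarray(scores, dtype=float)
    keys = -scores if higher_is_better else scores
    shuffle = np.random.default_rng(tie_seed).permutation(scores.size)
    order = np.lexsort((shuffle, keys))
    ranks = np.empty(scores.size, dtype=np.int64)
    ranks[order] = np.arange(scores.size)
    return ranks


def top_k_detection(scores, higher_is_better: bool, causal_indices, k: int, tie_seed) -> np.ndarray:
    """Per-causal-SNP indicator of ranking within the top k."""
    scores = np.asarray(scores, dtype=float)
    if k > scores.size:
        raise ValueError("k cannot exceed the number of SNPs")
    ranks = rank_scores(scores, higher_is_better, tie_seed)
    causal = np.atleast_1d(np.asarray(causal_indices, dtype=np.int64))
    return ranks[causal] < k


def region_detection(
    scores,
    higher_is_better: bool,
    causal_index: int,
    k: int,
    G,
    r2_threshold: float = 0.85,
    tie_seed=0,
) -> bool:
    """Detected iff the causal SNP or any high-LD proxy ranks in the top k.

    Proxy status is decided on the sample dosage correlation: SNP j is in the
    causal region iff ``corr(X_j, X_causal)^2 > r2_threshold`` (zero-variance
    SNPs have correlation 0).  Region detection therefore dominates plain
    causal-SNP detection.
    """
    X = (G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)).astype(float)
    scores = np.asarray(scores, dtype=float)
    target = X[:, causal_index]
    centred = X - X.mean(axis=0)
    t = target - target.mean()
    denom = np.sqrt(np.sum(centred**2, axis=0) * np.sum(t**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, centred.T @ t / np.where(denom > 0, denom, 1.0), 0.0)
    region = np.flatnonzero(r**2 > r2_threshold)
    region = np.union1d(region, [causal_index])
    ranks = rank_scores(scores, higher_is_better, tie_seed)
    return bool(np.any(ranks[region] < k))
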
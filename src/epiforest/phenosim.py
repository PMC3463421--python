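"""Binary phenotype simulation from genotypes.

Two data-generating mechanisms are provided:

* A liability-threshold (probit) model: a latent quantitative trait
  ``Y = b0 + sum_j b_j X_j + sum_(a,b) b_ab X_a X_b + E`` with Gaussian noise
  ``E ~ N(0, sigma^2)`` is dichotomized at its sample median, yielding exactly
  balanced case/control data (prevalence 0.5).
* Direct penetrance sampling: disease status drawn as Bernoulli(f_ab) from a
  3x3 two-locus penetrance table, with retrospective rejection sampling to a
  fixed number of cases and controls.

``threshold_to_penetrance`` connects the two views: it converts a threshold
model into an exact multi-locus penetrance table by enumerating all causal
genotype combinations and root-finding the population threshold, which is what
the heritability module consumes.  ``construct_penetrance_table`` builds 3x3
tables with a prescribed total heritability and marginal-effect pattern
(both / one / no marginal components), used for the pure-epistasis scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .gensim import GenotypeMatrix
from .heritability import genotype_measure, marginal_heritability, total_heritability

__all__ = [
    "ThresholdModel",
    "PenetranceModel",
    "simulate_threshold_phenotype",
    "simulate_penetrance_phenotype",
    "sample_case_control",
    "threshold_to_penetrance",
    "construct_penetrance_table",
]


@dataclass(frozen=True)
class ThresholdModel:
    """Liability-threshold disease model on a latent Gaussian trait.

    ``main_betas[i]`` multiplies the minor-allele count at panel column
    ``causal_indices[i]``; ``interactions`` lists ``(i, j, coeff)`` product
    terms where ``i``/``j`` index into ``causal_indices`` (not the panel).
    """

    main_betas: tuple[float, ...]
    causal_indices: tuple[int, ...]
    interactions: tuple[tuple[int, int, float], ...] = ()
    beta0: float = 20.0
    sigma2: float = 10.0
    target_prevalence: float = 0.5

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if len(self.main_betas) != len(self.causal_indices):
            raise ValueError("one main beta per causal locus required")
        if len(set(self.causal_indices)) != len(self.causal_indices):
            raise ValueError("causal indices must be distinct")
        k = len(self.causal_indices)
        for i, j, _ in self.interactions:
            if not (0 <= i < k and 0 <= j < k and i != j):
                raise ValueError(f"interaction ({i},{j}) does not name two causal loci")

    @property
    def k(self) -> int:
        return len(self.causal_indices)

    def latent_mean(self, causal_genotypes: np.ndarray) -> np.ndarray:
        """mu = b0 + sum_j b_j X_j + sum b_ab X_a X_b for rows of causal genotypes."""
        X = np.asarray(causal_genotypes, dtype=float)
        mu = self.beta0 + X @ np.asarray(self.main_betas, dtype=float)
        for i, j, coeff in self.interactions:
            mu = mu + coeff * X[..., i] * X[..., j]
        return mu


@dataclass(frozen=True)
class PenetranceModel:
    """Two-locus penetrance table P(D | G_ab) with its generating MAFs."""

    table: np.ndarray  # shape (3, 3)
    mafs: tuple[float, float]
    locus_a: int = 0
    locus_b: int = 1

    def __post_init__(self):
        table = np.asarray(self.table, dtype=float)
        if table.shape != (3, 3):
            raise ValueError("penetrance table must be 3x3")
        if np.any(table < 0) or np.any(table > 1):
            raise ValueError("penetrance values must lie in [0, 1]")
        object.__setattr__(self, "table", table)
        prev = self.prevalence
        if not (0.0 < prev < 1.0):
            raise ValueError(f"model prevalence {prev} not strictly inside (0, 1)")

    @property
    def prevalence(self) -> float:
        w = genotype_measure(self.mafs)
        return float(np.sum(w * self.table))


def simulate_threshold_phenotype(G: GenotypeMatrix, model: ThresholdModel, seed) -> np.ndarray:
    """Dichotomize the latent trait at its sample median.

    Returns a 0/1 label vector with exactly ``n // 2`` cases: individuals are
    ranked by latent trait and the upper half (strictly above the sample
    median rank) is affected; floating-point ties go to the control class by
    stable ordering.
    """
    n = G.values.shape[0]
    if n < 2:
        raise ValueError("need at least two individuals to dichotomize at the median")
    causal = np.asarray(model.causal_indices)
    if causal.max() >= G.values.shape[1]:
        raise ValueError("genotype panel does not cover the model's causal indices")
    rng = np.random.default_rng(seed)
    y_latent = model.latent_mean(G.values[:, causal]) + rng.normal(
        0.0, np.sqrt(model.sigma2), size=n
    )
    order = np.argsort(y_latent, kind="stable")
    labels = np.zeros(n, dtype=np.int8)
    labels[order[n - n // 2 :]] = 1
    return labels


def simulate_penetrance_phenotype(
    G: GenotypeMatrix, model: PenetranceModel, n_cases: int, n_controls: int, seed
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Retrospective sampling: draw disease per individual, keep fixed strata.

    Scans the pool ``G`` in row order, assigns each individual disease status
    Bernoulli(f_ab), and retains the first ``n_cases`` cases and first
    ``n_controls`` controls.  Raises if the pool is exhausted before both
    strata fill (use :func:`sample_case_control` to draw from an unbounded
    genotype stream).
    """
    rng = np.random.default_rng(seed)
    f = model.table[G.values[:, model.locus_a], G.values[:, model.locus_b]]
    disease = rng.random(G.values.shape[0]) < f
    case_rows = np.flatnonzero(disease)[:n_cases]
    control_rows = np.flatnonzero(~disease)[:n_controls]
    if case_rows.size < n_cases or control_rows.size < n_controls:
        raise RuntimeError(
            f"genotype pool exhausted: found {case_rows.size}/{n_cases} cases and "
            f"{control_rows.size}/{n_controls} controls"
        )
    keep = np.sort(np.concatenate([case_rows, control_rows]))
    labels = disease[keep].astype(np.int8)
    kept = GenotypeMatrix(values=G.values[keep], mafs=G.mafs)
    return kept, labels


def sample_case_control(
    model: PenetranceModel, mafs, n_cases: int, n_controls: int, seed
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Rejection-sample a balanced case/control dataset from fresh genotypes.

    Generates independent HWE genotype batches (panel MAF profile ``mafs``) and
    accumulates cases/controls until both quotas are met.
    """
    from .gensim import simulate_independent_genotypes

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    mafs = np.asarray(mafs, dtype=float)
    prev = model.prevalence
    need_total = n_cases / prev + n_controls / (1.0 - prev)
    got_G, got_y = [], []
    have_cases = have_controls = 0
    for child in ss.spawn(64):
        batch = int(1.5 * need_total) + 32
        g_seed, d_seed = child.spawn(2)
        pool = simulate_independent_genotypes(batch, mafs, g_seed)
        f = model.table[pool.values[:, model.locus_a], pool.values[:, model.locus_b]]
        labels = (np.random.default_rng(d_seed).random(batch) < f).astype(np.int8)
        got_G.append(pool.values)
        got_y.append(labels)
        have_cases += int(np.sum(labels == 1))
        have_controls += int(np.sum(labels == 0))
        if have_cases >= n_cases and have_controls >= n_controls:
            break
    else:  # pragma: no cover - 64 batches cover any sane prevalence
        raise RuntimeError("failed to fill case/control quotas")
    values = np.concatenate(got_G)
    labels = np.concatenate(got_y)
    case_rows = np.flatnonzero(labels == 1)[:n_cases]
    control_rows = np.flatnonzero(labels == 0)[:n_controls]
    keep = np.sort(np.concatenate([case_rows, control_rows]))
    return GenotypeMatrix(values=values[keep], mafs=mafs), labels[keep]


def threshold_to_penetrance(model: ThresholdModel, mafs) -> tuple[np.ndarray, float]:
    """Exact penetrance table of a threshold model under HWE causal loci.

    Enumerates all ``3**k`` causal genotype vectors, computes the latent mean
    of each, and root-finds the population threshold ``m`` so that the HWE
    average penetrance equals ``model.target_prevalence``.  Returns
    ``(table, m)`` where ``table[g1, ..., gk] = P(D | G) = 1 - Phi((m - mu_G)/sigma)``.
    """
    k = model.k
    if k > 6:
        raise ValueError("exact enumeration supported for at most 6 causal loci")
    mafs = np.atleast_1d(np.asarray(mafs, dtype=float))
    if mafs.size != k:
        raise ValueError("one MAF per causal locus required")
    grid = np.stack(
        [ax.ravel() for ax in np.meshgrid(*([np.arange(3)] * k), indexing="ij")], axis=-1
    )
    mu = model.latent_mean(grid)
    w = genotype_measure(mafs).ravel()
    sigma = float(np.sqrt(model.sigma2))

    def excess_prevalence(m):
        return float(np.sum(w * norm.sf((m - mu) / sigma))) - model.target_prevalence

    lo = float(mu.min() - 12 * sigma)
    hi = float(mu.max() + 12 * sigma)
    m = brentq(excess_prevalence, lo, hi, xtol=1e-12, rtol=8.9e-16)
    table = norm.sf((m - mu) / sigma).reshape((3,) * k)
    achieved = float(np.sum(w * table.ravel().reshape(-1)))
    if abs(achieved - model.target_prevalence) > 1e-9:
        raise RuntimeError(
            f"threshold root-finding did not converge: prevalence {achieved} "
            f"(bracket [{lo}, {hi}])"
        )
    return table, float(m)


def construct_penetrance_table(
    maf: float,
    target_total_h2: float,
    marginal_pattern: str,
    baseline: float = 0.5,
    h2_split=None,
) -> PenetranceModel:
    """Build a 3x3 penetrance table with prescribed heritability structure.

    The table is parameterized on an orthogonal ANOVA basis under the HWE
    product measure: with centred allele counts ``u(x) = x - 2q``,

        f(a, b) = K + alpha u(a) + beta u(b) + gamma u(a) u(b)

    The three non-constant terms are mutually orthogonal and have zero mean, so
    prevalence is exactly ``K`` and the marginal/interaction heritability of
    each term is available in closed form; coefficients are solved so total
    heritability hits ``target_total_h2`` with the requested marginal pattern:

    * ``"both"`` -- both loci carry a marginal component plus an interaction,
    * ``"one"``  -- only locus B carries a marginal component,
    * ``"none"`` -- pure epistasis: all heritability in the interaction term.

    ``h2_split`` optionally overrides the (marginal_A, marginal_B, interaction)
    shares of the total (defaults: both -> (1/4, 1/4, 1/2); one -> (0, 1/2, 1/2);
    none -> (0, 0, 1)).
    """
    if not (0 < maf <= 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    if not (0 < target_total_h2 < 0.2):
        raise ValueError("target_total_h2 must lie in (0, 0.2)")
    splits = {
        "both": (0.25, 0.25, 0.5),
        "one": (0.0, 0.5, 0.5),
        "none": (0.0, 0.0, 1.0),
    }
    if marginal_pattern not in splits:
        raise ValueError(f"marginal_pattern must be one of {sorted(splits)}")
    share = h2_split if h2_split is not None else splits[marginal_pattern]
    if len(share) != 3 or abs(sum(share) - 1.0) > 1e-12 or min(share) < 0:
        raise ValueError("h2_split must be three non-negative shares summing to 1")
    q = float(maf)
    K = float(baseline)
    var_u = 2 * q * (1 - q)  # variance of the allele count, hence of u
    phen_var = K * (1 - K)
    h2_a, h2_b, h2_i = (s * target_total_h2 for s in share)
    alpha = np.sqrt(h2_a * phen_var / var_u)
    beta = np.sqrt(h2_b * phen_var / var_u)
    gamma = np.sqrt(h2_i * phen_var / var_u**2)
    u = np.arange(3) - 2 * q
    table = K + alpha * u[:, None] + beta * u[None, :] + gamma * np.outer(u, u)
    if np.any(table < 0) or np.any(table > 1):
        raise ValueError(
            "penetrance family left [0,1]; widen the deviation family by lowering "
            "target_total_h2 or moving baseline toward 0.5"
        )
    model = PenetranceModel(table=table, mafs=(q, q))
    # exactness check against the independent enumeration
    mafs = (q, q)
    assert abs(total_heritability(model.table, mafs) - target_total_h2) < 1e-6
    if marginal_pattern == "none":
        assert marginal_heritability(model.table, mafs, 0) < 1e-8
        assert marginal_heritability(model.table, mafs, 1) < 1e-8
    elif marginal_pattern == "one":
        assert marginal_heritability(model.table, mafs, 0) < 1e-8
    return model
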
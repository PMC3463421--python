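"""Broad-sense heritability decomposition for multi-locus penetrance models.

A binary disease phenotype ``D`` controlled by ``k`` diallelic loci is fully
described by its penetrance function ``f(g) = P(D | G = g)``, a table over the
``3**k`` genotype combinations (minor-allele counts 0/1/2 per locus), together
with the population genotype distribution.  Loci are assumed independent and in
Hardy-Weinberg equilibrium, so ``P(G)`` is a product of per-locus HWE weights.

On that product measure the broad-sense heritability attributable to the loci is
the variance of the penetrance scaled by the Bernoulli phenotype variance::

    H^2 = Var_G[ f(G) ] / ( P(D) (1 - P(D)) )

The marginal (one-locus ANOVA) component of a focal locus is the same ratio
applied to the conditional prevalence ``P(D | X_locus)``, and the interaction
component of a pair of loci is the two-locus heritability minus both marginal
components.  Because the loci are independent, these ANOVA components are
orthogonal and for two loci decompose the total exactly:
``H^2_AB = H^2_M,A + H^2_M,B + H^2_I``.

All quantities here are computed by exact enumeration -- no sampling.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UndefinedHeritabilityError",
    "hwe_probs",
    "genotype_measure",
    "prevalence",
    "total_heritability",
    "marginal_heritability",
    "pair_heritability",
    "interaction_heritability",
    "HeritabilityDecomposition",
    "decompose",
]

#: treat a marginal/interaction component smaller than this as exactly zero
ZERO_TOL = 1e-10


class UndefinedHeritabilityError(ValueError):
    """Raised when P(D) is 0 or 1, so the variance ratio is undefined."""


def hwe_probs(maf: float) -> np.ndarray:
    """Genotype probabilities ((1-q)^2, 2q(1-q), q^2) for minor-allele counts 0,1,2."""
    q = float(maf)
    if not np.isfinite(q) or not (0.0 < q <= 0.5):
        raise ValueError(f"MAF must lie in (0, 0.5], got {maf!r}")
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def genotype_measure(mafs) -> np.ndarray:
    """Joint HWE genotype distribution over k independent loci, shape (3,)*k."""
    mafs = np.atleast_1d(np.asarray(mafs, dtype=float))
    w = np.ones(())
    for q in mafs:
        w = np.multiply.outer(w, hwe_probs(q))
    return w


def _validate(table, mafs):
    table = np.asarray(table, dtype=float)
    mafs = np.atleast_1d(np.asarray(mafs, dtype=float))
    k = mafs.size
    if table.shape != (3,) * k:
        raise ValueError(f"penetrance table shape {table.shape} does not match {k} loci")
    if np.any(table < -1e-12) or np.any(table > 1 + 1e-12):
        raise ValueError("penetrance values must lie in [0, 1]")
    return np.clip(table, 0.0, 1.0), mafs


def prevalence(table, mafs) -> float:
    """Population disease prevalence P(D) = sum_G P(G) P(D|G)."""
    table, mafs = _validate(table, mafs)
    return float(np.sum(genotype_measure(mafs) * table))


def _h2_of_surface(values: np.ndarray, weights: np.ndarray, p_d: float) -> float:
    if not (1e-12 < p_d < 1.0 - 1e-12):
        raise UndefinedHeritabilityError(f"P(D) = {p_d}; heritability undefined")
    return float(np.sum(weights * (values - p_d) ** 2) / (p_d * (1.0 - p_d)))


def total_heritability(table, mafs) -> float:
    """Total broad-sense heritability of the full k-locus penetrance table."""
    table, mafs = _validate(table, mafs)
    w = genotype_measure(mafs)
    return _h2_of_surface(table, w, float(np.sum(w * table)))


def _conditional_surface(table, mafs, loci: tuple[int, ...]):
    """Conditional prevalence P(D | X_loci) and its marginal weights."""
    w = genotype_measure(mafs)
    k = mafs.size
    other = tuple(ax for ax in range(k) if ax not in loci)
    joint = np.sum(w * table, axis=other)        # P(X_loci = s, weighted by f)
    marg_w = np.sum(w, axis=other)               # P(X_loci = s)
    return joint / marg_w, marg_w


def marginal_heritability(table, mafs, locus: int) -> float:
    """One-locus ANOVA heritability component of ``locus`` (Var of P(D|X_locus))."""
    table, mafs = _validate(table, mafs)
    if not 0 <= locus < mafs.size:
        raise ValueError(f"locus {locus} out of range for {mafs.size} loci")
    cond, w = _conditional_surface(table, mafs, (locus,))
    p_d = float(np.sum(w * cond))
    return _h2_of_surface(cond, w, p_d)


def pair_heritability(table, mafs, pair: tuple[int, int]) -> float:
    """Two-locus heritability of the conditional surface P(D | X_a, X_b)."""
    table, mafs = _validate(table, mafs)
    a, b = pair
    if a == b:
        raise ValueError("pair must name two distinct loci")
    cond, w = _conditional_surface(table, mafs, tuple(sorted((a, b))))
    p_d = float(np.sum(w * cond))
    return _h2_of_surface(cond, w, p_d)


def interaction_heritability(table, mafs, pair: tuple[int, int] = (0, 1)) -> float:
    """Interaction component H^2_I = H^2_pair - H^2_M,a - H^2_M,b.

    For independent loci this is the orthogonal two-way ANOVA interaction
    variance and is non-negative; values within ``ZERO_TOL`` of zero are
    clamped to exactly zero.
    """
    table, mafs = _validate(table, mafs)
    a, b = pair
    h2i = (
        pair_heritability(table, mafs, (a, b))
        - marginal_heritability(table, mafs, a)
        - marginal_heritability(table, mafs, b)
    )
    if h2i < -1e-8:
        raise AssertionError(
            f"interaction component {h2i} < 0 beyond tolerance; loci not independent?"
        )
    return 0.0 if abs(h2i) < ZERO_TOL else max(h2i, 0.0)


@dataclass
class HeritabilityDecomposition:
    """Total, per-locus marginal, per-pair interaction heritability, and remainder.

    ``remainder`` collects variance not attributable to the declared marginal
    and pairwise components (3-way and higher interactions); it is zero for the
    two-locus models this package simulates.
    """

    prevalence: float
    h2_total: float
    h2_marginal: dict[int, float]
    h2_interaction: dict[tuple[int, int], float] = field(default_factory=dict)
    remainder: float = 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "prevalence": self.prevalence,
                "h2_total": self.h2_total,
                "h2_marginal": {str(k): v for k, v in self.h2_marginal.items()},
                "h2_interaction": {f"{a},{b}": v for (a, b), v in self.h2_interaction.items()},
                "remainder": self.remainder,
            },
            indent=2,
        )


def decompose(table, mafs, pairs=None) -> HeritabilityDecomposition:
    """Full decomposition over all loci and the declared interacting pairs.

    If ``pairs`` is None, every pair of loci is examined and pairs with a
    nonzero interaction component are reported.
    """
    table, mafs = _validate(table, mafs)
    k = mafs.size
    p_d = prevalence(table, mafs)
    h2_tot = total_heritability(table, mafs)
    marg = {j: marginal_heritability(table, mafs, j) for j in range(k)}
    if pairs is None:
        pairs = list(itertools.combinations(range(k), 2)) if k > 1 else []
    inter = {(a, b): interaction_heritability(table, mafs, (a, b)) for a, b in pairs}
    remainder = h2_tot - sum(marg.values()) - sum(inter.values())
    if abs(remainder) < ZERO_TOL:
        remainder = 0.0
    return HeritabilityDecomposition(p_d, h2_tot, marg, inter, remainder)
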
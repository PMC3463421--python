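"""Synthetic genotype simulation under Hardy-Weinberg equilibrium.

Genotypes are minor-allele counts (0/1/2).  Two generators are provided:

* :func:`simulate_independent_genotypes` -- mutually independent SNPs, each a
  Binomial(2, MAF) draw (two independent allele draws per individual).
* :func:`simulate_ld_genotypes` -- independent SNPs plus disjoint LD blocks.
  Within a block each individual carries two haplotypes; a satellite haplotype
  copies the anchor allele with probability 1 - eps and otherwise draws a
  fresh allele with a probability chosen so the satellite's marginal MAF is
  exact.  The per-pair copy error eps is calibrated analytically so realized
  dosage R^2 hits a target regime (strong: R^2 > 0.95, weak: R^2 < 0.3),
  emulating genome-derived LD structure without external haplotype data.

Under this model the dosage correlation between anchor and satellite is

    r = (1 - eps) * sqrt( q_a (1 - q_a) / ( q_s (1 - q_s) ) )

so eps is recovered from a target R^2 = r^2 by one-dimensional root-finding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CalibrationError",
    "LDBlock",
    "LDSpec",
    "GenotypeMatrix",
    "validate_mafs",
    "simulate_independent_genotypes",
    "simulate_ld_genotypes",
    "calibrate_ld_epsilon",
    "STRONG_TARGET_R2",
    "WEAK_TARGET_R2",
]

#: default calibration targets for the two LD regimes; strong must exceed the
#: 0.95 reporting threshold and weak must stay below 0.3 for every block member
STRONG_TARGET_R2 = 0.98
WEAK_TARGET_R2 = 0.20


class CalibrationError(ValueError):
    """No copy-error probability achieves the requested LD at these MAFs."""


def validate_mafs(mafs) -> np.ndarray:
    mafs = np.atleast_1d(np.asarray(mafs, dtype=float))
    if mafs.ndim != 1 or mafs.size == 0:
        raise ValueError("MAF profile must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(mafs)) or np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("every MAF must be finite and lie in (0, 0.5]")
    return mafs


@dataclass(frozen=True)
class LDBlock:
    """One LD block: satellite ``members`` tied to an ``anchor`` SNP.

    ``regime`` is ``"strong"`` or ``"weak"``; ``target_r2`` overrides the
    regime's default calibration target.
    """

    anchor: int
    members: tuple[int, ...]
    regime: str = "strong"
    target_r2: float | None = None

    def __post_init__(self):
        if self.regime not in ("strong", "weak"):
            raise ValueError("regime must be 'strong' or 'weak'")
        if self.anchor in self.members:
            raise ValueError("members should list satellites only, not the anchor")

    @property
    def resolved_target(self) -> float:
        if self.target_r2 is not None:
            return self.target_r2
        return STRONG_TARGET_R2 if self.regime == "strong" else WEAK_TARGET_R2

    @property
    def indices(self) -> tuple[int, ...]:
        return (self.anchor, *self.members)


@dataclass(frozen=True)
class LDSpec:
    """Disjoint LD blocks over a p-SNP panel; unassigned SNPs are independent."""

    blocks: tuple[LDBlock, ...]
    p: int

    def __post_init__(self):
        seen: set[int] = set()
        for block in self.blocks:
            idx = set(block.indices)
            if idx & seen:
                raise ValueError("LD blocks must be disjoint")
            if min(idx) < 0 or max(idx) >= self.p:
                raise ValueError("block index out of panel range")
            seen |= idx


@dataclass(frozen=True)
class GenotypeMatrix:
    """n x p matrix of minor-allele counts with its generating MAF profile."""

    values: np.ndarray
    mafs: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (individuals x SNPs)")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mafs", np.asarray(self.mafs, dtype=float))
        if self.mafs.size != values.shape[1]:
            raise ValueError("MAF profile length must equal SNP count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def simulate_independent_genotypes(n: int, mafs, seed) -> GenotypeMatrix:
    """Independent HWE genotypes: each entry Binomial(2, maf_j)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    mafs = validate_mafs(mafs)
    rng = np.random.default_rng(seed)
    values = rng.binomial(2, mafs, size=(n, mafs.size)).astype(np.int8)
    return GenotypeMatrix(values=values, mafs=mafs)


def _r2_of_epsilon(eps: float, q_a: float, q_s: float) -> float:
    return (1.0 - eps) ** 2 * (q_a * (1 - q_a)) / (q_s * (1 - q_s))


def calibrate_ld_epsilon(maf_anchor: float, maf_satellite: float, target_r2: float) -> float:
    """Copy-error probability eps whose analytic dosage R^2 equals the target.

    Solves ``r2(eps) = target_r2`` on the closed-form allelic correlation of the
    copy-with-error haplotype model; raises :class:`CalibrationError` when no
    eps in [0, 1] attains the target or when the resampling allele probability
    needed to preserve the satellite MAF leaves [0, 1].
    """
    q_a = float(validate_mafs(maf_anchor)[0])
    q_s = float(validate_mafs(maf_satellite)[0])
    if not (0 < target_r2 <= 1):
        raise ValueError("target_r2 must lie in (0, 1]")
    r2_at_zero = _r2_of_epsilon(0.0, q_a, q_s)
    if target_r2 > r2_at_zero + 1e-12:
        raise CalibrationError(
            f"target R^2={target_r2} unattainable: MAFs ({q_a}, {q_s}) cap R^2 at "
            f"{r2_at_zero:.6f}"
        )
    if abs(target_r2 - r2_at_zero) <= 1e-12:
        eps = 0.0
    else:
        eps = brentq(
            lambda e: _r2_of_epsilon(e, q_a, q_s) - target_r2, 0.0, 1.0, xtol=1e-12
        )
    if eps > 0:
        pi = (q_s - (1 - eps) * q_a) / eps
        if not (-1e-12 <= pi <= 1 + 1e-12):
            raise CalibrationError(
                f"MAF mismatch too large: resample allele frequency {pi:.4f} "
                f"outside [0, 1] for MAFs ({q_a}, {q_s}) at R^2={target_r2}"
            )
    assert abs(_r2_of_epsilon(eps, q_a, q_s) - target_r2) < 1e-6
    return float(eps)


def simulate_ld_genotypes(n: int, mafs, ld: LDSpec, seed) -> GenotypeMatrix:
    """HWE genotypes with copy-with-error LD blocks.

    Each individual carries two independent haplotypes per SNP.  Anchor and
    unassigned SNP alleles are Bernoulli(MAF); satellite alleles copy their
    anchor with probability 1 - eps (eps calibrated per pair to the block's
    target R^2) and otherwise resample so the satellite MAF is preserved.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    mafs = validate_mafs(mafs)
    if ld.p != mafs.size:
        raise ValueError("LD spec panel size does not match MAF profile")
    rng = np.random.default_rng(seed)
    # base alleles for all SNPs: 2n haplotypes x p
    hap = (rng.random((2 * n, mafs.size)) < mafs).astype(np.int8)
    for block in ld.blocks:
        try:
            anchor_alleles = hap[:, block.anchor]
            for satellite in block.members:
                eps = calibrate_ld_epsilon(
                    mafs[block.anchor], mafs[satellite], block.resolved_target
                )
                if eps == 0.0:
                    hap[:, satellite] = anchor_alleles
                    continue
                pi = (mafs[satellite] - (1 - eps) * mafs[block.anchor]) / eps
                pi = min(max(pi, 0.0), 1.0)
                copy = rng.random(2 * n) >= eps
                fresh = (rng.random(2 * n) < pi).astype(np.int8)
                hap[:, satellite] = np.where(copy, anchor_alleles, fresh)
        except CalibrationError as err:
            raise CalibrationError(
                f"block anchored at SNP {block.anchor} ({block.regime}): {err}"
            ) from err
    values = hap[:n] + hap[n:]
    return GenotypeMatrix(values=values.astype(np.int8), mafs=mafs)
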
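"""Scenario registry and replicate runner for the three simulation studies.

The study design (its Table-1 grid):

* Simulation 1 -- independent SNPs, fixed MAF in {0.1, 0.2, 0.3, 0.4},
  p in {10, 100, 500, 1000}, four causal loci under a liability-threshold
  model (Models 1-5) dichotomized at the sample median (500 cases /
  500 controls).
* Simulation 2 -- independent SNPs at MAF 0.3, two interacting causal loci
  with phenotypes drawn directly from 3x3 penetrance tables of total
  heritability ~1% and two / one / zero marginal components (Models 6-8).
* Simulation 3 -- p = 1000 SNPs with genome-like MAFs (null MAFs uniform on
  (0.01, 0.50)) and LD blocks; two causal loci (MAF ~0.3) in strong
  (R^2 > 0.95) or weak (R^2 < 0.3) LD with their neighbours, phenotypes under
  the two-locus versions of Model 3 (main effects only) and Model 5
  (interaction effects only); scenario 4 has no LD.

Each replicate derives a child seed from the master seed (spawn key =
replicate index), simulates genotypes and phenotypes, runs the requested
ranking methods (forest importance measures and/or the logistic scan), and
records top-k detection per causal SNP (k = number of SNPs with a simulated
effect), plus region detection (R^2 > 0.85 proxies) for Simulation 3.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import ForestConfig, analyze
from .gensim import LDBlock, LDSpec, simulate_independent_genotypes, simulate_ld_genotypes
from .phenosim import (
    PenetranceModel,
    ThresholdModel,
    construct_penetrance_table,
    sample_case_control,
    simulate_threshold_phenotype,
)
from .screening import ScreeningResult, lr_scan, region_detection, top_k_detection

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "DetectionSummary",
    "FOREST_METHODS",
    "ALL_METHODS",
    "model_registry",
    "causal_effect_loci",
    "snp_type_map",
    "sim3_design",
    "run_scenario",
    "summarize",
    "table1_grid",
]

FOREST_METHODS = ("raw_mda", "scaled_mda", "meng_mda", "gini")
ALL_METHODS = FOREST_METHODS + ("lr",)

#: Simulation-1 coefficient vectors (beta1..beta4, beta5) -- SNPs 1 and 2 carry
#: main effects only; SNPs 3 and 4 interact through the product term.
_SIM1_BETAS = {
    1: ((0.9, 0.9, 1.3, 1.3), -1.3),
    2: ((1.0, 1.0, 1.0, 1.0), -1.0),
    3: ((0.8, 0.8, 0.0, 0.0), 0.0),
    4: ((0.8, 0.8, 1.5, 1.5), -1.5),
    5: ((0.0, 0.0, 1.3, 1.3), -1.3),
}

#: Simulation-2 marginal-effect patterns at total H^2 = 1%, MAF 0.3.
_SIM2_PATTERNS = {6: "both", 7: "one", 8: "none"}

#: Simulation-3 causal-SNP MAFs per LD scenario, as reported per table row.
_SIM3_CAUSAL_MAFS = {
    1: (0.294, 0.309),
    2: (0.294, 0.281),
    3: (0.294, 0.294),
    4: (0.294, 0.294),
}
_SIM3_REGIMES = {
    1: ("strong", "strong"),
    2: ("weak", "weak"),
    3: ("strong", "weak"),
    4: (None, None),
}


def model_registry(model_id: int, maf: float = 0.3, causal_indices=None):
    """Return the generating model for a study model id (1-8).

    Models 1-5: :class:`ThresholdModel` with the study's coefficient vector
    (beta0 = 20, sigma^2 = 10, four causal loci).  Models 6-8:
    :class:`PenetranceModel` with total H^2 = 0.01 at the given MAF and
    both/one/no marginal components.
    """
    if model_id in _SIM1_BETAS:
        betas, beta5 = _SIM1_BETAS[model_id]
        if causal_indices is None:
            causal_indices = (0, 1, 2, 3)
        interactions = ((2, 3, beta5),) if beta5 != 0.0 else ()
        return ThresholdModel(
            main_betas=betas, causal_indices=tuple(causal_indices), interactions=interactions
        )
    if model_id in _SIM2_PATTERNS:
        return construct_penetrance_table(maf, 0.01, _SIM2_PATTERNS[model_id])
    raise ValueError(f"unknown model id {model_id!r}")


def _two_locus_threshold(model_id: int, loci: tuple[int, int]) -> ThresholdModel:
    """Model 3/5 restricted to their two effect loci (Simulation-3 phenotypes)."""
    betas, beta5 = _SIM1_BETAS[model_id]
    effect = [j for j, b in enumerate(betas) if b != 0.0]
    if len(effect) != 2:
        raise ValueError(f"model {model_id} does not reduce to two effect loci")
    inter = ((0, 1, beta5),) if beta5 != 0.0 else ()
    return ThresholdModel(
        main_betas=tuple(betas[j] for j in effect), causal_indices=loci, interactions=inter
    )


def causal_effect_loci(model) -> tuple[int, ...]:
    """Panel indices of loci with a simulated causal effect (nonzero terms)."""
    if isinstance(model, PenetranceModel):
        return (model.locus_a, model.locus_b)
    in_interaction = set()
    for i, j, coeff in model.interactions:
        if coeff != 0.0:
            in_interaction |= {i, j}
    return tuple(
        idx
        for pos, idx in enumerate(model.causal_indices)
        if model.main_betas[pos] != 0.0 or pos in in_interaction
    )


def snp_type_map(model, p: int) -> dict[int, str]:
    """Classify panel SNPs as 'main', 'interacting', or 'null' under a model."""
    types = {j: "null" for j in range(p)}
    if isinstance(model, PenetranceModel):
        for idx in (model.locus_a, model.locus_b):
            types[idx] = "interacting"
        return types
    in_interaction = set()
    for i, j, coeff in model.interactions:
        if coeff != 0.0:
            in_interaction |= {i, j}
    for pos, idx in enumerate(model.causal_indices):
        if pos in in_interaction:
            types[idx] = "interacting"
        elif model.main_betas[pos] != 0.0:
            types[idx] = "main"
    return types


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation grid plus run parameters."""

    simulation: int
    model: int
    p: int
    maf: float | None = None  # fixed panel MAF (Simulations 1 and 2)
    scenario: int | None = None  # LD scenario 1-4 (Simulation 3)
    n_cases: int = 500
    n_controls: int = 500
    n_replicates: int = 100
    ntree: int = 5000
    mtry: int | None = None  # None -> round(0.1 p)
    min_node_size: int = 1
    seed: int = 0
    methods: tuple[str, ...] = ALL_METHODS
    detection_k: int | None = None  # None -> number of causal-effect loci
    region_r2: float = 0.85

    def __post_init__(self):
        if self.simulation not in (1, 2, 3):
            raise ValueError("simulation must be 1, 2, or 3")
        if self.n_replicates < 1:
            raise ValueError("at least one replicate required")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.simulation == 3 and self.scenario not in (1, 2, 3, 4):
            raise ValueError("Simulation 3 requires scenario in 1..4")
        if self.simulation in (1, 2) and self.maf is None:
            raise ValueError("Simulations 1 and 2 require a fixed MAF")


def sim3_design(scenario: int, p: int, rng, block_size: int = 4):
    """MAF profile, LD spec and causal loci for a Simulation-3 scenario.

    Null-SNP MAFs are drawn uniformly on (0.01, 0.50) -- the genome-like MAF
    spectrum -- and the two causal SNPs sit at fixed panel positions with the
    per-scenario MAFs from the study tables.  Strong/weak blocks give each
    causal SNP ``block_size`` satellite SNPs at the block's calibration target.
    """
    maf_a, maf_b = _SIM3_CAUSAL_MAFS[scenario]
    regime_a, regime_b = _SIM3_REGIMES[scenario]
    loc_a, loc_b = p // 4, 3 * p // 4
    mafs = rng.uniform(0.01, 0.50, size=p)
    mafs[loc_a] = maf_a
    mafs[loc_b] = maf_b
    blocks = []
    for loc, regime in ((loc_a, regime_a), (loc_b, regime_b)):
        if regime is None:
            continue
        members = tuple(range(loc + 1, loc + 1 + block_size))
        mafs[list(members)] = mafs[loc]  # satellites share the anchor MAF
        blocks.append(LDBlock(anchor=loc, members=members, regime=regime))
    spec = LDSpec(blocks=tuple(blocks), p=p) if blocks else None
    return mafs, spec, (loc_a, loc_b)


def _simulate_replicate(config: ScenarioConfig, rep: int):
    child = np.random.SeedSequence(config.seed, spawn_key=(rep,))
    s_geno, s_pheno, s_forest, s_imp, s_tie = child.spawn(5)
    n = config.n_cases + config.n_controls

    if config.simulation == 1:
        mafs = np.full(config.p, config.maf)
        model = model_registry(config.model)
        G = simulate_independent_genotypes(n, mafs, s_geno)
        y = simulate_threshold_phenotype(G, model, s_pheno)
    elif config.simulation == 2:
        mafs = np.full(config.p, config.maf)
        model = model_registry(config.model, maf=config.maf)
        G, y = sample_case_control(model, mafs, config.n_cases, config.n_controls, s_pheno)
    else:
        rng = np.random.default_rng(s_geno)
        mafs, ld, loci = sim3_design(config.scenario, config.p, rng)
        geno_seed = rng  # reuse the same stream for the genotype draw
        if ld is None:
            G = simulate_independent_genotypes(n, mafs, geno_seed)
        else:
            G = simulate_ld_genotypes(n, mafs, ld, geno_seed)
        model = _two_locus_threshold(config.model, loci)
        y = simulate_threshold_phenotype(G, model, s_pheno)
    return G, y, model, s_forest, s_imp, s_tie


@dataclass
class DetectionSummary:
    """Replicate-level detection indicators plus aggregation helpers."""

    config: ScenarioConfig
    replicates: pd.DataFrame  # one row per (replicate, method, causal snp)
    oob_errors: pd.DataFrame  # one row per replicate with a forest run

    @property
    def mean_oob_error(self) -> float:
        return float(self.oob_errors["oob_error"].mean()) if len(self.oob_errors) else np.nan

    def detection_probability(
        self, method: str, snp_id: int | None = None, region: bool = False
    ) -> float:
        col = "detected_region" if region else "detected"
        df = self.replicates[self.replicates["method"] == method]
        if snp_id is not None:
            df = df[df["snp_id"] == snp_id]
        return float(df[col].mean())

    def aggregate(self, by_type: bool = False) -> pd.DataFrame:
        """Long-format summary: one row per (method, snp) or (method, snp_type)."""
        key = "snp_type" if by_type else "snp_id"
        cols = ["detected"] + (
            ["detected_region"] if "detected_region" in self.replicates else []
        )
        agg = (
            self.replicates.groupby(["method", key], as_index=False)[cols]
            .mean()
            .rename(
                columns={
                    "detected": "detection_probability",
                    "detected_region": "region_detection_probability",
                }
            )
        )
        agg.insert(0, "simulation", self.config.simulation)
        agg.insert(1, "model", self.config.model)
        agg.insert(2, "scenario", self.config.scenario)
        agg.insert(3, "maf", self.config.maf)
        agg.insert(4, "p", self.config.p)
        agg["n_replicates"] = self.config.n_replicates
        agg["mean_oob_error"] = self.mean_oob_error
        return agg


def run_scenario(config: ScenarioConfig) -> DetectionSummary:
    """Run every replicate of one scenario and collect detection indicators.

    Any stage failure aborts the run with the replicate index and child seed
    in the exception chain -- replicates are never silently skipped.
    """
    want_forest = any(m in FOREST_METHODS for m in config.methods)
    rows = []
    oob_rows = []
    for rep in range(config.n_replicates):
        t_start = time.perf_counter()
        try:
            G, y, model, s_forest, s_imp, s_tie = _simulate_replicate(config, rep)
            causal = causal_effect_loci(model)
            types = snp_type_map(model, config.p)
            k = config.detection_k if config.detection_k is not None else len(causal)

            result = ScreeningResult()
            oob = np.nan
            if want_forest:
                fc = ForestConfig(
                    ntree=config.ntree,
                    mtry=config.mtry,
                    seed=int(s_forest.generate_state(1)[0] % (2**31 - 1)),
                    min_node_size=config.min_node_size,
                )
                report = analyze(G, y, fc, int(s_imp.generate_state(1)[0] % (2**31 - 1)))
                oob = report.oob_error
                oob_rows.append({"replicate": rep, "oob_error": oob})
                for m in FOREST_METHODS:
                    if m in config.methods:
                        result.add(m, getattr(report, m), higher_is_better=True)
            if "lr" in config.methods:
                result.add("lr", lr_scan(G, y), higher_is_better=False)

            tie_seeds = s_tie.spawn(len(result.methods))
            for m, tie in zip(result.methods, tie_seeds):
                hib = result.higher_is_better[m]
                detected = top_k_detection(result.scores[m], hib, causal, k, tie)
                for snp, hit in zip(causal, detected):
                    row = {
                        "replicate": rep,
                        "method": m,
                        "snp_id": snp,
                        "snp_type": types[snp],
                        "detected": bool(hit),
                        "oob_error": oob,
                    }
                    if config.simulation == 3:
                        row["detected_region"] = region_detection(
                            result.scores[m], hib, snp, k, G,
                            r2_threshold=config.region_r2, tie_seed=tie,
                        )
                    rows.append(row)
        except Exception as err:
            raise RuntimeError(
                f"replicate {rep} of {config} failed (child seed spawn_key=({rep},))"
            ) from err
        logger.info(
            "scenario sim=%s model=%s rep=%d done in %.2fs",
            config.simulation, config.model, rep, time.perf_counter() - t_start,
        )
    return DetectionSummary(
        config=config, replicates=pd.DataFrame(rows), oob_errors=pd.DataFrame(oob_rows)
    )


def summarize(summaries, by_type: bool = False) -> pd.DataFrame:
    """Merge per-scenario aggregates into one long-format table."""
    frames = [s.aggregate(by_type=by_type) for s in summaries]
    if not frames:
        raise ValueError("no completed scenarios to summarize")
    return pd.concat(frames, ignore_index=True)


def table1_grid(**overrides) -> list[ScenarioConfig]:
    """The full study grid: Sim 1 (5 models x 4 MAFs x 4 p), Sim 2 (3 models x
    4 p), Sim 3 (4 LD scenarios x Models 3 and 5).  Keyword overrides apply to
    every cell (e.g. ``ntree=500, n_replicates=25`` for a reduced-scale run)."""
    grid: list[ScenarioConfig] = []
    for model in (1, 2, 3, 4, 5):
        for maf in (0.1, 0.2, 0.3, 0.4):
            for p in (10, 100, 500, 1000):
                grid.append(
                    ScenarioConfig(simulation=1, model=model, p=p, maf=maf, **overrides)
                )
    for model in (6, 7, 8):
        for p in (10, 100, 500, 1000):
            grid.append(ScenarioConfig(simulation=2, model=model, p=p, maf=0.3, **overrides))
    for scenario in (1, 2, 3, 4):
        for model in (3, 5):
            grid.append(
                ScenarioConfig(simulation=3, model=model, p=1000, scenario=scenario, **overrides)
            )
    return grid
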
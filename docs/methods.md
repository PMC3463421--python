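# Methods

## Scope and design

`epiforest` studies the power of Random Forest (RF) variable-importance
rankings — versus univariate logistic regression — to place causal SNPs at
the top of a panel, as a function of panel size, effect architecture
(marginal vs. interaction heritability), minor allele frequency, and linkage
disequilibrium.  Everything is simulation: there is no real-data ingestion
beyond plain-text genotype/phenotype round-trips.

## Genotype simulation

Independent SNPs are Binomial(2, MAF) minor-allele counts, i.e. two
independent allele draws per individual (Hardy–Weinberg equilibrium).  MAFs
must lie in (0, 0.5]; panel profiles are either fixed (0.1–0.4 grids) or
drawn uniformly on (0.01, 0.50) to mimic a genome-wide MAF spectrum.

LD blocks use a haplotype copy-with-error construction: each individual
carries two haplotypes; a satellite haplotype copies its block anchor's
allele with probability 1 − ε and otherwise draws a fresh allele with a
probability chosen so the satellite's marginal MAF is preserved exactly.
The dosage correlation of anchor and satellite is then

    r = (1 − ε) · sqrt(q_a(1 − q_a) / (q_s(1 − q_s)))

and ε is calibrated by root-finding on this closed form so realized R² hits
the regime targets: 0.98 for "strong" blocks (each satellite must exceed the
0.95 reporting threshold with realization noise at n = 1000) and 0.20 for
"weak" blocks (comfortably below the 0.30 ceiling).  A copy-with-*flip*
variant would not preserve the satellite MAF when anchor and satellite
frequencies differ, which is why resampling is used.  Calibration fails
loudly (naming the block) when the MAF mismatch caps achievable R² below the
target.  The generator preserves per-SNP HWE because haplotypes remain
independent within individuals.  This is a parametric stand-in for
resampling real GWAS haplotypes: it reproduces target R² levels and MAF
spectra but not genome-scale LD decay, haplotype-block mosaics, or
higher-order haplotype structure — results under LD should be read as
regime-level, not locus-level, statements.

## Phenotype simulation

**Liability threshold.**  `Y = β₀ + Σβ_jX_j + β₅X₃X₄ + E`, `E ~ N(0, σ²)`,
with β₀ = 20 and σ² = 10 throughout; disease is `Y` above the *sample
median*, so every dataset of n = 1000 has exactly 500 cases and 500 controls
(floating-point median ties — probability zero in exact arithmetic — resolve
to the control class via stable sorting).  The five four-locus coefficient
vectors (β₁..β₄, β₅) are registered as Models 1–5:
(.9,.9,1.3,1.3,−1.3), (1,1,1,1,−1), (.8,.8,0,0,0), (.8,.8,1.5,1.5,−1.5),
(0,0,1.3,1.3,−1.3).  SNPs 1–2 are "main", SNPs 3–4 "interacting".

For analytic work, `threshold_to_penetrance` converts the same model to an
exact penetrance table by enumerating all 3^k causal genotypes and
root-finding (Brent, |Δprevalence| < 1e−10) the *population* threshold at
prevalence 0.5.  The population threshold and the per-dataset sample median
are deliberately distinct operations: the former defines heritability, the
latter guarantees exactly balanced samples.

**Penetrance tables.**  Direct two-locus disease models are built on the
orthogonal ANOVA basis under the HWE product measure: with centred allele
counts u(x) = x − 2q,

    f(a,b) = K + α·u(a) + β·u(b) + γ·u(a)u(b)

The three non-constant terms are orthogonal with zero mean, so prevalence is
exactly K (default 0.5) and each coefficient maps to its heritability
component in closed form.  Models 6–8 fix MAF = 0.3 and total H² = 0.01 with
marginal patterns both/one/none; where a pattern leaves shares unspecified
the split is (¼, ¼, ½), (0, ½, ½), (0, 0, 1) across (H²_M,A, H²_M,B, H²_I) —
an even split between marginal and interaction mass, chosen once as a
representative architecture.  Tables leaving [0, 1] raise immediately.
Sampling is retrospective: genotype batches are drawn, disease is
Bernoulli(f_ab), and individuals are retained until the case/control quotas
fill.

## Heritability decomposition

All components are exact enumerations on the HWE product measure (no
sampling): total H² is the variance of the penetrance over genotypes divided
by P(D)(1 − P(D)); the marginal component of a locus applies the same ratio
to the conditional prevalence at that locus; the interaction component of a
pair is the two-locus surface's H² minus both marginals.  For independent
loci these are orthogonal ANOVA components, so the two-locus decomposition is
exact to 1e−10 and interaction components are non-negative (values within
1e−10 of zero are clamped; "zero marginal effect" assertions use 1e−8).
With more than two loci, `decompose` reports per-locus marginals, per-pair
interactions, and a single remainder for higher-order terms.  Note the
threshold nonlinearity induces tiny (≈1e−5) pairwise interactions even
between "additive" loci; these are real properties of the model, not
numerical error.

## Random Forest

CART trees on bootstrap samples of size n, grown to purity by default
(`min_node_size = 1`).  Genotypes are treated as ordered with exactly two
cutpoints (≤0 and ≤1); three-way categorical splits are deliberately absent
since multi-category splitting is the known source of Gini's cardinality
bias.  At each node `mtry` variables are drawn without replacement (partial
Fisher–Yates); the split maximizes the Gini decrease, with exact ties broken
toward the lower variable index, then the lower cutpoint, making trees
deterministic given the candidate draw.  Leaf predictions are in-bag
majorities with ties to class 0.

OOB machinery follows Breiman: per-tree OOB accuracy, forest-level
majority-vote OOB error (vote ties → class 0; individuals never OOB are
excluded from the denominator).  Permutation importance permutes a
variable's values *within each tree's OOB set*, once per (tree, variable),
with per-tree seeds; the per-tree accuracy decrease d_t is zero by
definition for trees not containing the variable.  Raw MDA averages d_t over
all trees; scaled (Liaw) MDA divides by sqrt(s²/ntree) with s² the
across-tree variance of d_t (0 if s = 0); Meng MDA averages over containing
trees only; Gini importance sums (node size / n) × impurity decrease over a
variable's split nodes, averaged over trees.  Kernels are numba-compiled and
vectorized over node samples; one n = 1000, p = 1000, ntree = 500 fit plus
importance takes ~8 s on one CPU.

Defaults mirror GWAS screening practice: `mtry = round(0.1·p)`,
`ntree = 5000` at full scale.  Tests and the reduced-scale ("desk") profile
use ntree = 500 and 25–100 replicates; detection probabilities are
replicate-level binomial means, so the reduction mainly widens their noise
and mildly lowers MDA-based detection (fewer trees per variable).

## Logistic scan and detection

The univariate scan fits `logit P(D) = α + γX` per SNP.  Because the
likelihood depends only on the 2×3 status-by-genotype table, all SNPs are
fit at once by a damped Newton iteration on the table counts; the reported
score is the two-sided Wald p-value for γ (the GWAS convention).  Monomorphic
SNPs get p = 1; under (quasi-)separation (|γ| > 15 or non-convergence) the
scan falls back to a likelihood-ratio p-value at the capped slope — this only
matters at extreme signals where any reasonable statistic ranks the SNP
first.  The implementation agrees with a reference GLM fit to ~1e−13 (tested
against statsmodels).

A causal SNP is detected when it ranks in the top k (k = number of loci with
a simulated effect: 4 for Models 1, 2, 4; 2 for Models 3 and 5 and the
penetrance models).  Exact score ties are broken by a seeded random shuffle,
which preserves exchangeability: with all-null scores each SNP is detected
with probability k/p.  Region detection (LD scenarios) additionally credits
any SNP whose sample dosage R² with the causal SNP exceeds 0.85, and so
dominates SNP-level detection replicate by replicate.  A top-x% detection
variant is available via `detection_k`.

## Experiments and reproducibility

The scenario registry reproduces the study grid: Simulation 1 (Models 1–5 ×
MAF {.1,.2,.3,.4} × p {10,100,500,1000}, 100 replicates of 500/500),
Simulation 2 (Models 6–8 at MAF 0.3), Simulation 3 (p = 1000, LD scenarios
1–4 under the two-locus Models 3 and 5, causal MAFs .294/.309/.281 per
scenario, null MAFs uniform on (0.01, 0.50), causal loci at panel positions
p/4 and 3p/4 with four satellites per LD block).  In Simulation 3 the null
MAF profile is redrawn each replicate; the real-data analogue would hold one
empirical MAF/LD pattern fixed, so replicate-to-replicate variation here
includes MAF-spectrum noise.

Seeding: every replicate derives a `SeedSequence(master_seed, spawn_key=
(replicate,))` child, split into independent streams for genotypes,
phenotypes, forest bootstraps, permutations, and tie-breaks, so any
replicate is reproducible in isolation and reruns are byte-identical.  A
replicate failure aborts the scenario with the replicate index and seed; no
silent skipping.

`scripts/acceptance.py` problem sizes: exact heritability targets enumerate
81 (four-locus) or 9 (two-locus) genotype classes; logistic-scan detection
uses 100 replicates; forest detection uses ntree = 500 with 50 replicates
(Model 3) and 40 (Model 5); the OOB-error band uses 25 replicates at
p = 100.  Because the two causal SNPs in the no-LD scenario are exchangeable
(identical MAF and effect), per-SNP detection probabilities are estimated by
the mean over both SNPs, halving the binomial standard error at a given
replicate count.

## Known limitations

* The LD generator is parametric; it does not reproduce empirical haplotype
  structure (see above).
* Simulation 2's penetrance tables realize the documented heritability
  constraints, not any particular published cell values; other tables with
  the same (H²_M,A, H²_M,B, H²_I) signature would differ in higher moments.
* Only two-locus interactions are modelled in penetrance tables; the
  threshold model carries at most one product term.
* Regression forests, class weighting, proximity measures and joint/pairwise
  permutation importance are out of scope.
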
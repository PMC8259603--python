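# Methods

## The model

`sparsegs` analyses plot-level testcross yields from multi-environment
trials of bi-parental doubled-haploid (DH) families with the linear mixed
model

    y = 1 μ + X₁ b₁ + Z₁ u₁ + Z₂ u₂ + Z₃ u₃ + Z₄ u₄ + Z₅ u₅ + ε

where μ is the overall mean, b₁ a fixed location effect, u₁ the genetic
line-by-environment effect, u₂–u₅ iid random effects of tester, trial,
replicate-within-(environment, trial) and incomplete-block-within-replicate
(uₚ ~ N(0, I σ²ₚ)), and ε a residual with a heterogeneous diagonal
covariance — one variance σ²_εv per environment.  The genetic term carries
the genotype-by-environment structure through a Kronecker covariance

    u₁ ~ N(0, G₀ ⊗ G)

with `G` the g × g genomic relationship matrix over lines (fixed, computed
from markers) and `G₀` the v × v genetic covariance across the analysis
environments.  Three parameterizations of `G₀` are available:

* **US** — unstructured, every variance and covariance free
  (v(v+1)/2 parameters);
* **FA** — factor-analytic, G₀ = ΛΛ′ + Ψ with m latent environmental
  factors and a non-negative diagonal Ψ of specific variances.  Ψ entries
  may collapse toward zero (extended-FA behaviour, a non-full-rank GxE
  covariance); numerically they are floored at 10⁻⁶ of the mean genetic
  variance because the estimating equations use G₀⁻¹;
* **DIAG** — independent environments, used as a no-borrowing baseline.

The number of FA factors defaults to m = 1 for fewer than four
environments and m = 2 for four to six (and beyond), overridable.

Environments are whatever an `EnvironmentGrouping` maps the raw
(location, management, year) triples onto: `LM` (location × management) and
`M` (management) for single-year analyses, `MY` (management × year),
`M_plus` (management pooled over years) and `LMY` (the fully crossed
classification) for multi-year data.  Under groupings that merge locations
the fixed location contrast is retained — location is a real nuisance
regardless of how the covariance is grouped.  Replicate keys include the
year for multi-year groupings; block keys additionally include the
location, so merged environments never alias distinct physical blocks.

Derived summaries: per-environment plot heritability
h²_v = σ²_gv / (σ²_gv + σ²_εv) with σ²_gv = G₀[v,v], and genetic
correlations r_vw = G₀[v,w] / √(G₀[v,v] G₀[w,w]).

## REML estimation

Variance components are estimated by restricted maximum likelihood through
Henderson's mixed-model equations with a dense Cholesky factorization; the
restricted log-likelihood uses the identity
−2ℓ_R = (n−p) log 2π + log|R| + log|Σ_u| + log|C| + y′Py, where C is the
full coefficient matrix.  Each iteration computes closed-form EM updates
(from BLUPs plus traces of blocks of C⁻¹), which never decrease ℓ_R, and
from the third iteration attempts an average-information (AI) Newton step.
The AI step uses exact first derivatives, the average-information matrix
½ f′Pf over the parameter directions f_i = (∂V/∂θ_i) Py, and
Levenberg–Marquardt damping: a proposal that lowers ℓ_R or leaves the
feasible region raises the damping and is retried; if every damped step
fails, the EM update is applied instead.  Variance components sitting at
their floor with a score pushing further down are frozen out of the AI
system (active set) — without this, the clipped Newton direction is no
longer an ascent direction and the iteration stalls.

Numerical choices:

* convergence: |ΔlogL| < `tol` (default 1e-6) or `max_iter` (default 200);
  non-convergence is reported via `converged=False` with the full
  likelihood trace, never silently;
* variance floors: `floor_frac` (default 1e-8) × phenotypic variance;
  floored components are listed in `Results.pinned`;
* FA identifiability: Λ is rotated to lower-trapezoidal form (QR of Λ′
  with a positive-diagonal sign convention) after every EM update; the
  likelihood is rotation-invariant, the rotation only fixes the report;
* US updates keep G₀ invertible by flooring eigenvalues at 10⁻⁷ of the
  largest (the Kronecker prior needs G₀⁻¹);
* the GRM is ridged before fitting until its condition number is at most
  1e7.  A GRM built from fewer effective markers than lines — routine with
  close families — is numerically singular, and G⁻¹ enters the equations
  directly; the spectrum, not Cholesky success, decides the ridge;
* starting values come from method-of-moments on per-line cell means
  (pairwise covariances scaled by the mean GRM diagonal, shrunk toward
  independence and eigenvalue-clipped to the PD cone);
* sparse-testing gaps are handled by omitting records: the Kronecker
  covariance spans the full line × environment grid, so BLUPs of masked
  cells borrow strength through G and G₀.  GEBVs for every line in G,
  including fully unphenotyped ones, come from the same MME solve.

The engine is validated against independent oracles in the test suite: an
eigen-decomposition single-kernel REML solver for v = 1, US/FA
log-likelihood equivalence at v = 2 (FA(1) saturates a 2×2 covariance),
finite-difference checks of the score, EM monotonicity, and parameter
recovery at the study scale.

## Calibration-set optimization

**CDmean.**  The reliability of a set of zero-sum contrasts K of a full-sib
family with relationship block G is

    CD(K) = diag[ K′(G − λ(Z′DZ + λG⁻¹)⁻¹)K ] / diag[ K′GK ]

with Z the incidence of calibration phenotypes, D = I − X(X′X)⁻¹X′ the
projection removing the calibration-record mean, and λ the
residual-to-genetic variance ratio.  λ defaults to 0.5: the criterion is
driven by relationship structure far more than by heritability, and an
intermediate value behaves like the (unknowable, for untested lines) true
ratio.  The per-individual score CDmean(g) phenotypes individual g alone
and averages the reliabilities of the other N−1 contrasts; repeating over
g ranks the family.  With a single calibration record an intercept in D
would annihilate all information and make every score identically zero, so
mean adjustment is applied only for calibration sets of two or more
records; singleton calibration uses D = I, giving the closed form
CD_j(g) = (k_j′G e_g)² / ((λ + G_gg) · k_j′G k_j) and a non-degenerate
ranking.  The opposite reading — score g by how well the *others* predict
*it* — is available via `reverse=True`; the default matches the
phenotype-one-predict-the-rest description.  All ties break by line id.

**CV2 splits.**  The top half of each family by CDmean is observed in the
first WW environment, the bottom half in the second (odd line to the
first).  The WS calibration set takes the higher-CDmean half of each
WW-observed group — ceil from the first group, floor from the second — so
WS observes half the family, drawn from both WW environments.

**Avg_GRM.**  A historical candidate j is scored by its mean relationship
(1/n) Σ_g G_gj to the n members of a target family — a raw estimate of the
genome fraction shared — and the top `n_select` (default 300) candidates
per family are kept, union over families when augmenting.

## Cross-validation schemes

* **CV1** (new-population prediction): per repeat, a random half of the
  families is masked entirely in one WW environment and observed in the
  other, and vice versa; in WS, ⌊k/2⌋ random families from each WW-observed
  group of size k are masked.  At twelve families this is exactly the
  six-and-six WW split with three WS-masked families per group.  Ten
  repeats by default.
* **CV2** (within-family sparse testing): masking is the complement of the
  CDmean split; the plan is deterministic given the scores, so a single
  plan is run.

Validation targets are per-environment BLUEs from the *complete* data:
per environment, a cell-means model with genotype fixed and trial,
replicate and block random, fitted by the same REML engine.  Because every
nuisance factor and the residual are nested within environment, a combined
all-environment BLUE analysis factorizes exactly into these per-environment
fits, so both schemes validate against the same table.  Accuracy is the
Pearson correlation between masked lines' GEBVs and their BLUEs per family
and environment; cells with fewer than three masked lines are skipped;
the unweighted mean across families is reported.  Masked records are
removed from the training data before any fitting — a sentinel-substitution
test in the suite verifies bit-identical results when masked phenotypes are
corrupted.

Historical augmentation appends either all historical records or, per
current family, the Avg_GRM-selected individuals' records; multi-year
groupings (LMY, MY, M_plus) are then required.

## The synthetic-data generator

No real data ship with the package; the generator produces campaigns with
the statistical structure the analysis assumes.

* **Genotypes.**  Inbred founders (two per family) carry presence/absence
  markers with frequencies uniform on (0.02, 0.98) — so the progeny MAF
  spectrum straddles the 0.05 filter — on a random genetic map.  DH lines
  are doubled recombinant F1 gametes: crossovers are Poisson on Morgan
  distance (Haldane, no interference; validated against the closed-form
  recombination fraction), and every line is exactly homozygous, coded 0/2.
* **Genetic values.**  Drawn directly as vec(U) ~ N(0, G₀ ⊗ G) via matrix
  square roots, with G the realized GRM of the simulated genotypes.  The
  generator therefore produces data *from the model the analysis fits*,
  which makes parameter recovery a well-posed test; no marker-level QTL
  effects are simulated.
* **Phenotypes.**  y = μ + location + tester + trial + rep + block +
  genetic value + residual, with the residual variance per environment and
  all nuisance effects iid normal.  Families are packed contiguously into
  trials (default: one trial per family), testers cycle over families
  within year, replicates are complete within trial, blocks are random
  contiguous chunks within replicate.
* **Defaults** mirror a single-year campaign: 12 families × 70 DH lines,
  1 000 markers on 10 chromosomes of 1.5 Morgan, environments
  Kiboko-WW / Kakamega-WW / Kiboko-WS, 3 testers, 2 replicates, 5 blocks
  per replicate, μ = 5 (t/ha-scale arbitrary units), unit residual
  variances, plot h² cycling (0.25, 0.35, 0.30), within-year genetic
  correlations (0.2, 0.6, 0.3), across-year 0.2, nuisance variances
  tester 0.05, trial 0.05, rep 0.02, block 0.02.  With `n_years=2` a
  disjoint set of families is generated per year — the second year serves
  as a historical pool.

What the generator does *not* emulate, hence what passing tests do not
show about real data: linkage maps of a real genome, QTL architecture and
marker-QTL linkage-phase differences between families, selection during DH
production, shared check plots connecting trials, spatial field trend
beyond the block effects, year-specific agronomy, and genotyping error.
Real-data accuracies depend on exactly these, so the simulation validates
the machinery and the relative ordering of methods, not absolute accuracy
levels.

## Reproducibility

Every stochastic step takes an explicit seed.  The pipeline command
derives per-stage seeds from one global seed as
`SeedSequence(seed).generate_state(n_stages)`, reduced below 2³¹, and the
run manifest records configuration, input checksums, package version,
per-stage seeds, timings and convergence, sufficient to re-execute a run
bit-identically (asserted in the test suite).

Problem sizes used by the shipped checks are the package's own choices:
parameter recovery runs 20 replicates at the full study scale (12 × 70
lines, three environments); the FA/US equivalence check uses ten 600-line
datasets; the sparse-testing benefit and null-calibration checks use
8 × 24 and 6 × 16 line campaigns with 10 replicates/repeats; the
acceptance script runs one full-scale campaign with three CV1 repeats.

## Known limitations

* The AI step assembles the mixed-model equations densely; fits are
  comfortable up to a few thousand line × environment effects but the
  engine does not exploit sparse-inverse or XFA sparse-equation tricks.
* BLUE models assume genotype effects are estimable per environment from
  the trial design (they are, for the generated designs; heavily
  disconnected real designs may need checks or connected blocks).
* FA fits report one rotation of Λ; only ΛΛ′ + Ψ is identified.
* The exchange-algorithm CDmean and its accelerated variants are out of
  scope; the per-individual CDmean here is a deliberate, cheaper design.
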
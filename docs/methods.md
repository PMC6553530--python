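# Methods

This note documents the models, priors, algorithms, numerical choices
and known limitations behind `factorbn`.  The pipeline turns a panel of
genotyped accessions with many correlated phenotypes into a directed
network among the *genetic* parts of a few latent factors, in four
stages: confirmatory factor analysis, multivariate genomic BLUP,
Cholesky decorrelation, and Bayesian-network structure learning with
bootstrap model averaging.

## 1. Bayesian confirmatory factor analysis (`factorbn.bcfa`)

Measurement model for t traits and q factors, per accession:

    T = Λ F + s,        var(T) = Λ Φ Λ' + Ψ,

where each trait loads on exactly one factor (one nonzero per row of
Λ), Φ is the q×q factor covariance and Ψ is diagonal.  Priors: free
loadings N(0, precision 0.01) — i.e. essentially flat; Φ ~
InvWishart(I_q, q+1); ψ_ii ~ InvGamma(shape 0.5, scale 1).  The loading
prior is parameterized by *precision* because a loading prior with
variance 0.01 would shrink every loading to near zero, which is
incompatible with standardized loadings near 1 on well-measured
indicators; both interpretations are runnable through
`CfaPriorConfig`.

Identification fixes the first listed indicator of each factor at
loading 1 and leaves Φ free.  Reported loadings are the standardized
solution λ√Φ_jj / √(λ²Φ_jj + ψ), which is invariant to that scale
choice and to the unit-variance standardization applied to the
phenotypes before fitting (standardization stabilizes the single
shared Ψ prior across traits measured in wildly different units).

The Gibbs cycle treats F as missing data: (i) row-wise Gaussian
updates of free loadings; (ii) inverse-gamma updates of ψ; (iii) an
inverse-Wishart update of Φ given F; (iv) a joint multivariate-normal
update of each accession's factor vector from p(F|θ,T); (v) missing
phenotype cells drawn from their conditional normal.  Defaults are 3
chains × 5000 iterations with 2000 burn-in; convergence is monitored
with the Gelman–Rubin potential scale reduction factor (PSRF), with
1.2 as the conventional acceptance bound.  Chain starts are
overdispersed so the PSRF is a meaningful diagnostic.

## 2. Multivariate genomic BLUP (`factorbn.gblup`)

The q factor-score columns are treated as traits of a multivariate
mixed model

    F = 1μ' + X b + u + ε,  vec(u) ~ N(0, Σ_u ⊗ G),  vec(ε) ~ N(0, Σ_e ⊗ I),

with X an intercept plus reference-coded subpopulation classes (a full
one-hot plus intercept is rank-deficient), G the marker-standardized
(VanRaden, second form) genomic relationship matrix, and
InvWishart(I_q, q) priors on both covariance matrices with flat priors
on fixed effects.

Sampling is *marginalized*: rotating by the eigenvectors of G makes
the accessions conditionally independent, and the breeding values are
integrated out analytically, so each rotated residual is
N(0, d_i Σ_u + Σ_e).  The covariance matrices are updated with
random-walk Metropolis in a log-Cholesky parameterization, using a
proposal covariance from a Laplace approximation at the multi-start
MAP; fixed effects are drawn from their exact marginal GLS Gaussian;
breeding values are drawn from their exact conditional (joint
diagonalization of (Σ_u, Σ_e) reduces the n conditional draws to
elementwise operations — an exact congruence transform validated
against the brute-force Kronecker formula in the test suite).

Why not conditional inverse-Wishart Gibbs updates: on kinship matrices
whose spectra leave the genetic/residual split weakly informed
component by component (few very large structure eigenvalues, a
homogeneous bulk), the centered chain conditioned on a breeding-value
draw sees almost no information about Σ_e and random-walks under the
prior, far from where the marginal likelihood concentrates.  We
observed chains initialized at the generative truth drifting away from
it; the marginalized kernel does not have this failure mode.

Method-of-moments starting values come from regressing the rotated
residual outer products on d_i (E[e_i e_i'] = d_i Σ_u + Σ_e is linear
in d_i).  Defaults are 2 chains × 30,000 iterations with 5000 burn-in;
convergence is judged by PSRF on the variance components.  Analysis
and test scales are much smaller (2–4k iterations), which the PSRF
checks justify on those problems.

## 3. Decorrelation of predicted breeding values

With G = LL' (lower Cholesky, ridge escalated by decades from 0 to at
most 1e-4 until the factorization succeeds, and recorded), the
adjusted values are u* = (I_q ⊗ L⁻¹) û, computed with triangular
solves, never an explicit inverse.  If Var(vec u) = Σ_u ⊗ G then
Var(vec u*) = Σ_u ⊗ I: rows become independent with covariance Σ_u,
which is what downstream network learning assumes about its samples.
The adjustment is applied to the posterior-mean û; draw-wise
adjustment is the same linear map and therefore commutes with
averaging.

## 4. Gaussian Bayesian networks (`factorbn.bn`)

Scores.  BIC is the penalized Gaussian log-likelihood rescaled by −2
so that larger is better, with |Pa|+2 parameters per node (intercept,
coefficients, residual variance).  BGe is the Gaussian–inverse-Wishart
marginal likelihood computed node-wise as log m(v ∪ Pa) − log m(Pa)
with the dimension-adjusted degrees of freedom that make it exactly
constant on Markov equivalence classes (verified to 1e-13 over all
543 four-node DAGs).  Default hyperparameters: equivalent sample sizes
α_μ = 1 and α_w = q+2, prior mean the sample mean, prior scale
t·I with t = α_μ(α_w − q − 1)/(α_μ + 1); all exposed in `ScoreConfig`.

Searchers.  Hill climbing is steepest ascent over add/delete/reverse
moves from the empty graph with zero restarts; tabu search additionally
keeps a list (default length 10) of recently visited graphs and may
accept non-improving moves for up to 2q² stale steps, returning the
best network seen.  Because Gaussian scores are score-equivalent, the
two orientations of a freshly added arc tie exactly; naive
lexicographic tie-breaking then systematically commits to arbitrary
orientations and can lock the search out of collider configurations.
Exact ties are therefore resolved by a deterministic one-step
lookahead.  Known limitation: even with the lookahead, steepest-ascent
hill climbing can terminate in a lower-scoring equivalence class on
data with several interacting colliders (a W-shaped 4-node truth is
the smallest reliable counterexample); tabu search escapes essentially
all such traps in our experiments and is the recommended score-based
learner, consistent with it producing the best-scoring consensus on
real data.

Constraint-based machinery.  Fisher-z partial-correlation tests (α =
0.05 by default) drive a PC-style skeleton with sepset recording,
v-structure orientation, and Meek rules R1–R3 (R4 is only needed when
background knowledge supplies extra orientations, which never happens
here, so R1–R3 are complete).  `cpdag_of` uses the same closure to map
a DAG to its equivalence-class pattern.

Hybrids.  MMHC restricts with Max-Min Parents-Children (forward
max-min association growth with backward subset elimination,
symmetrized by intersection); the 2-phase restricted maximization
variant restricts with an interleaved HITON-PC-style selector.  Both
maximize with hill climbing confined to the whitelisted adjacencies,
so the result can only contain restricted arcs.

Bootstrap model averaging.  Accessions are resampled with replacement
(replicate size n, degenerate zero-variance replicates redrawn and
counted), one network learned per replicate; arc strength is the
presence frequency regardless of orientation and direction the
orientation frequency conditional on presence.  The consensus keeps
arcs with strength ≥ 0.85 (default), oriented by majority direction
(ties logged and broken lexicographically); a cyclic consensus is
repaired by dropping the weakest arc in the cycle, with a warning.

## 5. Synthetic data (`factorbn.simdata`)

The generator inverts the inference chain: Balding–Nichols genotypes
(subpopulation frequencies Beta-distributed around an ancestral
frequency with variance fst·p(1−p); dosages Binomial(2, p)); i.i.d.
"adjusted" genetic rows propagated through a known factor-level DAG so
their covariance is the SEM-implied Σ_u; coloring by L to give
Var(vec u) = Σ_u ⊗ G; factor scores adding subpopulation shifts and a
factor-level residual; phenotypes T = FΛ' + specific noise.  Placing
the DAG on the *decorrelated* level makes end-to-end recovery after
the Cholesky adjustment a well-posed target.

Panel-shaped defaults mirror the study system: 374 accessions split
92/85/77/52/12/56 across six subpopulations, Fst 0.25, 48 traits on
six factors with the 7/14/5/11/6/5 indicator split, anchor loadings 1
and free loadings cycling through ±0.4–0.9, specific variances cycling
0.25–0.6, unit exogenous genetic variances, identity factor-level
residual covariance, subpopulation shifts of roughly ±0.8 SD with a
deterministic sign pattern, and a 7-edge genetic DAG whose topology and
signs mirror the consensus structure score-based learners find on real
rice data.  Markers fixed to monomorphic or near-monomorphic states by
drift are removed by the standard MAF ≥ 0.05 filter before G is built.
What the generator does not emulate: linkage disequilibrium, marker-
level trait architecture, cross-loadings, non-Gaussian measurement
error, and genotype-by-environment structure — so passing tests
support the statistical machinery, not claims about any real panel.

## 6. Evaluation experiments (`factorbn.evaluation`)

* Decorrelation: 800 Monte-Carlo draws of u ~ N(0, Σ_u ⊗ G) at n=1000
  with a known 3-factor Σ_u (chain SEM), G from simulated structured
  genotypes.  Measures Frobenius relative error of the pooled row
  covariance of u* and the mean absolute cross-accession correlation
  (noise floor ≈ 0.028 at 800 replicates), with the unadjusted u as
  contrast.
* Searcher exactness: 20 i.i.d. Gaussian datasets (n=150), both scores,
  3- and 4-node systems; hill climbing and tabu must match exhaustive
  enumeration (25 and 543 DAGs).  Unstructured data isolates optimizer
  exactness; recovery under a true DAG is tested separately.
* BGe equivalence: maximum within-class spread over all 543 four-node
  DAGs grouped by CPDAG on correlated random data.
* Factor-analysis recovery: three replicate panel-shaped datasets at
  n=1000 drawn exactly from the factor model (identity kinship, no
  subpopulation shifts), reduced chains (2 × 2000/500).  RMSE and 95%
  credible-interval coverage of free standardized loadings are pooled
  across replicates because within one dataset the 42 loadings share
  realization-level fluctuations (a factor's realized variance shifts
  all its loadings together), which makes single-dataset coverage a
  noisy estimate of calibration.
* End-to-end recovery: n=400 accessions, 500 markers, Fst 0.05, path
  coefficients ±0.8, factor residual variance 0.25 (heritability ≈
  0.8), MMHC consensus over 200 bootstrap replicates at threshold
  0.85.  The weakly differentiated, broad-spectrum panel is the regime
  where the Σ_u/Σ_e split is well identified; with strong discrete
  structure the fixed-effect correction absorbs between-subpopulation
  genetic variance and the split degrades.  MMHC is the default
  learner here because its restrict phase suppresses the weak spurious
  dependencies that posterior-mean estimation error injects between
  parents of a common child ("moralization" artifacts); score-based
  learners pick those up as extra adjacencies, which matches the
  field observation that hybrid algorithms return sparser networks.
  Direction accuracy is reported but not gated — orienting edges is
  harder than detecting them.

## 7. Known limitations

* Two-stage uncertainty: factor scores and breeding values enter later
  stages as point estimates (posterior means); their estimation error
  is correlated across factors and can surface as weak extra
  dependencies in the learned network.  Under weak identification of
  the genetic/residual covariance split this is the dominant error
  mode; the hybrid learners are markedly more robust to it.
* Steepest-ascent hill climbing is not an exact optimizer on
  collider-rich structured data (see §4); tabu search is.
* The measurement model forbids cross-loadings; traits that genuinely
  measure two factors will distort loadings of their assigned factor.
* Missing genotypes are mean-imputed; no LD-aware imputation.
* The normality screen on latent variables (skewness / excess
  kurtosis) warns but never gates: Gaussian scores are used regardless.
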
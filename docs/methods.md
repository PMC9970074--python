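# Methods

## The model

Let `y_ipj` be physician *p*'s 0–5 rating of skill *j* in consultation
*i*. For each outcome skill *j* the package fits

    y_ipj = (β_j + u_pj)ᵀ x_ip(−j) + ε_ipj,   ε ~ N(0, σ_j²),
    u_pj ~ N(0, Σ_uj),

where `x_ip(−j)` collects an intercept and the eight other skills on
their raw 0–5 scale (no centering or standardization by default; a
grand-mean-centering flag exists). The physician-specific coefficient of
predictor *k*, `β_jk + u_pjk`, formed draw-by-draw from the posterior,
is the directed edge k→j of that physician's skills network. If the
nine items were jointly Gaussian with precision matrix Ω, these
node-wise conditionals identify `β_jk = −ω_jk/ω_jj`; that identity is
the backbone of every recovery test, because the synthetic generator
parameterizes truth exactly this way.

Network parameters per skill: **activation** = the physician's mean
rating across their consultations; **outstrength** (**instrength**) =
sum of retained outgoing (incoming) edge weights. An edge is retained
when its 95% equal-tailed credible interval — empirical quantiles of
the coefficient draws — excludes zero; physician networks are pruned on
physician-specific draws, the population network on the fixed-effect
draws. Because equal-tailed intervals are nested, pruning is monotone in
the level. Strength sums are accumulated in plain index order so a
brute-force re-summation reproduces stored values exactly.

Two population summaries are provided. `build_population_network` uses
the fixed-effect posteriors — the model's own population summary, with
the nominal ~5% per-edge false-retention rate any 95%-interval rule has.
`average_physician_network` instead averages the pruned physician
networks, retaining an edge only when a majority of physicians retain
it; per-physician intervals are wide, so this summary is far more
conservative about spurious edges and is the construction under which a
truly disconnected block of skills reliably shows no cross-edges.

## Estimation

No probabilistic-programming framework is used: all models have
conjugate full conditionals, so `sdmnet.samplers` implements plain Gibbs
samplers — Normal draws for coefficient blocks (Cholesky of the
posterior precision, batched over physicians), Huang–Wand hierarchical
inverse-Wishart steps for the random-effect covariance (half-t margins
on the SDs, marginally uniform correlations; a diagonal variant exists
for small samples), and inverse-gamma steps with auxiliary variables for
the half-Cauchy residual scale. Per-group sufficient statistics make the
per-iteration cost independent of the number of consultations. Chains
are independent (seeded from a `SeedSequence`), and convergence is
monitored with split Gelman–Rubin R̂ (verified to match arviz to
machine precision); zero-variance draws define R̂ = 1. Random-effect
scale parameters are the slow mixers, as usual for Gibbs on hierarchical
models; the default configuration — 4 chains × 8000 iterations, 3000
burn-in, thinning 10, hence 2000 retained draws — settles them, while
tests and the acceptance script use 2 × 1300/300/2 (1000 draws) and
state so.

Default priors are scale-matched to the data they face: for the 0–5
rating regressions, N(0, 10²) intercepts, N(0, 5²) slopes, half-Cauchy(10)
residual scale, half-t(A = 2.5) random-effect SDs; for the 0–100
competence regressions, N(0, 100²) intercepts, N(0, 50²) slopes,
half-Cauchy(25) residual scale. The wide intercept prior in the
prediction models is load-bearing: a tight one drags correlated slope
posteriors away from zero and inflates their null significance rate
(measured at 6.8% before the fix, 4.7% after, against a nominal 5%).
Informative priors — per-coefficient Gaussian means and SDs, e.g. taken
from a previous study's posterior — enter the confirmatory model through
a YAML/JSON `PriorSpec` file; absent a file, the model falls back to the
weakly informative defaults with a logged warning.

Degenerate designs: `fit_prediction` rejects rank-deficient predictor
matrices, naming the collinear columns (QR with pivoting). The
confirmatory/exploratory orchestration instead proceeds under the proper
Gaussian priors (`on_collinear="allow"`), because at realistic sample
sizes pruning can zero a skill's strength column for every physician and
the reporting surface (9 or 12 predictor rows) should survive that.

## Preprocessing

Consultations with more than two of the nine skills missing are
excluded (reported pair-by-pair). Remaining missing cells are imputed by
EM under a single multivariate Gaussian pooled over all consultations —
per-physician row counts are too small for stable per-physician fits.
The E-step groups rows by missingness pattern; convergence is declared
when the observed-data log-likelihood changes by less than `tol`
(default 1e-6), and the trace is exposed so monotonicity can be checked.
Imputed values are left continuous, never rounded back to the Likert
grid. Observer scores are affinely rescaled to 0–100 from configurable
instrument ranges and averaged per physician with equal weight per rated
consultation; physicians with no rated consultation for an instrument
stay absent, never zero-filled.

## The synthetic generator

The generator is the package's validation instrument, not a fixture: it
emulates a study of `n_physicians = 28` physicians with 11 consultations
each (308 rows), audio recordings for 24, and observer coverage
22/24/22 across OPTION-12/OPTION-5/4HCS — the scale of the motivating
dataset — while every estimand has an analytic truth.

Each physician's nine ratings are multivariate Gaussian with precision
matrix Ω_p. The population template places partial correlations of
0.15–0.40 on a sparse support shaped like the replicated skills-network
topology (skills 1–2 a strongly tied pair disconnected from a 3–4–6–7–8
cluster around hub 7, with 5 and 9 peripheral); a random-support
alternative with a sparsity parameter exists. Item conditional
precisions (the Ω diagonal) are drawn from U(0.7, 1.5): with equal
diagonals the true k→j and j→k coefficients would be exactly symmetric
and true in/outstrength exactly collinear — a degenerate design no real
data would show. Physician heterogeneity adds symmetric noise
(SD = `heterogeneity`, default 0.08) to the off-diagonal support plus
mild lognormal jitter (SD = half of that) on the diagonal, repaired to
positive definiteness by shrinking the perturbation toward the
population matrix (bounded retries, then an error). Physician-level item
means scatter around population means (SD 0.4 on the 0–5 scale), giving
activation genuine between-physician variance. Discretization is
clip-to-[0,5]-then-round; continuous mode is kept for exact recovery
tests. Missingness is independent per cell (MCAR).

Observer scores are linear in the *true* per-physician network
parameters plus Gaussian noise, clipped to [0, 100]. Default effects
route mainly through skill 6 (eliciting preferences) with smaller
contributions from skills 1 and 7 and noise SD 8 — chosen once to give
physician-level R in the 0.4–0.7 range observed for such instruments.
What the generator does **not** emulate: ordinal measurement (graded
response), response styles, informative missingness, or rater effects in
the observer scores — so passing tests demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness
to those violations.

## Validation design and problem sizes

The acceptance checks (and `scripts/acceptance.py`) use: a single
physician × 500 continuous consultations for the OLS/−ω_jk/ω_jj oracle;
five replicate studies of 30 physicians × 50 consultations for
population edge-sign recovery (fixed-effect network) and the
disconnected-block property (averaged-physician network, see above);
constructed bivariate and 9-variate cases against Schur-complement
conditional means for EM (agreement to ~1e-15); three replicate studies
of 100 physicians (observer noise SD 5) for prediction coefficient
recovery within ±2 posterior SDs; 100 pure-noise replicates at 200
physicians for null calibration of the significance flag; and one
study-scale run for the shape of the confirmatory (9 predictor rows) and
exploratory (12 rows for a 4-skill selection) reports. Exploratory
stage-1 selection is "any significant coefficient of that skill, any
parameter type, any instrument"; a `selected_skills` override allows
refitting a fixed selection.

## Known limitations

* The Gaussian likelihood treats 0–5 Likert ratings as continuous; the
  information loss from discretization is quantified by tests rather
  than corrected, and no ordinal-likelihood variant is provided.
* R is defined as the (zero-floored) posterior correlation between
  linear predictor and observed responses; other Bayesian R²
  definitions would differ in small samples.
* Fixed-effect edge pruning at the 95% level retains spurious edges at
  the nominal rate; use the averaged-physician summary when absence of
  edges is the claim of interest.
* With ~11 consultations per physician, physician-specific edges are
  strongly shrunk toward the population network; between-physician
  differences in network structure are only weakly identified at that
  scale (they recover well at ~200 consultations per physician).
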
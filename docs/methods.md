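# Methods

## Estimand and decomposition

The package targets the regression-based decomposition of a binary
exposure's effect on a continuous outcome through $K$ continuous
mediators, without exposure–mediator interaction. Mediator models
$M_k \sim A + C$ and the outcome model $Y \sim A + M_1 + \dots + M_K + C$
are marginal linear models; the per-mediator indirect effect is the
coefficient product $\hat\delta_k = \hat\alpha_k\hat\beta_k$, the
combined indirect effect their sum $\hat\Delta$, the direct effect the
outcome-model exposure coefficient $\hat\theta$, the total effect
$\hat\tau = \hat\theta + \hat\Delta$ (an identity, exact by
construction), and the mediated proportion $\hat\Delta/\hat\tau$. When
$|\hat\tau|$ falls below a threshold (default 0.1 s) the ratio is
reported with an instability flag rather than suppressed, since the
application's proportions legitimately carry very wide intervals. The
sign convention is substantive: negative indirect effects shorten the
clock-drawing time (protective), positive ones lengthen it
(deleterious).

Causal reading of these quantities requires the usual assumptions — no
unmeasured exposure–outcome, exposure–mediator or mediator–outcome
confounding given $C$, correctly specified linear models, and no
interaction. None of these are testable from the data; the package
implements the estimator, not the assumptions.

### Product ≡ difference identity

Under OLS on a common sample, $\sum_k \hat\alpha_k\hat\beta_k$ equals the
drop in the exposure coefficient between the outcome model without and
with mediators, exactly. `difference_method_oracle` computes the
right-hand side through an independent code path; the equality to 1e−8
is the module's principal correctness guarantee. With the exchangeable
GEE engine the identity is only approximate (different weighting per
fit), which the tests assert at a loose documented tolerance.

## GEE engine

`clustmed.gee` solves identity-link Gaussian estimating equations with
an exchangeable working correlation by iteratively reweighted least
squares. Conventions, fixed because software dialects differ:

- scale $\hat\phi$: residual sum of squares over $n - p$
  (bias-corrected);
- exchangeable parameter $\hat\rho$: within-cluster pair products of
  Pearson residuals summed over clusters, divided by
  (number of pairs − $p$), re-estimated each iteration and clamped to
  $(-1/(m_{\max}-1),\, 1)$ so every working matrix stays invertible;
- convergence: maximum absolute coefficient change < 1e−8, at most 100
  iterations, non-convergence raised as an error, never ignored;
- standard errors: cluster-robust sandwich.

The exchangeable inverse is applied in closed form
($R^{-1}v = (v - c\,\mathbf{1}\sum v)/(1-\rho)$ with
$c = \rho/(1+(m-1)\rho)$), and all per-cluster accumulations are segment
sums over rows sorted by cluster, so a fit costs a handful of
matrix-vector passes — necessary because the bootstrap re-fits $K+1$
models per replicate. The test suite cross-checks coefficients, sandwich
SEs and $\hat\rho$ against statsmodels' GEE (agreement ~1e−6) and
against the exact reductions: singleton clusters ≡ OLS, intercept-only
balanced fit ≡ grand mean.

`working="independence"` (engine `"ols"`) skips the iteration and yields
OLS point estimates with the same sandwich — the "GEE for standard
errors only" reading. Both engines are first-class; exchangeable GEE is
the default for point estimation.

Exposure coding is 0 = reference group (ε3/ε3), 1 = exposed group
(ε2 carrier); binary confounders are 0/1.

## Genotype groups

APOE alleles are called per haplotype from rs7412/rs429358: (T,T) → ε2,
(C,T) → ε3, (C,C) → ε4; (T,C) is undefined. Unphased double
heterozygotes (T/C at both SNPs) cannot be resolved into a diplotype —
ε2/ε4 and the undefined-haplotype alternative are indistinguishable —
and since ε4 carriage forces exclusion, the package refuses to guess:
both cases raise a dedicated ambiguity error (scalar API) or are
excluded with a separate count (table API). Groups: ε3/ε3 → APOE3
(reference), ε2/ε2 or ε2/ε3 → APOE2, any ε4 → excluded.

## Preprocessing and sample construction

The analysis sample is built complete-case (no imputation), dropping
excluded genotypes and any row missing exposure, a confounder, a
mediator or an outcome, with per-reason drop counts logged. `total_time`
is recomputed as think + ink so the identity holds exactly. The
`generation` indicator derives from birth year > 1935 when not supplied.

Mediators are natural-log-transformed and z-scored **after** exclusions,
so standardization constants describe the analysis sample (order
matters and is tested; a flag recomputes the transform inside bootstrap
replicates for sensitivity). The log base is irrelevant after
standardization; the sample SD uses the $n-1$ denominator. Both choices
are inert for the estimates but fixed for reproducibility.

## Bootstrap inference

Confidence intervals are Efron percentile intervals over cluster
(family) resamples: each replicate draws the observed number of families
with replacement, relabels duplicates as distinct clusters, and re-runs
every model fit plus the decomposition. Families — not individuals — are
the resampling unit because individual resampling would destroy the
within-family correlation the working model exists to respect
(`resample_unit="individual"` is available for sensitivity checks).
Quantiles use linear interpolation of the order statistics (numpy
default, R type 7). Replicates that fail to estimate are counted and
excluded; more than 1% failures aborts the analysis. The mediated
proportion's interval is the percentile interval of the replicate-wise
ratios, untruncated, and is exempt from the CI-excludes-zero
significance rule. One master seed spawns independent per-replicate
streams (`numpy.random.SeedSequence`), making runs bit-reproducible and
order-independent.

Percentile intervals are first-order asymptotic: at small cluster counts
(on the order of 100 families) they visibly undercover, which is a
property of the method rather than of the implementation; coverage
checks therefore run at the generator's study-scale default (~400
families).

## Stepwise selection (secondary analysis)

Backward deletion over mediator terms only, scored by the Gaussian
independence-likelihood AIC, $n\log(\mathrm{RSS}/n) + 2(p+1)$; GEE has
no likelihood, so selection runs on the ordinary linear model and the
retained set is refit with the requested engine. The accepted-step AIC
sequence is strictly decreasing; AIC ties break toward the earlier
mediator in the configured order, making selection deterministic. By
default selection happens once on the observed sample and the retained
set is held fixed across bootstrap replicates (the rerun-of-the-analysis
reading); per-replicate re-selection is available behind a flag, with
dropped mediators contributing a zero indirect effect so replicate
quantities stay aligned. An empty retained set is legal and collapses
the decomposition to $\hat\tau = \hat\theta$.

## Synthetic cohort generator

`clustmed.synthetic` draws the exact structural model the estimators
assume: latent log-mediators linear in exposure and confounders,
outcomes linear in exposure, latent mediators and confounders,
`total_time = think_time + ink_time` row-exact, and every noise term
carrying an exchangeable within-family correlation induced by a shared
Gaussian family intercept (variance $\rho\sigma^2$ plus individual
variance $(1-\rho)\sigma^2$, which yields correlation $\rho$ exactly).
Raw mediators are exponentiated, hence strictly positive, and the
pipeline's log-z-scoring recovers the latent scale up to an affine map;
since $\hat\alpha_k\hat\beta_k$ is invariant to mediator scaling, the
generator's true products, direct, total and proportion are directly
comparable to pipeline estimates. SNP genotypes consistent with the
group assignment are emitted (ε2/ε2 with probability 0.1 among exposed),
and an optional fraction of ε3/ε4 carriers exercises the exclusion path.

Defaults, chosen once to mimic the motivating cohort and held fixed:
400 families of 2–4 members (~1200 participants), exposure prevalence
240/1228 assigned per participant (family-level assignment behind a
flag), 24 mediators carrying the lipid-panel names, exposure→mediator
effects spread over 0.25–0.45 SD, outcome signal concentrated on a few
lipids so the true combined indirect effects are ≈ −0.80 s (think) and
≈ −0.16 s (ink) against direct effects of −1.90 and −0.98 s,
$\rho = 0.3$, outcome noise SDs 5 and 2.5 s, baselines 20 and 14 s.
Confounders are simple parametric sketches of the cohort's Table-1-style
summaries (age $\mathcal N(63, 8^2)$, 57% female, education ≈ 13.5 y,
BMI $\mathcal N(27, 4.5^2)$, 29% on lipid-lowering medication, birth
years 1916–1955).

What the generator does **not** emulate: empirical lipid–lipid
correlation (independent given exposure and confounders by default; an
optional correlation matrix is applied to both noise components),
skewed/heteroscedastic outcome distributions (outcomes are Gaussian and
may, rarely, go negative in the far tail — they are deliberately not
clipped, since clipping would break the linear structural model),
missing data, assay batch effects, and genotype–confounder dependence.
Passing recovery and coverage tests therefore demonstrates correctness
of the estimators under the assumed model, not robustness to violations
of it.

## Simulation sizes

Problem sizes used by the validation suite and `scripts/acceptance.py`,
chosen as a compromise between Monte-Carlo resolution and a single-CPU
run: parameter recovery at 200 cohorts of 300 families (×4 members) and
100 cohorts of 600 families; CI coverage and null calibration at 300
cohorts of 400 families with 200 bootstrap replicates each (the OLS
engine inside replicates — cluster resampling already carries the family
structure); selection retention over 30 cohorts of 200 families with 2
signal and 4 noise mediators. Stochastic assertions use 3σ
binomial/Monte-Carlo bands around the nominal values. The test suite
runs reduced versions of the same checks.

## Known limitations

- Exposure–mediator interactions and exposure-induced confounding are
  out of scope; the decomposition is the no-interaction product method.
- Percentile (not BCa/bootstrap-t) intervals only; no analytic
  delta-method SEs for the products.
- AIC selection ignores the working correlation by construction; a
  QIC-based criterion is not implemented.
- The mediated proportion is unstable near $\hat\tau = 0$ and is
  reported with a flag rather than an interval-based fix.
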
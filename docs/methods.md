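# Methods

This note documents the statistical models in `sdmnet`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Node-wise multilevel network estimation

The skills network of physician *p* is defined through nine conditional
regressions: for each outcome skill *k*, the item score is modelled as

y_ik = (β₀k + b₀,p(i),k) + Σ_j (β_jk + b_j,p(i),k)·x_ij + ε_ik,
ε_ik ~ N(0, σ_k²),  b_·pk ~ N(0, diag(τ_·k²)),

over all consultations of all physicians, with the eight predictor items
grand-mean centred (the outcome is centred too; the grand mean is added back
so intercepts live on the 0–5 item scale). Physician-specific coefficients
are posterior means of β + b — partial pooling shrinks poorly informed
physicians toward the population, which is the intended behaviour for ~10
consultations per physician. The edge j→k of physician p's network is the
physician-specific coefficient of item j in outcome k's model.

*Fixed vs random.* Each outcome is fitted twice — all coefficients common
(fixed) vs physician-varying (random intercept + random slopes) — and the
deviance information criterion (conditional parameterization, p_D = mean
deviance − deviance at posterior means) selects the random model only when
its DIC undercuts the fixed model's by at least 3 points.

*Purging.* The default retains an edge when the 95% equal-tailed credible
interval of the physician-specific coefficient lies entirely above zero
("not credibly higher than zero" read literally as a one-sided rule);
`purge_rule="two-sided"` retains credibly negative edges as well. Retention
can be decided per physician (default) or once at the population level
(`purge_level="population"`); the former lets individual networks differ in
their edge sets, the latter gives a retention mask that is consistent across
physicians, which matters when comparing strength parameters *between*
physicians — under per-physician retention, which edges survive fluctuates
from physician to physician, and the resulting selection noise propagates
into the strength sums. Parameter-recovery evaluations therefore use the
population-level mask; the pipeline default remains per-physician.

*Activation.* Defined as the physician-specific model intercept (default).
Because predictors are grand-mean centred — not physician-mean centred —
the intercept is the physician's adjusted item level, close to but not
identical with the raw item mean; `activation="raw_mean"` switches to the
raw mean. Both are exposed because the two readings are equally defensible
and differ only by the adjustment for the other items.

## Bayesian machinery

All models are conditionally conjugate Gaussian hierarchies sampled with a
blocked Gibbs sampler: coefficients in one multivariate Normal block,
per-group deviations batched across groups, variances via inverse-gamma full
conditionals. Priors: N(0, 100²) on every regression coefficient (the
outcome scales are 0–5 and 0–100, so this is effectively flat), and
half-Cauchy(5) on every scale parameter (residual SDs and random-effect
SDs), implemented exactly through the inverse-gamma mixture representation,
keeping the sampler free of Metropolis steps. Three chains with
overdispersed seeded starts; split-chain Gelman–Rubin R̂ with threshold 1.1
(non-convergence is signalled as a warning carrying the diagnostics and
recorded on the fit — at desk settings occasional variance-parameter R̂
excursions above 1.1 occur in small data and are visible to the caller);
equal-tailed 95% credible intervals throughout. Two schedules are named:
`desk` (3 × 4000 iterations, half burn-in, no thinning — sized so the full
default pipeline runs in about half a minute) and `paper` (3 × 150 000
iterations, 60 000 burn-in, thinning 30 — the original WinBUGS schedule).
DIC requires a tracked per-draw deviance; adding chains never perturbs
existing ones because chain seeds are spawned children of the root seed.

## Observer competence scoring and quality checks

Composites are unweighted item means (formative measurement model),
linearly rescaled to 0–100, averaged over raters within consultation and
consultations within physician. Incomplete rating records are dropped
listwise with a logged count; physicians without observer data are omitted,
never imputed.

Variance decomposition (physician / consultation-within-physician /
residual) is fitted by REML (statsmodels MixedLM) on the per-rater rescaled
composites, negative components truncated at zero; the physician ICC is
var_physician over the total. The inter-rater model adds a rater factor
that is *crossed* with physicians (raters form a shared pool), which plain
nested REML cannot express; those four components come instead from the
package's crossed-random-intercepts Gibbs model, summarized by posterior
means. Reliability of the physician-level mean of c consultations × k
raters follows the Spearman–Brown-style composite

P / (P + C/c + (R·[random-rater] + E)/(c·k)),

reported in random-rater (generalizing over raters) and fixed-rater
(conditioning on the panel) variants. The exact three-level formula used in
the original analysis is unpublished; this composite is the package's
documented choice.

## Prediction of observer-rated competence

Screening fits, per outcome, three physician-level Bayesian regressions —
all nine skills' activations, outstrengths, instrengths respectively,
centred — and flags coefficients whose 95% interval excludes zero
(two-sided; the original text's "very likely non-zero association" does not
fix sidedness, and two-sided is the conservative reading). Skills with at
least one flag for at least one outcome enter the final model: intercept
plus the three parameter types of each retained skill. Physicians
contribute to fitting only with both data sources; predictions are emitted
for every physician with complete node parameters.

R, R² and adjusted R² are computed **per posterior draw** — model variance
as the sample variance (ddof 1) of the linear predictor across physicians,
R² = model/(model+residual), adjusted R² = 1 − (1−R²)(n−1)/(n−p−1) — and
then summarized. Point transforms of posterior means would be mutually
inconsistent (the posterior mean of R² is not the square of the posterior
mean of R); per-draw computation is the only coherent reading. When p ≥
n−1 the model is still reported but the adjusted R² is refused. Prediction
is exact linear algebra under posterior-mean coefficients with the stored
training means — no sampling.

## Synthetic-data generator

The generator defines the study conditions: 29 physicians, 10 SDM-Q-9
ratings each, 3 recorded consultations scored by 2 of 4 raters, chosen to
match the original design.

*Patient ratings.* The estimation model regresses each item on the other
eight cross-sectionally, so a recoverable ground-truth network must consist
of the conditional-regression coefficients of some joint distribution. The
conditionals of a joint Gaussian are constrained — Γ_jk/d_k = Γ_kj/d_j,
with d_k the conditional variance of item k — so an arbitrary asymmetric
matrix is *not* a valid truth (the earlier simultaneous-equation
formulation fails exactly here: its node-wise regression estimand is a
symmetrized transform of the structural matrix, not the matrix itself). The
generator is therefore parameterized by a symmetric association matrix S_p
(eigenvalues < 1) and per-skill conditional SDs; the directed edges are
Γ_jk = S_jk·√(d_k/d_j), the joint precision is D^{-1/2}(I−S_p)D^{-1/2},
and the node-wise regression of item k has coefficients exactly Γ_p[·,k].
Directedness arises from skills differing in predictability: the default
gives "sharing the decision" and "deliberating" small conditional SDs
(high outstrength) and "focusing" and "eliciting preferences" large ones
(high instrength), with a dense core around eliciting preferences — the
qualitative structure reported for real consultations. Physician
heterogeneity: item means vary N(population mean, 0.4²) — the intercept
random effect lives on the mean scale so means stay inside the Likert range
whatever the association draw does — and symmetric association entries vary
N(population value, 0.07²), redrawn until the spectral radius is below one
(Γ and S are similar matrices, so one check covers both). Latent scores are
rounded half away from zero and clipped to 0–5.

*True competence* is a documented linear map of skill-6 node parameters,
9·(activation−pop) + 9·(outstrength−pop) + 9·(instrength−pop) above an
instrument-specific base (16 / 12 / 33 on the 0–100 scale), giving a true
competence SD ≈ 5 across physicians.

*Observer ratings* follow location(competence) + physician + consultation +
rater + item-residual Gaussian effects, discretized to the instrument range;
rater main effects persist across consultations so rater variance is
estimable. Default components are calibrated (on the composite 0–100
scale: 13 / 34.6 / 8 / 18.4·m per item for an m-item instrument) so the
physician ICC lands near 0.4 and the 3×2 inter-rater reliability near 0.72
— the midpoints of the ranges the framework was developed against.

*What it does not emulate:* ordinal response processes (items are rounded
Gaussians, not cumulative-link draws), informative missingness, patient
covariates, floor-effect asymmetries beyond clipping, and rater drift.
Passing recovery tests therefore show the estimators are correct under the
assumed Gaussian mechanism at the study's scale — not that the model is
right for any particular clinic's data.

## Evaluation scales and numerical choices

Recovery experiments run at 30 physicians × 30 consultations — the scale
the framework's own power discussion recommends — where edge recovery
reaches r ≈ 0.78 and activation r ≈ 0.87; closed-form ICC/IRR recovery uses
200 physicians with a wide single-item instrument, component scale ×100 and
rater pools of 30–40, so that integer quantization (variance 1/12) and the
chi-squared scatter of a small rater pool's realized variance do not
displace the closed form from the quantity actually estimated. Replicated
rates (screening retention, DIC preference) use 20 replicates at a reduced
3 × 1500 schedule. Degenerate inputs are handled explicitly: zero-variance
outcomes are flagged and retained nowhere; constant chains are reported as
degenerate rather than failing R̂; variance draws are floored at 1e−12;
all-identical observer scores yield a flagged zero-variance decomposition.

## Known limitations

Node models use a Gaussian likelihood on 0–5 integer items; with strong
floor/ceiling effects coefficients attenuate. The DIC is the conditional
variant and shares its known optimism about random-effects models. The
final regression ignores estimation uncertainty in the node parameters
(they enter as point estimates, as in the original two-stage analysis), and
collinearity among parameters of central skills makes individual
coefficients hard to interpret — the predicted scores, not the weights, are
the robust output. No cross-validation is performed at n ≈ 29.
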
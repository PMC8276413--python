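# Methods

This note documents the statistical procedures implemented in `cogreserve`,
the choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about behaviour on real data.

## Variable preparation

**Standardization.** All analysis variables are z-scored with the sample
standard deviation (ddof = 1), computed over non-missing entries.

**Robust Winsorization.** Outliers are clamped, not removed: values outside
`median ± k·b·MAD` are replaced by the nearer bound, with `MAD =
median(|x − median(x)|)`, threshold `k = 3`, and scale constant `b = 1.4826`
(which makes the MAD consistent with the SD under normality). `k` and `b`
are configurable (`WinsorSpec`). A MAD of zero on non-constant data is a
hard error rather than a silent clamp-to-median, because that would destroy
the variable; constant data pass through unchanged. Brain variables are
instead clamped at |z| = 3 after z-scoring, mirroring the z-score-based rule
conventionally used for volumetric measures.

**Order of operations.** For individual proxies: raw score → MAD-Winsorize →
standardize. For composite proxies: element-wise mean of the members'
standardized values → MAD-Winsorize (no re-standardization; the composite's
slightly sub-unit variance is immaterial to R², F and p, which are
scale-invariant). Whether Winsorization precedes or follows z-scoring is not
fixed by the framework's description; the order above is a documented choice,
applied uniformly. Cognitive timed tasks are reverse-coded (negated after
standardization) so higher always means better performance. The episodic
composite averages the processed immediate and delayed recall scores; the
global composite averages the five processed cognitive variables and is then
Winsorized and standardized itself.

**Missing data.** Transformations use non-missing entries; a composite is
missing wherever any member is missing (no prorated mean); each model cell
is fitted on its own complete cases, so n can differ across cells.

## Composite enumeration

With k individual proxies, every subset of size ≥ 2 defines a composite:
`2^k − k − 1` composites and `2^k − 1` proxies in total (127 for k = 7,
31 for k = 5). Composite names are the sorted member names joined by `+`,
giving stable join keys across cohorts for the replication gate.

## The hierarchical moderated regression

Each cell fits three nested OLS models (intercept always included): age (z),
sex (0/1, female = 1), brain; + proxy; + brain × proxy. The interaction is
the product of the *complete-case* z-scores of brain and proxy, which
centres it by construction and avoids step-3 collinearity. ΔR² values are
clipped at zero (they are non-negative by least-squares nesting up to
floating-point error). The added-term p-value is the coefficient's two-sided
t-test, identical to the 1-df partial-F p (`partial_f_test` verifies
t² = F). Standardized coefficients are reported as `coef·sd(x)/sd(y)` for
continuous predictors and `coef/sd(y)` for the binary sex indicator.

The overall model F reported with each step is `(R²/p) / ((1−R²)/(n−p−1))`.
A consistency check in the test-suite confirms that the published step-1
statistics for both source cohorts (30 rows in
`cogreserve.reference_tables`) are reproduced by this formula from their
printed R² and n within 3-decimal rounding — establishing that this is the
correct reading of those tables' "f" column.

## Robust re-fit

The robust pass is iteratively reweighted least squares with Tukey's
redescending biweight, `w(u) = (1 − (u/c)²)²` for |u| ≤ c and 0 beyond, and
MAD residual scaling `s = b·median(|r − median(r)|)` re-estimated each
iteration. Defaults: `c = 4.685` (95% efficiency under normality),
`b = 1.4826`, OLS start, convergence when the largest coefficient change is
below `1e−8`, cap of 50 iterations (non-convergence is flagged, not
raised). Standard errors use the large-sample M-estimator covariance
`s²·Σψ² / (n−p) / (mean ψ′)²·(XᵀX)⁻¹` with Huber's small-sample correction
factor, and p-values are two-sided normal; the framework's description names
the estimator but no inference method, so standard asymptotic normal theory
is used. With `scale_center="zero"` the implementation agrees with
statsmodels' RLM (Tukey biweight, MAD scale) to ~1e−6 in coefficients and
standard errors, which the test-suite uses as an independent cross-check;
the default centres the MAD at the residual median, consistent with the
Winsorization definition.

Significance of a step, in both the OLS and robust fits, is the two-sided p
of that step's own added coefficient (proxy at step 2, interaction at
step 3), symmetric across steps.

## Gating and summaries

An effect in one cohort passes the **dual gate** when its OLS and robust
p-values are both below α (default 0.05). It **replicates** when it passes
the dual gate in both cohorts *and the coefficient signs agree* — a
sign-flipped pair is not treated as a replication, because replicated
effects are interpreted directionally. Sign agreement is configurable
(`require_sign_agreement=False`) since a purely significance-based
criterion is also defensible. Robustness is `100·(replicated cells)/(cells)`
to two decimals over the 15-model grid; the headline effect size is the
mean ΔR², over both cohorts, of replicated cells only, with an all-cells
mean emitted alongside for transparency. Bonferroni corrections are applied
per brain-cognition model using the per-cohort proxy count (α/127 → 0.0004,
α/31 → 0.0016 at 4 decimals); the stricter whole-grid budget (1905 / 465
comparisons) is available through `comparison_budget`.

## Proxy scoring

Occupational complexity reverses each Dictionary-of-Occupational-Titles
rating on its dimension range (data 0–6, people 0–8, things 0–7; lower raw
rating = more complex) and sums, giving 0–21. IPAQ-style physical activity
is MET-weighted minutes with the scoring-protocol weights 8.0 / 4.0 / 3.3
(the framework's description cites the instrument without printing weights;
these defaults are configurable). Godin-style activity is session counts ×
assumed duration (0.5 / 0.75 / 1 h) × MET value (9 / 5 / 3), in MET-hours.
Activity-frequency instruments are plain sums of Likert responses whose item
count and range are declared per instrument, not inferred (the published
instrument descriptions are internally inconsistent about leisure item
counts and score ranges). Reading-test scoring applies the half-test gate:
second half administered only above 20 first-half words; 0–11 stands as the
full score; 12–20 requires an injected half-to-full conversion lookup (the
published conversion table is not bundled and the hook is untested against
it); above 20 without a second half is rejected. Years of education and the
Social Network Index pass through unscored; missing education is refused
rather than imputed (the original imputation model's coefficients are not
public — the hook accepts pre-imputed values).

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with cohort
templates matching the two source samples in size and design: `tilda`
(n = 313, ages 54–88, 50.48% female, seven proxies) and `crrann` (n = 234,
ages 50–80, 51.28% female, five proxies). Proxies are multivariate normal
with a configurable correlation matrix; the published proxy correlations
exist only as heatmaps, so the default matrix is a one-time choice: an
attainment cluster (education-verbal 0.50, education-occupation 0.45,
occupation-verbal 0.30) and weaker activity correlations (0.05–0.35),
positive definite by construction. Brain variables are unit-variance with
an age loading of −0.3 (age-related atrophy; a zero default would make the
step-1 covariate adjustment vacuous). Cognition variables are linear in
z-age, sex, the three brain variables and the proxies, plus Gaussian noise
with residual SD 0.85. Default planted effects: age −0.25 (tilda) / −0.10
(crrann), sex +0.15 / −0.10 (matching the reported direction difference
between cohorts), brain +0.12 / +0.15, verbal intelligence +0.30 on every
outcome, education +0.15 on executive function and +0.05 elsewhere, small
(0–0.05) effects for the remaining proxies, stimulating activities +0.20
(tilda only), and *no* interaction terms — moderation is null by default.
These defaults put step-1 R² and the strongest independent effects in the
same range as the published step-1 tables. A contamination switch replaces
a fraction of residuals with draws from a `contamination_scale`-times wider
normal (for exercising the robust pass), and an MCAR mask can blank proxy
and cognition entries.

**Closed-form oracle.** For any cell without planted moderation, the
population incremental R² of adding a proxy to age + sex + brain follows
from the generative covariance: `ΔR² = [c₂ᵀΣ₂⁻¹c₂ − c₁ᵀΣ₁⁻¹c₁] / Var(Y)`
with `c = Cov(X, Y) = Σβ`. `planted_delta_r2` evaluates this exactly and is
validated against a 200 000-subject empirical fit (agreement within 0.005).

**What the synthetic cohorts do not show.** They are multivariate normal
with linear effects and (by default) homoscedastic Gaussian noise: passing
tests demonstrate that the pipeline's arithmetic, inference and gating are
correct under the assumed generative law, not that real proxy distributions
(skewed MET minutes, discrete Likert sums, bounded network indices), real
missingness mechanisms, or real brain-measure artefacts behave equally
well. No attempt is made to reproduce the source cohorts' marginal
distributions, longitudinal waves, or any published real-data coefficient.

## Simulation sizes and calibration checks

The test-suite's behavioural checks use: 500 replicates at n = 313 for ΔR²
parameter recovery (a planted population ΔR² of 0.10 is recovered in mean
within ±0.01); 1000 replicate pairs for type-I calibration (per-cohort OLS
rejection of null step-2/step-3 effects within binomial 99% bounds of 5%,
replicated dual-gate rate ≤ 0.5% of cells); 200 replicates for the
contamination comparison of robust vs OLS slopes; and one full two-cohort
grid (127×15 + 31×15 cells, OLS + IRLS) as an end-to-end smoke test. These
sizes keep the whole suite under a few minutes while leaving Monte-Carlo
error well inside each tolerance.

## Known limitations

- Robust inference is asymptotic; at small n its p-values are approximate,
  and the dual gate inherits that approximation.
- The replication gate treats the two cohorts symmetrically and requires a
  complete 15-model grid in each; there is no meta-analytic pooling.
- Bonferroni is the only multiplicity correction offered.
- The NART conversion hook and the education-imputation hook are interfaces
  only; their published parameter tables are not distributed here.
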
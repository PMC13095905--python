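# Methods

## The behavioral model

Each design cell pits a smaller effortless reward (an *offer*) against a
fixed larger reward R that requires performing a cognitively effortful task
(backward typing at four word counts, or an n-back task at loads 1–6),
scheduled at one of six delays: right now, 1 day, 3 days, 1 week, 2 weeks,
1 month. Delays are treated as a six-level categorical factor (canonical
day codes 0, 1, 3, 7, 14, 30); ordinal position is used only for display.
The *indifference point* is the offer at which the decider has no
preference; *subjective value* is SV = indifference point / R, the fraction
of the effortful reward the decider would accept to avoid the effort.

## Synthetic agents

An agent's noise-free SV for cell (e, d) is

    SV(e, d) = clamp( base(e) + delta(e, d) + b_subject , 0, 1 )

* `base(e)` — nonincreasing in effort; default 0.92 → 0.60 across six
  n-back loads (0.90 → 0.60 across four word counts). The anchors place
  the nondepressed top-load immediate SV near 0.6 and the depressed
  lowest-load immediate SV near the same value, matching the qualitative
  crossover the two-group design exhibits.
* `delta(e, d)` — the temporal effect. Nondepressed agents get positive
  shifts confined to the upper half of the effort range, ramping to the
  top-level profile (0, 0.040, 0.070, 0.090, 0.077, 0.056) across the six
  delays; the one-week/two-week/one-month values are printed group-level
  coefficients used as calibration anchors, the 1- and 3-day values
  interpolate the same rise-then-ease profile. Depressed agents get
  `delta = 0` everywhere (the flat-trajectory construction) plus an
  overall SV offset of −0.313.
* `b_subject` — Normal(0, 0.1) subject intercept.

Choices are logistic in the value difference:
P(effortful) = 1 / (1 + exp(−(SV·R − offer)/τ)) with temperature τ = 0.2
(currency units), i.e. a noise scale of τ/R = 0.1 SV units for the n-back
design — chosen so the titrated SV noise is of the same order as the
titration's quantization, which is what single-shot six-trial titration of
human choices realistically delivers.

Questionnaire scores are drawn from truncated normals conditioned on group
(means/SDs from the two screened groups' characteristics: depressed PHQ-9
18.9 ± 3.6 on [15, 27], CES-D 40.4 ± 7.5 on [16, 60]; nondepressed 1.3 ±
1.4 on [0, 4] and 5.3 ± 3.9 on [0, 15]; GAD-7, age and gender likewise),
so that every generated agent passes its group's screening rule
(depressed iff CES-D ≥ 16 and PHQ-9 ≥ 15; nondepressed iff CES-D < 16 and
PHQ-9 ≤ 4; everything else excluded). Only cutoff membership matters
downstream; no claim of psychometric realism is made.

The n-back battery simulates 32 signal and 96 noise trials per load (two
64-trial practice runs at 25% targets) with an equal-bias criterion: hit
rate Φ(d/2), false-alarm rate Φ(−d/2), where d is the per-load target d′
(3.70 down to 0.86) plus Normal(0, 0.8) subject jitter. Mean RTs come from
per-load anchors (588 ms up to 849 ms, subject SD 150 ms); NASA-TLX
ratings vary linearly between level-1 and level-6 anchors on a 0–21 scale
(the response bounds are an assumption; the instrument's printed means
reach ~18, which a 0–20 scale could not comfortably accommodate with the
reported SDs).

### The null cohort

`null_spec` zeroes *every* effect: delay shifts, the group offset, and the
effort gradient (base SV flat at the mid value). Flattening the effort
gradient matters: with a gradient, titration noise varies with the cell's
true SV, the mixed model's pooled residual variance is then wrong per
level, and type-I error for delay contrasts is miscalibrated for reasons
unrelated to the delay factor. The all-effects-zero cohort is the
exchangeable reference condition under which the calibration properties
(type-I within the binomial band, family-wise error ≈ α) are defined.

### What the generator does *not* emulate

No attrition, no reward-magnitude manipulation, no within-session learning
or fatigue, no correlation between questionnaire traits and SV (traits are
independent of the SV surface except through group), and drift rates do
not depend on the current offer (condition-level drift only). Passing
recovery tests therefore shows the *analysis chain* is sound at realistic
noise levels, not that real populations obey the generating model.

## Titration algorithms

**Reversal staircase** (R = 10, integer offers 1–9). Bisection on the
bracket [offer_min − 1, offer_max + 1] with round-half-up midpoints,
starting at round(R/2) = 5. An effortful choice raises the lower bracket
edge, an effortless choice lowers the upper edge; the procedure stops when
two adjacent integers have elicited opposite preferences and reports the
smaller offer at which the effortless option was preferred (the worked
trajectory 5 → 8 → 9 yields £9). An agent effortless even at the minimum
offer is flagged `floor` (indifference = offer_min); effortful even at the
maximum is flagged `ceiling` (indifference = R, SV = 1). The source design
specifies the stopping rule and one trajectory but not the full schedule;
round-half-up bisection is the simplest schedule consistent with that
trajectory. Whether offers were integer throughout is likewise implied
rather than stated; integer offers are assumed.

**Halving titration** (R = 2, six trials). Trial 1 offers R/2; the first
adjustment is R/4 and each subsequent adjustment halves; the offer
presented on trial 6 is the indifference point (resolution R/64 ≈ 0.03 SV).
The starting magnitude R/4 follows the canonical COG-ED configuration.
Probabilistic agents are called once per trial — no retries or smoothing,
mirroring single-shot participant choices. For deterministic threshold
agents the estimate provably errs by at most the final step; the test
suite verifies this exhaustively on a 500-point threshold grid.

## Mixed-model analysis

`SVMixedModel` fits SV ~ effort × delay (× group) with treatment contrasts
against the highest effort level, "right now", and the nondepressed group,
plus optional covariates (subject mean d′, standardized age, a binary
gender indicator, GAD-7), by REML. The random-effects ladder starts at
by-subject intercepts plus *uncorrelated* by-subject effort slopes
(variance components), and drops to intercept-only if the larger structure
fails to converge or the slope variance collapses to zero; the structure
actually fitted is recorded. Fixed-effect p-values use the large-sample
normal approximation — the Python stack provides no Satterthwaite degrees
of freedom — which at hundreds-to-thousands of observations per fit is
indistinguishable from the t-based version; all calibration claims are
stated (and tested) in terms of realized type-I/power, which do not depend
on the df convention at these sizes. An lme4 fit via Rscript serves as an
independent oracle for the fixed effects in the test suite.

Planned pairwise comparisons take all C(6,2) = 15 delay pairs *within*
each effort level (and group) on estimated marginal means (covariates at
their sample means; they cancel in the differences), with Tukey adjustment
via the studentized-range distribution applied within each 15-comparison
family — not across levels, since each level's delay family is the
hypothesis-bearing unit.

## Drift-diffusion model

Choices and RTs follow a two-boundary Wiener process: drift v (positive →
effortful boundary), boundary separation a, relative start z = 0.5,
non-decision time t0, diffusion coefficient 1.

* **Simulator**: Euler–Maruyama with a Brownian-bridge crossing
  correction — within each step the probability that the unobserved path
  crossed a boundary is exp(−2 d₀d₁/dt) for endpoint distances d₀, d₁ —
  which removes the O(√dt) first-passage bias of the plain scheme; the
  default dt = 1e-3 with this correction is more accurate than plain Euler
  at 1e-4 and an order of magnitude faster. A guard refines dt when
  a/√dt < 10.
* **Likelihood**: the first-passage density via the small-time and
  large-time series with per-element truncation at tolerance 1e-7,
  switching at the standard fewer-terms criterion; the upper-boundary
  density follows from the lower by (v, z) → (−v, 1 − z). Trials with
  rt ≤ t0 contribute −∞ and are counted.
* **Hierarchical fit**: drift varies by group × effort cell (the delay
  factor is excluded from the default model and available behind a flag);
  subject-by-cell drifts are partially pooled toward cell means μ_v[g, e]
  with common SD σ_v; a and t0 are per-subject with group-level lognormal /
  truncated-normal population distributions. Priors: μ_v ~ Normal(0, 2);
  log a population mean ~ Normal(log 1.5, 1); t0 population mean ~
  Normal(0.4, ·); variances Inv-Gamma(2, 0.1) for conjugacy. Sampling is
  Metropolis-within-Gibbs: one vectorized random-walk sweep over all
  subject-by-cell drifts (conditionally independent blocks), per-subject
  sweeps for a (log scale) and t0 (truncated to (0.01, min rt)), then
  conjugate group-level draws. Proposal scales adapt toward ~35%
  acceptance during burn-in only, preserving detailed balance afterwards.
  Default settings are 4 chains × 5,000 iterations after a 200-draw
  burn-in; convergence is declared when every group-level split-chain
  R-hat ≤ 1.1 (the statistic is standard; the cutoff is this package's
  choice), and non-converged fits are flagged, not silently used.
* **Model comparison**: DIC = D̄ + pD with pD = D̄ − D(θ̄) evaluated at the
  posterior-mean parameters; |ΔDIC| > 5 is flagged as substantial.

Default generating drift patterns: the nondepressed profile is anchored at
the printed 1-back group mean (+0.471) and declines through zero to −0.445
at 6-back using the printed effort contrasts as the descent profile — the
printed coefficients, read literally as offsets from 1-back, never cross
zero, while the accompanying figure and text describe drifts turning
negative at high load; the figure's sign structure is followed. The
depressed profile uses the printed per-level posterior means verbatim
(−0.187 … −0.126, negative throughout). Between-subject drift SD defaults
to 0.15, moderate relative to the ~0.9 span of the cell means.

## Power analysis

Within-subject repeated-measures power uses df1 = (m−1)ε,
df2 = (n−1)(m−1)ε and noncentrality λ = n·m·f²·ε/(1−ρ) — the convention of
the standard power tool's repeated-measures module, with its defaults
ρ = 0.5 and ε = 1 (neither is printed in the source designs; under these
defaults the published minimum Ns of 13 and 10 reproduce exactly, so no
alternative convention was needed). The alternative effect-size convention
can be had by rescaling f before the call.

## Problem sizes in the test suite

The suite runs the full validation at sizes chosen to characterize each
property with useful Monte-Carlo resolution: titration resolution on a
500-threshold grid; diffusion closed forms and simulator/likelihood KS at
10,000 trials (both boundaries pooled through the signed-RT
representation, so the whole sample informs one statistic); hierarchical
drift recovery at 20 subjects/group × 30 trials/cell with 2 chains × 2,000
iterations; type-I calibration on 200 null cohorts of 20 subjects; power
and the headline delay-by-load pattern on 50–100 cohorts of 50
subjects/group. Larger runs change none of the qualitative conclusions.

## Known limitations

* No inter-trial variability parameters (sv, sz, st) and no regression
  links beyond factor cells in the DDM.
* Satterthwaite/Kenward-Roger df are unavailable; small-sample fixed-effect
  p-values are mildly anticonservative in principle (immaterial at the
  design sizes used here, as the calibration tests document).
* The titration estimate is quantized (R/64), so SV residuals are discrete;
  the mixed model treats them as Gaussian.
* Heteroscedasticity of titration noise across cells with very different
  true SV is real and intentional in non-null cohorts; the pooled-variance
  mixed model is then an approximation, exactly as it is for real data.
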
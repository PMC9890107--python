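# Methods

## Models

Every analysis concerns the probability *p* of a correct guess on an
erotic trial.  Two models are contrasted:

* **M0** — the point null, p = 0.5 on every trial;
* **M1** — above-chance guessing, p ∈ (0.5, 1), with a prior density on p.

The hypotheses are one-sided by construction (the phenomenon, if real, is
claimed to raise the success rate), so all M1 priors are beta densities
truncated at 0.5 and renormalized on (0.5, 1):

| label       | Beta(a, b) | rationale                                           |
|-------------|-----------|------------------------------------------------------|
| uniform     | (1, 1)    | flat on (0.5, 1)                                     |
| buj         | (7, 7)    | knowledge-based: ~90% of truncated mass below the probability equivalent of d = 0.5 |
| replication | (829, 733)| posterior implied by the seeding study's 828 successes / 732 failures |

The effect-size conversion is logistic–normal variance matching:
log-odds = d·π/√3, p = logit⁻¹(log-odds), so d = 0.5 ↦ p = 0.7124.  Note a
deliberate imprecision inherited from the design: the constant 0.712 is
this conversion rounded to 3 d.p., while the exact 90th percentile of the
truncated Beta(7, 7) is 0.71295; the two agree to ~1.4 × 10⁻³ and the
package computes each exactly rather than forcing them equal.

## The four simultaneous tests and the stopping rule

At each preregistered analysis point (cumulative erotic trials
37 836, 62 388, 86 958, 111 528, 136 080):

1. **Mixed-model CI.**  An intercept-only random-intercept logistic
   regression is fit by maximum marginal likelihood; the Wald CI for
   β₀ is mapped through logit⁻¹.  The confidence level for look ℓ is
   1 − α/(2ℓ) with α = 0.005 (two CI-based decisions per look, Bonferroni
   across looks): 99.75, 99.875, 99.91667, 99.9375%.  The design lists
   four levels for five looks; the same formula extends to 99.95% at
   look 5.  Decision rule: CI_ub < 0.51 (the SESOI) → M0; else
   CI_lb > 0.50 → M1; else inconclusive.
2. **–4. Bayes factors.**  BF01 of the pooled counts under each truncated
   prior.  With a truncated Beta(a, b) prior the M1 marginal likelihood is
   closed-form: B(k+a, n−k+b)·(1 − I₀.₅(k+a, n−k+b)) / [B(a, b)·(1 − I₀.₅(a, b))],
   with I the regularized incomplete beta; everything is evaluated in log
   space (shapes up to ~10³ and n up to ~10⁵ need stable differencing; the
   complement betaincc is used for the upper tails).  BF01(0, 0) ≡ 1 by
   convention.  BF01 > 25 → M0; BF01 < 1/25 → M1; else inconclusive.

The study stops at the first look where **all four verdicts are decisive
and identical**; exhausting all looks without unanimity yields an
inconclusive study.  Pooling all trials for the BF tests makes them immune
to premature-stopping strategies by participants; the mixed model instead
accounts for within-participant dependence — the conjunction inherits both
protections.

## Mixed-model fitting

The marginal likelihood factorizes over participants and depends on each
only through (successes_i, trials_i), so identical patterns are collapsed
(at most 19 patterns when all sessions complete).  Each pattern's integral
over the random intercept uses adaptive Gauss–Hermite quadrature with 21
nodes: the integrand is centred at its mode (per-pattern Newton iteration)
and scaled by the curvature there.  21 nodes reproduce an adaptive-quadrature
oracle to ~10⁻⁸ across the (β₀, τ) plane, including τ → 0.

Optimization is L-BFGS-B over (β₀, τ) with τ ≥ 0, started from the
fixed-effects solution, with a Nelder–Mead polish if the line search
stalls (the profile in τ is nearly flat near the boundary under null
data).  The τ = 0 boundary is handled by profile comparison against the
closed-form binomial fit.  The SE of β₀ is the (β₀, β₀) entry of the
inverse observed information (central-difference Hessian of the marginal
log-likelihood); when the τ direction is numerically singular (optimum
hugging the boundary) the β₀-only information is used, which coincides
with the binomial information in that regime.  Complete separation
(k = 0 or k = n) is flagged as unconverged rather than reported.

## Robustness and exploratory analyses

* **Proportion tests** — one-sided exact binomial tails at α = 0.005:
  first H0: p ≥ 0.51 (rejection → M0), then H0: p ≤ 0.50 (rejection → M1).
  Exact tails were chosen over the normal approximation for
  reproducibility; the approximation is available behind a flag.
* **Parameter estimation** — conjugate update of the *untruncated*
  Beta(829, 733) prior (the registered update rule adds counts to the
  plain shapes; only the BF priors are truncated), summarized by the mode,
  the shortest 90% HDI (found by minimizing interval width over the lower
  tail mass; mass accurate to ~10⁻⁸ and endpoint densities equal by
  construction), and the ROPE rule on [0, 0.506] at 95% mass.
* **Rate distribution** — per-participant success rates of complete
  (18-trial) participants vs a simulated reference of 10⁶ Binomial(18, 0.5)/18
  draws; distance is the Wasserstein-1 metric on the raw samples (CDF
  difference integral, not binned histograms — binning would add an
  arbitrary choice).
* **Split-half** — Pearson correlation of odd- vs even-trial success
  rates, odd/even indexed by within-participant erotic-trial order
  (1-based), with a 95% Fisher-z interval.

## Synthetic stream generator

The generator emulates the deposited study stream: 36-trial sessions with
exactly 18 erotic trials at random (without-replacement) positions;
guessed side Bernoulli with a 49.08% left-choice rate; per-trial success
drawn from the participant's true chance and the target side derived from
(guess, success) — equivalent to the protocol's draw-target-after-guess
under any p, and it keeps the truth model explicit.  Non-erotic successes
are drawn at 0.5.  Pre-trial dropout (4.17%) removes a recruit before any
rows; mid-session termination (1.18%) truncates a session at a uniform
random trial.  Deposit order is the global row index; timestamps are
opaque random tokens (the real stream hashes them).  Defaults reproduce
the observed operational rates of the study this design comes from.

What the generator does *not* emulate: lab-level clustering of abilities,
nonstationarity over the collection period, software outages, and any
dependence between consecutive trials.  Tests passing on synthetic
streams therefore validate the decision machinery and its calibration,
not the absence of such artefacts in real data.

## Design simulation

Operating characteristics are estimated by simulating complete studies.
Truth models: fixed p; one shared Beta(829, 733) draw per experiment;
heterogeneous per-participant chances clip(p + N(0, 0.15)) (clipping mass
~5 × 10⁻⁴, negligible but deterministic); and a two-point sheep-goat
mixture.  The fast path draws each participant's success count directly
as Binomial(18, p_i) and maintains collapsed patterns, so a full
five-look study needs no row-level data; equivalence with the row-level
pipeline is asserted in the tests.  At a look, the mixed model is only
fit when the three BF verdicts are already unanimous and decisive —
otherwise the conjunction continues regardless of the CI verdict, so the
short-circuit is decision-equivalent and saves most of the runtime.

Each (scenario, replicate) pair gets an independent RNG substream spawned
from the plan seed, making scenario tables reproducible and replicates
independently re-runnable.  Replicate counts used by the test suite and
the acceptance script (200–300 per power scenario, 20 000 for the null
false-positive rate) are sized so that every registered claim is resolved
within ±3 Monte-Carlo standard errors on one CPU in minutes; the original
calibration used 5 000–10 000 replicates per scenario, and the same code
reproduces those tables when asked.

## Numerical choices and edge cases

* BF01 may overflow to +∞ when the M1 marginal underflows (success rates
  far below chance at large n); the verdict is then M0, which is the
  correct direction of the evidence.
* Thresholds are strict inequalities: BF01 exactly 25 or 1/25 is
  inconclusive, mirroring the registered wording ("higher than").
* Truncation at an analysis point cuts strictly after the Nth retained
  erotic trial in deposit order, so in-progress sessions contribute
  partial data; invalid rows on read are excluded and counted with row
  numbers, never repaired.
* The empty table yields (k, n) = (0, 0) and BF01 = 1.

## Known limitations

* The mixed model is intercept-only by design; no covariates or crossed
  random effects (lab, experimenter) are supported.
* The HDI routine requires an interior mode (both posterior shapes > 1);
  boundary-modal betas are out of scope.
* The exploratory EMD is reported on raw rate samples only; with real
  data a binned-histogram variant could differ in the third decimal.
* The generator's lab/experimenter assignment is uniform; real
  participant-per-lab distributions are configurable but not calibrated.
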
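# Methods

## Task and design model

The simulated experiment is a two-interval forced-choice (2IFC) tactile
motion-direction task on the palm. Three axis conditions (vertical 0–180°,
horizontal 90–270°, oblique 45–225°) are run in blocked order; condition
orders cycle through all six permutations of the three conditions, shuffled
once per cohort seed, so counts differ by at most one for any cohort size.
Each condition comprises five 40-trial blocks: four repetitions of each of
ten stimulus durations, log-spaced from 200 ms to 8 s, shuffled within
block; correct intervals are balanced within block to ⌈n/2⌉ / ⌊n/2⌋.
Duration values are kept at full floating precision — the pure log grid
gives 684.0 and 2339.4 ms where rounded display values of roughly 680 and
2430 ms are sometimes quoted for this kind of grid; no rounding rule is
imposed. Dot start configurations s_n are a pure function of
(seed, participant, trial index within condition), never of condition, so
the three conditions see byte-identical start points at matched trial
indices. A crash top-up rule marks lost trials and appends replacements
(same condition, durations redrawn to restore per-duration balance) so each
condition keeps at least 200 completed trials. Training blocks (six
one-second feedback trials per condition) can be generated but are dropped
by the exclusion stage before any analysis.

## Stimulus simulation

Six 8.5 mm dots move coherently at 4 cm/s inside a square palm region
(default 8 × 8 cm; the proximal–distal extent equals the medial–lateral
width). Coordinates are cm from the ulnar–proximal corner; directions are
degrees from the +y (distal) axis. The update rate is a parameter (default
100 Hz — the dot-pattern update rate of the hardware is not modelled, so
this is a simulation resolution choice; all invariants are
frame-rate-independent). A trajectory spans the full duration: k =
⌈duration · rate⌉ steps, k + 1 stored frames. A dot "extends beyond" the
region when any part of its disc crosses the boundary (centre within one
radius of an edge); such dots are relocated by rejection sampling (cap 10⁴
tries) to a uniform position whose disc is inside the region and whose
centre is at least one dot diameter from every other dot's centre — the
overlap metric throughout is centre distance < diameter. Each dot owns an
independent random substream for respawns, so one dot's relocations never
perturb another's trajectory. The motion summarizer reports the median
per-step displacement × rate (respawn steps excluded) as empirical speed
and the circular mean of step angles as direction.

## Synthetic observers

No observer model is fitted anywhere in the analysis, so the generator is a
deliberately minimal stand-in whose job is to realize chosen accuracies,
AROCs and confidence profiles:

* **Accuracy** — Bernoulli per trial with per-condition probability p_c,
  duration-independent by default (a slope switch exists for power
  studies). Population defaults: p_vertical = p_horizontal = 0.63,
  p_oblique = 0.56, logit-normal heterogeneity (between-subject SD 0.40,
  condition jitter 0.12), truncated below at chance — the generator never
  produces below-chance observers; the `mapping-flip` injection mode covers
  that pathology explicitly. Truncation makes the realized population mean
  sit slightly above the nominal p values (combined mean ≈ 61%).
* **Confidence** — a two-distribution ordinal model: latent
  = drive·w(d) + (±m/2) + N(0, 1), cut at four fixed thresholds
  (−0.9, −0.1, 0.7, 1.5) into ratings 1–5. m is the metacognitive
  separation (evidence mean is +m/2 on correct trials, −m/2 on incorrect);
  w(d) is a positive inverted-U multiplier over the duration grid (Gaussian
  bump in log duration peaking at ≈1.3 s, range 0.55–1.45), so mean
  confidence is highest at intermediate durations and lowest at the 200 ms
  and 8 s extremes while AROC stays duration-independent (the drive shifts
  correct and incorrect trials equally). The mapping m ↔ expected AROC is
  available in closed form (`expected_aroc`: exact rating pmfs via the
  normal CDF, tie-aware rank probability over the pooled duration mixture)
  and is inverted by bracketed root finding to hit each observer's AROC
  target, drawn N(0.57, 0.10) and censored at chance (m ≥ 0). Censoring
  lifts the realized group-mean AROC to ≈0.58.
* **Covariates** — age (normal 24.2 ± 5, clipped 19–40), hand and finger
  size (palm size = hand − finger), baseline hand (≈30.5 °C) and body
  (≈36.6 °C) temperatures with per-block jitter. All covariates are drawn
  independently of performance, so the covariate batteries should favour
  the null on generated data.

What the generator does **not** emulate: learning or fatigue across blocks,
below-chance responders (except via injection), lapses correlated with
duration, serial dependence between trials, and any physical link between
palm size or temperature and sensitivity. Passing tests therefore show the
*analysis machinery* behaves correctly under the assumed structure, not
that real palms behave this way.

## Bayesian battery

* **One-sample / paired t-tests** — JZS form: Cauchy(0, r) prior on the
  standardized effect, r = √2/2 by default; BF₁₀ computed by adaptive
  quadrature of the noncentral-t likelihood over the prior. Directional
  tests ('greater' for the above-chance tests) renormalize the prior to the
  half-line. Zero-variance input is an error (t undefined).
* **Correlations** — uniform prior on ρ over (−1, 1); BF₁₀ integrates the
  exact sampling density of Pearson r (hypergeometric form). |r| = 1 yields
  an infinite BF₁₀ by construction and is reported as such.
* **RM ANOVA** — fixed effects coded with orthonormal sum-to-zero
  contrasts; each factor block shares one g with prior
  InverseGamma(1/2, h²/2) (Cauchy-inducing), h = 0.5 for fixed effects.
  Subject effects default to their own g block (h = 1.0), the convention of
  the JASP/BayesFactor lineage; a `flat` treatment sweeps subject means out
  exactly, and under it a two-level single-factor design reduces *exactly*
  to the JZS paired t-test with the same scale (verified algebraically and
  by test). Conditional on g the marginal-likelihood ratio to the null is
  closed-form; the g integral is averaged by plain Monte Carlo, 10,000
  iterations by default, with the relative MC standard error reported on
  every result. The model space is {null, each admissible main-effect
  combination, + interaction}, interaction admitted only on top of both
  main effects (marginality); inclusion BFs use equal prior model
  probabilities. Subjects with any missing cell (e.g. degenerate AROC
  cells) are dropped for that ANOVA and the count reported.
* **Sequential BFs** — recompute the effect's inclusion BF on the first
  n participants for n = 2..N; the threshold rule is BF ≥ 6 or ≤ 1/6 at or
  after n = 12. The run at n uses the derived seed (seed, n), making each
  point independently reproducible. The pipeline's recruitment curve uses
  the one-way participant × condition table rather than the full 3 × 10
  ANOVA at every n — the factor being monitored is condition, the collapsed
  test tracks the same effect, and it keeps the 41-fold recomputation
  cheap; `bayes.sequential_bf` accepts any factor structure if the full
  model is wanted.
* **Verdict bands** — BF₁₀ > 3 "evidence for", < 1/3 "evidence against",
  otherwise indeterminate, applied uniformly in reports.

## Metacognition

`type2_aroc` sweeps criteria k = 2..5 (the scale bound is a parameter),
plots type-II hit rate P(conf ≥ k | correct) against type-II false-alarm
rate P(conf ≥ k | incorrect), adds the (0,0) and (1,1) endpoints and takes
the trapezoidal area. This makes ties at a criterion worth half credit, so
the estimator equals the tie-aware Mann–Whitney probability that a random
correct trial out-rates a random incorrect one — the property the test
suite checks against a brute-force pair-counting oracle. Cells with no
errors or no correct responses have no defined AROC and are reported as
missing, never imputed at 0.5 (imputation would bias the group ANOVA toward
chance); downstream stages apply participant-wise deletion.

## Pipeline choices

* Exclusion threshold: modal response share > 0.90 ("almost exclusively
  one key" is not quantified in the protocol; 0.90 is configurable).
* "Combined" is the trial-weighted pool of all conditions, not the mean of
  condition means.
* Within-subject error bars: subject-centred (Cousineau) normalization with
  the Morey k/(k−1) bias correction.
* Duration post-hocs on confidence cover all 45 unordered pairs of the ten
  levels; an explicit pair list can restrict reporting (a 35-pair scheme is
  sometimes quoted for such grids without a stated rule, so none is
  hard-coded).
* Battery cardinalities on complete inputs: 24 between-subject
  correlations, 12 order ANOVAs, 36 within-subject coefficients per
  participant — enforced by tests.

## Numerical and testing notes

Quadratures split integration ranges at prior discontinuities and likelihood
modes. The MC marginal-likelihood averages are computed in log space
(shifted exponentials) to avoid overflow at extreme Bayes factors. All
simulation entry points take explicit seeds and spawn child streams, so
every result in a report is reproducible byte-for-byte from (config, seed),
timestamps excluded.

Test problem sizes are chosen to keep the default suite fast while leaving
the statistics meaningful: the ANOVA calibration suites use 100 seeded
cohorts (n = 20 null / n = 42 oblique-deficit) at 800 MC iterations — MC
error at 800 iterations is far smaller than the decision bands being
checked — and the quadrature-oracle suites compare ~50 random datasets per
statistic against dense-grid integration. The acceptance script runs the
full 42-participant × 600-trial chance-level simulation, a 100,000-trial
AROC independence check, and a 1 s trajectory summary.

## Known limitations

* The RM ANOVA's g-prior Monte Carlo is simple averaging, not importance
  sampling; for very extreme effects the reported MC error on the winning
  model grows, though inclusion verdicts are stable (dispersion across
  seeds is tested against the reported error).
* The inclusion-BF model space covers one- and two-factor within-subject
  designs; higher-order designs are out of scope.
* No likelihood-based metacognitive efficiency (meta-d′) — the AROC is the
  study's measure and the only one implemented.
* The synthetic generator's parameters are study-condition defaults, not
  fits to any dataset.
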
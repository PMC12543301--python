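# Methods

## Task model

A participant experiences, per session, four interleaved conditions — the
crossing of Agent (Self / Other) and Ability (High / Low) — each bound to one
of four estimation categories (heights, weights, quantities, distances) and
comprising 20 trials.  Categories rotate through the condition cells in a
Latin-square cycle across participants, so every category serves every cell
equally often.

Feedback on trial *t* of a category is

    FB_t = clip(ref_t + m_t, 0, 100),

where `ref_t` is the mean of the participant's last five expectation ratings
in that category (50 before the first rating) and `m_t` is a predefined
signed modifier.  High-ability cells carry 14 positive and 6 negative
modifiers; low-ability cells the reverse.  Modifier magnitudes are the
multiset {5, 8, 11, 14, 17, 20, 23, 26} cycled to 20 values and shuffled per
cell, a spread chosen to cover small through large prediction errors without
saturating the percentile scale; magnitudes are configurable.  Within a cell
the sign order is seeded-random subject to the constraint (switchable off)
that the first two trials are not both incongruent with the cell's majority
valence, avoiding degenerate early reversals.  Feedback values are kept
continuous internally; rounding is a presentation concern.  Clipping events
are recorded on the trial.

At the second session every category keeps its cell assignment but flips its
ability label, implemented by negating the session-one modifier sequence:
prediction errors preserve their magnitudes and flip valence, which is the
design's definition of the reversal.  Double reversal is the identity.

The per-trial accuracy incentive is linear: 6 cents at zero expectation
error, falling to 0 at an error of 100 points.

## Learning models

All learning models share the delta rule `EXP[t+1] = EXP[t] + α·PE[t]` with
`PE[t] = FB[t] − EXP[t]` and differ in how α is partitioned: by agent only
(M1), agent × ability (M2), agent × PE valence (M3), the same three
partitions with separate rates per session (M4–M6), the extended valence
model (M7), agent × PE congruency per session (M8), and a no-learning mean
model (M9).  M7 adds a per-session weight w that discounts updates from
extreme feedback through the relative normal density
`ND(FB) = exp(−(FB − 50)² / (2σ_ND²))`, normalized to 1 at mid-scale.

Decisions where the design was genuinely open:

* **σ_ND = 17** (fixed, configurable).  The discounting curve's scale is not
  a free parameter — only w is fitted per session — and 17 ≈ scale/6 puts the
  density near zero at the extremes of the percentile scale.
* **Starting values.**  Every learning model carries 8 SVs (session × agent ×
  ability), the trial-1 predictions, as free parameters; M9 instead has one
  free mean per condition (8) and no learning rates.  Using the same SV
  structure across the space keeps the model comparison about the learning
  rule rather than about initial-condition flexibility.
* **Observation model.**  Ratings are noisy readouts of the latent
  expectation: a normal truncated to [0, 100], centred on the model's
  prediction, with a single free σ per participant shared across sessions and
  cells — the simplest observation model consistent with a bounded scale.
  The first trial of each cell is scored against the SV.
* **Latent recursion.**  The fitted trajectory is driven by observed feedback
  only (`PE_t = FB_t − latent EXP_t`); observed ratings enter through the
  likelihood, not the state.  This makes simulation and fitting use the
  identical recursion.
* **M8 congruency.**  A PE is congruent when its valence matches the cell's
  majority (positive in High, negative in Low, under the current session's
  labels).  Congruency replaces valence in the α index (session × agent ×
  congruency); within a cell the two factorizations are confounded, so the
  crossed variant is not separately identifiable from these designs.
* **PE = 0** is a no-op; it cannot arise from nonzero modifiers except
  through clipping, and such trials are classified by modifier sign for
  contingency bookkeeping.

Nesting: M7 with w = 0 reproduces M6; M6 with equal session rates reproduces
M3; M3 with equal valence rates reproduces M1.  These identities hold exactly
in the trajectory code and are asserted to machine precision in the tests.

## Inference

Per participant and model, the posterior over parameters (α, w ∈ [0, 1],
SV ∈ [0, 100] uniform; σ half-normal with scale 20) is explored two ways:

* **MCMC (canonical).**  Affine-invariant ensemble sampling with a vectorized
  likelihood; defaults mirror the study's bookkeeping — three chains' worth
  of 2400 kept draws after 1000 burn-in steps with thinning 3 — and the kept
  draw count is honoured exactly.  R-hat and effective sample size come from
  arviz; any parameter with R-hat > 1.05 flags the fit (the threshold is our
  operationalization of "convergence was inspected").
* **MAP + importance-corrected Laplace (fast).**  Multi-start L-BFGS-B on the
  log posterior (gradients by batched finite differences), a batched
  central-difference Hessian, then draws from an inflated multivariate-t
  (df = 4) proposal that are importance-resampled toward the true posterior.
  If the importance effective sample size collapses (< 8% of the requested
  draws), the draws are regenerated by a short MAP-initialized MCMC run.
  This route is deterministic given the seed and is used for the recovery
  experiments; it is an approximation, clearly labelled in the summaries
  (`method="map_laplace"`).

Posterior means summarize each parameter for downstream analyses (one value
per parameter and participant).

## Model comparison

Per-trial out-of-sample log densities are estimated by PSIS-LOO on the
pointwise log-likelihood matrix (draws × trials); the smoothing of the upper
20% tail of the importance ratios and the generalized-Pareto k̂ follow the
canonical recipe (arviz implementation).  k̂ > 0.7 marks unreliable trials;
the fraction is reported.  An exact-refit LOO on a conjugate normal-mean toy
bounds the approximation error in the tests (< 0.05 nats/trial).

Population-level selection uses random-effects BMS: participant-wise model
attributions and a Dirichlet posterior over model frequencies (prior α₀ = 1
per model) are updated variationally until the free energy changes by less
than 1e−6.  Exceedance probabilities are integrated by 10⁵ seeded Dirichlet
Monte-Carlo draws.  The Bayesian omnibus risk compares the fitted model's
free energy against the null model of fixed equal frequencies,
`BOR = 1/(1 + exp(F1 − F0))`, and protects the exceedance probabilities:
`pxp = (1 − BOR)·xp + BOR/K`.  With identical evidence columns this yields
pxp = 1/K and BOR ≈ 0.73–0.95 depending on cohort size (the null's free
energy advantage is a fixed complexity term, so BOR does not tend to exactly
1).  LOO totals enter BMS as log-evidence proxies without rescaling;
session-specific selection uses each session's trial subset of the jointly
fitted models.

## Synthetic cohorts

The generator closes the loop between a model agent and the task engine:
latent expectations start at the SVs, update by the generating model's rule,
and are read out with truncated-normal observation noise; feedback follows
the adaptive rule applied to the reported (noisy) ratings.  T2 starting
values carry over the end-of-T1 latent belief of each category into its
relabelled cell (clipped to [1, 99]), matching the empirical observation that
session-two expectations begin where session one ended.

Two regimes:

* **uniform** — every learning rate is drawn i.i.d. uniform [0.05, 0.6],
  w uniform [0.2, 0.8], T1 SVs uniform [10, 90], σ fixed (8 by default).
  This is the regime for parameter- and model-recovery experiments.
* **structured** (the paper-like preset) — truncated-normal populations with
  a mean learning-rate level of 0.40 (SD 0.10), a self-negativity asymmetry
  (mean α_self,PE− − α_self,PE+ = 0.11) and an other-positivity asymmetry
  (−0.09), giving mean T1 valence bias scores of about −0.13 (Self) and
  +0.13 (Other) with SD ≈ 0.26; T2 rates are the T1 rates times a
  participant-specific suppression factor (mean 0.5, SD 0.18); a shared
  latent factor induces a correlation of 0.45 between self starting values
  and the self bias score, chosen so that the correlation surviving
  estimation attenuation is near the empirically plausible ~0.2–0.3;
  confidence rises by ~11 points over T1 (plus an extra self-related gain),
  decays slightly at T2, couples positively to T1 learning rates, and —
  through the suppression factor — negatively to T2 learning rates.

What the generator does **not** emulate: actual estimation answers and their
difficulty, reaction times, session-spacing effects, questionnaire measures,
any confidence-weighted learning inside the generating models (confidence is
descriptive, a measured covariate), and the idiosyncratic modifier sequences
of the original experiment (magnitudes are stand-ins; the real sequences are
not published).  Passing recovery tests therefore demonstrates that the
estimator identifies parameters and models *under the stated observation
model and design*, not that real participants satisfy those assumptions.

## Validation experiments and problem sizes

* Parameter recovery: 30 uniform-regime M7 participants, σ = 8; Spearman
  rank correlation between generating and recovered values per learning-rate
  index, and mean absolute SV error.  Thirty participants give stable rank
  correlations while keeping a full experiment in the tens of seconds.
* Model recovery: cohorts of 30 from M1, M3, and M7, each fitted with all
  three candidates; the highest-pxp model must be the generating one or a
  model that can exactly mimic it at the generating parameter regime.
* Directional reproduction: a 60-participant preset cohort fitted with M7
  (plus M1/M3/M9 for per-session selection); checks are sign-level — the
  mean fitted T1 self bias negative, other bias positive, T2 learning rates
  below T1, and a positive initial-expectation × self-bias correlation —
  because effect magnitudes are attenuated by estimation noise in a way that
  depends on cohort size.  Sixty participants keep the sign tests'
  wrong-sign probability at the percent level.

## Numerical notes and limitations

* The truncated-normal log density uses a tail-reflected `log(Φ(b) − Φ(a))`
  for stability far from the interval.
* The likelihood recursion is vectorized across condition cells and batched
  parameter vectors; a per-cell scalar path covers unequal cell lengths and
  serves as its oracle in tests.
* MAP multi-starts: one data-driven start (SV = first ratings, α = 0.3,
  σ from first-difference variance) plus seeded uniform restarts; four starts
  by default.
* w is weakly identified in 20-trial cells (it only matters on extreme
  feedback); its recovery is not asserted, and the importance correction plus
  MCMC fallback exist largely because of this flat direction.
* Group-level (hierarchical) priors are deliberately absent: participants
  are fitted individually, matching the analysis this package implements.
* With a single session or constant ratings the fit proceeds but is flagged
  (`single_session`, `degenerate_constant_ratings`).
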
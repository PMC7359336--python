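# Methods

This note documents the models and procedures implemented in `magclass`,
the defaults chosen where the design was genuinely open, and what the
synthetic generator does and does not emulate.

## Task and generative model

The magnitude-classification task presents one digit d ∈ {1,2,3,4,6,7,8,9}
per trial; the participant presses a left or right key for "smaller/larger
than 5". The design has two blocks of 240 trials with reversed response-key
assignment; each digit appears 30 times per block; trial order is random
subject to no digit appearing more than twice in a row; responses are
censored at 2,000 ms. Block order (which mapping comes first) is
counterbalanced by alternating across consecutive participants.

Each simulated participant i has parameters drawn from population
distributions:

    RT = a_i + bD_i · |d − 5| + bM_i · d + s · bS_i · (d − 5) + ε,
    ε ~ Normal(μ, σ) + Exponential(τ)   (ex-Gaussian trial noise)

where s = +½ for right-hand and −½ for left-hand responses. The ±½ coding
makes the generative SNARC parameter bS land on the same scale as the
measured one: the right-minus-left RT difference per digit is
dRT(d) = bS · (d − 5), so the fitted dRT-on-magnitude slope recovers bS
directly.

Errors occur with probability `error_base · exp(−error_distance_decay ·
distance)` — a one-parameter monotone model of the accuracy distance
effect. Timeouts (RT ≥ ceiling) are recorded as incorrect with missing RT,
since a non-response cannot enter RT analyses. Anticipation contaminants
(rate `anticipation_rate`) get RT ~ U(80, 200) ms, a random response side,
and are correct with probability 0.5, so that they are removable purely by
the < 200 ms screen.

### Default parameters (the emulated study conditions)

| parameter | default | unit | rationale |
|---|---|---|---|
| n_per_group | M 13, E 14, S 15, R 56 | participants | post-exclusion cohort sizes of the emulated study |
| intercept | N(455, 70) | ms | yields grand mean RT ≈ 500 ms |
| bD (distance slope) | N(−13, 8) | ms/unit | reported group mean (SD) of the distance effect |
| bM (size slope) | N(1.2, 3.2) | ms/unit | reported group mean (SD) of the size effect |
| bS (SNARC slope) | N(0, 0) | ms/unit | disabled by default; the emulated study's SNARC values are not in its main text. Tests configure it explicitly |
| noise (μ, σ, τ) | (0, 50, 75) | ms | ex-Gaussian SD √(σ²+τ²) ≈ 90 ms, the reported intraindividual RT SD, with the right-skew typical of RT data |
| error_base, decay | 0.07, 0.35 | —, /unit | average error rate ≈ 3%, matching 96.9% accuracy |
| anticipation_rate | 0.0005 | — | 0.05% of trials, as reported |
| rt_ceiling_ms | 2000 | ms | response deadline of the paradigm |

The constrained shuffler draws each next digit among those that would not
create a run longer than 2, weighted by remaining counts, restarting on the
(rare) dead end; a bounded number of restarts turns infeasible multisets
into an error.

## Preprocessing

Per participant, in order: (1) exclusion when the overall error rate is
≥ 0.40 — the threshold separates instruction-confused performers (~50%
errors, one response mapping applied to both blocks) from ordinary poor
performers, and is configurable; (2) error trials (incorrect or missing RT)
removed; (3) correct trials with RT < 200 ms removed as anticipations
(strictly below, so a 200 ms trial survives); (4) sequential ±3 SD
trimming: RTs outside mean ± 3 SD of the participant's remaining correct
RTs are removed and mean/SD recomputed until no further removal
(`single_pass` does one round). Participants with fewer than 3 RTs are left
untrimmed (SD degenerate). Accuracy summaries use the variance-stabilising
transform 2·arcsin(√p).

The report keeps the exact identity `retained + anticipations + trimmed +
errors = total` per participant. The retention proportion divides retained
trials by *all* experimental trials of non-excluded participants — errors,
anticipations and trimmed trials all count as lost. This denominator choice
is an interpretation (the alternative excludes error trials); it is the one
that bridges an overall accuracy near 97% to a low-90s retention figure.

**Trimming attenuates slopes slightly.** The ±3 SD band is computed on the
participant's pooled RTs, while digit means differ by up to ~40 ms; slower
digits therefore lose more of their right tail, shrinking slope magnitudes
by roughly 5–10% under the default noise model. This is a property of the
procedure itself, not of the implementation; parameter-recovery tests
therefore run on untrimmed correct trials, and analyses of trimmed data
should expect mildly conservative slopes.

## Slope estimation

Digit-level mean RTs (8 points) are regressed on D = |d − 5| and M = d by
OLS. Because ΣD_c·M_c = 0 over the digit set, each slope equals its
simple-regression counterpart; the tests assert this identity at 1e-10
against an independent normal-equations solve. Degenerate inputs (all means
equal) return zero slopes with R² = 0. Cells with fewer than `min_cell`
(default 5) retained trials are flagged: an 8-point regression with
near-empty cells is not interpretable.

The ratio effect uses r(d) = min(d, 5)/max(d, 5) ∈ (0, 1], the dominant
convention (the alternative max/min only flips the slope sign). The SNARC
slope regresses dRT(d) = mean RT(right) − mean RT(left) on d, pooling both
blocks: within a block every digit is answered with exactly one hand, so
the right/left contrast for a digit exists only across the two
reversed-mapping blocks. Standardized slopes refit after z-scoring the
means and predictors; with orthogonal predictors they equal the Pearson
correlations r(RT, D) and r(RT, M).

## H0 bootstrap and prevalence

The resampling pool is the participant's retained correct RTs pooled over
digits and blocks — pooling is what destroys the digit–RT association the
null asserts. Per iteration, 8 sets of `set_size` = 60 RTs (30 per digit ×
2 blocks) are drawn with replacement, assigned to the digits, averaged, and
fed to the same distance+size regression; 5,000 iterations by default. The
90% CI uses linear interpolation between order statistics (the type-7
percentile definition, the default of the R environment the procedure
originates from, so exact replication against existing scripts is
possible). A slope exactly on a bound counts as inside ("outside" is read
strictly). Classification: outside the CI in the typical direction
(negative for distance, positive for size) → *reliable typical*; outside in
the other direction → *reliable reverse*; otherwise *not reliable*.

Each participant gets an independent RNG stream seeded by (master seed,
SHA-256 of the participant id), so results are independent of cohort
ordering and parallelisation. Calibration: on 500 simulated null
participants (both slopes 0, realistic noise, 1,000 iterations) the
fraction labelled reliable in either direction is ≈ 10% at a 90% CI, split
≈ 5/5 between the two directions.

Prevalence tables report counts and integer-rounded percentages per group
and overall, for each label.

## Split-half reliability

Each random split partitions every participant × digit × block cell into
two halves (stratified, so each half preserves the design; unstratified
splits would bias the 8-point regression). Slopes are fitted per half,
correlated across participants, the correlation averaged over `n_splits`
splits on the raw r scale, and Spearman–Brown corrected (2r/(1+r)).
Averaging on the raw scale (rather than Fisher-z) is the default; at the
reliabilities this task produces (r ≈ 0.7–0.9 with hundreds of splits) the
difference is far below the Monte-Carlo error. Single-trial cells are
assigned to a random half by default (`singleton_policy="exclude"` drops
them). The split count used by the original analyses is not published;
defaults here are documented, not claimed identical.

Attenuation correction divides an observed correlation by √(rel_x·rel_y),
clipping to [−1, 1] with a warning. Partial correlation uses the standard
first-order formula with a t-based p-value on n − 3 df; tests verify it
against residual-regression and pingouin oracles.

## Group statistics

* **t-tests**: one-sample, one-sided toward the typical direction (negative
  for distance, positive for size); d = mean/SD, so d = t/√n exactly. A
  summary-statistics form (mean, SD, n) supports re-deriving printed test
  statistics from reported descriptives.
* **ANOVA**: one-way fixed effects; η²_p = SS_b/(SS_b+SS_w).
* **JZS t-test BF**: BF10 = ∫ f_nct(t; ν, δ√n) π(δ) dδ / f_t(t; ν) with
  π = Cauchy(0, √2/2). The integral is computed after the substitution
  δ = r·tan θ, which maps the Cauchy prior to a uniform density on
  (−π/2, π/2) and removes the heavy tail; adaptive quadrature converges to
  1e-6 relative tolerance or raises. One-sided (order-restricted) variants
  truncate the prior to the predicted half-line; the two-sided BF is the
  mean of the two one-sided BFs by construction. Verified against a
  10⁶-point brute-force trapezoid at 1e-4 relative tolerance and against
  pingouin's two-sided implementation.
* **JZS ANOVA BF**: y = μ1 + Zθ + ε with θ ~ N(0, g σ² I) on an orthonormal
  sum-to-zero projection Z of the group indicators, Jeffreys prior on
  (μ, σ²), and g ~ InverseGamma(½, rscale²/2) with rscale = 0.5 (the
  "medium" fixed-effects default of the reference R implementation). After
  integrating μ, σ² and θ analytically, BF10 is a 1-D integral over g,
  evaluated with the Woodbury identity on the (k−1)-dimensional inner
  matrices. This is an independent re-implementation of the default-prior
  one-way ANOVA BF and is expected to agree with the reference
  implementation to a few percent, not to machine precision. Because the
  original analysis environment's exact prior options are not published,
  only approximate agreement with printed BFs is claimed.
* **Fisher r×c**: exact p = Σ P(T) over all margin-fixed tables with
  P(T) ≤ P(observed)·(1 + 1e-12) (ties included, the standard convention),
  with P the multivariate hypergeometric mass computed via log-Γ.
  Enumeration is depth-first over rows with margin pruning (the last row
  and last cell of each row are determined); above a configurable
  feasible-table budget it falls back, with a warning, to conditional Monte
  Carlo (random permutations of the column-label vector), reporting p̂ and
  its binomial SE. The enumerator reproduces scipy's 2×2 p-values at 1e-10
  and R `fisher.test` values on 4×2 and 4×3 prevalence tables.

## What the generator does not emulate

Passing tests on synthetic data demonstrate that the pipeline's estimators
and classifiers recover known ground truth under the stated noise model.
Real data differ in ways the generator deliberately omits: sequential
dependencies (post-error slowing, priming), speed–accuracy trade-offs,
practice and fatigue drifts within a block, response-side error asymmetries,
and any relation between a participant's speed and their slopes. Accuracy
is modelled only through the distance-dependent error rate; error RTs
follow the same RT model as correct ones. Claims about real data therefore
rest on the procedures, not on the simulation.

## Problem sizes in the test suite

Unit and property tests run on cohorts of 6–98 participants; calibration
tests use 500 null participants × 1,000 bootstrap iterations and 200
participants for recovery; the full-scale bootstrap (98 × 5,000) runs in
the acceptance script. These sizes give Monte-Carlo error well inside the
asserted tolerances while keeping the default test run around a minute.

## Known limitations

* The recursive trimming attenuation described above.
* Reliability of the size effect in synthetic cohorts tends to be higher
  than in real data, because the generator's between-participant slope
  variance is exactly the configured value and trial noise is homogeneous.
* `jzs_anova_bf` treats groups as fixed effects only; random-effect and
  covariate models are out of scope.
* The bootstrap assumes exchangeability of pooled RTs under H0; trial-wise
  permutation of digit labels would be a stricter alternative and is noted
  as an extension, not implemented.
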
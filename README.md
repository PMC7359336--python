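# magclass

Analysis pipeline for **symbolic magnitude-classification** reaction-time
experiments — the task in which a participant decides as fast as possible
whether a single Arabic digit is smaller or larger than 5.

It is written for researchers in numerical cognition who want to quantify,
per participant and per group:

* the **numerical distance effect (NDE)** — responses are faster for digits
  farther from the standard (slope *b*<sub>D</sub> of mean RT on distance
  |d − 5|; negative = typical effect);
* the **numerical size effect (NSE)** — at a fixed distance, responses to
  larger digits are slower (slope *b*<sub>M</sub> of mean RT on magnitude
  d; positive = typical effect);
* optionally **ratio** and **SNARC** slopes;
* the **individual prevalence** of these effects via an H0 bootstrap;
* split-half **reliability**, and frequentist + Bayesian **group statistics**.

A synthetic experiment generator with known ground truth is included, so the
entire pipeline runs and is testable without any data download.

## The statistics at the core

**Slopes.** For each participant, RTs of retained correct trials are
averaged per digit d ∈ {1,2,3,4,6,7,8,9} and the 8 means are regressed on
D = |d − 5| and M = d jointly. Over this digit set, D and M are exactly
orthogonal (Σ(D−D̄)(M−M̄) = 0), so each multiple-regression slope equals its
simple-regression counterpart and there is no collinearity.

**H0 bootstrap.** Under the null that RT does not depend on the digit, a
participant's slope distribution is simulated by drawing, with replacement,
8 sets of 60 RTs from their pooled retained RTs, labelling the sets
arbitrarily with the 8 digits, and refitting the regression; this is
repeated 5,000 times. An empirical slope outside the mid 90% of the null
distribution, in the typical (resp. opposite) direction, labels the
participant *reliable typical* (resp. *reliable reverse*); otherwise *not
reliable*.

**Reliability.** Trials are randomly split in half within each participant
× digit × block cell; half-slopes are correlated across participants,
averaged over splits, and Spearman–Brown corrected: r<sub>SB</sub> =
2r/(1+r).

**Group statistics.** One-sample t-tests toward the predicted direction with
Cohen's d = mean/SD; one-way ANOVA with partial η²; JZS Bayes factors
(Cauchy prior with scale √2/2 on effect size for t-tests, g-prior with
scale 0.5 for ANOVA fixed effects, both by 1-D numerical integration;
one-sided BFs use order-restricted priors); and an exact r×c Fisher test
(full enumeration with margin pruning, or conditional Monte Carlo) on the
prevalence tables.

## Worked example

```python
from magclass import (SimConfig, generate_experiment, preprocess,
                      fit_all_participants, classify_cohort, prevalence_table)

cfg = SimConfig(n_per_group={"M": 13, "E": 14, "S": 15, "R": 56}, seed=1)
trials, truth = generate_experiment(cfg)
retained, report = preprocess(trials)
print(f"accuracy {report.overall_accuracy:.1%}, RT retained {report.proportion_rt_retained:.1%}")

slopes = fit_all_participants(retained)
print(slopes[["participant_id", "nde_slope", "nse_slope", "mean_rt"]].head(3).round(2))

cls = classify_cohort(retained, slopes, n_iter=5000, seed=1)
print(prevalence_table(cls, "nde")[["group", "reliable_typical_pct",
      "reliable_reverse_pct", "not_reliable_pct"]])
```

prints

```
accuracy 96.9%, RT retained 94.7%
participant_id  nde_slope  nse_slope  mean_rt
          E001      -4.76       6.53   573.46
          E002      -5.62       7.93   487.66
          E003      -5.14      -3.25   510.33
  group  reliable_typical_pct  reliable_reverse_pct  not_reliable_pct
      E                    79                     0                21
      M                    85                     0                15
      R                    84                     4                12
      S                    60                     7                33
Overall                    80                     3                17
```

Read top to bottom: the simulated cohort performs at 96.9% accuracy and
94.7% of trials survive screening; each participant gets a distance and a
size slope in ms per unit (E001 responds ~4.8 ms faster per unit of
distance); and the bootstrap classifies 80% of participants as showing a
reliable typical distance effect, with almost none reversed — the distance
effect behaves as a *dominant* phenomenon, while the size effect (not
shown) is reliable only in a minority.

## Command line

```bash
magclass simulate   --config sim.yaml --seed 1 --out data/
magclass preprocess data/trials.csv --out work/
magclass effects    work/retained.csv --out work/
magclass prevalence work/retained.csv work/slopes.csv --iters 5000 --out work/
magclass reliability work/retained.csv --out work/
magclass groupstats work/slopes.csv work/classifications.csv --out work/
magclass run --config pipeline.yaml --seed 1 --out results/
```

`run` chains every stage from one YAML config (any subset of the keys
`seed`, `simulate` (SimConfig fields), `input`/`colmap` (to analyse an
external trial CSV instead), `preprocess`, `effects`, `prevalence`,
`reliability`) and writes a manifest so outputs are reproducible
byte-for-byte. External CSVs with different headers or correctness codings
are adapted with a `ColumnMap` — no code changes needed.

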
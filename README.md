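# thermoflor

Flowers are often not uniformly warm: captured sunlight and floral structure
create within-flower temperature *patterns* (hot centres, warm rims, heated
reproductive structures) that bumblebees — which resolve temperature
differences of about 2 °C through sensors in their antennae and tarsi — can
in principle use as a learning cue. `thermoflor` is a Python package for
analysing this question end to end: it simulates differential-conditioning
experiments in which bees forage on artificial flowers whose only
distinguishing cue is the spatial layout of a temperature pattern, fits
hierarchical learning-curve models to the resulting foraging-success data,
runs the stepwise AIC model-simplification ladder and test-phase ANOVA used
to analyse such experiments, and generates synthetic floral thermographs for
survey-style statistics of temperature-pattern detectability.

It is written for behavioural ecologists and biostatisticians who want a
tested, reproducible implementation of this analysis pipeline — to plan
experiments by simulation, to validate the statistical machinery (parameter
recovery, type-I error, power), or to reanalyse comparable conditioning
data.

## The model

Each bee completes a learning phase of 60 counted flower landings followed
(in the small-flower design) by a nonrewarding test phase of 20 landings.
Landings are scored correct/incorrect (probing a rewarding flower or
withholding on a nonrewarding one), revisits to emptied flowers are
excluded, and success is aggregated in blocks of 10 visits.  The block
success rate y of bee *n* at visit count *x* ∈ {10, …, 60}, arcsine
(arcsin √p) transformed, follows the hierarchical model

    y_nx = i + l·ln x + T·s_t + C·s_c + T·ln x·c_t + C·ln x·c_c
           + b_n + r_n·ln x + ε_nx

with Boolean indicators T (circle/cross reward group) and C (control group;
the bar reward group is the baseline), per-bee random intercepts
b_n ~ N(0, σ_b²) and slopes r_n ~ N(0, σ_r²), and Gaussian residuals.  The
model is fitted by maximum likelihood; deviance = −2 log L and
AIC = deviance + 2k.  Model simplification proceeds stepwise — random
slopes, then group × experience interactions, then group terms, then the
learning slope — keeping the simpler model at each rung unless it raises
AIC by more than a threshold (default 2).  When interactions are retained,
the per-group model y = i + l·ln x + b_n tests whether each group learned.
Test-phase success is compared between groups by one-way ANOVA on the
arcsine scale with Tukey HSD letter groupings.

Thermographs are temperature grids with a flower mask; pattern generators
(hot edge circle, hot bar, hot cross, hot centre, uniform) match heated
area and mean temperature across paired shapes — the "no alternative cue"
constraint of the behavioural experiments — and within-flower range is the
hottest-minus-coldest masked pixel.

## Worked example

```python
import thermoflor as tf

visits = tf.simulate_cohort(tf.CohortConfig(seed=11))   # 3 groups x 12 bees
series = tf.success_series(visits)                      # blocks of 10 visits
ladder = tf.run_ladder(series)
print(ladder.table().to_string(index=False))
```

```
         step   AIC_full  AIC_reduced  delta_AIC  deviance_change  df            p     decision
random_slopes -87.986213   -89.842701  -1.856488         0.143512   1 7.048140e-01 keep_reduced
 interactions -89.842701   -34.683670  55.159031        59.159031   2 1.424885e-13    keep_full
```

Dropping the per-bee random slopes costs nothing (ΔAIC −1.9), but removing
the group × experience interactions raises AIC by 55 — the relationship
between success and experience differs between test groups, so the ladder
stops and per-group learning tests follow:

```python
for g in ("control", "bar_rewarded", "circle_rewarded"):
    c = tf.per_group_learning_test(series, g)
    print(g, round(c.delta_aic, 2), round(c.p, 3), c.decision)
```

```
control -1.99 0.918 keep_reduced
bar_rewarded 58.23 0.0 keep_full
circle_rewarded 46.18 0.0 keep_full
```

The control group (no perceivable temperature pattern) shows no effect of
experience and forages at chance, while both reward groups improve with
experience.  The test phase confirms the conditioned preference:

```python
tbl = tf.testphase_table(visits)
print(tf.testphase_anova(tbl))
print(tf.testphase_summary(tbl).to_string(index=False))
```

```
F_2,33 = 22.0, p = 8.48e-07
          group  n  mean_success      sem letter
   bar_rewarded 12      0.808333 0.051798      a
circle_rewarded 12      0.845833 0.032832      a
        control 12      0.408333 0.050690      b
```

Both reward groups outperform the control (shared letter "a" vs "b").  On
the thermograph side:

```python
survey = tf.simulate_survey(seed=11)
s = tf.survey_summary(survey["range_c"])
print(f"{s.n_detectable}/{s.n_species} species ({s.percent_display}%) "
      f">= {s.threshold} C; mean {s.mean_range:.2f}, sd {s.sd_range:.2f}")
```

```
75/118 species (64%) >= 2.0 C; mean 4.89, sd 2.46
```

i.e. well over half the simulated species display a within-flower
temperature range a bee could detect.

A command-line interface mirrors these stages
(`thermoflor simulate|score|fit|ladder|testphase|thermal|run`); `thermoflor
run` executes the whole pipeline and writes every stage's table as CSV with
the seed and a configuration hash in the header.

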
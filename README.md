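# infotrans

How much information does a person extract from a stimulus, and how
much of that depends on the stimulus versus on the person? `infotrans`
implements a complete analysis pipeline for psychophysical studies
that probe this question with short texts: participants read a small
set of stimuli spanning a gradient of objective complexity and rate
each one for perceived information, boredom, creativity, valence and
arousal (1–7 scales), alongside Big Five and clinical questionnaires.
The package is aimed at researchers in quantitative psychology /
computational psychiatry who want the full chain — stimulus scoring,
per-participant modeling, cohort contrasts — as tested, scriptable
library code.

## The model

A text's objective information content is its **cumulated empirical
entropy**: with `f` the relative word frequencies of the prefix ending
at (and including) position `i`,

    H_i = −Σ f·log f        H_cum = Σ_i H_i

(0 for a fully repetitive text, log(N!) for N distinct words). Each
participant's information ratings over the T texts are then fit
without an intercept as

    y_t = β_H·H_t + Σ_k β_k·trait_k + ε_t

where the five Big Five scores are constant within a participant.
Because that design is rank-deficient, the fit is ridge-penalized
(λ·n·‖β‖², default λ = 0.2 = 1/n for five texts). The fit decomposes
per text into relative contributions r_{j,t} = |x_j β_j| / Σ_j |x_j β_j|;
the entropy share r_{H,t} is the *external* contribution, the traits
sum to the *internal* one (external + internal = 1), and the mean of
r_{H,t} over texts is the participant's **information sensitivity** —
an index in [0,1] compared between cohorts (e.g. controls vs. an
ADHD-like group) and correlated with boredom. A shuffled-data null
(regressors permuted, every participant refit) shows the real fit
error beats chance pairing, and exact small-sample tests (enumerated
rank-sum and signed-rank, Fisher-z correlation intervals, Cohen's d,
Bonferroni control) carry the group statistics.

A synthetic-data generator produces the entire study structure — five
100-word texts with a strictly increasing entropy gradient, rating
cohorts with an inverse-U entropy response, negative
information-boredom coupling, heterogeneous sensitivity, and a
reduced-sensitivity clinical cohort — so every stage is testable
without any deposited data. See `docs/methods.md` for model details,
generator defaults and their rationale.

## Worked example

```python
import numpy as np
import infotrans as it

ds = it.generate_two_cohorts()   # seeded defaults: 142 control, 19 clinical
ctrl = ds.participants[ds.participants.cohort == "control"]
clin = ds.participants[ds.participants.cohort == "clinical"]

print("H_cum per text:", [round(p.cumulated_entropy, 1) for p in ds.profiles])

fit_c = it.fit_cohort(it.build_design(ctrl, ds.profiles), lam=0.2)
fit_a = it.fit_cohort(it.build_design(clin, ds.profiles), lam=0.2)
print("mean information sensitivity: control %.3f, clinical %.3f" % (
    np.mean([f.information_sensitivity for f in fit_c.fits]),
    np.mean([f.information_sensitivity for f in fit_a.fits])))

comp = it.compare_cohorts(ctrl, clin, fit_c, fit_a, alternative="less")
print("clinical entropy contribution lower on all texts:",
      bool((comp.entropy_contribution.clinical < comp.entropy_contribution.control).all()))
print("one-sided exact signed-rank p = %.5f" % comp.entropy_contribution_test.p)

link = it.sensitivity_boredom_link(fit_c, ctrl)
print("sensitivity~boredom (control): r=%.3f, p=%.4f, CI=[%.3f, %.3f]" % (
    link.r, link.p, link.ci_low, link.ci_high))
```

prints

```
H_cum per text: [62.1, 152.2, 226.2, 289.2, 341.9]
mean information sensitivity: control 0.261, clinical 0.199
clinical entropy contribution lower on all texts: True
one-sided exact signed-rank p = 0.03125
sensitivity~boredom (control): r=-0.630, p=0.0000, CI=[-0.720, -0.519]
```

The five texts span a ~6× entropy range; the clinical cohort's entropy
contribution is lower on every text (the most extreme pattern five
paired values allow, hence the exact one-sided p of 1/32); and
participants whose ratings track entropy less are the ones reporting
more boredom.

The same pipeline runs from the shell:

```sh
infotrans simulate --out data/ --seed 1
infotrans fit --participants data/participants.csv --profiles data/profiles.csv --out fits/
infotrans run --seed 1 --out results/      # full end-to-end pipeline
```

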
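# whalecues

Analysis toolkit for behavioural response experiments testing whether baleen
whales sense food-related chemical cues. In such experiments a boat deploys a
drifting diffuser releasing either a prey-odour stimulus (krill hydrolysate),
dimethyl sulfide (DMS — a zooplankton-grazing by-product proposed as a
long-range foraging cue), or a visually matched control, and observers record
for 22 minutes how whale groups behave around two concentric exposure zones
(50 m and 300 m radius) while a hydrophone records vocal activity.

`whalecues` implements the complete desk-side analysis of such a campaign,
plus ground-truthed synthetic generators so every stage is testable without
field data:

* **Call detection** — a spectrogram front end that binarizes each
  time-frequency pixel against a per-bin robust noise profile
  (median + k·MAD across frames) and keeps continuous time-frequency tracks;
  each track carries its frequency contour.
* **Call descriptors** — 13 per-call statistics: min/max/median/mean
  frequency, duration, and min/max/median/mean of the contour's velocity
  (Hz/s) and acceleration (Hz/s²); the *n* longest (most complete) calls are
  retained for clustering.
* **Repertoire clustering** — z-scored descriptors → 2-D t-SNE → truncated
  variational Dirichlet-process Gaussian mixture; cluster–condition
  correspondence is scored by normalized mutual information,
  `NMI(X,Y) = I(X,Y) / √(H(X)·H(Y))` (entropies in bits), with a grid scan
  over mixture settings returning the maximum-NMI clustering.
* **Behavioural statistics** — Tobit (censored Gaussian) regression for
  zero-inflated zone residence times, Poisson GLM for new-group appearances,
  negative-binomial regression for over-dispersed bird counts, linear models
  on square-root-transformed respiratory rates, two-sided probability-mass
  Fisher exact tests for surface-behaviour occurrence tables, exhaustive AIC
  model selection (`dredge_aic`, with the ΔAIC ≥ 2 rule), and post-hoc
  stimulus-vs-control contrasts with family-wise adjustment.

The censored-regression core is a statsmodels-style model: build
`Tobit(y, X, left=0)`, call `.fit()`, and read estimates, standard errors,
confidence intervals, AIC, a `summary()` table and McFadden pseudo-R² off
the results object.

## Worked example

Run the full pipeline on synthetic data (audio with condition-dependent call
types, and a trial table whose krill-extract condition adds ~8 min of
300 m-zone residence over control):

```bash
whalecues run-all --seed 3 --out runs/demo
```

Selected numbers from `runs/demo/report.json`:

```
acoustics.best_nmi            0.7074   with 2 clusters
acoustics.detections          krill 23, krill-control 24, DMS 27, DMS-control 23
tobit_time_in_300m            krill vs control: estimate 7.19 min, z = 3.74, p_adj = 0.0004
                              DMS vs control:   estimate -0.15 min, p_adj = 1.0
fisher  K:stopping            p = 0.0049
```

Reading them: the detector recovers the simulated calls in each one-minute
file; clustering the call descriptors splits them into exactly the two
simulated call types, and because the chemical conditions were simulated to
elicit one type and the controls the other, the cluster labels share
~1 bit of information with the 2-bit condition label — NMI
1/√(1·2) ≈ 0.71, the theoretical score for a perfect chemical-vs-control
split. The Tobit contrast recovers the simulated ~8-minute krill-extract
attraction effect (the DMS effect is correctly null), and the exact test
flags the elevated stopping occurrence built into the krill condition.

Library use mirrors the CLI:

```python
from whalecues import Tobit, fisher_exact_2x2, nmi
from whalecues.synth import TrialGenConfig, generate_trials

table, truth = generate_trials(TrialGenConfig(seed=3))
p = fisher_exact_2x2([[7, 30], [0, 20]])   # 0.0447
```

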
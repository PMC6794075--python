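# reachprior

Analysis pipeline for electrophysiology experiments in which **graded action
priors** bias **rule-guided reach selection**. In the task this package
models, a monkey fixates centrally while a pre-cue at one of four cardinal
locations announces two potential reach goals, 90° clockwise (cw) and
counter-clockwise (ccw) from the cue. The relative arrowhead sizes of the
pre-cue encode the likelihood ratio — one of {6:0, 5:1, 4:2, 3:3, 2:4, 1:5,
0:6}, constant within 8-trial blocks (6 instructed, 2 free-choice) — with
which the cw or ccw transformation rule will later be instructed. Expressed
as the normalized difference of the rules' initial expected values, these
ratios realize four prior levels {0, 0.25, 0.5, 0.75}. On rare free-choice
trials both goals are rewarded equally, so any residual choice bias reveals
the influence of the preceding action prior on movement planning in
frontoparietal areas (dorsal premotor cortex, PMd, and the parietal reach
region, PRR).

The package implements the full analysis chain as a tested, reusable
library, together with a synthetic-data generator that emulates the task
and its neural populations so that every stage can be validated by
parameter recovery:

- **Spike densities** — causal EPSP-like kernel
  `k(t) ∝ (1 − e^(−t/τ_g)) e^(−t/τ_d)` (τ_g = 2 ms, τ_d = 50 ms) for
  display, Gaussian kernel (σ = 50 ms) for all velocity analyses; unit-area
  normalization on a 1-ms grid.
- **Direction selectivity** — directional tuning vector (DTV), PD_max,
  Kruskal–Wallis gating (p < 0.01, > 5 Hz), trigonometric (ideal low-pass)
  tuning interpolation, PD-aligned normalized population tuning per prior
  level.
- **UR/DR classification** — per-unit linear model
  `Activity ~ PRIOR × PRIORDIR` on normalized planning rates; the slope
  pair maps to an angle `arctan2(max(s_PD, 0), max(−s_OD, 0))`; bimodality
  of the angle distribution is established with an exact, from-scratch
  implementation of Hartigans' dip test (Monte-Carlo calibrated).
- **Behavioral bias models** — error rates, RTs and choice probabilities by
  prior × congruency; `X ~ PRIOR + PRIOR:CONGRUENCY` and binomial
  `choice ~ PRIOR` fits with per-subject pooling and Bonferroni-corrected
  successive post-hocs.
- **Selection-signal latencies** — neural distance (ND): the Euclidean
  distance in the full state space spanned by all units between
  condition-averaged trajectories for opposing reach goals; latency = time
  of maximal ND velocity (MVT) and plateau time (PT); unit-bootstrap CIs
  (N = 1000, 90%) and between-area permutation tests (N = 10,000).
- **Choice prediction** — within-/between-condition ROC discriminability of
  planning activity, and pairwise signal correlations as a function of
  PD distance and prior.

## Worked example

```python
from reachprior.config import validate_config
from reachprior.pipeline import run_pipeline

cfg = validate_config({"simulation": {"n_units_per_area": 20,
                                      "n_blocks": 28, "seed": 2},
                       "analysis": {"n_boot": 200, "n_perm": 500,
                                    "dip_n_boot": 500}})
manifest = run_pipeline(cfg, "out/demo")
print(manifest["checks"])
```

This simulates a compact session (40 units, 448 trials), runs every stage,
and writes CSV/JSON artifacts plus `report.md` into `out/demo`. The report
for this configuration reads:

```
- PMd: 12/20 motor-goal neurons
- PRR: 9/20 motor-goal neurons
- PMd modulation-angle dip test: dip=0.1494, p=0.01 (n=11)
- PRR modulation-angle dip test: dip=0.2367, p=0 (n=8)
- choice probability at the strongest prior: 0.91 (n=32)
- MVTs (ms after rule-cue, level 0.5): PMd-DR: 166, PMd-UR: 175,
  PRR-DR: 175, PRR-UR: 239
```

Reading: roughly half the units pass the motor-goal gate (matching the
configured 60% tuned fraction at this small sample), the prior-modulation
angles split bimodally into up- and down-regulating classes in both areas,
free choices follow the strongest prior ~90% of the time, and the
selection signal (maximal-velocity time of the neural distance) appears
first in PMd down-regulating neurons, as configured. The final `Checks`
section of the report asserts the population-level signatures — all nine
pass here (UR: graded PD_max upregulation only; DR: graded OD
downregulation only; no orthogonal modulation; angle bimodality per area;
PMd-DR earliest selection signal).

The same stages are available individually from the command line:

```bash
reachprior simulate --seed 1 --out-dir data/
reachprior classify --in-dir data/ --out-dir out/
reachprior run --seed 1 --out-dir out/full
```

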
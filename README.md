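# swimassay

Analysis pipeline for **individual-based behavioral assays in larval and
juvenile fish** — the kind of test battery used to compare exploratory
drive, anxiety-like avoidance, behavioral consistency, and spontaneous
alternation between species such as zebrafish and paradise fish.

The package takes zone-labelled swim tracks (or raw per-frame positions
plus an arena geometry) and produces:

* **assay endpoints** — per-zone occupancy times, entry counts, first-entry
  latencies; the slalom-maze *mean transition latency* (MTL); the plus-maze
  *anxiety score*; open-tank thigmotaxis measures; sociability-zone
  preferences;
* **Y-maze action classification** — alternations, direct revisits and
  indirect revisits over sliding windows of three arm visits, and the
  alternation percentage (50% = random choice, 100% = perfect alternation);
* **behavioral consistency** — repeatability (intraclass correlation) with
  parametric-bootstrap confidence intervals, and single-measure (SiM) vs
  summary-measure (SuM) inter-test correlations;
* **modality decisions** — uni- vs multimodality of an endpoint
  distribution by 1-D Gaussian-mixture fitting with BIC model selection;
* **standardized effect sizes** — |Δ mean| / total SD summaries across
  assays and manipulations.

A seeded **synthetic behavior generator** (continuous-time Markov walks on
the arena zone graph, parameterized Y-maze choice policies, random-
intercept repeated measures, Gaussian-mixture populations) provides data
with known ground truth for every stage, so the whole pipeline is testable
without any video tracking.

## The statistics at the core

**Endpoint scaling.** Slalom chamber entry latencies are min-max scaled to
[0, 1] across the analysis population per chamber and averaged per subject
(MTL). The plus-maze anxiety score is

```
score = scaled(latency to aversive arm) − scaled(time in aversive arm) ∈ [−1, 1],
```

higher meaning stronger avoidance.

**Y-maze actions.** Each window of three consecutive arm visits (x, y, z)
is labelled: *direct revisit* if x = y or y = z; otherwise *alternation*
if all three differ; otherwise *indirect revisit* (x = z ≠ y).
Alternation% = 100 · alternations / (visits − 2).

**Repeatability.** For a subject × session endpoint matrix,
R = σ²_between / (σ²_between + σ²_within), estimated by one-way
random-effects ANOVA (method of moments, negative estimates truncated at
0), with a 95% percentile CI from 1000 parametric bootstrap replicates of
the fitted normal random-intercept model. A CI excluding 0 flags the
endpoint as significantly repeatable.

**Modality.** Gaussian mixtures with K = 1..3 components are fitted by EM
(quantile-initialised restarts, variance floor); the winning K maximises
BIC = 2·logL − p·ln n (higher is better, p = 3K − 1), and BIC values are
min-max scaled to [0, 1] over the K grid for plotting.

**Effect size.** d = |mean(a) − mean(b)| / SD(a ∪ b) with the n − 1
denominator on the pooled observations (Cohen-style pooled-within SD is
available as an option).

## Worked example

```python
import numpy as np
import swimassay as sa

# Y-maze: random chooser vs memory-driven alternator
seqs = sa.simulate_ymaze(n_subjects=32, n_visits=200,
                         p_alt=0.5, p_direct=0.0, seed=1)
alts = [sa.alternation_percent(sa.classify_actions(a)) for a in seqs.values()]
print(f"random-choice alternation: {np.mean(alts):.2f}%")

# plus-maze avoidance: control vs strong-avoidance simulation
times, lats, group = [], [], []
for g, seed, a in (("ctrl", 2, 0.0), ("avoider", 3, 3.0)):
    cfg = sa.SimConfig(assay_id="spm", n_subjects=24, seed=seed, avoidance=a)
    for s in sa.simulate_visits(cfg)[0]:
        m = sa.session_metrics(s, zone_ids=["shallow_1", "shallow_2",
                                            "deep_1", "deep_2", "center"])
        times.append(m.per_zone["shallow_1"].time_s
                     + m.per_zone["shallow_2"].time_s)
        lats.append(min(m.per_zone["shallow_1"].latency_s,
                        m.per_zone["shallow_2"].latency_s))
        group.append(g)
scores = sa.anxiety_score(times, lats)
group = np.array(group)
e = sa.standardized_effect(scores[group == "ctrl"],
                           scores[group == "avoider"])
print(f"standardized effect d = {e.d:.3f}")

# repeatability of a simulated endpoint with known truth
d = sa.simulate_repeated(mu=10, sd_between=1.2, sd_within=0.8,
                         n_subjects=24, k_sessions=3, seed=4)
est = sa.repeatability(d, n_boot=1000, seed=4)
print(f"R = {est.r:.3f} [{est.ci_low:.3f}, {est.ci_high:.3f}] "
      f"(true {d.true_r:.3f})")
```

prints

```
random-choice alternation: 49.64%
standardized effect d = 1.843
R = 0.731 [0.533, 0.841] (true 0.692)
```

The random-choice policy lands at the 50% alternation reference; the
avoidance manipulation separates the groups by nearly two pooled standard
deviations; and the repeatability estimate brackets the generating
intraclass correlation of 0.69.

## Command line

```bash
swimassay simulate --assay spm --n-subjects 24 --seed 7 --out visits.csv
swimassay endpoints --visits visits.csv --assay spm --out endpoints.csv
swimassay simulate-ymaze --seed 7 --out arms.csv
swimassay ymaze --arms arms.csv --out actions.csv
swimassay repeatability --input rm.csv --nboot 1000 --seed 7 --out rep.json
swimassay modality --input mtl.csv --kmax 3 --seed 11 --out modality.json
swimassay effects --input endpoints.csv --out effects.csv
swimassay run --config run.yaml          # full pipeline with manifest
```

All commands exit 0 on success and 2 on validation errors; every output of
`run` carries a manifest with the seed and a configuration hash, and
re-running the same config reproduces the outputs byte-identically.

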
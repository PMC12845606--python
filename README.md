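# synkick

Muscle-synergy analysis of cyclic breaststroke-kick surface EMG: a tested,
reusable pipeline from raw multi-channel recordings to group-level
statistics, plus a synthetic-cohort generator with known ground truth.

## Who this is for

Researchers in sports biomechanics and motor control who record surface
EMG during cyclic aquatic movement and want a reproducible, scriptable
implementation of the standard synergy workflow — and a way to validate
every stage of it without access to athlete data, via simulation with
known synergy structure.

## The method

A stroke cycle is divided into four consecutive phases (leg-retraction,
leg-flipping, pedal-clamp, glide). Raw sEMG from *m* muscles is band-pass
filtered (10–400 Hz), demeaned, full-wave rectified, low-pass filtered at
10 Hz (linear envelope, zero phase), normalized to each channel's peak,
time-normalized to 101 points per phase, and ensemble-averaged over the
middle three cycles, giving the activation matrix **V** (*m* × 404).

Non-negative matrix factorization decomposes **V** ≈ **W**·**H** with
**W** (*m* × *k*) the spatial synergy weights and **H** (*k* × 404) the
temporal activation coefficients. The model order *k* is the smallest
value whose variance accounted for,

    VAF = 1 − SSE/SST,

first exceeds 0.9. Each **W** column is normalized to max 1; muscles with
weight ≥ 0.3 are major contributors. Subject synergies are pooled per
group × session cell, clustered by k-means into reference synergies
(SYN1..SYNs, cluster count by SSE-trend elbow), and matched back by
Pearson correlation (r > 0.6). From each matched **H** row, timing
features are extracted as cycle fractions: activation duration T (time
above 20% of peak), peak moment Tmax, onset Tstart. Measures then enter a
2 × 2 (group × time) mixed-design testing scheme: Shapiro–Wilk screening,
repeated-measures ANOVA with Bonferroni-corrected simple effects, or a
Wilcoxon/Holm fallback with effect size r = |Z|/√n.

The synthetic generator runs this model forward: envelopes **W**·**H**
from published weight and timing structure, modulated onto a 20–400 Hz
Gaussian carrier with additive noise and smooth synergy-unmodeled muscle
activity, with per-subject jitter and injectable group × time effects.
See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a small cohort (5 subjects per group), run the whole pipeline,
and test one synergy weight for a group × time interaction. A demo this
small has a shallow clustering elbow, so the cluster-count tolerance is
coarsened from its full-cohort default of 0.10:

```python
from synkick.emg_io import PipelineConfig
from synkick.synthetic_emg import CohortSpec
from synkick import pipeline

cfg = PipelineConfig(cluster_drop_tol=0.2)
spec = CohortSpec(seed=0, subjects_per_group=5)
manifest = pipeline.run_all(cfg, "runs/demo/cohort", "runs/demo/out",
                            spec=spec,
                            stats_measures=["weight:SYN2:biceps-femoris"])
print(pipeline.report("runs/demo/out"))
```

Output (abridged):

```
# synkick run report

## Model order
selected k distribution: k=3: 5, k=4: 14, k=5: 1
VAF at selected k: min 0.902, median 0.913, max 0.933

## Reference synergies (per group x session cell)
- control,pre: s = 4
- experimental,pre: s = 4
- experimental,post: s = 5
- control,post: s = 4

## Activation timing (mean ± SD per cell)
- timing:SYN1:Tmax [control, pre]: 0.28 ± 0.04
...
## Statistics
- weight:SYN2:biceps-femoris / normality[control,pre] (shapiro): stat=0.978, p=0.892, adj p=0.892
- weight:SYN2:biceps-femoris / group (rm-anova): stat=0.0259, p=0.878, adj p=0.878
- weight:SYN2:biceps-femoris / time (rm-anova): stat=0.499, p=0.506, adj p=0.506
- weight:SYN2:biceps-femoris / interaction (rm-anova): stat=0.0366, p=0.855, adj p=0.855
```

Read it as: most synthetic subjects recover the four planted synergies
with reconstruction VAF just above the 0.9 criterion; the SYN1 activation
peak sits near 0.27 of the cycle (the planted value); the measure passes
normality screening in every cell; and with no injected effect the
interaction test is, correctly, not significant. Inject an effect via
`CohortSpec(effects=...)` to watch the same table light up. The same run
is available from the shell via `synkick run-all`.

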
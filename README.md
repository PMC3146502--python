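# eeg-microstates

Resting-state EEG microstate analysis for two-group (patient vs control)
designs: polarity-invariant topographic clustering, segmentation into
microstate runs, transition-syntax statistics and the group-comparison
statistical layer — plus a synthetic cohort generator so the entire pipeline
can be validated end-to-end without access to raw clinical recordings.

## The problem

The momentary scalp potential field of resting EEG does not wander
continuously: it stays in one quasi-stable topography for ~50–120 ms, then
switches abruptly to another. During such a period the *shape* of the map is
fixed while its polarity oscillates with the dominant rhythm. These periods
are called **microstates**, and in eyes-closed recordings four prototypical
map classes (conventionally lettered A–D) recur across subjects and explain
most of the topographic variance. Per-class temporal statistics — mean
duration, occurrence rate, fraction of time covered — and the syntax of
transitions between classes are compact, testable descriptors of resting
brain dynamics that differ between clinical groups.

## The method

For each subject, epochs are band-pass filtered (2–20 Hz), re-referenced to
the common average, and the **global field power**

```
GFP(t) = sqrt( (1/N) Σ_i ( u_i(t) − ū(t) )² )
```

(the spatial SD over the N electrodes) is computed per sample. Topography is
most reliable at GFP peaks, so only the maps at interior local maxima of
GFP(t) enter clustering.

**Modified K-means** clusters the peak maps into k = 4 classes. Because a
map and its negation are the same brain state, assignment uses the *squared*
spatial (Pearson) correlation, and each class template is re-estimated as
the dominant eigenvector of its members' outer-product scatter rather than
their arithmetic mean. Quality is the **global explained variance**

```
GEV = Σ_m ( GFP_m · corr(u_m, T_{L(m)}) )² / Σ_m GFP_m²
```

over peak maps m with labels L(m) and templates T. Per-subject template
sets are aligned across subjects by exhaustively searching the k! label
permutations per subject that maximize the common variance, and the aligned
class-mean maps are lettered A–D against canonical prototypes.

Labels are then back-fitted to every sample (nearest-GFP-peak rule),
maximal same-class runs form the microstates (no minimum duration; runs with
a single GFP peak are kept), and each subject gets a per-class profile of
duration (ms), occurrence (/s) and percent total time, plus the normalized
fractions of the 12 doublet and 36 triplet between-class transition
sequences. The statistical layer runs a split-plot ANOVA (group × class) per
measure, per-class pooled-variance two-tailed t-tests, Spearman rank
correlations with ordinal clinical severity, and per-transition t-tests.

## Worked example

```python
import numpy as np
from microstates import SynthConfig, generate_cohort
from microstates.pipeline import PipelineConfig, analyze_cohort

cfg = SynthConfig(n_subjects_per_group=6, epochs_per_subject=(12, 16),
                  snr=2.0, seed=7)
cohort = generate_cohort(cfg)                      # 12 synthetic subjects
result = analyze_cohort(cohort, PipelineConfig(n_restarts=10, seed=0))

print("mean GEV:", round(np.mean(list(result.log["subject_gev"].values())), 3))
for r in result.anova["duration"]:
    print(f"ANOVA {r.effect}: F={r.F:.2f} "
          f"df=({r.df_numerator},{r.df_denominator}) p={r.p:.4f}")
for letter, res in result.posthoc["duration"].items():
    print(f"duration class {letter}: patients {res.mean1:.1f} ms "
          f"vs controls {res.mean2:.1f} ms, t={res.t:+.2f} df={res.df} "
          f"p={res.p:.3f}")
```

prints

```
mean GEV: 0.937
ANOVA group: F=86.26 df=(1,10) p=0.0000
ANOVA class: F=127.10 df=(3,30) p=0.0000
ANOVA group x class: F=10.61 df=(3,30) p=0.0001
duration class A: patients 66.6 ms vs controls 57.0 ms, t=+10.04 df=10 p=0.000
duration class B: patients 60.4 ms vs controls 62.7 ms, t=-4.84 df=10 p=0.001
duration class C: patients 68.3 ms vs controls 66.6 ms, t=+0.95 df=10 p=0.362
duration class D: patients 84.5 ms vs controls 77.8 ms, t=+3.22 df=10 p=0.009
```

The four templates explain ~94% of the peak-map variance at this noise
level; the group × class interaction and the class A post-hoc test recover
the planted group difference in class A duration (the generator's default
plants longer class A microstates in patients), and t > 0 means patients
exceed controls.

The same analysis is available from a shell:

```bash
microstate simulate --out cohort/ --seed 7
microstate all --manifest cohort/manifest.tsv --out report/ --seed 0
```

which writes `profiles.tsv`, `syntax.tsv`, `mean_maps.tsv`, `stats.json`
and a `run_log.json` recording every parameter, seed and per-subject GEV.

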
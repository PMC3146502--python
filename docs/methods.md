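# Methods

This note documents the models, algorithms and numerical choices behind the
package, what the synthetic data does and does not emulate, and the known
limitations.

## Analysis model

The pipeline treats resting EEG as a concatenation of quasi-stable
topographic states. Its stages, in order:

1. **Preprocessing.** Each epoch (default 16 channels × 512 samples at
   200 Hz, i.e. 2.56 s) is band-pass filtered 2–20 Hz with a 4th-order
   Butterworth applied forward–backward (`sosfiltfilt`). Zero-phase
   filtering is essential: a causal filter would shift topography timing and
   bias run boundaries. The epoch is then re-referenced to the common
   average. Filtering and referencing are both linear and channel-wise/
   sample-wise respectively, so they commute (a tested property).

2. **GFP and peak picking.** GFP is computed as the spatial *standard
   deviation* (normalized by channel count). The alternative unnormalized
   RMS convention rescales GFP by a constant and changes neither peak
   locations nor any clustering result; the SD form was chosen so GFP has
   the units and magnitude of a per-channel potential. Peaks are interior
   strict local maxima; a plateau of equal maximal values contributes its
   center sample, with the left-center sample on even-length plateaus —
   deterministic and independent of scan order. No amplitude threshold is
   applied to peaks: low-GFP peaks carry noisier maps, but their GEV weight
   is proportionally small, and thresholds would introduce a free parameter
   the analysis does not need.

3. **Polarity-invariant modified K-means** (k = 4 by default; four classes
   are the field's standard for eyes-closed resting EEG and the basis of
   comparability across studies). Peak maps are unit-normalized; assignment
   maximizes squared spatial correlation; the template update is the
   dominant eigenvector of the members' outer-product scatter, which is the
   polarity-free analogue of the mean (averaging would cancel
   polarity-inverted members). With uniform peak strengths both steps are
   exact coordinate ascent on GEV. By default the scatter is unweighted
   (every peak map counts equally); a `gfp_weighted_update` flag weights
   maps by GFP, making the update an exact GEV-ascent step also for
   heterogeneous peak strengths. Each restart initializes templates from k
   distinct randomly chosen data maps; 20 restarts by default; convergence
   when the labelling is stable or the relative GEV gain falls below 1e-6.
   The best iterate per restart is retained, so the reported GEV trajectory
   is non-decreasing by construction. An empty cluster is re-seeded with the
   currently worst-explained map.

   *Known limitation:* on structure-free inputs (pure noise maps, no
   cluster structure), data-map initialization can converge to the same
   local optimum from every possible initialization, so no number of
   restarts reaches the global optimum of the assignment search. On maps
   with genuine class structure — the regime the algorithm exists for — the
   iteration attains the exhaustive-search optimum (verified against a
   brute-force assignment oracle on small instances).

4. **Cross-subject alignment.** Subjects are processed in sorted-id order;
   the first subject seeds the class order. Each iteration exhaustively
   scores all k! = 24 label permutations per subject against the current
   class-mean maps (squared correlation objective) and re-estimates each
   mean as the dominant eigenvector of the across-subject scatter — again
   polarity-blind, with the overall sign fixed by the convention that the
   largest-magnitude channel is positive. The objective is non-decreasing
   and the permutation lattice is finite, so the procedure terminates. Class
   indices are lettered A–D by solving the 4×4 assignment problem against
   canonical prototype maps (the generator's prototypes by default; users
   may supply their own template file).

5. **Back-fitting and segmentation.** GFP peaks get the label of their
   best-matching template (squared correlation); every other sample inherits
   the label of the nearest peak, with exact midpoints going to the earlier
   peak. This nearest-peak reconstruction preserves peak-level syntax while
   labelling every sample; a `per-sample` mode (label each sample by its own
   correlation) exists for sensitivity analysis. Runs are maximal same-class
   stretches: no minimum duration, no smoothing, single-peak runs kept,
   edge-truncated runs included (an `include_edge_runs=False` flag drops
   them from duration/occurrence for sensitivity checks; coverage always
   uses all samples). Because durations count the inter-peak extension, not
   only peak-to-peak spans, the convention is recorded here and in the
   output metadata.

6. **Profiles, syntax, statistics.** Per subject, pooling all epochs:
   duration = mean run length (ms; NaN if a class never occurs), occurrence
   = runs/s of total analyzed time, coverage = percent of samples. Doublet
   and triplet transition counts never cross epoch boundaries (epochs are
   discontinuous artifact-free selections) and are normalized per subject.
   The split-plot ANOVA (between: group; within: class) is computed by a
   standard mixed-design routine and verified in the tests against an
   explicit sums-of-squares decomposition; the canonical within-error df is
   (k−1)(N−g), while the (k−1)·N convention that sometimes appears in print
   is reported alongside (`df_denominator_alt`) — the two conventions are
   both emitted rather than forced to agree. Post-hoc tests are
   pooled-variance (Student) two-tailed t-tests with df = n1+n2−2, which is
   the form that reproduces published t-values from group means/SDs
   exactly. Severity correlations use Spearman's rho with midranks,
   patients only, full measure × class grid, uncorrected. Syntax t-tests
   are uncorrected as well (the analysis treats the count of significant
   triplet tests against the 36·α chance expectation); a Bonferroni column
   is included in the output for transparency.

## Synthetic cohort generator

The generator emulates a two-group eyes-closed resting study so every stage
is testable without external recordings:

- **Montage:** the 16-electrode 10–20 subset (Fp1…O2) with approximate
  unit-disc positions.
- **Prototypes:** A and B are smooth potential gradients along diagonal
  axes tilted 30° off the left–right axis (right-anterior/left-posterior
  and mirror image), C a pure anterior–posterior gradient, D a
  fronto-central Gaussian extreme. The 30° tilt keeps all pairwise absolute
  correlations ≤ 0.58 (quasi-orthogonal) while preserving the canonical
  appearance of the four classes.
- **State dynamics:** a first-order chain over classes (uniform over the
  other three by default; configurable matrix with zero diagonal), with run
  durations drawn from a normal distribution truncated below at two
  sampling intervals. Truncated normal is the simplest family matching a
  reported mean/SD pair while excluding non-physical durations. Default
  group × class duration means/SDs are the published two-group magnitudes
  (patients: 63.81/58.47/64.21/83.40 ms; controls: 54.55/61.03/66.63/74.14
  ms), so the default cohort carries a realistic class-specific group
  effect; `null_config()` removes it.
- **Rendering:** within a state the signal is the prototype times
  `a·sin(2πft+φ)` with a 10 Hz carrier (eyes-closed alpha dominance; two
  GFP peaks per cycle, i.e. one every ~50 ms, matching the microstate
  time scale) and amplitude/phase redrawn at every state boundary, plus
  spatially and temporally white Gaussian noise at a configured RMS SNR
  (default 2, moderate-quality scalp EEG), then average-referenced.
- **Cohort:** 18 subjects per group, 18–61 epochs per subject drawn
  uniformly (the within-subject epoch-count distribution is otherwise
  unconstrained), patient severities uniform over {1..4} and independent of
  the planted effects by default; `severity_duration_slope_ms` optionally
  plants a monotone severity → class A duration effect for power-testing
  the correlation stage. Everything is reproducible from a single seed.

What the generator does *not* emulate: volume conduction and realistic
source geometry, 1/f background spectra and non-alpha rhythms, artifacts
(blinks, muscle, drowsiness — the emulated design analyzes visually cleaned
epochs), spatially correlated sensor noise, and between-subject topographic
variability of the prototypes. Consequently, passing tests demonstrate the
correctness and statistical calibration of the pipeline under the planted
model, not the clinical validity of microstate differences in real data.
Explained variance on this synthetic data (≈0.87 unfiltered, ≈0.94 after
the 2–20 Hz band-pass at SNR 2) is accordingly somewhat higher than the
availability of four templates typically achieves on real recordings
(~0.75–0.80), because the planted maps are exact and noise is white; the
plausibility checks therefore use a band (0.6–0.95) rather than a point.

Power studies use `simulate_sequence_profiles`, which pushes the
generator's ground-truth label sequences directly through the same
run-segmentation/profile/statistics code, bypassing rendering and
clustering. This isolates the statistical layer and keeps replicated
designs (50–200 cohorts) inside seconds. Because run-duration variability
is run-to-run (not between-subject) in the generator, subject means are
estimated from hundreds of runs and the planted 9.3 ms class A effect is
detected with near-certain power at n = 18 per group, while unplanted
classes stay at the nominal 5% false-positive rate.

## Numerical choices and degenerate inputs

- Convergence tolerance 1e-6 (relative GEV) for clustering; alignment
  iterates to permutation fixed point (cap 100 iterations).
- Correlation of a zero-variance map is an error, not NaN.
- Epochs with no GFP peak cannot be back-fitted (error); a subject class
  with zero runs yields NaN duration and excludes the subject from that
  measure's ANOVA with a warning.
- Zero-variance duration configs degenerate to the class mean clamped at
  the truncation bound.
- All output files carry the package version, a configuration hash
  (excluding the output path) and the seed; identical configuration+seed
  reruns are byte-identical.

## Problem sizes in tests

The replicated designs in the test-suite and acceptance script use
deliberately compact sizes chosen to estimate each quantity stably: 50
replicates for power/oracle checks, 200 for the null false-positive rate,
cohorts of 3–18 subjects per group with 10–40 epochs each depending on the
stage under test. These are the package's own validation defaults;
full-size runs simply scale the same configuration fields.
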
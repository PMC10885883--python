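# Methods

## The detection problem

A doe entering labor lies on her side with her legs stretched out and keeps
moving them. A triaxial accelerometer strapped to the tibia sees this as a
joint signature: the static gravity component moves from the X axis (leg
upright) to the Z axis (leg horizontal), while movement jitter stays high.
Neither cue alone is reliable — normal lying also loads Z, and walking is
also active — so the pipeline classifies *records* by posture and then
aggregates *windows* by the product of activity and labor-classified
counts, which is large only when both cues persist together.

## Pipeline model

**Per-record classification.** A CART decision tree (Gini impurity,
`max_depth=10`, `min_samples_leaf=5`, fixed seed) on the integer (x, z)
count pair, trained on a balanced labeled dataset (labor vs non-labor),
split 80/20 by a seeded shuffle with a contiguous cut (sizes ⌊0.8n⌋ and
the remainder). An RBF-kernel SVM is kept as the comparison baseline; on
both real and synthetic data the two classes overlap non-linearly in
(x, z), and the tree matches or beats the SVM here. Feature choice is
checked by information gain and gain ratio with each integer count as its
own category — this avoids an arbitrary binning choice; the cost is that
gain-ratio magnitudes are not comparable to tools that discretize
differently, so only the *ranking* (x and z above y) is meaningful.

**Windowing.** For a window of length `w` minutes, `TA` counts
activity-flagged records, `TLP` counts labor-classified records (inactive
records are still classified — a laboring doe can be momentarily still —
they just do not add to TA), and `LPI = TA × TLP` exactly. Windows are
anchored at the stream start and slide by a 60 s stride by default:
detection-time resolution should be finer than the window length. Tiled
(stride = length) windows are available for partition-style analyses.

**Calibration.** Per candidate window length (8, 10, 12, 14 min): the
labor group is each goat's maximum LPI over its parturition day (the
`day_hours` ending at birth, 24 h by default); the non-labor group is the
`k = 110` highest LPIs pooled across goats from all labor-free windows of
the monitored pre-birth stream. `CRV = (mean_L − sd_L) − (mean_NL +
sd_NL)`; the largest CRV picks the window, ties going to the shorter
window (earlier alarms). The alarm threshold is `TCKG = mean_NL + 3 sd_NL`
over the chosen window's non-labor pool. The non-labor pool is computed on
the same sliding window grid the detector scans: a threshold must bound
the statistic it is later compared against (a tiled pool systematically
undershoots, because tiles split bursts that sliding windows center). A
Kolmogorov–Smirnov normality check (against the fitted normal) and an
independent two-sample t-test (equal-variance by default, Welch by flag)
compare parturition-day maxima with pre-labor maxima.

**Detection.** The first window with `lpi > TCKG` — strictly greater, per
the three-sigma outlier rule — fires one event per goat per day at
`DPT = window_start`; later crossings that day do not re-alarm. The
predicted first-birth time is `PPT = DPT + MDV`, with MDV the mean of
(birth − DPT) over detected goats during calibration. Detection and
failure rates are percentages rounded to one decimal, half-up
(14/17 → 82.4%).

## Numerical and convention choices

- Quartiles: linear interpolation between order statistics (numpy's
  default, the "type 7" rule). Alternative estimators move the Tukey
  fences by under one count at realistic sample sizes.
- Standard deviations: sample form (n − 1) everywhere, fixed for
  reproducibility; at pool size 110 the difference from the population
  form is negligible.
- Label intervals are half-open `[start, end)` at 1 s resolution.
- Range filtering retains exactly [0, 255]; the fence filter then retains
  `CLO ≤ v ≤ CUO`, per goat and per axis, in that order.
- Zero-denominator metrics are defined as 0 and flagged on the report.
- Degenerate inputs raise typed errors (`InsufficientDataError`,
  `SingleClassError`, `EmptyClassError`, ...) rather than returning NaN.

## The synthetic herd

The generator's defaults are the study conditions: 17 pregnant does; a
single contiguous labor episode per doe of 30 min of `labor_lateral`
beginning at onset = birth − 90 min (so detections lead first birth by
roughly the 90 min onset lead); counts encoded with 0 g ↦ 128 and
64 counts/g, both configurable; dual-rate sampling (every active second;
one end-stamped record per completed 10 s of inactivity); optional
corruption of one axis per record to [−20, −1] ∪ [256, 300] for the range
filter to catch.

Behavior is a per-second Markov chain over six states with dwell times of
minutes. Two modeling points matter:

- `inactive_rest` is quiet lateral recumbency (gravity on Z): herds
  contain ordinary side-lying unrelated to labor, so the classifier must
  separate labor from normal lying by movement, not posture alone.
- Movement tilts the leg: each second the gravity vector rotates in the
  sensor's sagittal (x–z) plane by |N(0, `tilt_deg_per_count` ×
  jitter_sd)| degrees with a random off-axis sign (default 1°/count, so
  walking sweeps ~12° and labor ~15°). Without this, rigid postures leave
  the high-x/high-z quadrant empty of training data and a tree may assign
  that unobserved region arbitrarily — an artifact no real dataset
  exhibits, because swinging legs populate intermediate orientations.

The activity flag emulates an undocumented motion trigger: a second is
active when the movement-axis jitter exceeds a per-state threshold chosen
so the marginal active probability equals the state's `activity_prob`.

What the simulator does **not** emulate: circadian structure in lying
bouts, gait periodicity and impact spectra, litter-size effects on pain
intensity, sensor detachment/transmission loss, and between-goat
temperament differences. Consequently the synthetic classes separate more
cleanly than field data (tree accuracy ≈ 0.98 here), the synthetic
non-labor LPI level is lower than a barn's, and CRV grows monotonically
with window length on synthetic herds (labor windows gain quadratically),
so synthetic calibration tends to choose the longest candidate window
where the field study found an interior optimum at 10 min. Passing the
simulation tests therefore demonstrates that the pipeline's *mechanics*
(counting, statistics, threshold logic, end-to-end recovery of planted
labor episodes) are correct — not that field-scale accuracies or lead
times transfer to a specific barn.

## Design choices that were genuinely open

- **Non-labor pool construction**: descriptions of the pool differ between
  the calibration narrative ("non-parturition behaviors prior to
  parturition") and the threshold computation ("the 24 h preceding
  parturition"); implemented as all labor-free pre-birth windows, with
  `pool ∈ {pooled_topk, per_goat_topk}` as a knob.
- **Episode placement**: the labor episode occupies
  `[birth − lead, birth − lead + len)`; with the default 90/30 the doe is
  in labor posture for 30 min and then delivers an hour later. Lead and
  length are configurable because real onset variability is large.
- **SVM kernel**: RBF by default (the class boundary is non-linear), a
  config knob otherwise.
- **One event per goat per day**: alarm semantics after the first crossing
  are an operational choice; re-alarming adds nothing once a manager is
  notified.

## Known limitations

- A `mean + 3 sd`-of-top-k threshold lies, for light-tailed window
  statistics, within the fluctuation range of the sample maximum, so
  labor-free days can occasionally produce a marginal crossing (across
  simulation seeds: 0–2 per 17 goat-days, each within a few percent of
  TCKG). The field study's clean non-parturition record shares this
  knife-edge structure.
- MDV on synthetic herds is tight (sd ≈ 1 min) because every simulated doe
  expresses the same episode; field lead-time spread is far larger.
- Per-goat adaptive thresholds and multiple-testing control are out of
  scope, as is any modeling of litter size.

## Problem sizes

Tests and the acceptance script simulate 17 does × 26 h at 1 s resolution
(≈ 1.6 M behavior-seconds, ≈ 0.4 M records), train on up to 3938 samples
per class, calibrate over four window lengths at 60 s stride, and detect
over 12 h parturition days with the preceding stream as the labor-free
control. One full run takes a few seconds on one CPU.
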
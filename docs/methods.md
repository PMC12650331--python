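# Methods

This note documents the models and procedures implemented in `alarmscape`,
the defaults chosen where the underlying analysis left details open, and
what the synthetic cohorts do and do not establish.

## Alarm episode model

A threshold alarm is modeled as a *maximal run* of consecutive samples on
which one signal violates one side of its age-specific limit.

- **Strict violation.** A sample alarms iff `value > upper` or
  `value < lower`. A value exactly at the limit is treated as normal: the
  tabulated cut-offs are limits of the normal range, and "crossing" a
  limit means exceeding it.
- **Gaps terminate runs.** A missing sample (sensor disconnection) or a
  timestamp gap wider than the sampling interval ends the episode.
  Bridging gaps would fabricate alarm time that was never observed; the
  cost is that a one-sample dropout inside a long violation splits it in
  two, which the tests exercise explicitly.
- **Duration = member samples × interval.** A single violating sample at
  1 Hz yields a 1 s episode. The alternative (`end − start`) gives 0 s for
  single samples and breaks the conservation invariant that summed
  episode durations equal the violating-sample count times the interval.
- **Representative value = run median** (configurable: mean, extremum).
  The value recorded for an episode must reflect where the signal sat, not
  which limit it crossed — the pre-event clusters live beyond the
  cut-offs (e.g. ECGRR 40–60 against a limit of 40) — and the median is
  robust to single-sample spikes.

### Age bands

Cut-off tables partition age in half-open month intervals: WHO
[0, 12), [12, 36), [36, ∞); GOAL3 [0, 12), [12, 36), [36, 48), [48, ∞).
The WHO table defines no band above 4 years, so its top band is extended
upward (a warning is emitted past 60 months); neonates use the "<1 year"
band, which has no neonate-specific limits. Exactly-12-month-olds fall in
the 1–3 year band by the half-open convention.

## Pre-event windowing

Episodes belong to the window iff their **start** lies in
[*t*₍event₎ − 8 h, *t*₍event₎); episodes are not split across the window
edge or across segment boundaries (durations are almost all < 30 s, so
assignment-by-start loses essentially nothing). Patients with several
events are anchored at the earliest. Event-free patients get a
pseudo-anchor at the recording midpoint (configurable: recording end);
they need *some* window for feature parity, and the midpoint avoids the
end-of-recording censoring that discharge introduces. Segment 1 is the
earliest ([−8 h, −6 h)); four 2 h segments by default. No debouncing is
applied: violations separated by a single in-range sample are distinct
episodes.

## Density-based clustering

DBSCAN is implemented from first principles (it is the analytical core of
the pattern-extraction step, and the test suite checks it against both a
brute-force density-connected-components oracle and scikit-learn's
implementation):

- core point: ≥ `min_pts` points, itself included, within Euclidean
  distance `eps`;
- clusters: maximal density-connected sets; border points (non-core within
  `eps` of a core) join the lowest-id adjacent cluster, making the
  labeling deterministic for a fixed input order;
- everything else is noise.

Defaults: `min_pts = 10`; `eps = 0.5` after per-dimension standardization
of the (value, duration) coordinates within each group. The radius has no
stated value in the source analysis; standardizing first makes one number
meaningful across signals whose native scales differ by an order of
magnitude, and 0.5 SD is tight enough to isolate a planted burst from
scattered artifact alarms. The clustering space is 2-D (value, duration)
because that is the plane in which pre-event alarm clouds are described; a
1-D value-only mode is available (`space="value"`).

Groups with fewer than `min_pts` alarms skip clustering and take the mode
over all points — otherwise every sparse group would be all-noise and
yield no feature. Likewise, if clustering labels everything noise, the
mode falls back to all points.

**Modal features.** The feature of a group is the mode of the values (and
of the durations) within the largest non-noise cluster; ties are broken
toward the value closest to the group median, then toward the smaller
value. The tie rule is this package's choice — a bare mode is undefined
on ties — and the closest-to-median rule keeps the feature central rather
than letting dictionary order decide. The mode is never replaced by an
average: features are observed alarm values by construction.

## Classification

Three-class problem: `none`, `death_cpr_picu` (death, CPR and PICU
transfer pooled), `sepsis`. The pooled death class matches how outcomes
are grouped clinically in this setting; a two-class CIE-vs-none reading
would discard the event-free cohort's role as controls. Feature vectors
have 4 entries per signal-bound group (modal value, modal duration, alarm
count, presence flag) × 5 groups; absent groups are zero-filled with the
presence flag marking them, since "no alarms in this channel" is itself
informative. Balancing subsamples the `none` class (seeded) to the event
count.

The 70/30 split is stratified by label and grouped by patient: each class
is shuffled and split separately, every class with ≥ 2 members appears in
both partitions, and `train_and_evaluate` refuses partitions that share a
patient. Families and hyperparameters: random forest (200 trees, Gini,
unlimited depth), SVM (RBF, C = 1.0, gamma = "scale", probability
outputs, features standardized with train-fitted parameters — RBF kernels
need comparable scales; trees take raw features), decision tree (Gini,
unlimited depth); estimator seeds default to 42. AUC is one-vs-rest per
reported class plus a micro average; a class absent from the test
partition is reported as undefined with a reason, never as zero. Note
that the micro average is biased above 0.5 under label permutation when
class priors are unequal (probability columns track the priors), so the
chance-behavior tests average the per-class AUCs, whose null expectation
is exactly one half.

## Synthetic cohort generator

The generator emulates the *structure* of high-dependency-unit
monitoring, not its physiology:

- **Sampling**: 1 Hz, ≥ 24 h per patient (shorter records are allowed
  only via an explicit smoke-test flag). Time is an epoch-seconds axis;
  calendar handling is out of scope.
- **Cohort mix** (defaults): 31% CIE prevalence; death:sepsis 73:46 among
  modeled events; ages 0.14% neonatal (< 1 month), 42.61% infant,
  57.25% pediatric (1–5 y), uniform within each band; 58% male.
- **Baseline signals**: mean-reverting random walks (AR(1), reversion
  0.01/step; innovation SDs 0.6 bpm, 0.4 breaths/min, 0.15%) around the
  midpoint of the WHO normal band for the patient's age (97% for SPO2,
  which has no upper limit), clipped inside the intersection of the WHO
  and GOAL3 bands with a 2-unit margin and rounded to integers as
  monitors report them. A healthy stream therefore never alarms under
  either table, which makes the false-positive tests sharp.
- **Planted pre-event patterns**: for each event patient, each
  signal-bound pattern spec injects Poisson(burst_rate × window) episodes
  at uniform times in the 8 h before the event, with integer values
  uniform in the pattern's value range, constant within an episode, and geometric
  durations around 12 s (clipped to [2, 120] samples) so most alarms last
  under 30 s. The default ranges are the observed pre-event clusters per
  organization and event type (WHO death: ECGRR upper 40–60 / lower 0–20,
  ECGHR lower 80–85 / upper 140–160, SPO2 85–90; WHO sepsis: ECGRR upper
  40–50 / lower 0–20, ECGHR upper 150–180, SPO2 85; GOAL3 analogues).
  The GOAL3 SPO2 cluster sits at the 90% limit itself; since a value at
  the limit never alarms under strict violation, the planted range is
  [88, 90]. Note that a planted value need not violate the cut-off of
  every age band (e.g. ECGHR 140–160 does not alarm for infants, whose
  upper limit is 160); recovery statistics are computed over alarms that
  actually fired, whose values still lie inside the planted range.
- **Artifacts**: event-free patients receive brief (< 30 s) excursions
  just beyond the WHO limits (1–8 units past, split over the six
  signal-bound slots) at ~2/h — crying/coughing analogues that give the
  control class a realistic nonzero alarm load.
- **Dropout**: each sample is missing independently with probability 2%
  by default; the same mask hits all three signals, as a disconnection
  drops the whole frame.
- **Determinism**: per-patient streams are seeded from a spawned seed
  sequence, so a (config, seed) pair reproduces the cohort byte for byte.

**What the simulator does not model** — and what passing tests therefore
do not show: inter-signal coupling during deterioration (signals are
independent), waveform morphology, gradual physiological drift toward an
event (patterns appear as bursts, not trends), age-dependent artifact
profiles, and the "other" event types (transfusion, convulsion, …) that a
real cohort contains. Classifier accuracies on synthetic cohorts are
properties of the planted separation, not forecasts of real-ward
performance; real-data accuracies cannot be recomputed without the
original hospital recordings, so the harness instead guarantees the
report schema (per-class precision/recall/F1, accuracy, AUC, confusion
matrix) into which real data could be dropped.

## Pipeline and reproducibility

The orchestrated run derives each stage's seed as
`master_seed + stage ordinal` (simulate = 0 … train = 4) so stages can be
re-run independently with identical randomness. All interchange is CSV
(timestamps as epoch seconds) plus JSON reports; the run manifest records
the config snapshot, stage seeds, SHA-256 checksums of every output and
wall-clock times, and re-running a config reproduces identical checksums.

### Problem sizes

The reference synthetic cohort used throughout the tests and the
acceptance script is 238 patients × 24 h at 1 Hz (≈ 62 M samples cohort-
wide, generated and processed patient-by-patient), the size of the
balanced analysis cohort. Oracle comparisons run on 1,000 random series
(length ≤ 50) for episode detection and 200 random point sets (n ≤ 40)
for DBSCAN — small enough for the deliberately naive oracles to stay
readable. The permutation null uses 100 label shuffles with a 50-tree
forest, a size at which the null mean is estimated to about ±0.01.

## Known limitations

- The WHO table's top band is an extrapolation above 4 years.
- Per-patient clustering needs ≥ 10 windowed alarms per group to engage
  DBSCAN; sparser groups use the raw mode, which is noisier.
- The pseudo-anchor for event-free patients is a convention; alarm
  features for controls depend (weakly) on it.
- `SVC(probability=True)` is deprecated in recent scikit-learn in favor
  of explicit calibration wrappers; the pinned behavior is retained here
  because the stated SVM configuration includes probability outputs.
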
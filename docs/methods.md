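# Methods

This note documents the models, defaults and design decisions behind
`larvaction`, and what the simulator-based tests do and do not demonstrate.

## Problem setting

Dorsal-view tracking of *Drosophila* larvae yields, per animal, a timestamped
midline ("spine") series: `T` frames of `S` ordered head-to-tail points in
arena coordinates. The package turns these series into (a) a continuous
latent representation of short posture sequences and (b) a per-timestep
discrete action readout over the seven-class dictionary `crawl`, `bend`,
`back`, `hunch`, `roll`, `stop`, `small_action`, and then compares
populations of tagged animals statistically.

## Posture windows

A window is the track slice of `window_seconds` (default 2 s) centred on a
timestep, linearly resampled to `L = 20` uniform time samples, with each
frame's midline resampled to `S = 5` points uniform in arc length. Only the
2-s horizon is fixed by the tagging approach itself; `L` and `S` are the
smallest values that preserve peristaltic and bend dynamics at the ~10 Hz
frame rates typical of larval tracking, and both are configuration-exposed.

Normalization is per-window (no track-level statistics are needed at
prediction time): subtract the window centroid, divide by the mean body
length over the window, rotate so the head-to-tail axis of the first time
sample lies along +x. The result is invariant to translation, rotation and
uniform scaling of the raw track (verified to 1e-6 in tests) and is
idempotent. Note a consequence used when interpreting results: the *level*
of body-length contraction is normalized away; only length *changes within
the window* remain visible.

Boundary and gap handling: timestamps are authoritative and never assumed
equispaced. Windows overlapping the track ends are completed by replicating
the first/last frame (so every timestep gets a prediction); a window is
invalidated — its timestep left untagged — when the raw sampling gap inside
its span exceeds half the window length. Head/tail orientation is taken from
the file (head-first convention); there is no automatic head detection.

Each window can carry an extended target of `1 + 2*context_windows`
window-lengths (default 3: one past, centre, one future), normalized with
the centre window's transform.

## Autoencoder

The encoder is `flatten(L*S*2 = 200) -> dense(64, tanh) -> dense(10)`; the
decoder mirrors it up to the extended length (600 features). This is
deliberately the smallest architecture that makes the latent space useful
(positive silhouette between action clusters; crawl-vs-bend linear probe
accuracy > 0.9); all sizes are configuration-exposed. The latent dimension
`D = 10` and single context window are package defaults, not claims about
any other implementation.

Pre-training minimizes MSE of the extended reconstruction, centre and flanks
equally weighted, with Adam (lr 1e-3, batch 64), holding out 10% of windows
and restoring the best-validation weights. Everything is float64 numpy and
bit-reproducible given a seed; the CLI's `--deterministic` flag pins seeds
and ordering (numpy's sequential kernels are already deterministic, so no
thread pinning is required). Weight initialization is Xavier/Glorot uniform
throughout, which doubles as the "no pre-training" baseline.

## Tagger

A linear softmax head maps `Z` to class probabilities; training uses
cross-entropy with inverse-frequency class weights (class imbalance is the
norm in behavioural data; the weighting is standard and documented rather
than prescribed by the approach). Two fine-tuning choices matter and were
genuinely open:

- **Discriminative learning rates.** The encoder (when not frozen) is
  updated at `encoder_lr_fraction = 0.15` of the head's learning rate.
  A randomly-initialized head sends large, initially uninformative gradients
  into the encoder; at full learning rate these destroy pre-trained features
  before the head has settled, cancelling the benefit of pre-training.
- **Step-based budget.** The budget is `max(epochs * batches_per_epoch,
  min_steps)` Adam steps with `min_steps = 1500`, so a 60-window training
  set still gets a full optimization run rather than 60 steps. Larger
  datasets naturally earn proportionally more steps.

Predictions are per-window, mapped to the window's centre timestep, with no
temporal smoothing of the argmax sequence (a smoothing hook exists, default
off): window-local decisions are a known source of inter-tagger
disagreement, and no principled smoothing rule is available. Ties resolve to
the first class in dictionary order. `small_action` has no priority rules —
it is a class like any other. Invalidated windows yield an explicit
"untagged" marker, never a guess.

## Simulator

The simulator is a kinematic cartoon, not a biomechanical model. Its job is
to give the learning and statistics modules distinguishable, labelled
classes with controllable difficulty. Midline kinematics (body length 4 mm,
10 Hz, S = 5):

- `crawl`: travelling longitudinal compression wave (amplitude 6% of
  segment length, 1.5 Hz) plus net head-first displacement of 0.15 body
  lengths per cycle; body length oscillates at the wave frequency.
- `back`: the wave reversed, net tail-first displacement at 0.6 mm/s.
- `bend`: the head half rotates about the neck with a 1-rad amplitude over a
  4-s cast cycle; the centroid barely moves.
- `hunch`: cyclic rapid retraction — contract 25% of body length at 5 mm/s,
  hold ~0.6 s, re-extend at half speed, rest ~0.4 s. The retraction rate
  exceeds the crawl wave's length-change rate (≈1.9 mm/s) *by construction*,
  and both scale with the phenotype multiplier, so the ordering is
  speed-invariant — slow mutant hunches stay faster than slow crawls.
- `roll`: dorsal-view rolling has no faithful midline signature, so it is
  approximated as alternating-sign body curvature with lateral centroid
  oscillation (0.8 Hz). This is deliberately the weakest, most confusable
  class.
- `stop`: static posture; jitter only (a multiple of the global noise sd,
  so zero-noise stops are exactly static).

Additive Gaussian coordinate noise (default sd 0.1 mm, i.e. 2.5% of body
length — typical tracking noise at screen resolutions) is applied last. Per-
track phenotype multipliers drawn from [0.7, 1.4] emulate slow/fast genetic
lines in the labelled-window generator. Assay simulation draws actions from
a pre-onset mixture until the stimulus onset (default 45 s, 38-s stimulus)
and from a post-onset mixture afterwards, with the first post-onset segment
starting exactly at onset, so action frequencies in a 1-s post-onset window
converge to the mixture.

What the simulator does **not** emulate: contours beyond the midline,
larva-larva contact and track swaps, head/tail detection errors, gradual
behavioural drift, and the real actions' within-class variability beyond
speed scaling. Consequently, passing tests show the pipeline's mechanics and
statistics are correct and that transfer learning behaves as designed on
separable classes; they do not certify accuracy on real screen data.

## Screen statistics

- Counting is larva-level: an animal "performs the action in the window" if
  any of its tagged timesteps in `[t0, t1)` carries the label (frame-level
  counting would conflate action duration with prevalence; the choice is an
  interpretation and is flagged here). `n` counts animals with at least one
  tagged timestep in the window.
- The test is Pearson chi-square on the 2x2 table `[[k_t, n_t-k_t], [k_c,
  n_c-k_c]]`, 1 df, without Yates continuity correction (switchable).
  Degenerate tables (zero margin) give chi2 = 0, p = 1.
- Bonferroni: corrected p = min(1, m*p). `m` defaults to the number of tests
  actually performed; it can be pinned to an external comparison inventory
  (e.g. 471) when reproducing a screen analysed at that multiplicity.
- alpha defaults to 0.05 (an interpretation; only the correction count is
  prescribed by the procedure being emulated).
- Outcomes are three-level: positive/negative difference (direction of the
  proportion difference at corrected p < alpha) or none. Inter-tagger
  agreement counts concordant pairs, effects lost, effects gained, and
  opposite signs.
- macro-f1 excludes untagged entries pairwise and classes absent from both
  truth and prediction.

Calibration checks run the full machinery on simulated assays with a 5-s
onset and 3-s post period (the chi-square only reads the 1-s post-onset
window, so the pre-onset length is statistically irrelevant; generator
defaults keep the 45-s onset): 200 null replicates bound the family-wise
error, and 100 replicates of a 0.1-vs-0.6 hunch mixture at 60 animals/line
with m = 471 measure power.

## Labels on disk

Labels are stored per defined timestep (segments are a write-time
convenience), as a WCON-like JSON document: `units`, `metadata`, `labels`
(ordered names + colours), `data` (per-larva `id`, `t`, per-timestep label
lists, provenance). Keys are sorted on write, so canonical files round-trip
byte-identically; unknown top-level keys are preserved through a passthrough
field. Coordinates in tracking files are carried opaquely (no unit
conversion) since normalization removes scale.

## Problem sizes

Defaults used by the test suite and `scripts/acceptance.py`, chosen as the
smallest sizes at which the measured quantities are stable: 2000 unlabelled
windows / 200 epochs for pre-training; 500 labelled windows per class for
recovery, 100 per class held out; transfer at 10 and 200 windows per class,
5 seeds; 200 null and 100 alternative replicates for the statistics; 60
animals per line in simulated screens.

## Known limitations

- The numpy network is small by design; it is not intended to match any
  external tagger's weights or exact architecture.
- Hunch/stop confusion is the dominant residual error on simulated data:
  once scale is normalized away, a held contraction is indistinguishable
  from a stop, and slow-phenotype hunch cycles can exceed the 2-s window.
- Roll is a 2-D proxy and remains the least faithful class.
- No head/tail disambiguation; files with tail-first spines will be
  mis-normalized.
- Per-window normalization discards absolute size and speed; analyses that
  need them should use the raw tracks.
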
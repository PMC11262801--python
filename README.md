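# larvaction

Action tagging for *Drosophila* larva tracking data.

Large-scale behavioural screens film dozens of larvae from above and keep
only tracked midlines ("spines") and contours, not the video. Downstream
analysis needs a *discrete behavioural readout*: at every timestep of every
track, which archetypal action is the animal performing — forward crawl
(`crawl`), backward crawl (`back`), head cast (`bend`), `hunch`, `roll`,
`stop`, or a catch-all `small_action` for weak/undecided movements? Because
action definitions and tracking hardware keep changing, taggers must be
retrainable, and because expert annotation is expensive, they should learn as
much as possible from *unlabelled* data.

`larvaction` implements that workflow end to end:

- **I/O** for Choreography-style (Multi-Worm Tracker) spine/outline text
  files, FIMTrack-style `table.csv`, and a WCON-like JSON label format.
- **Preprocessing** of raw tracks into normalized 2-s posture windows
  `X_t` (translation-, rotation- and scale-invariant; L=20 time samples x
  S=5 spine points).
- A **self-supervised autoencoder**: `X_t` is compressed to a latent code
  `Z` (D=10) from which an *extended* sequence — one window-length of past
  and of future postures around `X_t` — is reconstructed. Predicting the
  flanks forces `Z` to encode dynamics, not just shape.
- A **tagger**: a softmax head over `Z`, fine-tuned with class-weighted
  cross-entropy; the encoder is updated at a reduced learning rate.
  Per-window predictions map back to each window's centre timestep.
- **Screen statistics**: per-action probability time series, larva counts in
  a 1-s post-stimulus window, Pearson chi-square tests of each line against a
  control with Bonferroni correction, three-level outcomes
  (positive / negative / none), inter-tagger outcome concordance, macro-f1.
- A **kinematic simulator** generating labelled synthetic larvae for all six
  actions (peristaltic crawling waves, head casts, rapid hunches, reversed
  waves, alternating-curvature rolls, stops) with tracking noise and
  slow/fast phenotype variation, so everything is testable offline.

## Worked example

```python
import numpy as np
import larvaction as la

cfg = la.WindowingConfig()          # 2-s windows, L=20, S=5, 1 context window

# unlabelled pool for self-supervised pre-training
rng = np.random.default_rng(0)
pool = []
while len(pool) < 2000:
    steps = [(str(a), float(rng.uniform(2, 4))) for a in rng.choice(la.ACTIONS, 4)]
    track, _ = la.simulate_track(la.SimScript(steps=steps, seed=int(rng.integers(2**31))))
    pool.extend(la.extract_windows(track, cfg)[::2])
encoder = la.pretrain(pool[:2000], la.TrainConfig(epochs=200, seed=0))
print(f"held-out reconstruction MSE: {encoder.history[-1]['val_loss']:.4f}")

# fine-tune a tagger on labelled windows (500 per class) and score it
train_w, train_y = la.make_labelled_windows(cfg, 500, seed=1)
test_w, test_y = la.make_labelled_windows(cfg, 100, seed=2)
tagger = la.train_tagger(encoder, list(zip(train_w, train_y)),
                         la.TrainConfig(epochs=150, seed=0))
from larvaction.tagger import predict_windows
pred = [tagger.dictionary.names[i]
        for i in predict_windows(tagger, test_w).argmax(axis=1)]
print(f"held-out macro-f1: {la.macro_f1(test_y, pred, tagger.dictionary):.3f}")
```

Output:

```
held-out reconstruction MSE: 0.0045
held-out macro-f1: 0.838
```

The reconstruction MSE is on normalized coordinates (body length = 1), far
below the ~0.08 of the constant mean-posture baseline; the macro-f1 of 0.84
over the six simulated classes is dominated by residual hunch/stop confusion
(a held hunch is indistinguishable from a stop once scale is normalized
away), with crawl/bend/back/roll near 1.0.

The same pipeline is available from the shell:

```sh
larvaction simulate -n 20 --seed 1 -o assay/
larvaction pretrain -i assay/ -o encoder/ --epochs 100
larvaction train -i assay/ --encoder encoder/ -o tagger/
larvaction predict -i assay/ --model tagger/ -o tagged/
larvaction compare --line ctrl=tagged_ctrl/ --line mut=tagged_mut/ \
    --control ctrl --window-start 45 -o screen.csv
```

Every subcommand writes a `manifest.json` (configuration + seed + versions)
beside its outputs, and `--deterministic` runs are byte-reproducible.

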
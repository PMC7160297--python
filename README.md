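# spectronet

Reusable pipeline for discriminating two subject groups (ADHD vs healthy
controls) from event-related spectral EEG:

1. **`spectronet.synth`** — synthetic flanker-task cohorts: truncated-normal
   ages, randomized congruent/incongruent trial sequences on the component
   timing grid, and multi-channel 1 s epochs (7 channels, 500 Hz,
   −200…+798 ms) built from 1/f background noise, a sustained alpha
   oscillation (attenuated in the ADHD group), a transient delta–theta burst
   near 100 ms (boosted in ADHD), and an N100-like deflection. An eyes-closed
   resting mode keeps only the tonic alpha effect. Gamma reaction times are
   generated as behavioural colour.
2. **`spectronet.preprocess`** — zero-phase Butterworth band-pass (1–20 Hz)
   and pre-stimulus baseline correction ([−200, 0] ms).
3. **`spectronet.ersp`** — single-trial complex-Morlet spectrograms:
   22 log-spaced frequencies (3–20 Hz), cycle counts linear from 1 to 10,
   power averaged into 20 linear time bins over [0, 800] ms, in dB re 1 µV²,
   stacked per channel → 22×20×7 frames.
4. **`spectronet.nets`** — a small NumPy neural-network framework and the
   three classifier architectures: a CNN with exactly **75106** trainable
   parameters (two conv/pool blocks + 128/64 dense layers, locked by a
   configuration invariant), a 3-layer stacked-LSTM RNN (32 hidden units),
   and a 1024-unit shallow network. Training: Adam (lr 0.001, β₁=β₂=0.9,
   batch 32, ≤600 epochs), N(0, 0.1) weight init, dropout, early stopping on
   the training-loss plateau, optional per-sample weights.
5. **`spectronet.crossval`** — leave-pair-out cross-validation (all
   ADHD×HC pairs), subject scoring by frame-probability averaging with a 50%
   threshold, accuracy and Wilcoxon–Mann–Whitney AUC, inverse-probability
   age weighting from a logistic propensity fit, single-channel ablation,
   and model comparison by t-test.
6. **`spectronet.dream`** — DeepDream-style activation maximization of
   trained models (30 iterations, step 1, mean-|gradient| normalization),
   fold-averaged class maps and the ADHD−HC difference map with band/latency
   summaries.
7. **`spectronet.pipeline` / `spectronet.cli`** — end-to-end orchestration,
   YAML configuration, HDF5/CSV/JSON artifacts, deterministic under a single
   global seed.

Since no clinical recordings ship with this repository, the synthetic module
is a first-class, tested component: every downstream stage is exercised on
generated cohorts whose injected spectral structure the pipeline must
recover.

## CLI

```bash
spectronet simulate  --n-per-group 20 --frames 140 --seed 1 --out run/sim
spectronet preprocess --in run/sim/epochs.h5 --out run/clean.h5
spectronet ersp      --in run/clean.h5 --subjects run/sim/subjects.csv --out run/frames.h5
spectronet evaluate  --arch cnn --frames run/frames.h5 --subjects run/sim/subjects.csv \
                     --epochs 100 --out run/results.json
spectronet train     --arch cnn --frames run/frames.h5 --out run/model
spectronet dream     --models run/model --iters 30 --seeds 8 --out run/dream.h5
spectronet run-all   --desk-scale --seed 1 --out run/all      # end-to-end
spectronet make-fixtures --size tiny --out fixtures/
```

Exit codes: 0 ok, 1 usage error, 2 stage failure. `run-all` also accepts a
YAML config (`--config cfg.yaml`) mirroring `spectronet.pipeline.RunConfig`;
flags override the file.

## Notes

- The CNN's printed parameter total does not pin down its kernel/filter
  hyperparameters; the frozen configuration (conv 3×5×5 same → pool →
  conv 3×3×17 same → pool → dense 128 → 64 → 2) was found by exhaustive
  search over a constrained family so that the total is exactly 75106, and
  is documented as a reconstruction rather than the original.
- Everything is NumPy/SciPy; no GPU or deep-learning framework is required.
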
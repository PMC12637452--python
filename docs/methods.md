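# Methods

## Problem and model

`budcall` quantifies replicative aging of budding yeast (*Saccharomyces
cerevisiae*) from mother-machine time-lapse movies: microfluidic traps hold
each mother cell in the field of view for its whole life while daughters
are flushed away, and a phase image is taken every 15 minutes. The
analysis task is to find the frame of every bud emergence; the count of
emergences over a mother's movie is her replicative lifespan (RLS).

Detection is a two-phase transformer pipeline:

1. **Self-supervised pretraining.** A masked auto-encoder (MAE) is trained
   on single-cell crops. Each 64x64 crop is split into non-overlapping
   square patches, a large random fraction (default 75%) is hidden, the
   visible patches (plus fixed 2-D sinusoidal positional embeddings) pass
   through a transformer encoder, and a lighter decoder reconstructs the
   full image from the encoded latents with a learnable mask token standing
   in at every hidden position. The loss is mean squared error on the
   masked patches (optionally all patches). Reconstruction under heavy
   masking forces the encoder to internalize cell morphology without any
   division labels.

2. **Supervised division detection.** The pretrained encoder (decoder
   discarded) encodes each frame of an 11-frame window (frame of interest
   +/- 5) independently, with no masking and a learnable classification
   token prepended; the classification-token outputs, plus sinusoidal
   temporal embeddings of the window position, pass through a second
   transformer with full self-attention across the 11 positions. Every
   position emits two logits (budded vs. non-budded); the softmax division
   probability at the center position is the window's prediction.
   Training minimizes class-weighted cross-entropy on the center frame.

3. **Post-processing.** Sliding the window over a movie gives frame-wise
   division probabilities. These are thresholded (default 0.5) and maximal
   runs of positive calls are collapsed to a single event at the run start
   (a bud stays visible for several frames, so one emergence produces a
   run of positives across overlapping windows). The number of events is
   the predicted RLS.

4. **Evaluation.** Predicted and ground-truth event timelines are matched
   one-to-one within a +/- k frame tolerance. Events lie on a line and each
   prediction's admissible truths form an interval, so a sorted greedy
   sweep attains the maximum-cardinality matching (cross-checked against
   exhaustive enumeration in the tests). Reported metrics: match rates at
   exact/+/-1/+/-2 tolerance (fraction of truth events matched; a switch
   reports the per-prediction denominator instead), pooled
   precision/recall/F1 at +/-1, and lifespan agreement as the OLS fit of
   predicted on true RLS (R^2 = squared correlation of that fit, slope,
   intercept, and the sample SD of predicted minus true, in divisions).

## Training machinery

All models run on a small reverse-mode automatic-differentiation engine
over numpy (`budcall._tensor`), gradient-checked against central finite
differences. Optimization uses Adam with decoupled weight decay (weight
matrices decay; biases, layer-norm gains, and learnable tokens do not), a
learning-rate schedule with linear warmup followed by cosine annealing
with periodic restarts (`lr_at_step` is the closed form: ramp 0 -> base
over the warmup steps, then base * (1 + cos(pi t/T))/2 within each restart
period of T steps), gradient accumulation (micro-batch losses scaled by
their share of the pooled batch, making the accumulated update equal to
the large-batch update to float32 tolerance), and an exponential moving
average of the parameters (shadow <- decay * shadow + (1 - decay) * live
after every optimizer step, decay 0.999). Pretraining retains the
checkpoint with the lowest held-out reconstruction loss; fine-tuning
retains the epoch with the highest event-level F1 at +/-1 frame on
held-out cells. Both splits are by cell, never by frame: temporally
adjacent crops and overlapping windows are near-duplicates, so a per-frame
split would leak.

There is no dropout or other stochastic regularization at train time; with
a fixed seed (masking, initialization, shuffling, and splits all derive
from it) every run is bit-reproducible in a single-threaded setting.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `frame_interval_min` | 15 | minutes between frames |
| `crop_size_px` / `resized_px` | 224 / 64 | raw crop edge; model input edge |
| `half_window` | 5 | frames each side of the frame of interest (11 total) |
| `patch_size_px` | 8 | token edge on the resized image (64 tokens) |
| `mask_ratio` | 0.75 | fraction of patches hidden during pretraining |
| `ema_decay` | 0.999 | parameter EMA decay per optimizer step |
| `probability_threshold` | 0.5 | division call threshold on the softmax |
| `merge_gap_frames` | 0 | zeros tolerated inside one collapsed run |
| `class_weighting` | auto | positive-class weight = negatives/positives |

Design points that were genuinely open and how they were settled:

- **Patch size.** 8 px on 64-px inputs (64 tokens) as the standard ViT
  granularity at this resolution; configurable. The bundled benchmark uses
  16 px (16 tokens) to keep CPU runtimes in minutes.
- **Window boundaries.** Windows that extend past the movie replicate the
  first/last frame rather than zero-padding, so divisions near the
  boundaries are detectable without an artificial intensity step.
- **Positional embeddings.** Fixed 2-D sinusoidal (row/column halves) for
  determinism; a 1-D fallback covers embedding widths not divisible by 4.
- **Loss support.** Masked patches only by default, following the MAE
  convention the architecture derives from; supervision is applied to the
  center position of the window only (per-position logits exist and an
  all-position auxiliary loss is available behind config).
- **Two logits per frame.** A per-frame "binary logit converted via
  softmax" is read as a 2-way softmax over budded/non-budded logits; a
  softmax over one scalar is degenerate.
- **Encoder transfer.** The EMA weights of the best pretraining checkpoint
  seed the detector by default (switchable to the live weights); the full
  encoder is updated during fine-tuning unless frozen.
- **Event time within a run.** Run start, because bud emergence is the
  biologically meaningful instant; run midpoint available.
- **Match-rate denominator.** Ground-truth events by default; the
  per-prediction rate is also computed and reported in the verbose field.
- **Death calling.** Prediction sums events over the whole provided movie;
  deciding where life ends is left upstream of this package.

## The synthetic benchmark

Real mother-machine data cannot ship with the package, so every stage is
validated on a simulator (`budcall.synthetic_data`) whose ground truth is
exact: a stationary elliptical mother sits in a trap; at each scheduled
division frame a bud appears on the trap side of the mother, grows for
`bud_growth_frames` frames (default 4), and vanishes (daughter flushed).
Schedules are an arithmetic progression (`first_bud_frame`, period mean 6
frames ~ a 90-minute cell cycle) with optional integer-rounded Gaussian
period jitter, truncated at the movie end and, when the death model is
enabled, at a per-cell replicative lifespan drawn from a normal
distribution — lifespan heterogeneity across mothers is the defining
feature of RLS data and is what makes lifespan-agreement statistics
informative. Two aging morphologies mirror the two canonical wild-type
trajectories: `mode1` cells switch to elongated daughters (aspect ratio
>= 2) after a configurable fraction of their lifespan; `mode2` cells bud
round daughters throughout. Scenes are lightly smoothed and Gaussian
imaging noise (SD 0.05 on a 0.1 background against 0.6-0.8 cell
intensities) is added; all randomness derives from the config seed, and
cohorts derive per-cell seeds as seed + index.

What the simulator does **not** emulate: phase-contrast optics (halos,
interference rings), focus drift, segmentation/tracking errors, debris and
trap clogging, cell-death morphology, fluorescence channels, and the
gradual morphological drift of aging mothers. Passing benchmarks therefore
demonstrates that the architecture, training loop, post-processing, and
metrics are correct and that pretraining transfers on in-distribution
imagery — not that the model reaches any particular accuracy on real
microscopy.

The reference benchmark (`budcall.benchmark`, also what
`scripts/acceptance.py` runs) uses 40 training + 10 held-out mothers,
170-frame movies, lifespans ~ N(20, 5^2), alternating aging modes, a
16-px-patch encoder (embed 32, depth 2, 2 heads), 15 pretraining epochs on
every second frame of the training movies, and 4 fine-tuning epochs.
These sizes are the package's desk-scale choice; they are not the point at
which accuracy saturates.

## Numerical notes and limitations

- Per-image z-score normalization precedes tokenization (constant images
  map to zeros with a float32-safe tolerance); the simulator's background
  offset is thereby removed.
- Resizing is bilinear and skipped entirely when sizes already match, so
  64->64 is an exact identity.
- Greedy matching breaks ties toward the earlier truth frame; the
  timeline CSV schema is identical for predictions and annotations so the
  two are directly comparable.
- `rls_agreement` requires >= 3 cells and non-constant true lifespans;
  cohort reports carry NaN lifespan statistics when that fails rather than
  discarding the event-level metrics.
- The autodiff engine is single-threaded-deterministic and CPU-only; it
  supports exactly the ops these models need and does not aim at GPU-scale
  training (the hundreds of epochs used for full-scale pretraining are a
  config value, not something the bundled tests run).
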
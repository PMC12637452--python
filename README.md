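# budcall

Budding-event detection and replicative lifespan quantification for
single-cell yeast time-lapse movies.

## What this is for

Replicative lifespan (RLS) — the number of daughters a mother cell of
*Saccharomyces cerevisiae* produces before she stops dividing — is the
central measurement of yeast aging studies. Microfluidic "mother machine"
devices trap hundreds of mothers for their whole lives while a microscope
images each trap every 15 minutes, but turning those movies into lifespans
has traditionally meant a human annotating the exact frame of every bud
emergence: tens of thousands of clicks per experiment. `budcall` automates
that step for anyone who already has per-cell crops and tracking tables
(e.g. from Cellpose + a tracker) and wants frame-accurate division
timelines and lifespans with a small annotation budget.

## The method

Two phases, then post-processing:

1. **Masked-auto-encoder pretraining** (no labels). Each 64x64 crop is
   tokenized into patches; 75% are hidden; a transformer encoder sees only
   the visible patches and a lighter decoder reconstructs the image from
   the latents plus a learnable mask token at each hidden position,
   minimizing masked-patch MSE. This teaches the encoder cell morphology
   from unannotated frames, which is what makes the supervised stage
   label-efficient.
2. **Temporal division detection** (few labeled cells). For every frame
   *t*, the 11-frame window *t* ± 5 is encoded frame-by-frame with the
   pretrained encoder (classification token prepended, no masking); a
   second transformer attends across the 11 positions (with sinusoidal
   temporal embeddings) and emits two logits — budded vs. non-budded — per
   position. softmax at the center position gives p(division at *t*).
3. **Post-processing.** Probabilities are thresholded and consecutive
   positive calls are collapsed into single division events (one bud spans
   several windows); events per movie = predicted RLS.

Evaluation mirrors standard practice for event timelines: maximum
one-to-one matching of predicted to true events within ±k frames, match
rates at exact/±1/±2, pooled F1 at ±1, and OLS agreement (R², slope,
error SD) between predicted and true lifespans.

Because real annotated microscopy cannot ship with the package, a
simulator (`budcall.synthetic_data`) renders trap-like movies — a
stationary mother, periodic bud emergence and daughter flushing, two
aging-mode daughter morphologies (late elongated vs. persistently round),
per-cell lifespans, imaging noise — with exact ground-truth schedules, so
the whole pipeline is testable end-to-end. Everything runs on a small
numpy autodiff engine; no GPU or deep-learning framework is required.

## Worked example

```python
from budcall.benchmark import (
    make_benchmark_cohort, pretrain_on_cohort, finetune_on_cohort,
    evaluate_on_cohort,
)

train_movies, train_truths = make_benchmark_cohort(12, seed=1, id_prefix="train")
test_movies, test_truths = make_benchmark_cohort(4, seed=700, id_prefix="test")

mae_state = pretrain_on_cohort(train_movies, seed=0, epochs=10)
state = finetune_on_cohort(train_movies, train_truths, seed=0,
                           mae_state=mae_state, epochs=3)
report = evaluate_on_cohort(state.best_model(), test_movies, test_truths)
print(report.format_table())
```

Output (a few minutes on one CPU):

```
tolerance   match rate (of truth)
exact        98.8%
+/-1 frame  100.0%
+/-2 frames 100.0%

F1 (+/-1 frame tolerance): 0.994
RLS agreement: R^2=0.997 slope=0.868 error SD=0.50 divisions (4 cells)
```

Reading it: 98.8% of the held-out cells' true bud emergences were matched
by a prediction on the exact frame and all within one frame; pooled
precision/recall give F1 0.994 at the ±1-frame tolerance; per-cell
predicted lifespans track the true ones (R² 0.997) with an error SD of
half a division.

The same workflow is available from the shell:

```bash
budcall simulate --config run.yaml --outdir data/
budcall pretrain --config run.yaml --data-dir data/ --outdir mae/
budcall finetune --config run.yaml --data-dir data/ \
        --mae-checkpoint mae/mae_checkpoint.npz --outdir det/
budcall predict  --config run.yaml --data-dir data/ \
        --detector-checkpoint det/detector_checkpoint.npz --outdir pred/
budcall evaluate --pred pred/events.csv --truth data/annotations.csv \
        --outdir eval/
```

On real data, skip `simulate` and point `--data-dir` at a directory with
`movies/*.tif` (one multi-page TIFF per mother, one page per frame) and an
`annotations.csv` (`cell_id,division_frame`) for the labeled training
cells; per-frame crop centers can come from a tracking table
(`cell_id,frame_index,center_x,center_y,area,aspect_ratio`).

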
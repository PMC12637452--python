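"""Reference synthetic benchmark: the full simulate -> pretrain -> finetune
-> predict -> evaluate protocol at desk scale.

The benchmark emulates a wild-type aging experiment: mother cells imaged
every 15 minutes, budding every ~6 frames with one frame of period jitter,
daughters visible for four frames, half the cohort aging in each
morphology mode, and per-cell replicative lifespans drawn around 20
divisions (SD 5) so lifespan scatter is informative. Models are tiny
(16-px patches, 2-block encoders) so the whole protocol runs in minutes on
one CPU; the quantities it reports are therefore analogs of a full-scale
study, not reproductions of one.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .detector import (
    DetectorConfig,
    DivisionDetector,
    StackDataset,
    finetune,
    predict_movie,
)
from .evaluation import EvalReport, evaluate_cohort
from .events import PostprocessConfig, timeline_from_probabilities
from .mae import MAEConfig, MAEState, pretrain
from .preprocessing import CropConfig
from .synthetic_data import SimulationConfig, generate_mother_movie

__all__ = [
    "benchmark_simulation_config",
    "benchmark_mae_config",
    "benchmark_detector_config",
    "benchmark_crop_config",
    "make_benchmark_cohort",
    "pretrain_on_cohort",
    "finetune_on_cohort",
    "evaluate_on_cohort",
    "run_end_to_end",
    "run_transfer_comparison",
]

_N_FRAMES = 170  # fits lifespans up to ~27 divisions at a 6-frame period


def benchmark_simulation_config(aging_mode: str = "mode1",
                                seed: int = 0) -> SimulationConfig:
    return SimulationConfig(
        n_frames=_N_FRAMES,
        first_bud_frame=5,
        budding_period_mean=6.0,
        budding_period_jitter=1.0,
        bud_growth_frames=4,
        aging_mode=aging_mode,
        mode1_switch_fraction=0.6,
        lifespan_mean=20.0,
        lifespan_sd=5.0,
        noise_sd=0.05,
        background_level=0.1,
        seed=seed,
    )


def benchmark_mae_config(seed: int = 0, **overrides) -> MAEConfig:
    base = dict(
        patch_size_px=16, embed_dim=32, depth=2, n_heads=2,
        decoder_embed_dim=16, decoder_depth=1, decoder_n_heads=2,
        mlp_ratio=2.0, epochs=15, base_lr=1.5e-3, warmup_epochs=2,
        cosine_restart_period=20, batch_size=64, seed=seed,
    )
    base.update(overrides)
    return MAEConfig(**base)


def benchmark_detector_config(seed: int = 0, **overrides) -> DetectorConfig:
    base = dict(
        patch_size_px=16, embed_dim=32, depth=2, n_heads=2, mlp_ratio=2.0,
        temporal_depth=2, temporal_heads=2, epochs=4, base_lr=1e-3,
        batch_size=32, seed=seed,
    )
    base.update(overrides)
    return DetectorConfig(**base)


def benchmark_crop_config() -> CropConfig:
    return CropConfig(crop_size_px=64, resized_px=64, patch_size_px=16)


def make_benchmark_cohort(n_cells: int, seed: int, id_prefix: str = "cell"):
    """Cohort with alternating aging modes and per-cell seeds."""
    movies, truths = [], []
    for i in range(n_cells):
        mode = "mode1" if i % 2 == 0 else "mode2"
        cfg = benchmark_simulation_config(aging_mode=mode, seed=seed + i)
        movie, truth = generate_mother_movie(
            cfg, cell_id=f"{id_prefix}_{i:03d}"
        )
        movies.append(movie)
        truths.append(truth)
    return movies, truths


def pretrain_on_cohort(movies, seed: int, frame_stride: int = 2,
                       **overrides) -> MAEState:
    crops = np.concatenate([m.frames[::frame_stride] for m in movies])
    cell_ids = np.concatenate(
        [[m.cell_id] * len(m.frames[::frame_stride]) for m in movies]
    )
    return pretrain(crops, benchmark_mae_config(seed=seed, **overrides),
                    cell_ids=cell_ids)


def finetune_on_cohort(movies, truths, seed: int, mae_state=None,
                       **overrides):
    cfg = benchmark_detector_config(seed=seed, **overrides)
    if mae_state is None and cfg.encoder_init == "from_mae":
        cfg = replace(cfg, encoder_init="random")
    dataset = StackDataset(movies, truths, benchmark_crop_config())
    return finetune(dataset, cfg, mae_state=mae_state)


def evaluate_on_cohort(model: DivisionDetector, movies, truths,
                       post: PostprocessConfig | None = None) -> EvalReport:
    crop = benchmark_crop_config()
    predictions = [
        timeline_from_probabilities(
            predict_movie(m, model, crop).probabilities, post,
            cell_id=m.cell_id,
        )
        for m in movies
    ]
    return evaluate_cohort(predictions, truths)


def run_end_to_end(seed: int = 0, n_train: int = 40, n_test: int = 10):
    """Full protocol; returns (report, untrained_report, mae_state, state).

    Train and test cohorts use disjoint seed ranges; the untrained baseline
    is the same architecture with random weights and no fine-tuning.
    """
    train_movies, train_truths = make_benchmark_cohort(
        n_train, seed=seed * 1000 + 1, id_prefix="train"
    )
    test_movies, test_truths = make_benchmark_cohort(
        n_test, seed=seed * 1000 + 500_000, id_prefix="test"
    )
    mae_state = pretrain_on_cohort(train_movies, seed=seed)
    state = finetune_on_cohort(train_movies, train_truths, seed=seed,
                               mae_state=mae_state)
    report = evaluate_on_cohort(state.best_model(), test_movies, test_truths)
    untrained = DivisionDetector(
        benchmark_detector_config(seed=seed, encoder_init="random")
    )
    untrained_report = evaluate_on_cohort(untrained, test_movies, test_truths)
    return report, untrained_report, mae_state, state


def run_transfer_comparison(seed: int = 0, n_labeled: int = 10,
                            n_test: int = 10, seeds=(0, 1, 2),
                            mae_state: MAEState | None = None):
    """Held-out F1(+/-1) with pretrained vs random encoder initialization
    at a small labeled budget, averaged over fine-tuning seeds."""
    labeled_movies, labeled_truths = make_benchmark_cohort(
        n_labeled, seed=seed * 1000 + 1, id_prefix="train"
    )
    test_movies, test_truths = make_benchmark_cohort(
        n_test, seed=seed * 1000 + 500_000, id_prefix="test"
    )
    if mae_state is None:
        mae_state = pretrain_on_cohort(labeled_movies, seed=seed)
    f1 = {"from_mae": [], "random": []}
    for s in seeds:
        for init in ("from_mae", "random"):
            state = finetune_on_cohort(
                labeled_movies, labeled_truths, seed=seed + 31 * s + 7,
                mae_state=mae_state if init == "from_mae" else None,
                encoder_init=init,
            )
            report = evaluate_on_cohort(state.best_model(), test_movies,
                                        test_truths)
            f1[init].append(report.f1_at_1)
    return f1
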
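"""Shared fixtures: tiny model configs and small synthetic cohorts.

Model sizes here are deliberately small (16-px patches on 64-px crops,
2-block encoders) so training-based tests finish in seconds to minutes on
one CPU while still exercising the full masking/encoding/decoding and
fine-tuning paths.
"""

import numpy as np
import pytest

from budcall.detector import DetectorConfig
from budcall.mae import MAEConfig, pretrain
from budcall.preprocessing import CropConfig
from budcall.synthetic_data import SimulationConfig, generate_cohort


def tiny_mae_config(**overrides) -> MAEConfig:
    base = dict(
        patch_size_px=16, embed_dim=32, depth=2, n_heads=2,
        decoder_embed_dim=16, decoder_depth=1, decoder_n_heads=2,
        mlp_ratio=2.0, epochs=8, batch_size=64, seed=0,
    )
    base.update(overrides)
    return MAEConfig(**base)


def tiny_detector_config(**overrides) -> DetectorConfig:
    base = dict(
        patch_size_px=16, embed_dim=32, depth=2, n_heads=2, mlp_ratio=2.0,
        temporal_depth=2, temporal_heads=2, epochs=4, base_lr=1e-3,
        batch_size=32, seed=0,
    )
    base.update(overrides)
    return DetectorConfig(**base)


def tiny_crop_config(**overrides) -> CropConfig:
    base = dict(crop_size_px=64, resized_px=64, patch_size_px=16)
    base.update(overrides)
    return CropConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """8 mother cells, 60 frames each (~9 divisions per cell)."""
    sim = SimulationConfig(n_frames=60, seed=0)
    return generate_cohort(sim, 8, seed=100)


@pytest.fixture(scope="session")
def tiny_mae_state(small_cohort):
    """A briefly pretrained tiny MAE shared across detector tests."""
    movies, _ = small_cohort
    crops = np.concatenate([m.frames[::2] for m in movies])
    cells = np.concatenate([[m.cell_id] * len(m.frames[::2]) for m in movies])
    return pretrain(crops, tiny_mae_config(), cell_ids=cells)
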
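"""Temporal-transformer division detector.

Each frame of an 11-frame window is encoded independently by the (MAE-
pretrained) vision-transformer encoder with a classification token
prepended and no masking; the per-frame classification-token embeddings,
augmented with sinusoidal temporal embeddings of the window position, pass
through a second transformer with full self-attention across the window.
Every position emits two logits (budded vs. non-budded); the softmax
probability of the division class at the center position is the window's
prediction. Sliding the window over a movie yields frame-wise division
probabilities for the whole lifespan.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ._nn import AdamW, Linear, Module, TransformerStack
from ._tensor import Tensor, concat, cross_entropy
from .errors import ValidationError
from .events import timeline_from_probabilities
from .preprocessing import (
    CropConfig,
    TemporalStack,
    build_temporal_stack,
    normalize_batch,
    patchify_batch,
    spatial_positional_embedding,
)
from .synthetic_data import CellMovie, GroundTruthAnnotations

__all__ = [
    "DetectorConfig",
    "FrameProbabilities",
    "DivisionDetector",
    "DetectorState",
    "StackDataset",
    "temporal_embedding",
    "init_detector",
    "init_from_mae",
    "encode_frame",
    "classify_stack",
    "finetune",
    "predict_movie",
    "write_predictions_csv",
    "save_detector_checkpoint",
    "load_detector_checkpoint",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Architecture and fine-tuning settings.

    Encoder fields must agree with the pretraining checkpoint when
    ``encoder_init='from_mae'``. ``class_weighting=None`` weights the rare
    division class by the negative/positive count ratio of the training
    labels.
    """

    image_size_px: int = 64
    patch_size_px: int = 8
    embed_dim: int = 64
    depth: int = 4
    n_heads: int = 4
    mlp_ratio: float = 4.0
    temporal_depth: int = 2
    temporal_heads: int = 4
    half_window: int = 5
    encoder_init: str = "from_mae"
    use_ema_weights: bool = True
    freeze_encoder: bool = False
    epochs: int = 3
    base_lr: float = 1e-3
    weight_decay: float = 0.01
    batch_size: int = 32
    seed: int = 0
    class_weighting: float | None = None
    loss_positions: str = "center"
    val_fraction: float = 0.15
    normalization: str = "per_image_zscore"

    def __post_init__(self):
        if self.encoder_init not in ("from_mae", "random"):
            raise ValidationError(
                f"encoder_init must be 'from_mae' or 'random', "
                f"got {self.encoder_init!r}"
            )
        if self.half_window < 0:
            raise ValidationError("half_window must be >= 0")
        if self.loss_positions not in ("center", "all"):
            raise ValidationError("loss_positions must be 'center' or 'all'")
        if self.image_size_px % self.patch_size_px:
            raise ValidationError("image_size_px not divisible by patch_size_px")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")

    @property
    def n_classes(self) -> int:
        return 2  # budded vs. non-budded

    @property
    def stack_length(self) -> int:
        return 2 * self.half_window + 1

    @property
    def n_tokens(self) -> int:
        return (self.image_size_px // self.patch_size_px) ** 2


@dataclass
class FrameProbabilities:
    """Per-frame division probability over a cell's whole movie."""

    cell_id: str
    probabilities: np.ndarray

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 1:
            raise ValidationError("probabilities must be 1-D")
        if self.probabilities.size and (
            self.probabilities.min() < 0 or self.probabilities.max() > 1
        ):
            raise ValidationError("probabilities must lie in [0, 1]")


def temporal_embedding(index: int, embed_dim: int) -> np.ndarray:
    """Sinusoidal encoding of a window position:
    component 2i = sin(index / 10000^(2i/d)), 2i+1 = cos(same)."""
    if embed_dim % 2:
        raise ValidationError("embed_dim must be even")
    if index < 0:
        raise ValidationError("index must be >= 0")
    i = np.arange(embed_dim // 2)
    angle = index / (10000.0 ** (2 * i / embed_dim))
    out = np.empty(embed_dim, dtype=np.float64)
    out[0::2] = np.sin(angle)
    out[1::2] = np.cos(angle)
    return out


def _temporal_embedding_matrix(length: int, embed_dim: int) -> np.ndarray:
    return np.stack(
        [temporal_embedding(i, embed_dim) for i in range(length)]
    ).astype(np.float32)


class DivisionDetector(Module):
    """Frame encoder (ViT + classification token) + temporal transformer."""

    def __init__(self, config: DetectorConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.config = config
        d = config.embed_dim
        patch_dim = config.patch_size_px ** 2
        self.patch_embed = Linear(patch_dim, d, rng)
        self.encoder = TransformerStack(d, config.depth, config.n_heads, rng,
                                        config.mlp_ratio)
        self.cls_token = Tensor(
            (rng.standard_normal(d) * 0.02).astype(np.float32),
            requires_grad=True,
        )
        self.temporal = TransformerStack(d, config.temporal_depth,
                                         config.temporal_heads, rng,
                                         config.mlp_ratio)
        self.head = Linear(d, config.n_classes, rng)
        self.pos_embed = spatial_positional_embedding(config.n_tokens, d)
        self.temporal_pos = _temporal_embedding_matrix(config.stack_length, d)

    # -- forward pieces ---------------------------------------------------

    def frame_embeddings(self, images: np.ndarray) -> Tensor:
        """Encode (M, s, s) raw crops into (M, d) classification-token
        embeddings; all patches visible (no masking)."""
        cfg = self.config
        if images.shape[1:] != (cfg.image_size_px, cfg.image_size_px):
            raise ValidationError(
                f"crops must be {cfg.image_size_px}px square, "
                f"got {images.shape[1:]}"
            )
        images = normalize_batch(images, cfg.normalization)
        tokens = patchify_batch(images, cfg.patch_size_px).astype(np.float32)
        m = tokens.shape[0]
        x = self.patch_embed(Tensor(tokens)) + Tensor(self.pos_embed[None])
        cls = self.cls_token.reshape(1, 1, cfg.embed_dim) + Tensor(
            np.zeros((m, 1, cfg.embed_dim), dtype=np.float32)
        )
        x = concat([cls, x], axis=1)
        out = self.encoder(x)
        return out[:, 0, :]

    def temporal_logits(self, embeddings: Tensor) -> Tensor:
        """(B, L, d) frame embeddings -> (B, L, 2) per-position logits."""
        x = embeddings + Tensor(self.temporal_pos[None])
        return self.head(self.temporal(x))

    def stack_logits(self, stacks: np.ndarray) -> Tensor:
        """(B, L, s, s) image stacks -> (B, L, 2) logits."""
        b, length, s, _ = stacks.shape
        if length != self.config.stack_length:
            raise ValidationError(
                f"stack length {length} != 2*half_window+1 = "
                f"{self.config.stack_length}"
            )
        emb = self.frame_embeddings(stacks.reshape(b * length, s, s))
        emb = emb.reshape(b, length, self.config.embed_dim)
        return self.temporal_logits(emb)


def init_detector(config: DetectorConfig,
                  mae_state=None) -> DivisionDetector:
    """Build a detector, importing encoder weights from a pretraining
    checkpoint when the config asks for it."""
    model = DivisionDetector(config)
    if config.encoder_init == "from_mae":
        if mae_state is None:
            raise ValidationError(
                "encoder_init='from_mae' requires a pretraining checkpoint"
            )
        enc = mae_state.encoder_state(use_ema=config.use_ema_weights)
        own = dict(model.named_parameters())
        for name, value in enc.items():
            if name not in own:
                raise ValidationError(f"unexpected encoder parameter {name!r}")
            if own[name].data.shape != value.shape:
                raise ValidationError(
                    f"dimension mismatch for {name!r}: checkpoint "
                    f"{value.shape} vs detector {own[name].data.shape}"
                )
            own[name].data = value.astype(np.float32).copy()
    return model


def init_from_mae(mae_state, config: DetectorConfig) -> DivisionDetector:
    """Encoder weights copied from the checkpoint; decoder discarded;
    classification token and temporal head freshly seeded."""
    return init_detector(config, mae_state)


def encode_frame(crop: np.ndarray, detector: DivisionDetector) -> np.ndarray:
    """Classification-token embedding of a single resized crop."""
    crop = np.asarray(crop, dtype=np.float32)
    if crop.ndim != 2:
        raise ValidationError("crop must be 2-D")
    return detector.frame_embeddings(crop[None]).data[0]


def classify_stack(stack: TemporalStack,
                   detector: DivisionDetector) -> np.ndarray:
    """Per-position (length, 2) logits for one temporal stack."""
    return detector.stack_logits(stack.images[None].astype(np.float32)).data[0]


# -- training -------------------------------------------------------------


class StackDataset:
    """Lazy labeled-stack dataset over a cohort of movies.

    Materializes one :class:`TemporalStack` per (cell, frame) on demand so
    cohorts of movies fit in memory; the label is 1 when the center frame
    is an annotated division frame.
    """

    def __init__(self, movies: list[CellMovie],
                 annotations: list[GroundTruthAnnotations],
                 crop_config: CropConfig, track=None):
        truth = {a.cell_id: set(a.division_frames) for a in annotations}
        missing = [m.cell_id for m in movies if m.cell_id not in truth]
        if missing:
            raise ValidationError(f"no annotations for cells {missing}")
        self.movies = movies
        self.crop_config = crop_config
        self.track = track
        self.items: list[tuple[int, int, int]] = []  # (movie idx, frame, label)
        for mi, movie in enumerate(movies):
            events = truth[movie.cell_id]
            for f in range(movie.n_frames):
                self.items.append((mi, f, int(f in events)))

    def __len__(self) -> int:
        return len(self.items)

    def cell_id(self, index: int) -> str:
        return self.movies[self.items[index][0]].cell_id

    def label(self, index: int) -> int:
        return self.items[index][2]

    def __getitem__(self, index: int) -> TemporalStack:
        mi, frame, label = self.items[index]
        return build_temporal_stack(
            self.movies[mi], frame, self.crop_config, self.track, label=label
        )


@dataclass
class DetectorState:
    """Result of fine-tuning: model + best-checkpoint bookkeeping."""

    model: DivisionDetector
    config: DetectorConfig
    history: list[dict] = field(default_factory=list)
    best_state: dict[str, np.ndarray] | None = None
    best_val_f1: float = -1.0
    best_epoch: int = -1

    def best_model(self) -> DivisionDetector:
        model = DivisionDetector(self.config)
        model.load_state_dict(self.best_state or self.model.state_dict())
        return model


def _as_indexed(stacks):
    """Uniform access to list-of-TemporalStack or StackDataset."""
    if isinstance(stacks, StackDataset):
        return stacks
    stacks = list(stacks)

    class _ListView:
        def __len__(self):
            return len(stacks)

        def cell_id(self, i):
            return stacks[i].cell_id

        def label(self, i):
            if stacks[i].label is None:
                raise ValidationError("every training stack needs a label")
            return int(stacks[i].label)

        def __getitem__(self, i):
            return stacks[i]

    return _ListView()


def _val_f1(model: DivisionDetector, data, val_indices,
            tolerance: int = 1) -> float:
    """Event-level F1 at +/-1 frame over held-out cells, pooled."""
    from .evaluation import MatchResult, match_events, precision_recall_f1

    by_cell: dict[str, list[int]] = {}
    for i in val_indices:
        by_cell.setdefault(data.cell_id(i), []).append(i)
    tp = fp = fn = 0
    for cell, idxs in by_cell.items():
        idxs = sorted(idxs, key=lambda i: data[i].center_frame_index)
        frames = [data[i].center_frame_index for i in idxs]
        probs = _predict_indices(model, data, idxs)
        n = max(frames) + 1
        calls = np.zeros(n, dtype=np.int8)
        calls[frames] = (probs >= 0.5).astype(np.int8)
        pred = timeline_from_probabilities(
            np.where(calls > 0, 1.0, 0.0), cell_id=cell
        )
        truth_frames = sorted(
            data[i].center_frame_index for i in idxs if data.label(i) == 1
        )
        from .events import EventTimeline

        m = match_events(pred, EventTimeline(cell, truth_frames), tolerance)
        tp += m.n_tp
        fp += m.n_fp
        fn += m.n_fn
    _, _, f1 = precision_recall_f1(MatchResult([], tp, fp, fn, tolerance))
    return f1


def _predict_indices(model: DivisionDetector, data, idxs,
                     batch_size: int = 64) -> np.ndarray:
    probs = np.empty(len(idxs))
    length = model.config.stack_length
    center = model.config.half_window
    for lo in range(0, len(idxs), batch_size):
        chunk = idxs[lo:lo + batch_size]
        batch = np.stack([data[i].images for i in chunk]).astype(np.float32)
        logits = model.stack_logits(batch)
        p = logits.softmax(axis=-1).data[:, center, 1]
        probs[lo:lo + len(chunk)] = p
    return probs


def finetune(stacks, config: DetectorConfig,
             mae_state=None) -> DetectorState:
    """Fine-tune on labeled temporal stacks.

    Minimizes class-weighted cross-entropy on the center-frame prediction;
    the best checkpoint is the epoch with the highest event-level F1 at
    +/-1 frame on held-out cells (cells, never frames, are held out).
    """
    data = _as_indexed(stacks)
    n = len(data)
    if n == 0:
        raise ValidationError("training set is empty")
    labels = np.array([data.label(i) for i in range(n)])
    if labels.min() == labels.max():
        raise ValidationError(
            "training set must contain both classes (budded and non-budded)"
        )
    rng = np.random.default_rng(config.seed)
    cells = np.array([data.cell_id(i) for i in range(n)])
    unique = np.unique(cells)
    rng.shuffle(unique)
    n_val = (
        max(1, int(round(config.val_fraction * len(unique))))
        if len(unique) > 1 else 0
    )
    val_cells = set(unique[:n_val].tolist())
    val_idx = [i for i in range(n) if cells[i] in val_cells]
    train_idx = [i for i in range(n) if cells[i] not in val_cells]
    if not train_idx:
        train_idx, val_idx = val_idx, []
    train_labels = labels[train_idx]
    if train_labels.min() == train_labels.max():
        raise ValidationError("training split lost one class; use more cells")

    if config.class_weighting is None:
        pos_w = float((train_labels == 0).sum() / max(1, (train_labels == 1).sum()))
    else:
        pos_w = float(config.class_weighting)
    class_weights = np.array([1.0, pos_w], dtype=np.float32)

    model = init_detector(config, mae_state)
    frozen_prefixes = ("patch_embed.", "encoder.") if config.freeze_encoder else ()
    trainable = [
        (name, p) for name, p in model.named_parameters()
        if not name.startswith(frozen_prefixes)
    ]
    opt = AdamW(trainable, lr=config.base_lr,
                weight_decay=config.weight_decay)
    state = DetectorState(model=model, config=config)
    center = config.half_window

    for epoch in range(config.epochs):
        order = rng.permutation(len(train_idx))
        epoch_loss, seen = 0.0, 0
        for lo in range(0, len(order), config.batch_size):
            sel = [train_idx[k] for k in order[lo:lo + config.batch_size]]
            batch = np.stack([data[i].images for i in sel]).astype(np.float32)
            y = labels[sel]
            logits = model.stack_logits(batch)
            if config.loss_positions == "center":
                loss = cross_entropy(logits[:, center, :], y, class_weights)
            else:
                b, length, c = logits.shape
                rep = np.repeat(y, length)
                loss = cross_entropy(logits.reshape(b * length, c), rep,
                                     class_weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(sel)
            seen += len(sel)
        row = {"epoch": epoch, "train_loss": epoch_loss / max(1, seen)}
        if val_idx:
            f1 = _val_f1(model, data, val_idx)
            row["val_f1_pm1"] = f1
            if f1 > state.best_val_f1:
                state.best_val_f1 = f1
                state.best_epoch = epoch
                state.best_state = model.state_dict()
        state.history.append(row)
    if state.best_state is None:
        state.best_state = model.state_dict()
        state.best_epoch = config.epochs - 1
    return state


# -- inference ------------------------------------------------------------


def predict_movie(movie: CellMovie, detector: DivisionDetector,
                  crop_config: CropConfig | None = None,
                  track=None, batch_size: int = 256) -> FrameProbabilities:
    """Frame-wise division probabilities over a whole movie.

    Each frame is encoded once; the temporal transformer then runs on
    sliding windows of the cached frame embeddings (windows at the movie
    boundaries replicate the first/last frame, matching
    :func:`~budcall.preprocessing.build_temporal_stack`).
    """
    if crop_config is None:
        crop_config = CropConfig(
            crop_size_px=detector.config.image_size_px,
            resized_px=detector.config.image_size_px,
            half_window=detector.config.half_window,
            patch_size_px=detector.config.patch_size_px,
        )
    n = movie.n_frames
    if n == 0:
        raise ValidationError("movie is empty")
    if crop_config.half_window != detector.config.half_window:
        raise ValidationError("crop_config.half_window != detector half_window")
    # crop + resize every frame once
    from .preprocessing import extract_centered_crop, resize_crop

    h, w = movie.frames[0].shape
    crops = np.empty(
        (n, crop_config.resized_px, crop_config.resized_px), dtype=np.float32
    )
    for t in range(n):
        if track is not None:
            center = track.center(movie.cell_id, t)
        else:
            center = (w / 2.0, h / 2.0)
        crop = extract_centered_crop(movie.frames[t], center,
                                     crop_config.crop_size_px)
        crops[t] = resize_crop(crop, crop_config.resized_px)

    d = detector.config.embed_dim
    emb = np.empty((n, d), dtype=np.float32)
    for lo in range(0, n, batch_size):
        emb[lo:lo + batch_size] = detector.frame_embeddings(
            crops[lo:lo + batch_size]
        ).data
    hw = detector.config.half_window
    idx = np.clip(
        np.arange(n)[:, None] + np.arange(-hw, hw + 1)[None, :], 0, n - 1
    )
    windows = emb[idx]  # (n, L, d)
    probs = np.empty(n)
    for lo in range(0, n, batch_size):
        chunk = windows[lo:lo + batch_size]
        logits = detector.temporal_logits(Tensor(chunk))
        probs[lo:lo + batch_size] = logits.softmax(axis=-1).data[:, hw, 1]
    return FrameProbabilities(movie.cell_id, probs)


def write_predictions_csv(predictions: list[FrameProbabilities], path) -> None:
    rows = [
        {"cell_id": p.cell_id, "frame_index": t, "p_division": float(v)}
        for p in predictions
        for t, v in enumerate(p.probabilities)
    ]
    pd.DataFrame(rows, columns=["cell_id", "frame_index", "p_division"]).to_csv(
        path, index=False
    )


def save_detector_checkpoint(state: DetectorState, path) -> None:
    arrays = {
        "param/" + k: v
        for k, v in (state.best_state or state.model.state_dict()).items()
    }
    arrays["_config_json"] = np.frombuffer(
        json.dumps(asdict(state.config)).encode(), dtype=np.uint8
    )
    arrays["_history_json"] = np.frombuffer(
        json.dumps(state.history).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_detector_checkpoint(path) -> DetectorState:
    with np.load(path) as data:
        config = DetectorConfig(
            **json.loads(bytes(data["_config_json"]).decode())
        )
        history = json.loads(bytes(data["_history_json"]).decode())
        params = {
            k[len("param/"):]: data[k] for k in data.files
            if k.startswith("param/")
        }
    model = DivisionDetector(config)
    model.load_state_dict(params)
    return DetectorState(model=model, config=config, history=history,
                         best_state=params)
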
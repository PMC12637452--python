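"""Masked-auto-encoder pretraining on single-cell crops.

A large random fraction of image patches is hidden; only the visible
patches pass through the transformer encoder, and a lighter decoder
reconstructs the full image from the encoded latents plus a learnable mask
token inserted at every hidden position. Training the reconstruction
objective forces the encoder to learn cell morphology without any division
labels, which is what makes the downstream detector label-efficient.

Training machinery follows common large-batch practice: AdamW (decoupled
weight decay), linear warmup followed by cosine annealing with periodic
restarts, gradient accumulation, an exponential-moving-average shadow of
the parameters, and best-checkpoint selection on a held-out split (split by
cell so temporally adjacent, near-duplicate crops never straddle the
split).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from ._nn import AdamW, Linear, Module, TransformerStack, ema_update_
from ._tensor import Tensor, concat, gather_rows
from .errors import ValidationError
from .preprocessing import (
    normalize_batch,
    patchify,
    patchify_batch,
    spatial_positional_embedding,
)

__all__ = [
    "MAEConfig",
    "MaskingPlan",
    "MAEState",
    "MaskedAutoencoder",
    "make_masking_plan",
    "mae_encode",
    "mae_decode",
    "reconstruction_loss",
    "lr_at_step",
    "ema_update",
    "pretrain",
    "save_mae_checkpoint",
    "load_mae_checkpoint",
]


@dataclass(frozen=True)
class MAEConfig:
    """Architecture and optimization settings for pretraining.

    Sizes default to desk-scale values (a few minutes of CPU); they are not
    meant to saturate reconstruction quality.
    """

    image_size_px: int = 64
    patch_size_px: int = 8
    mask_ratio: float = 0.75
    embed_dim: int = 64
    depth: int = 4
    n_heads: int = 4
    decoder_embed_dim: int = 32
    decoder_depth: int = 2
    decoder_n_heads: int = 4
    mlp_ratio: float = 4.0
    epochs: int = 30
    base_lr: float = 1.5e-3
    weight_decay: float = 0.01
    warmup_epochs: int = 2
    cosine_restart_period: int = 20
    ema_decay: float = 0.999
    grad_accum_steps: int = 1
    batch_size: int = 64
    seed: int = 0
    loss_on: str = "masked_only"
    val_fraction: float = 0.1
    normalization: str = "per_image_zscore"

    def __post_init__(self):
        if not 0.0 < self.mask_ratio < 1.0:
            raise ValidationError("mask_ratio must be in (0, 1)")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if not 0.0 < self.ema_decay < 1.0:
            raise ValidationError("ema_decay must be in (0, 1)")
        if self.grad_accum_steps < 1:
            raise ValidationError("grad_accum_steps must be >= 1")
        if self.image_size_px % self.patch_size_px:
            raise ValidationError("image_size_px not divisible by patch_size_px")
        if self.loss_on not in ("masked_only", "all_patches"):
            raise ValidationError(
                f"loss_on must be 'masked_only' or 'all_patches', "
                f"got {self.loss_on!r}"
            )
        if self.cosine_restart_period < 1:
            raise ValidationError("cosine_restart_period must be >= 1")

    @property
    def n_tokens(self) -> int:
        return (self.image_size_px // self.patch_size_px) ** 2


@dataclass(frozen=True)
class MaskingPlan:
    """Disjoint visible/masked token index sets covering the whole grid."""

    visible_indices: tuple[int, ...]
    masked_indices: tuple[int, ...]
    seed: int

    @property
    def n_tokens(self) -> int:
        return len(self.visible_indices) + len(self.masked_indices)


def make_masking_plan(n_tokens: int, mask_ratio: float, seed: int) -> MaskingPlan:
    """Uniform random token partition; deterministic per seed."""
    n_masked = int(round(mask_ratio * n_tokens))
    if not 1 <= n_masked <= n_tokens - 1:
        raise ValidationError(
            f"mask_ratio {mask_ratio} leaves {n_masked} masked of {n_tokens} "
            "tokens; both sides must be non-empty"
        )
    perm = np.random.default_rng(seed).permutation(n_tokens)
    masked = np.sort(perm[:n_masked])
    visible = np.sort(perm[n_masked:])
    return MaskingPlan(tuple(visible.tolist()), tuple(masked.tolist()), seed)


def lr_at_step(step: int, base_lr: float, warmup_steps: int,
               period_steps: int) -> float:
    """Linear warmup to ``base_lr`` then cosine decay to 0 over each restart
    period, resetting at period boundaries."""
    if step < 0:
        raise ValidationError("step must be >= 0")
    if warmup_steps > 0 and step < warmup_steps:
        return base_lr * step / warmup_steps
    t = (step - warmup_steps) % period_steps
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * t / period_steps))


def ema_update(shadow: dict[str, np.ndarray], live: dict[str, np.ndarray],
               decay: float) -> dict[str, np.ndarray]:
    """Functional EMA step: returns decay*shadow + (1-decay)*live."""
    out = {k: v.copy() for k, v in shadow.items()}
    ema_update_(out, live, decay)
    return out


class MaskedAutoencoder(Module):
    """Asymmetric encoder/decoder transformer over flattened patches."""

    def __init__(self, config: MAEConfig, rng: np.random.Generator | None = None):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.config = config
        p = config.patch_size_px
        patch_dim = p * p
        d, dd = config.embed_dim, config.decoder_embed_dim
        self.patch_embed = Linear(patch_dim, d, rng)
        self.encoder = TransformerStack(d, config.depth, config.n_heads, rng,
                                        config.mlp_ratio)
        self.decoder_embed = Linear(d, dd, rng)
        self.mask_token = Tensor(
            (rng.standard_normal(dd) * 0.02).astype(np.float32),
            requires_grad=True,
        )
        self.decoder = TransformerStack(dd, config.decoder_depth,
                                        config.decoder_n_heads, rng,
                                        config.mlp_ratio)
        self.pred = Linear(dd, patch_dim, rng)
        n_tok = config.n_tokens
        # fixed sinusoidal positions for encoder and decoder token grids
        self.pos_embed = spatial_positional_embedding(n_tok, d)
        self.decoder_pos_embed = spatial_positional_embedding(n_tok, dd)

    # -- batched forward --------------------------------------------------

    def _encode_tokens(self, tokens_visible: np.ndarray,
                       ids_visible: np.ndarray) -> Tensor:
        pos = self.pos_embed[ids_visible]  # (B, K, d)
        x = self.patch_embed(Tensor(tokens_visible)) + Tensor(pos)
        return self.encoder(x)

    def _decode_latents(self, latents: Tensor, ids_visible: np.ndarray,
                        ids_restore: np.ndarray) -> Tensor:
        b, k, _ = latents.shape
        t = ids_restore.shape[1]
        y = self.decoder_embed(latents)
        dd = self.config.decoder_embed_dim
        mask_tokens = self.mask_token.reshape(1, 1, dd) + Tensor(
            np.zeros((b, t - k, dd), dtype=np.float32)
        )
        full = concat([y, mask_tokens], axis=1)
        full = gather_rows(full, ids_restore)
        full = full + Tensor(self.decoder_pos_embed[None, :, :])
        return self.pred(self.decoder(full))

    def batch_loss(self, images: np.ndarray, ids_shuffle: np.ndarray,
                   loss_scale: float = 1.0) -> Tensor:
        """Masked-reconstruction MSE on a batch.

        ``ids_shuffle`` is (B, T): the first K = T - n_masked columns are the
        visible token ids of each image. ``loss_scale`` supports gradient
        accumulation (each micro-batch contributes batch_fraction * loss).
        """
        cfg = self.config
        images = normalize_batch(images, cfg.normalization)
        tokens = patchify_batch(images, cfg.patch_size_px).astype(np.float32)
        t = cfg.n_tokens
        n_masked = int(round(cfg.mask_ratio * t))
        k = t - n_masked
        ids_visible = ids_shuffle[:, :k]
        ids_restore = np.argsort(ids_shuffle, axis=1)
        tokens_vis = np.take_along_axis(
            tokens, ids_visible[:, :, None], axis=1
        )
        latents = self._encode_tokens(tokens_vis, ids_visible)
        recon = self._decode_latents(latents, ids_visible, ids_restore)
        diff = recon - Tensor(tokens)
        sq = diff * diff
        if cfg.loss_on == "masked_only":
            mask = np.zeros(ids_shuffle.shape, dtype=np.float32)
            np.put_along_axis(mask, ids_shuffle[:, k:], 1.0, axis=1)
            denom = float(mask.sum()) * tokens.shape[2]
            loss = (sq * Tensor(mask[:, :, None])).sum() * (1.0 / denom)
        else:
            loss = sq.mean()
        if loss_scale != 1.0:
            loss = loss * loss_scale
        return loss

    def reconstruct(self, image: np.ndarray, plan: MaskingPlan) -> np.ndarray:
        """Full-image reconstruction of one (normalized) crop."""
        cfg = self.config
        latents = self.encode(image, plan)
        return self.decode(latents, plan)

    def encode(self, image: np.ndarray, plan: MaskingPlan) -> np.ndarray:
        """Latent vectors for the visible tokens of one image."""
        cfg = self.config
        if plan.n_tokens != cfg.n_tokens:
            raise ValidationError(
                f"plan covers {plan.n_tokens} tokens, model expects {cfg.n_tokens}"
            )
        image = normalize_batch(image[None], cfg.normalization)[0]
        tokens = patchify(image, cfg.patch_size_px).tokens.astype(np.float32)
        vis = np.asarray(plan.visible_indices)
        latents = self._encode_tokens(tokens[None, vis, :], vis[None, :])
        return latents.data[0]

    def decode(self, latents: np.ndarray, plan: MaskingPlan) -> np.ndarray:
        """Reconstructed image from visible-token latents + mask tokens."""
        cfg = self.config
        vis = np.asarray(plan.visible_indices)
        if latents.shape[0] != len(vis):
            raise ValidationError(
                f"{latents.shape[0]} latents do not match "
                f"{len(vis)} visible tokens in the plan"
            )
        order = np.concatenate([vis, np.asarray(plan.masked_indices)])
        ids_restore = np.argsort(order)
        recon = self._decode_latents(
            Tensor(latents[None].astype(np.float32)),
            vis[None, :], ids_restore[None, :],
        )
        from .preprocessing import PatchSequence, unpatchify

        g = cfg.image_size_px // cfg.patch_size_px
        rows, cols = np.divmod(np.arange(cfg.n_tokens), g)
        seq = PatchSequence(recon.data[0], np.stack([rows, cols], 1),
                            cfg.image_size_px, cfg.patch_size_px)
        return unpatchify(seq)


def mae_encode(model: MaskedAutoencoder, image: np.ndarray,
               plan: MaskingPlan) -> np.ndarray:
    """One latent vector per visible token of ``image``."""
    return model.encode(image, plan)


def mae_decode(model: MaskedAutoencoder, latents: np.ndarray,
               plan: MaskingPlan) -> np.ndarray:
    """Full-size reconstruction from latents under ``plan``."""
    return model.decode(latents, plan)


def reconstruction_loss(reconstruction: np.ndarray, original: np.ndarray,
                        plan: MaskingPlan, patch_size_px: int,
                        loss_on: str = "masked_only") -> float:
    """Mean squared error over masked patches (or all patches)."""
    reconstruction = np.asarray(reconstruction, dtype=float)
    original = np.asarray(original, dtype=float)
    if reconstruction.shape != original.shape:
        raise ValidationError(
            f"shape mismatch: {reconstruction.shape} vs {original.shape}"
        )
    rec = patchify(reconstruction, patch_size_px).tokens
    org = patchify(original, patch_size_px).tokens
    if loss_on == "masked_only":
        idx = np.asarray(plan.masked_indices)
    elif loss_on == "all_patches":
        idx = np.arange(rec.shape[0])
    else:
        raise ValidationError(f"unknown loss_on {loss_on!r}")
    return float(np.mean((rec[idx] - org[idx]) ** 2))


@dataclass
class MAEState:
    """Result of pretraining: model + EMA shadow + best checkpoint."""

    model: MaskedAutoencoder
    ema: dict[str, np.ndarray]
    config: MAEConfig
    history: list[dict] = field(default_factory=list)
    best_state: dict[str, np.ndarray] | None = None
    best_ema: dict[str, np.ndarray] | None = None
    best_val_loss: float = float("inf")
    best_epoch: int = -1

    def encoder_state(self, use_ema: bool = True) -> dict[str, np.ndarray]:
        """Encoder-side parameters of the best checkpoint (patch embedding +
        encoder blocks); the decoder is dropped for transfer."""
        source = (self.best_ema if use_ema else self.best_state)
        if source is None:
            source = self.ema if use_ema else self.model.state_dict()
        return {
            k: v.copy() for k, v in source.items()
            if k.startswith(("patch_embed.", "encoder."))
        }


def _batch_masking(rng: np.random.Generator, n_images: int,
                   n_tokens: int) -> np.ndarray:
    noise = rng.random((n_images, n_tokens))
    return np.argsort(noise, axis=1)


def _split_by_cell(n: int, cell_ids, val_fraction: float,
                   rng: np.random.Generator):
    if cell_ids is None:
        cell_ids = np.arange(n) // max(1, n // 10)  # contiguous pseudo-cells
    cell_ids = np.asarray(cell_ids)
    cells = np.unique(cell_ids)
    rng.shuffle(cells)
    n_val = max(1, int(round(val_fraction * len(cells)))) if len(cells) > 1 else 0
    val_cells = set(cells[:n_val].tolist())
    val_mask = np.array([c in val_cells for c in cell_ids])
    return np.flatnonzero(~val_mask), np.flatnonzero(val_mask)


def pretrain(crops: np.ndarray, config: MAEConfig,
             cell_ids=None) -> MAEState:
    """Run the full masking -> encode -> decode -> loss loop.

    ``crops``: (N, s, s) raw intensity crops. ``cell_ids`` (optional,
    length N) group crops by mother cell for the held-out split; without
    them contiguous blocks stand in for cells.
    """
    crops = np.asarray(crops, dtype=np.float32)
    if crops.ndim != 3 or len(crops) == 0:
        raise ValidationError("crops must be a non-empty (N, s, s) array")
    if crops.shape[1] != config.image_size_px:
        raise ValidationError(
            f"crop edge {crops.shape[1]} != config.image_size_px "
            f"{config.image_size_px}"
        )
    rng = np.random.default_rng(config.seed)
    mask_rng = np.random.default_rng(config.seed + 1)
    train_idx, val_idx = _split_by_cell(len(crops), cell_ids,
                                        config.val_fraction, rng)
    if len(train_idx) == 0:
        train_idx = val_idx
    train = crops[train_idx]
    val = crops[val_idx] if len(val_idx) else crops[train_idx[:1]]

    model = MaskedAutoencoder(config, np.random.default_rng(config.seed + 2))
    params = list(model.named_parameters())
    opt = AdamW(params, lr=config.base_lr, weight_decay=config.weight_decay)
    ema = {k: v.copy() for k, v in model.state_dict().items()}

    micro = max(1, config.batch_size // config.grad_accum_steps)
    micro_per_epoch = math.ceil(len(train) / micro)
    opt_steps_per_epoch = math.ceil(micro_per_epoch / config.grad_accum_steps)
    warmup_steps = config.warmup_epochs * opt_steps_per_epoch
    period_steps = max(1, config.cosine_restart_period * opt_steps_per_epoch)

    state = MAEState(model=model, ema=ema, config=config)
    n_tok = config.n_tokens
    opt_step = 0

    def val_loss() -> float:
        v_rng = np.random.default_rng(config.seed + 9999)
        total, count = 0.0, 0
        for lo in range(0, len(val), config.batch_size):
            batch = val[lo:lo + config.batch_size]
            ids = _batch_masking(v_rng, len(batch), n_tok)
            loss = model.batch_loss(batch, ids)
            total += loss.item() * len(batch)
            count += len(batch)
        return total / count

    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        epoch_loss, seen = 0.0, 0
        accum = 0
        pending: list[tuple[np.ndarray, np.ndarray]] = []
        for lo in range(0, len(order), micro):
            sel = order[lo:lo + micro]
            pending.append((train[sel], _batch_masking(mask_rng, len(sel), n_tok)))
            accum += 1
            last = lo + micro >= len(order)
            if accum == config.grad_accum_steps or last:
                group_n = sum(len(b) for b, _ in pending)
                opt.zero_grad()
                for batch, ids in pending:
                    loss = model.batch_loss(batch, ids,
                                            loss_scale=len(batch) / group_n)
                    loss.backward()
                    epoch_loss += loss.item() * group_n
                    seen += len(batch)
                lr = lr_at_step(opt_step, config.base_lr, warmup_steps,
                                period_steps)
                opt.step(lr=lr)
                ema_update_(ema, model.state_dict(), config.ema_decay)
                opt_step += 1
                pending, accum = [], 0
        vl = val_loss()
        state.history.append({
            "epoch": epoch,
            "train_loss": epoch_loss / max(1, seen),
            "val_loss": vl,
            "lr": lr_at_step(max(0, opt_step - 1), config.base_lr,
                             warmup_steps, period_steps),
        })
        if vl < state.best_val_loss:
            state.best_val_loss = vl
            state.best_epoch = epoch
            state.best_state = model.state_dict()
            state.best_ema = {k: v.copy() for k, v in ema.items()}
    return state


def save_mae_checkpoint(state: MAEState, path) -> None:
    arrays: dict[str, np.ndarray] = {}
    best = state.best_state or state.model.state_dict()
    best_ema = state.best_ema or state.ema
    for k, v in best.items():
        arrays["param/" + k] = v
    for k, v in best_ema.items():
        arrays["ema/" + k] = v
    arrays["_config_json"] = np.frombuffer(
        json.dumps(asdict(state.config)).encode(), dtype=np.uint8
    )
    arrays["_history_json"] = np.frombuffer(
        json.dumps(state.history).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_mae_checkpoint(path) -> MAEState:
    with np.load(path) as data:
        config = MAEConfig(
            **json.loads(bytes(data["_config_json"]).decode())
        )
        history = json.loads(bytes(data["_history_json"]).decode())
        params = {
            k[len("param/"):]: data[k] for k in data.files
            if k.startswith("param/")
        }
        ema = {
            k[len("ema/"):]: data[k] for k in data.files if k.startswith("ema/")
        }
    model = MaskedAutoencoder(config)
    model.load_state_dict(params)
    state = MAEState(model=model, ema=ema, config=config, history=history,
                     best_state=params, best_ema=ema)
    if history:
        state.best_val_loss = min(h["val_loss"] for h in history)
    return state
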
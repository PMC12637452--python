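"""Movie-to-model-input preprocessing.

Turns per-cell time-lapse movies plus tracking information into the inputs
the models consume: centered crops, bilinearly resized images, temporal
stacks of 2*half_window + 1 consecutive frames, flattened patch-token
sequences, and fixed sinusoidal positional embeddings.

Conventions: frame indices and pixel coordinates are 0-based; crop centers
are (x, y) in pixel units, taken from a tracking table when available and
falling back to the frame center otherwise (a stationary trap). Temporal
stacks at the movie boundaries replicate the first/last frame so that every
frame of a movie yields a full-length stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .errors import SchemaError, ValidationError
from .synthetic_data import CellMovie

__all__ = [
    "TrackTable",
    "CropConfig",
    "TemporalStack",
    "PatchSequence",
    "extract_centered_crop",
    "resize_crop",
    "normalize_image",
    "build_temporal_stack",
    "patchify",
    "unpatchify",
    "spatial_positional_embedding",
    "patchify_batch",
    "normalize_batch",
    "read_track_table_csv",
    "write_track_table_csv",
    "write_stack_tiff",
]

_TRACK_COLUMNS = ["cell_id", "frame_index", "center_x", "center_y", "area",
                  "aspect_ratio"]


@dataclass
class TrackTable:
    """Per-frame tracking rows: one row per (cell_id, frame_index)."""

    frame: pd.DataFrame

    def __post_init__(self):
        for col in _TRACK_COLUMNS:
            if col not in self.frame.columns:
                raise SchemaError(f"track table missing column {col!r}")
        if self.frame.duplicated(["cell_id", "frame_index"]).any():
            raise SchemaError("track table has duplicate (cell_id, frame_index) rows")
        if (self.frame["frame_index"] < 0).any():
            raise SchemaError("track table has negative frame_index")

    def center(self, cell_id: str, frame_index: int) -> tuple[float, float]:
        sel = self.frame[
            (self.frame["cell_id"] == cell_id)
            & (self.frame["frame_index"] == frame_index)
        ]
        if sel.empty:
            raise KeyError(f"no track row for ({cell_id!r}, frame {frame_index})")
        row = sel.iloc[0]
        return float(row["center_x"]), float(row["center_y"])


def read_track_table_csv(path) -> TrackTable:
    return TrackTable(pd.read_csv(path))


def write_track_table_csv(table: TrackTable, path) -> None:
    table.frame.to_csv(path, index=False)


@dataclass
class CropConfig:
    """Cropping / resizing / tokenization parameters.

    ``crop_size_px`` is the raw crop edge extracted around the tracked
    center, ``resized_px`` the model input edge, ``half_window`` the number
    of frames on each side of the frame of interest, and ``patch_size_px``
    the token edge on the resized image.
    """

    crop_size_px: int = 224
    resized_px: int = 64
    half_window: int = 5
    patch_size_px: int = 8
    normalization: str = "per_image_zscore"

    def __post_init__(self):
        if self.crop_size_px < 1:
            raise ValidationError("crop_size_px must be >= 1")
        if self.half_window < 0:
            raise ValidationError("half_window must be >= 0")
        if self.resized_px % self.patch_size_px:
            raise ValidationError(
                f"resized_px {self.resized_px} not divisible by "
                f"patch_size_px {self.patch_size_px}"
            )
        if self.normalization not in ("none", "per_image_zscore"):
            raise ValidationError(
                f"normalization must be 'none' or 'per_image_zscore', "
                f"got {self.normalization!r}"
            )

    @property
    def stack_length(self) -> int:
        return 2 * self.half_window + 1

    @property
    def n_tokens(self) -> int:
        return (self.resized_px // self.patch_size_px) ** 2


@dataclass
class TemporalStack:
    """A window of consecutive resized crops centered on a frame of interest."""

    cell_id: str
    center_frame_index: int
    images: np.ndarray  # (2*half_window+1, resized_px, resized_px)
    label: int | None = None

    def __post_init__(self):
        self.images = np.asarray(self.images)
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValidationError("stack images must be (length, s, s)")


@dataclass
class PatchSequence:
    """Row-major flattened patch tokens plus their grid positions."""

    tokens: np.ndarray     # (n_tokens, patch_size**2)
    positions: np.ndarray  # (n_tokens, 2) grid (row, col)
    image_size: int
    patch_size: int


def extract_centered_crop(frame: np.ndarray, center: tuple[float, float],
                          crop_size_px: int) -> np.ndarray:
    """Extract a square crop centered at ``center`` (x, y), edge-padding
    regions that fall outside the frame."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValidationError("frame must be 2-D")
    if crop_size_px < 1:
        raise ValidationError("crop_size_px must be >= 1")
    h, w = frame.shape
    cx, cy = center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValidationError(
            f"center {center} outside frame bounds {(w, h)}"
        )
    half = crop_size_px // 2
    r0 = int(round(cy)) - half
    c0 = int(round(cx)) - half
    r1, c1 = r0 + crop_size_px, c0 + crop_size_px
    pad_top = max(0, -r0)
    pad_left = max(0, -c0)
    pad_bottom = max(0, r1 - h)
    pad_right = max(0, c1 - w)
    sub = frame[max(0, r0):min(h, r1), max(0, c0):min(w, c1)]
    if pad_top or pad_left or pad_bottom or pad_right:
        sub = np.pad(sub, ((pad_top, pad_bottom), (pad_left, pad_right)),
                     mode="edge")
    return sub.copy()


def resize_crop(crop: np.ndarray, resized_px: int) -> np.ndarray:
    """Bilinear resize of a square crop; identity when sizes already match."""
    crop = np.asarray(crop)
    if crop.ndim != 2 or crop.shape[0] != crop.shape[1]:
        raise ValidationError(f"crop must be square 2-D, got shape {crop.shape}")
    if crop.shape[0] == resized_px:
        return crop.copy()
    out = _sk_resize(crop, (resized_px, resized_px), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def normalize_image(image: np.ndarray, mode: str = "per_image_zscore") -> np.ndarray:
    """Per-image z-score; constant images map to all-zeros."""
    image = np.asarray(image, dtype=np.float32)
    if mode == "none":
        return image.copy()
    if mode != "per_image_zscore":
        raise ValidationError(f"unknown normalization {mode!r}")
    mu = image.mean()
    sd = image.std()
    # float32 round-off leaves constant images with a tiny nonzero SD
    if sd <= 1e-6 * (abs(mu) + 1.0):
        return np.zeros_like(image)
    return (image - mu) / sd


def build_temporal_stack(movie: CellMovie, center_frame_index: int,
                         config: CropConfig,
                         track: TrackTable | None = None,
                         label: int | None = None) -> TemporalStack:
    """Crop+resize the 2*half_window+1 frames around ``center_frame_index``.

    Out-of-range window indices are clipped, replicating the first/last
    frame. Crop centers come from ``track`` when given, else the frame
    center (fixed-trap fallback).
    """
    n = len(movie.frames)
    if not 0 <= center_frame_index < n:
        raise ValidationError(
            f"center_frame_index {center_frame_index} outside [0, {n})"
        )
    idx = np.clip(
        np.arange(center_frame_index - config.half_window,
                  center_frame_index + config.half_window + 1),
        0, n - 1,
    )
    h, w = movie.frames[0].shape
    images = np.empty((len(idx), config.resized_px, config.resized_px),
                      dtype=np.float32)
    for k, i in enumerate(idx):
        if track is not None:
            center = track.center(movie.cell_id, int(i))
        else:
            center = ((w - 1) / 2.0 + 0.5, (h - 1) / 2.0 + 0.5)
        crop = extract_centered_crop(movie.frames[i], center, config.crop_size_px)
        images[k] = resize_crop(crop, config.resized_px)
    return TemporalStack(movie.cell_id, center_frame_index, images, label)


def write_stack_tiff(stack: TemporalStack, path) -> None:
    """Dump a temporal stack as a multi-page TIFF for visual inspection."""
    import tifffile

    tifffile.imwrite(path, stack.images.astype(np.float32))


def patchify(image: np.ndarray, patch_size_px: int) -> PatchSequence:
    """Split a square image into row-major non-overlapping flattened patches."""
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValidationError("image must be square 2-D")
    s = image.shape[0]
    if s % patch_size_px:
        raise ValidationError(
            f"image edge {s} not divisible by patch size {patch_size_px}"
        )
    g = s // patch_size_px
    tokens = (
        image.reshape(g, patch_size_px, g, patch_size_px)
        .transpose(0, 2, 1, 3)
        .reshape(g * g, patch_size_px * patch_size_px)
    )
    rows, cols = np.divmod(np.arange(g * g), g)
    positions = np.stack([rows, cols], axis=1)
    return PatchSequence(tokens.copy(), positions, s, patch_size_px)


def unpatchify(sequence: PatchSequence) -> np.ndarray:
    """Exact inverse of :func:`patchify`; tolerates shuffled token order
    because placement uses the stored grid positions."""
    p = sequence.patch_size
    s = sequence.image_size
    g = s // p
    if sequence.tokens.shape[0] != g * g:
        raise ValidationError(
            f"expected {g * g} tokens, got {sequence.tokens.shape[0]}"
        )
    seen = set(map(tuple, sequence.positions.tolist()))
    if len(seen) != g * g:
        raise ValidationError("positions do not cover the full patch grid")
    out = np.empty((s, s), dtype=sequence.tokens.dtype)
    for tok, (r, c) in zip(sequence.tokens, sequence.positions):
        out[r * p:(r + 1) * p, c * p:(c + 1) * p] = tok.reshape(p, p)
    return out


def patchify_batch(images: np.ndarray, patch_size_px: int) -> np.ndarray:
    """Vectorized :func:`patchify` over a stack: (M, s, s) -> (M, T, p*p),
    row-major patch order matching the single-image version."""
    images = np.asarray(images)
    m, s, s2 = images.shape
    if s != s2 or s % patch_size_px:
        raise ValidationError("images must be square with edge divisible by patch")
    g = s // patch_size_px
    p = patch_size_px
    return (
        images.reshape(m, g, p, g, p)
        .transpose(0, 1, 3, 2, 4)
        .reshape(m, g * g, p * p)
    )


def normalize_batch(images: np.ndarray,
                    mode: str = "per_image_zscore") -> np.ndarray:
    """Vectorized per-image z-score over a (M, s, s) stack."""
    images = np.asarray(images, dtype=np.float32)
    if mode == "none":
        return images.copy()
    if mode != "per_image_zscore":
        raise ValidationError(f"unknown normalization {mode!r}")
    mu = images.mean(axis=(1, 2), keepdims=True)
    sd = images.std(axis=(1, 2), keepdims=True)
    const = sd <= 1e-6 * (np.abs(mu) + 1.0)
    out = (images - mu) / np.where(const, 1.0, sd)
    # constant images normalize to exactly zero
    return np.where(const, 0.0, out).astype(np.float32)


def _sincos_1d(positions: np.ndarray, dim: int) -> np.ndarray:
    """Standard 1-D sin/cos embedding of ``positions`` into ``dim`` (even)."""
    half = dim // 2
    freqs = 1.0 / (10000.0 ** (np.arange(half) / half))
    args = positions[:, None] * freqs[None, :]
    out = np.empty((len(positions), dim), dtype=np.float64)
    out[:, 0::2] = np.sin(args)
    out[:, 1::2] = np.cos(args)
    return out


def spatial_positional_embedding(n_tokens: int, embed_dim: int) -> np.ndarray:
    """Fixed (non-learned) sinusoidal embeddings for a square patch grid.

    For ``embed_dim`` divisible by 4 the embedding is two-dimensional (half
    the channels encode the row, half the column); otherwise a 1-D encoding
    of the row-major token index is used. Rows are distinct across
    positions in either case.
    """
    if embed_dim % 2:
        raise ValidationError("embed_dim must be even")
    g = int(round(np.sqrt(n_tokens)))
    if g * g == n_tokens and embed_dim % 4 == 0:
        rows, cols = np.divmod(np.arange(n_tokens), g)
        emb = np.concatenate(
            [_sincos_1d(rows.astype(float), embed_dim // 2),
             _sincos_1d(cols.astype(float), embed_dim // 2)],
            axis=1,
        )
    else:
        emb = _sincos_1d(np.arange(n_tokens, dtype=float), embed_dim)
    return emb.astype(np.float32)
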
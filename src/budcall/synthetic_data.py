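"""Synthetic mother-machine movie generator with exact division schedules.

Renders a stationary elliptical mother cell held in a trap; at each
scheduled division frame a bud appears on a fixed side of the mother (the
trap opening), grows for a configurable number of frames, and then vanishes
(the daughter is flushed away). Two daughter-morphology modes mirror the two
canonical wild-type aging trajectories: in ``mode1`` buds produced late in
life are elongated (aspect ratio >= 2), while ``mode2`` cells bud small
round daughters throughout. Gaussian imaging noise is added on top of a
constant background. The division schedule is emitted exactly as ground
truth, so every downstream stage can be tested without real microscopy
data.

Intensities are arbitrary units on a [0, ~1] scale; geometry is in pixels
and time in frames (one frame per ``frame_interval_min`` minutes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as _ellipse

from .errors import FormatError, SchemaError, ValidationError

__all__ = [
    "SimulationConfig",
    "CellMovie",
    "GroundTruthAnnotations",
    "generate_mother_movie",
    "generate_cohort",
    "write_movie_tiff",
    "read_movie_tiff",
    "write_annotations_csv",
    "read_annotations_csv",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated aging movie.

    The defaults describe a wild-type-like mother imaged every 15 minutes
    whose buds emerge roughly every six frames (~90 min cell cycle) and
    whose daughters persist four frames before being flushed.
    """

    image_size_px: int = 64
    n_frames: int = 120
    frame_interval_min: float = 15.0
    first_bud_frame: int = 5
    budding_period_mean: float = 6.0
    budding_period_jitter: float = 1.0
    bud_growth_frames: int = 4
    aging_mode: str = "mode1"
    mode1_switch_fraction: float = 0.6
    lifespan_mean: float | None = None
    lifespan_sd: float = 0.0
    noise_sd: float = 0.05
    background_level: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.image_size_px < 16:
            raise ValidationError("image_size_px must be >= 16")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.frame_interval_min <= 0:
            raise ValidationError("frame_interval_min must be positive")
        if not 0 <= self.first_bud_frame < self.n_frames:
            raise ValidationError(
                f"first_bud_frame must be in [0, n_frames); got "
                f"{self.first_bud_frame} with n_frames={self.n_frames}"
            )
        if self.budding_period_mean <= 0:
            raise ValidationError("budding_period_mean must be positive")
        if self.budding_period_jitter < 0:
            raise ValidationError("budding_period_jitter must be >= 0")
        if self.bud_growth_frames < 1:
            raise ValidationError("bud_growth_frames must be >= 1")
        if self.aging_mode not in ("mode1", "mode2"):
            raise ValidationError(
                f"aging_mode must be 'mode1' or 'mode2', got {self.aging_mode!r}"
            )
        if not 0.0 <= self.mode1_switch_fraction <= 1.0:
            raise ValidationError("mode1_switch_fraction must be in [0, 1]")
        if self.lifespan_mean is not None and self.lifespan_mean < 1:
            raise ValidationError("lifespan_mean must be >= 1 when set")
        if self.lifespan_sd < 0:
            raise ValidationError("lifespan_sd must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.background_level < 0:
            raise ValidationError("background_level must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__ | {}, fh)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} is not a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class CellMovie:
    """One mother cell's ordered crop sequence."""

    cell_id: str
    frames: np.ndarray  # (n_frames, h, w) non-negative intensities
    frame_interval_min: float = 15.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be a (n_frames, h, w) array")
        if len(self.frames) < 1:
            raise ValidationError("movie must contain at least one frame")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class GroundTruthAnnotations:
    """Strictly increasing 0-based division frames for one cell."""

    cell_id: str
    division_frames: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.division_frames = [int(f) for f in self.division_frames]
        if any(f < 0 for f in self.division_frames):
            raise ValidationError("division_frames must be >= 0")
        if any(
            b <= a for a, b in zip(self.division_frames, self.division_frames[1:])
        ):
            raise ValidationError("division_frames must be strictly increasing")

    @property
    def rls(self) -> int:
        return len(self.division_frames)


# -- rendering ------------------------------------------------------------

_MOTHER_INTENSITY = 0.6
_BUD_INTENSITY = 0.8
_SMOOTH_SIGMA = 0.8


def _division_schedule(config: SimulationConfig,
                       rng: np.random.Generator) -> list[int]:
    """Bud-emergence frames: arithmetic progression with period jitter,
    truncated at the movie end and, when a death model is configured, at
    the cell's drawn replicative lifespan (after which the senescent
    mother persists without budding)."""
    if config.lifespan_mean is not None:
        draw = config.lifespan_mean + config.lifespan_sd * rng.standard_normal()
        max_divisions = max(1, int(round(draw)))
    else:
        max_divisions = None
    frames = []
    t = config.first_bud_frame
    while t < config.n_frames:
        if max_divisions is not None and len(frames) >= max_divisions:
            break
        frames.append(int(t))
        draw = rng.standard_normal()
        period = config.budding_period_mean + config.budding_period_jitter * draw
        t += max(1, int(round(period)))
    return frames


def _bud_geometry(age: int, growth_frames: int, elongated: bool,
                  anchor_row: float, anchor_col: float):
    """Semi-axes and center of a bud ``age`` frames after emergence."""
    f = (age + 1) / growth_frames
    r = 2.0 + 3.0 * f
    if elongated:
        r_rad, c_rad = 0.65 * r, 1.6 * r  # aspect ~2.5, long axis out of the trap
    else:
        r_rad, c_rad = r, r
    return anchor_row, anchor_col + c_rad, r_rad, c_rad


def generate_mother_movie(
    config: SimulationConfig,
    cell_id: str = "cell_000",
    return_bud_masks: bool = False,
):
    """Render one mother-cell movie and its exact division annotations.

    When ``return_bud_masks`` is true, also returns the (n_frames, h, w)
    boolean masks of the rendered bud, which tests use to assert the
    morphology-mode contrast without re-segmenting.
    """
    rng = np.random.default_rng(config.seed)
    schedule = _division_schedule(config, rng)

    s = config.image_size_px
    mother_row = s / 2.0
    mother_col = s / 2.0 - 6.0
    mother_rr, mother_cc = _ellipse(mother_row, mother_col, 9.0, 7.0, shape=(s, s))
    anchor_col = mother_col + 7.0  # bud sprouts at the trap-side edge

    n_div = len(schedule)
    if config.aging_mode == "mode1":
        switch_index = int(np.ceil(config.mode1_switch_fraction * n_div))
    else:
        switch_index = n_div + 1  # never elongated

    frames = np.empty((config.n_frames, s, s), dtype=np.float32)
    bud_masks = np.zeros((config.n_frames, s, s), dtype=bool)
    bounds = schedule + [config.n_frames]
    for t in range(config.n_frames):
        scene = np.full((s, s), config.background_level, dtype=np.float64)
        scene[mother_rr, mother_cc] += _MOTHER_INTENSITY
        for k, d in enumerate(schedule):
            visible_until = min(d + config.bud_growth_frames, bounds[k + 1])
            if d <= t < visible_until:
                elongated = k >= switch_index
                row, col, r_rad, c_rad = _bud_geometry(
                    t - d, config.bud_growth_frames, elongated,
                    mother_row, anchor_col,
                )
                rr, cc = _ellipse(row, col, r_rad, c_rad, shape=(s, s))
                scene[rr, cc] += _BUD_INTENSITY
                bud_masks[t, rr, cc] = True
        scene = gaussian_filter(scene, _SMOOTH_SIGMA)
        if config.noise_sd > 0:
            scene = scene + config.noise_sd * rng.standard_normal((s, s))
        frames[t] = np.clip(scene, 0.0, None)

    movie = CellMovie(cell_id, frames, config.frame_interval_min)
    truth = GroundTruthAnnotations(cell_id, schedule)
    if return_bud_masks:
        return movie, truth, bud_masks
    return movie, truth


def generate_cohort(config: SimulationConfig, n_cells: int, seed: int):
    """Generate ``n_cells`` movies with per-cell seeds ``seed + index``."""
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    movies, truths = [], []
    for i in range(n_cells):
        cfg_i = replace(config, seed=seed + i)
        movie, truth = generate_mother_movie(cfg_i, cell_id=f"cell_{i:03d}")
        movies.append(movie)
        truths.append(truth)
    return movies, truths


# -- I/O ------------------------------------------------------------------


def write_movie_tiff(movie: CellMovie, path) -> None:
    """Write one page per frame; cell id and frame interval go into the
    TIFF description so the round-trip is lossless."""
    desc = json.dumps(
        {"cell_id": movie.cell_id, "frame_interval_min": movie.frame_interval_min}
    )
    tifffile.imwrite(path, movie.frames, description=desc)


def read_movie_tiff(path) -> CellMovie:
    try:
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            desc = tif.pages[0].description
    except (tifffile.TiffFileError, FileNotFoundError, OSError) as exc:
        raise FormatError(f"cannot read TIFF movie at {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    cell_id = "unknown"
    interval = 15.0
    if desc:
        try:
            meta = json.loads(desc)
            cell_id = meta.get("cell_id", cell_id)
            interval = float(meta.get("frame_interval_min", interval))
        except (json.JSONDecodeError, TypeError, ValueError):
            pass
    return CellMovie(cell_id, frames, interval)


def write_annotations_csv(annotations, path) -> None:
    """Long-format CSV with one row per division event."""
    if isinstance(annotations, GroundTruthAnnotations):
        annotations = [annotations]
    rows = [
        {"cell_id": a.cell_id, "division_frame": f}
        for a in annotations
        for f in a.division_frames
    ]
    pd.DataFrame(rows, columns=["cell_id", "division_frame"]).to_csv(
        path, index=False
    )


def read_annotations_csv(path) -> list[GroundTruthAnnotations]:
    df = pd.read_csv(path)
    for col in ("cell_id", "division_frame"):
        if col not in df.columns:
            raise SchemaError(f"annotations CSV missing column {col!r}")
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        frames = sorted(int(f) for f in grp["division_frame"])
        out.append(GroundTruthAnnotations(str(cell_id), frames))
    return out
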
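"""Generation of oriented line-segment search arrays.

Two stimulus families are produced:

* **split-half** arrays: one half of the grid holds narrowly distributed
  ("homogeneous", easy) distractor orientations, the other half widely
  distributed ("heterogeneous", hard) ones.  The boundary can be horizontal
  (up/down halves) or vertical (left/right halves).
* **jumbled** arrays: local orientation variability is controlled by a
  smooth per-pixel difficulty field built from 1/f^2 noise that is
  histogram-equalised to a U-shaped parabolic reference distribution, so
  most cells end up clearly easy or clearly hard.

Uniformly easy/hard arrays are available as the degenerate cases.

Coordinate conventions: pixel origin at the screen top-left, x rightward,
y downward; half-open pixel intervals; cell indices 0-based ``(col, row)``.
Orientations are radians counter-clockwise from horizontal-rightward and
are stored modulo pi (line segments are unoriented).  The default target
orientation is pi/4.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

__all__ = [
    "DEFAULT_THETA",
    "GENERATION_SIZE",
    "EXP1_GRID",
    "EXP2_GRID",
    "GridSpec",
    "DifficultyMap",
    "OrientationRangeMapping",
    "TargetSpec",
    "StimulusArray",
    "generate_noise_field",
    "parabola_cdf",
    "parabola_ppf",
    "equalize_to_parabola",
    "cell_difficulties",
    "range_from_difficulty",
    "sample_orientation_grid",
    "orientation_in_interval",
    "split_hard_mask",
    "eligible_target_cells",
    "place_target",
    "make_split_half",
    "make_uniform",
    "make_jumbled",
    "render_stimulus",
    "stimulus_to_dict",
    "write_stimulus_json",
]

DEFAULT_THETA = math.pi / 4
#: FFT generation size for the noise field (powers of two).
GENERATION_SIZE = 1024

_SIDES_BY_AXIS = {"horizontal": ("up", "down"), "vertical": ("left", "right")}


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the search array: a grid of square cells on the screen."""

    n_cols: int
    n_rows: int
    cell_px: int
    origin_px: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.n_cols < 2 or self.n_rows < 2:
            raise ValueError("grid must be at least 2x2 cells")
        if self.cell_px <= 0:
            raise ValueError("cell_px must be positive")

    @property
    def extent_px(self) -> tuple[int, int]:
        """(width, height) of the array in pixels."""
        return (self.n_cols * self.cell_px, self.n_rows * self.cell_px)

    @property
    def centre_px(self) -> tuple[float, float]:
        w, h = self.extent_px
        return (self.origin_px[0] + w / 2.0, self.origin_px[1] + h / 2.0)

    def contains(self, x: float, y: float) -> bool:
        """Half-open containment test: [origin, origin + extent)."""
        ox, oy = self.origin_px
        w, h = self.extent_px
        return (ox <= x < ox + w) and (oy <= y < oy + h)

    def cell_centre(self, col: int, row: int) -> tuple[float, float]:
        ox, oy = self.origin_px
        return (ox + (col + 0.5) * self.cell_px, oy + (row + 0.5) * self.cell_px)

    def cell_at(self, x: float, y: float) -> tuple[int, int] | None:
        """(col, row) of the cell containing the pixel, or None if outside."""
        if not self.contains(x, y):
            return None
        ox, oy = self.origin_px
        col = int((x - ox) // self.cell_px)
        row = int((y - oy) // self.cell_px)
        return (col, row)


#: 22 x 16 array of 32-px cells centred on a 1024 x 768 screen.
EXP1_GRID = GridSpec(22, 16, 32, origin_px=((1024 - 22 * 32) // 2, (768 - 16 * 32) // 2))
#: 32 x 24 array of 32-px cells (1024 x 768 extent) centred on a 1280 x 1024 screen.
EXP2_GRID = GridSpec(32, 24, 32, origin_px=((1280 - 32 * 32) // 2, (1024 - 24 * 32) // 2))


@dataclass(frozen=True)
class DifficultyMap:
    """Per-pixel scalar field in [0, 1] controlling local heterogeneity."""

    values: np.ndarray  # shape (height, width)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("difficulty map must be a non-empty 2-D array")
        if not np.isfinite(v).all():
            raise ValueError("difficulty map values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def width_px(self) -> int:
        return self.values.shape[1]

    @property
    def height_px(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class OrientationRangeMapping:
    """Linear map from difficulty to the full width of the orientation range.

    Difficulty 0 maps to ``range_min`` (default pi/6) and difficulty 1 to
    ``range_max`` (default 2*pi/3).
    """

    range_min: float = math.pi / 6
    range_max: float = 2 * math.pi / 3

    def __post_init__(self) -> None:
        if not (0 < self.range_min < self.range_max <= math.pi):
            raise ValueError("require 0 < range_min < range_max <= pi")


@dataclass(frozen=True)
class TargetSpec:
    present: bool
    cell: tuple[int, int] | None = None  # (col, row)
    orientation: float = DEFAULT_THETA


@dataclass(frozen=True)
class StimulusArray:
    """A fully specified search array.

    ``orientations`` and ``cell_difficulty`` have shape (n_rows, n_cols);
    orientations are stored modulo pi.  Regenerating with the same seed and
    configuration reproduces the array bit-exactly.
    """

    grid: GridSpec
    orientations: np.ndarray
    cell_difficulty: np.ndarray
    condition: str  # easy | hard | split_half | jumbled
    configuration: str  # hard_up | hard_down | hard_left | hard_right | none
    target: TargetSpec
    seed: int
    mapping: OrientationRangeMapping = field(default_factory=OrientationRangeMapping)

    def __post_init__(self) -> None:
        shape = (self.grid.n_rows, self.grid.n_cols)
        if self.orientations.shape != shape or self.cell_difficulty.shape != shape:
            raise ValueError(f"per-cell arrays must have shape {shape}")

    def cell_ranges(self) -> np.ndarray:
        return range_from_difficulty(self.cell_difficulty, self.mapping)


def generate_noise_field(
    size_px: tuple[int, int],
    exponent: float = 2.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    generation_px: int = GENERATION_SIZE,
) -> DifficultyMap:
    """Build a random-phase noise field with amplitude spectrum ~ 1/f**exponent.

    The field is generated at ``generation_px`` squared via an inverse FFT of
    the deterministic amplitude spectrum combined with i.i.d. uniform random
    phases, cropped from the top-left corner to ``size_px = (width, height)``
    and min-max scaled to [0, 1].  Taking the real part of the inverse
    transform is equivalent to enforcing Hermitian symmetry on the spectrum.
    """
    width, height = size_px
    if width <= 0 or height <= 0:
        raise ValueError("field dimensions must be positive")
    if width > generation_px or height > generation_px:
        raise ValueError(
            f"requested size {size_px} exceeds generation size {generation_px}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    n = generation_px
    freq = np.fft.fftfreq(n)
    f = np.hypot(freq[None, :], freq[:, None])
    with np.errstate(divide="ignore"):
        amplitude = np.where(f > 0, f ** -float(exponent), 0.0)  # DC term zeroed
    phase = rng.uniform(0.0, 2 * np.pi, size=(n, n))
    field = np.fft.ifft2(amplitude * np.exp(1j * phase)).real
    field = field[:height, :width]
    lo, hi = field.min(), field.max()
    if hi > lo:
        field = (field - lo) / (hi - lo)
    else:  # degenerate constant field
        field = np.zeros_like(field)
    return DifficultyMap(field)


def parabola_cdf(x):
    """CDF of the U-shaped parabolic reference density f(x) = 3(2x-1)^2 on [0,1]."""
    x = np.asarray(x, dtype=float)
    return ((2 * x - 1) ** 3 + 1) / 2


def parabola_ppf(u):
    """Inverse CDF of the parabolic reference density."""
    u = np.asarray(u, dtype=float)
    return 0.5 * (1 + np.cbrt(2 * u - 1))


def equalize_to_parabola(dmap: DifficultyMap) -> DifficultyMap:
    """Histogram-equalise a map to the U-shaped parabolic reference density.

    Pixels are rank-transformed to fractional ranks u = (rank - 0.5) / n
    (ties broken by stable ordering on pixel index) and pushed through the
    parabola's inverse CDF.  The output depends on the input only through the
    ordering of its pixels, so any strictly monotone transform of the input
    leaves the output unchanged.
    """
    flat = dmap.values.ravel()
    n = flat.size
    if n == 0:
        raise ValueError("empty difficulty map")
    order = np.argsort(flat, kind="stable")
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(n, dtype=float)
    u = (ranks + 0.5) / n
    out = parabola_ppf(u).reshape(dmap.values.shape)
    return DifficultyMap(out)


def cell_difficulties(dmap: DifficultyMap, grid: GridSpec) -> np.ndarray:
    """Per-cell difficulty: the mean of the map over each cell's pixel block."""
    expected = (grid.n_rows * grid.cell_px, grid.n_cols * grid.cell_px)
    if dmap.values.shape != expected:
        raise ValueError(
            f"map shape {dmap.values.shape} does not match grid extent {expected}"
        )
    c = grid.cell_px
    blocks = dmap.values.reshape(grid.n_rows, c, grid.n_cols, c)
    return blocks.mean(axis=(1, 3))


def range_from_difficulty(d, mapping: OrientationRangeMapping | None = None):
    """Orientation-range width for difficulty ``d`` (linear interpolation)."""
    if mapping is None:
        mapping = OrientationRangeMapping()
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(d > 1):
        raise ValueError("difficulty must lie in [0, 1]")
    out = mapping.range_min + d * (mapping.range_max - mapping.range_min)
    return float(out) if out.ndim == 0 else out


def sample_orientation_grid(
    cell_ranges: np.ndarray,
    target: TargetSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample distractor orientations uniformly around theta + pi/2.

    Each cell's orientation is drawn from Uniform(centre - range/2,
    centre + range/2) with centre = theta + pi/2 and that cell's range width.
    The target cell, if present, is set to theta exactly.  Results are
    reduced modulo pi.
    """
    theta = target.orientation
    centre = theta + math.pi / 2
    cell_ranges = np.asarray(cell_ranges, dtype=float)
    ori = centre + (rng.random(cell_ranges.shape) - 0.5) * cell_ranges
    ori = np.mod(ori, math.pi)
    if target.present:
        if target.cell is None:
            raise ValueError("present target must have a cell")
        col, row = target.cell
        ori[row, col] = theta % math.pi
    return ori


def orientation_in_interval(orientation, centre: float, width: float, atol: float = 1e-9):
    """Whether an orientation (mod pi) lies within ``centre +/- width/2``.

    Membership is assessed on the circle of unoriented lines (period pi), so
    intervals that wrap past pi are handled correctly.
    """
    o = np.asarray(orientation, dtype=float)
    d = np.mod(o - centre + math.pi / 2, math.pi) - math.pi / 2
    return np.abs(d) <= width / 2 + atol


def split_hard_mask(grid: GridSpec, axis: str, hard_side: str) -> np.ndarray:
    """Boolean (n_rows, n_cols) mask of the heterogeneous (hard) half.

    ``axis`` is the orientation of the dividing line: a *horizontal* boundary
    splits the array into up/down halves, a *vertical* one into left/right.
    """
    if axis not in _SIDES_BY_AXIS:
        raise ValueError(f"unknown axis {axis!r}")
    if hard_side not in _SIDES_BY_AXIS[axis]:
        raise ValueError(f"hard_side {hard_side!r} inconsistent with axis {axis!r}")
    mask = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    if axis == "horizontal":
        upper = np.arange(grid.n_rows) < grid.n_rows / 2
        mask[upper if hard_side == "up" else ~upper, :] = True
    else:
        left = np.arange(grid.n_cols) < grid.n_cols / 2
        mask[:, left if hard_side == "left" else ~left] = True
    return mask


def eligible_target_cells(grid: GridSpec, half_mask: np.ndarray | None = None) -> np.ndarray:
    """Cells where a target may be placed.

    Excludes the outermost ring of cells and the four cells nearest the
    array centre; optionally intersected with a half mask.
    """
    mask = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    mask[1:-1, 1:-1] = True
    # four central cells = the four cell centres nearest the array centre
    dc = (np.arange(grid.n_cols) + 0.5) - grid.n_cols / 2
    dr = (np.arange(grid.n_rows) + 0.5) - grid.n_rows / 2
    d2 = dr[:, None] ** 2 + dc[None, :] ** 2
    central = np.argsort(d2.ravel(), kind="stable")[:4]
    rows, cols = np.unravel_index(central, d2.shape)
    mask[rows, cols] = False
    if half_mask is not None:
        mask = mask & half_mask
    return mask


def place_target(
    grid: GridSpec,
    rng: np.random.Generator,
    half_mask: np.ndarray | None = None,
    theta: float = DEFAULT_THETA,
) -> TargetSpec:
    """Choose a target cell uniformly at random among eligible cells."""
    mask = eligible_target_cells(grid, half_mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("no eligible target cell for this grid/condition")
    i = int(rng.integers(rows.size))
    return TargetSpec(True, (int(cols[i]), int(rows[i])), theta)


def make_split_half(
    grid: GridSpec = EXP1_GRID,
    axis: str = "horizontal",
    hard_side: str = "up",
    target_half: str = "absent",
    mapping: OrientationRangeMapping | None = None,
    seed: int = 0,
    theta: float = DEFAULT_THETA,
) -> StimulusArray:
    """Generate a split-half stimulus.

    ``target_half`` is one of ``{"easy", "hard", "absent"}`` and controls
    where (and whether) the target is placed.
    """
    if mapping is None:
        mapping = OrientationRangeMapping()
    if target_half not in ("easy", "hard", "absent"):
        raise ValueError(f"unknown target_half {target_half!r}")
    rng = np.random.default_rng(seed)
    hard = split_hard_mask(grid, axis, hard_side)
    difficulty = hard.astype(float)
    if target_half == "absent":
        target = TargetSpec(False, None, theta)
    else:
        target = place_target(grid, rng, hard if target_half == "hard" else ~hard, theta)
    ranges = range_from_difficulty(difficulty, mapping)
    ori = sample_orientation_grid(ranges, target, rng)
    return StimulusArray(
        grid, ori, difficulty, "split_half", f"hard_{hard_side}", target, seed, mapping
    )


def make_uniform(
    condition: str,
    grid: GridSpec = EXP2_GRID,
    target_present: bool = False,
    mapping: OrientationRangeMapping | None = None,
    seed: int = 0,
    theta: float = DEFAULT_THETA,
) -> StimulusArray:
    """Generate a uniformly easy (difficulty 0) or hard (difficulty 1) stimulus."""
    if condition not in ("easy", "hard"):
        raise ValueError(f"uniform condition must be easy or hard, got {condition!r}")
    if mapping is None:
        mapping = OrientationRangeMapping()
    rng = np.random.default_rng(seed)
    level = 0.0 if condition == "easy" else 1.0
    difficulty = np.full((grid.n_rows, grid.n_cols), level)
    target = place_target(grid, rng, theta=theta) if target_present else TargetSpec(False, None, theta)
    ranges = range_from_difficulty(difficulty, mapping)
    ori = sample_orientation_grid(ranges, target, rng)
    return StimulusArray(grid, ori, difficulty, condition, "none", target, seed, mapping)


def make_jumbled(
    grid: GridSpec = EXP2_GRID,
    mapping: OrientationRangeMapping | None = None,
    target_present: bool = False,
    seed: int = 0,
    theta: float = DEFAULT_THETA,
    exponent: float = 2.0,
) -> StimulusArray:
    """Generate a jumbled stimulus from a parabola-equalised 1/f^2 field."""
    if mapping is None:
        mapping = OrientationRangeMapping()
    rng = np.random.default_rng(seed)
    noise = generate_noise_field(grid.extent_px, exponent=exponent, rng=rng)
    equalised = equalize_to_parabola(noise)
    difficulty = cell_difficulties(equalised, grid)
    target = place_target(grid, rng, theta=theta) if target_present else TargetSpec(False, None, theta)
    ranges = range_from_difficulty(difficulty, mapping)
    ori = sample_orientation_grid(ranges, target, rng)
    return StimulusArray(grid, ori, difficulty, "jumbled", "none", target, seed, mapping)


def render_stimulus(
    stim: StimulusArray,
    out_path: str | Path | None = None,
    line_len: float | None = None,
    line_width: int = 2,
    background: int = 180,
    screen_px: tuple[int, int] | None = None,
) -> Image.Image:
    """Render the array as black line segments on a uniform grey background.

    The image spans the full screen extent (inferred from the grid origin if
    not given).  Each segment is drawn through its cell centre at the cell's
    orientation; a 0-orientation segment is horizontal.
    """
    grid = stim.grid
    if screen_px is None:
        w, h = grid.extent_px
        screen_px = (grid.origin_px[0] * 2 + w, grid.origin_px[1] * 2 + h)
    if line_len is None:
        line_len = 0.75 * grid.cell_px
    img = Image.new("L", screen_px, color=background)
    draw = ImageDraw.Draw(img)
    half = line_len / 2.0
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            cx, cy = grid.cell_centre(col, row)
            o = stim.orientations[row, col]
            dx, dy = half * math.cos(o), -half * math.sin(o)  # screen y points down
            draw.line([(cx - dx, cy - dy), (cx + dx, cy + dy)], fill=0, width=line_width)
    if out_path is not None:
        img.save(Path(out_path), format="PNG")
    return img


def stimulus_to_dict(stim: StimulusArray) -> dict:
    """JSON-serialisable metadata for a stimulus."""
    return {
        "grid": {
            "n_cols": stim.grid.n_cols,
            "n_rows": stim.grid.n_rows,
            "cell_px": stim.grid.cell_px,
            "origin_px": list(stim.grid.origin_px),
        },
        "condition": stim.condition,
        "configuration": stim.configuration,
        "seed": stim.seed,
        "target": {
            "present": stim.target.present,
            "cell": list(stim.target.cell) if stim.target.cell else None,
            "orientation": stim.target.orientation,
        },
        "mapping": {"range_min": stim.mapping.range_min, "range_max": stim.mapping.range_max},
        "cell_difficulty": stim.cell_difficulty.tolist(),
        "orientations": stim.orientations.tolist(),
        "viewing_distance_cm": 50,
    }


def write_stimulus_json(stim: StimulusArray, path: str | Path) -> None:
    Path(path).write_text(json.dumps(stimulus_to_dict(stim)))
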
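"""Gridworld MDP on a lesion-bearing 2-D image.

The image is tiled into square blocks (default 60 px on a 240 px image,
giving a 4x4 grid).  The agent occupies one block, starts in the top-left
corner, and may stay still, move down, or move right.  Rewards encourage
reaching and remaining on a block that overlaps the lesion mask:

* stay on a non-overlapping block: -2
* stay on an overlapping block:    +1
* move to a non-overlapping block: -0.5
* move to an overlapping block:    +1

Moves past the last row/column are clipped (the block is unchanged) and
rewarded by the move rule at the unchanged position, so every action is
defined in every state and the MDP has no terminal states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "Action",
    "GridSpec",
    "LesionImage",
    "AgentState",
    "StepOutcome",
    "REWARD_STAY_OFF",
    "REWARD_MOVE_OFF",
    "REWARD_ON_LESION",
    "build_grid",
    "initial_state",
    "block_overlap",
    "step",
    "encode_observation",
    "reachable_blocks",
]

REWARD_STAY_OFF = -2.0
REWARD_MOVE_OFF = -0.5
REWARD_ON_LESION = 1.0

REWARD_VALUES = (REWARD_STAY_OFF, REWARD_MOVE_OFF, REWARD_ON_LESION)


class Action(IntEnum):
    """The three actions. Integer codes follow the stay/down/right ordering."""

    STAY = 1
    DOWN = 2
    RIGHT = 3

    @property
    def index(self) -> int:
        """0-based index used for array lookups and network outputs."""
        return int(self) - 1


@dataclass(frozen=True)
class GridSpec:
    """Tiling of an image into square blocks."""

    image_height: int
    image_width: int
    block_size: int = 60

    def __post_init__(self) -> None:
        if self.block_size <= 0:
            raise ValueError("block_size must be positive")
        for axis, dim in (("height", self.image_height), ("width", self.image_width)):
            if dim % self.block_size != 0:
                raise ValueError(
                    f"image {axis} {dim} is not divisible by block size "
                    f"{self.block_size}"
                )

    @property
    def n_rows(self) -> int:
        return self.image_height // self.block_size

    @property
    def n_cols(self) -> int:
        return self.image_width // self.block_size

    @property
    def n_blocks(self) -> int:
        return self.n_rows * self.n_cols

    def block_slices(self, row: int, col: int) -> tuple[slice, slice]:
        """Half-open pixel ranges covered by block (row, col)."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"block ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        b = self.block_size
        return slice(row * b, (row + 1) * b), slice(col * b, (col + 1) * b)


@dataclass
class LesionImage:
    """A grayscale raster in [0, 1] with a same-shape binary lesion mask.

    ``meta`` carries optional provenance (e.g. the generator's lesion
    placement) and plays no role in the MDP.
    """

    id: str
    intensities: np.ndarray
    lesion_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        self.lesion_mask = np.asarray(self.lesion_mask) != 0
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D array")
        if self.intensities.shape != self.lesion_mask.shape:
            raise ValueError(
                f"mask shape {self.lesion_mask.shape} does not match image "
                f"shape {self.intensities.shape}"
            )
        if not self.lesion_mask.any():
            raise ValueError("lesion mask has no positive pixel")
        lo = float(self.intensities.min())
        hi = float(self.intensities.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"intensities outside [0, 1] (range [{lo}, {hi}])")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


def normalize_intensities(raw: np.ndarray) -> np.ndarray:
    """Per-image min-max normalization to [0, 1] (constant images map to 0)."""
    raw = np.asarray(raw, dtype=np.float32)
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


@dataclass(frozen=True)
class AgentState:
    """Agent block coordinates on an image; row grows downward."""

    image: LesionImage
    grid: GridSpec
    row: int
    col: int

    def __post_init__(self) -> None:
        if not (0 <= self.row < self.grid.n_rows):
            raise ValueError(f"row {self.row} outside [0, {self.grid.n_rows})")
        if not (0 <= self.col < self.grid.n_cols):
            raise ValueError(f"col {self.col} outside [0, {self.grid.n_cols})")

    @property
    def block(self) -> tuple[int, int]:
        return (self.row, self.col)


@dataclass(frozen=True)
class StepOutcome:
    next_state: AgentState
    reward: float
    moved: bool
    clipped: bool


def build_grid(image: LesionImage, block_size: int = 60) -> GridSpec:
    """Tile ``image`` exactly with square blocks of ``block_size`` pixels."""
    h, w = image.shape
    return GridSpec(image_height=h, image_width=w, block_size=block_size)


def initial_state(image: LesionImage, block_size: int = 60) -> AgentState:
    """The fixed starting state: the top-left block."""
    return AgentState(image=image, grid=build_grid(image, block_size), row=0, col=0)


def block_overlap(image: LesionImage, row: int, col: int, grid: GridSpec | None = None) -> bool:
    """True iff at least one lesion-mask pixel lies inside block (row, col)."""
    if grid is None:
        grid = build_grid(image)
    rs, cs = grid.block_slices(row, col)
    return bool(image.lesion_mask[rs, cs].any())


# Displacement (drow, dcol) per action.
_MOVES = {Action.STAY: (0, 0), Action.DOWN: (1, 0), Action.RIGHT: (0, 1)}


def step(state: AgentState, action: Action) -> StepOutcome:
    """Deterministic transition + reward.  Off-grid moves are clipped."""
    action = Action(action)
    grid = state.grid
    drow, dcol = _MOVES[action]
    row = state.row + drow
    col = state.col + dcol
    clipped = False
    if row >= grid.n_rows or col >= grid.n_cols:
        row, col = state.row, state.col
        clipped = True
    next_state = AgentState(image=state.image, grid=grid, row=row, col=col)
    on_lesion = block_overlap(state.image, row, col, grid)
    if action is Action.STAY:
        reward = REWARD_ON_LESION if on_lesion else REWARD_STAY_OFF
    else:
        # A clipped move is still a move: the move rule applies at the
        # (unchanged) landing block.
        reward = REWARD_ON_LESION if on_lesion else REWARD_MOVE_OFF
    return StepOutcome(next_state=next_state, reward=reward,
                       moved=action is not Action.STAY, clipped=clipped)


def encode_observation(state: AgentState) -> np.ndarray:
    """Two-channel float32 raster the network sees.

    Channel 0 is the (state-independent) normalized image; channel 1 is a
    binary indicator of the agent's current block, so the encoding is
    injective in the agent position while preserving image content.
    """
    h, w = state.image.shape
    obs = np.zeros((2, h, w), dtype=np.float32)
    obs[0] = state.image.intensities
    rs, cs = state.grid.block_slices(state.row, state.col)
    obs[1, rs, cs] = 1.0
    return obs


def reachable_blocks(grid: GridSpec) -> set[tuple[int, int]]:
    """Blocks reachable from (0, 0) under {STAY, DOWN, RIGHT} (the full grid)."""
    seen: set[tuple[int, int]] = set()
    frontier = [(0, 0)]
    while frontier:
        row, col = frontier.pop()
        if (row, col) in seen:
            continue
        seen.add((row, col))
        if row + 1 < grid.n_rows:
            frontier.append((row + 1, col))
        if col + 1 < grid.n_cols:
            frontier.append((row, col + 1))
    return seen
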
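"""Half-plane whisker stimulation.

A tactile stimulus is modelled as a half plane sweeping across a rectangular
grid of whiskers: whiskers already passed over by the plane's leading edge are
deflected, the rest are untouched.  Each deflected whisker's deflection
direction is drawn from a Von Mises distribution centred on the movement
direction of the plane, so the concentration parameter ``kappa`` controls how
tightly the single-whisker directions agree with the global stimulus motion
(``kappa = 0`` — independent uniform directions; ``kappa = inf`` — every
whisker deflected exactly along the stimulus direction).

Control conditions (location shuffling, direction decorrelation) and the
simulated experimental manipulations (chessboard whisker deprivation,
anti-correlated central whisker) operate on sampled events and are composed
by :func:`stimulus_stream`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "WhiskerField",
    "StimulusEvent",
    "StimulusConfig",
    "GenerationError",
    "make_whisker_field",
    "half_plane_deflection",
    "sample_stimulus",
    "apply_shuffle_control",
    "apply_decorrelate_control",
    "apply_manipulations",
    "stimulus_stream",
    "events_to_csv",
]

TWO_PI = 2.0 * math.pi


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot produce a non-empty stimulus."""


@dataclass(frozen=True)
class WhiskerField:
    """Rectangular grid of whisker base positions.

    Whisker ``i`` sits at row ``i // cols``, column ``i % cols``; its planar
    coordinate is ``(col * spacing, row * spacing)``, so horizontally and
    vertically adjacent whiskers are ``spacing`` apart and diagonal
    neighbours ``spacing * sqrt(2)`` apart.
    """

    rows: int
    cols: int
    spacing: float
    positions: np.ndarray  # (rows*cols, 2), x = col*spacing, y = row*spacing

    @property
    def n_whiskers(self) -> int:
        return self.rows * self.cols

    def index(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise IndexError(f"whisker (row={row}, col={col}) out of range")
        return row * self.cols + col

    def row_col(self, index: int) -> tuple[int, int]:
        if not (0 <= index < self.n_whiskers):
            raise IndexError(f"whisker index {index} out of range")
        return divmod(index, self.cols)


def make_whisker_field(rows: int = 5, cols: int = 5, spacing: float = 1.0) -> WhiskerField:
    """Build the whisker grid (default: the 5x5 pad with unit spacing)."""
    if rows < 1 or cols < 1:
        raise ValueError(f"grid dimensions must be positive, got {rows}x{cols}")
    if not spacing > 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    r, c = np.divmod(np.arange(rows * cols), cols)
    positions = np.column_stack([c * spacing, r * spacing]).astype(float)
    return WhiskerField(rows=rows, cols=cols, spacing=float(spacing), positions=positions)


@dataclass(frozen=True)
class StimulusEvent:
    """One half-plane contact.

    ``deflection_dir`` is NaN wherever ``deflected`` is False.  ``kappa`` is
    the per-whisker Von Mises concentration the directions were drawn with;
    ``math.inf`` marks the exact delta case (no sampling performed).
    """

    origin: np.ndarray          # (2,) point on the boundary line
    theta_s: float              # movement direction, radians in [0, 2pi)
    deflected: np.ndarray       # (n,) bool
    deflection_dir: np.ndarray  # (n,) radians, NaN where undeflected
    kappa: float

    @property
    def n_deflected(self) -> int:
        return int(self.deflected.sum())


@dataclass(frozen=True)
class StimulusConfig:
    """Training-condition parameters for the stimulus generator.

    Parameters
    ----------
    kappa : Von Mises concentration of per-whisker deflection noise around the
        stimulus movement direction (``math.inf`` = no noise).
    direction_anisotropy : concentration of the distribution of the movement
        direction itself; 0 means uniform, ``math.inf`` fixes it at
        ``direction_mean``.
    direction_mean : centre of the movement-direction distribution, radians.
    origin_margin : how far beyond the whisker bounding box (grid units, per
        side) the boundary's anchor point may fall.
    control : one of ``none`` / ``shuffle_locations`` / ``decorrelate_direction``.
    decorrelate_kappa : concentration used when redrawing directions in the
        decorrelation control (defaults to 3, the headline training condition).
    deprived_mask : per-whisker booleans; True = whisker never deflected
        (trimming manipulation).
    anticorrelated_whisker : index of a whisker whose deflection direction is
        rotated by pi whenever it is deflected.
    """

    kappa: float = 3.0
    direction_anisotropy: float = 0.0
    direction_mean: float = math.pi / 2.0
    origin_margin: float = 0.5
    control: str = "none"
    decorrelate_kappa: float = 3.0
    deprived_mask: Optional[np.ndarray] = None
    anticorrelated_whisker: Optional[int] = None
    max_rejections: int = 1000

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if self.direction_anisotropy < 0:
            raise ValueError("direction_anisotropy must be >= 0")
        if self.origin_margin < 0:
            raise ValueError("origin_margin must be >= 0")
        if self.control not in ("none", "shuffle_locations", "decorrelate_direction"):
            raise ValueError(f"unknown control {self.control!r}")


def half_plane_deflection(
    positions: np.ndarray, origin: np.ndarray, theta_s: float
) -> np.ndarray:
    """Which positions a half plane moving along ``theta_s`` has swept over.

    The boundary passes through ``origin`` with outward normal
    ``(cos theta_s, sin theta_s)``; points with signed projection <= 0 onto
    that normal (boundary included) have been swept and are deflected.
    """
    normal = np.array([math.cos(theta_s), math.sin(theta_s)])
    return (np.asarray(positions, dtype=float) - np.asarray(origin, dtype=float)) @ normal <= 0.0


def _sample_von_mises(mu, kappa: float, rng: np.random.Generator, size=None) -> np.ndarray:
    """Von Mises draw wrapped to [0, 2pi); kappa=0 is exactly uniform."""
    if math.isinf(kappa):
        return np.mod(np.broadcast_to(mu, () if size is None else size), TWO_PI).copy()
    if kappa == 0.0:
        return rng.uniform(0.0, TWO_PI, size=size)
    return np.mod(rng.vonmises(mu, kappa, size=size), TWO_PI)


def sample_stimulus(
    field: WhiskerField,
    cfg: StimulusConfig,
    rng: np.random.Generator,
    rejection_log: Optional[list] = None,
) -> StimulusEvent:
    """Draw one half-plane contact event.

    The boundary line passes through a point drawn uniformly over the whisker
    bounding box expanded by ``origin_margin`` per side, with outward normal
    along the movement direction ``theta_s``.  Whiskers on the swept side
    (signed projection onto the normal <= 0, boundary points included) are
    deflected; each deflected whisker's direction is an independent Von Mises
    draw centred on ``theta_s``.  Events deflecting no whisker are rejected
    and resampled; the number of rejections is appended to ``rejection_log``
    if given.
    """
    lo = field.positions.min(axis=0) - cfg.origin_margin
    hi = field.positions.max(axis=0) + cfg.origin_margin
    rejections = 0
    while True:
        origin = rng.uniform(lo, hi)
        if math.isinf(cfg.direction_anisotropy):
            theta_s = float(np.mod(cfg.direction_mean, TWO_PI))
        elif cfg.direction_anisotropy == 0.0:
            theta_s = float(rng.uniform(0.0, TWO_PI))
        else:
            theta_s = float(_sample_von_mises(cfg.direction_mean, cfg.direction_anisotropy, rng))
        deflected = half_plane_deflection(field.positions, origin, theta_s)
        if deflected.any():
            break
        rejections += 1
        if rejections >= cfg.max_rejections:
            raise GenerationError(
                f"no non-empty stimulus after {rejections} tries; "
                f"origin_margin={cfg.origin_margin} may be degenerate"
            )
    if rejection_log is not None:
        rejection_log.append(rejections)

    directions = np.full(field.n_whiskers, np.nan)
    idx = np.flatnonzero(deflected)
    directions[idx] = _sample_von_mises(theta_s, cfg.kappa, rng, size=idx.size)
    return StimulusEvent(
        origin=origin, theta_s=theta_s, deflected=deflected,
        deflection_dir=directions, kappa=cfg.kappa,
    )


def apply_shuffle_control(
    event: StimulusEvent, field: WhiskerField, rng: np.random.Generator
) -> StimulusEvent:
    """Relocate the deflected set to a uniformly random subset of positions.

    The number of deflected whiskers and the multiset of deflection directions
    are preserved; all somatotopic information about *which* whiskers moved is
    destroyed.
    """
    k = event.n_deflected
    new_idx = rng.choice(field.n_whiskers, size=k, replace=False)
    deflected = np.zeros(field.n_whiskers, dtype=bool)
    deflected[new_idx] = True
    directions = np.full(field.n_whiskers, np.nan)
    # new_idx is already in random order, so this is a random bijection from
    # old deflected whiskers to new ones — no index/direction coupling
    directions[new_idx] = event.deflection_dir[event.deflected]
    return replace(event, deflected=deflected, deflection_dir=directions)


def apply_decorrelate_control(
    event: StimulusEvent, kappa: float, rng: np.random.Generator
) -> StimulusEvent:
    """Redraw all deflection directions about a random mean.

    The deflected set is kept, so whiskers still move in similar directions to
    one another, but the shared mean ``mu*`` is uniform on the circle and
    independent of the stimulus movement direction.
    """
    mu_star = float(rng.uniform(0.0, TWO_PI))
    directions = np.full(event.deflection_dir.shape, np.nan)
    idx = np.flatnonzero(event.deflected)
    directions[idx] = _sample_von_mises(mu_star, kappa, rng, size=idx.size)
    return replace(event, deflection_dir=directions)


def apply_manipulations(event: StimulusEvent, cfg: StimulusConfig) -> StimulusEvent:
    """Apply whisker deprivation and/or the anti-correlated-whisker rotation."""
    deflected = event.deflected
    directions = event.deflection_dir
    if cfg.deprived_mask is not None:
        mask = np.asarray(cfg.deprived_mask, dtype=bool)
        if mask.shape != deflected.shape:
            raise ValueError("deprived_mask length does not match whisker count")
        deflected = deflected & ~mask
        directions = np.where(deflected, directions, np.nan)
    if cfg.anticorrelated_whisker is not None:
        w = cfg.anticorrelated_whisker
        if not (0 <= w < deflected.size):
            raise ValueError(f"anticorrelated_whisker {w} out of range")
        if deflected[w]:
            directions = directions.copy()
            directions[w] = math.fmod(directions[w] + math.pi, TWO_PI)
    return replace(event, deflected=deflected, deflection_dir=directions)


def stimulus_stream(
    field: WhiskerField,
    cfg: StimulusConfig,
    rng: np.random.Generator,
    n_events: Optional[int] = None,
) -> Iterator[StimulusEvent]:
    """Yield fully processed events: sampling, then control, then manipulations."""
    count = 0
    while n_events is None or count < n_events:
        event = sample_stimulus(field, cfg, rng)
        if cfg.control == "shuffle_locations":
            event = apply_shuffle_control(event, field, rng)
        elif cfg.control == "decorrelate_direction":
            event = apply_decorrelate_control(event, cfg.decorrelate_kappa, rng)
        if cfg.deprived_mask is not None or cfg.anticorrelated_whisker is not None:
            event = apply_manipulations(event, cfg)
        yield event
        count += 1


def events_to_csv(events, path) -> None:
    """Dump an event stream to CSV.

    Columns: ``event, origin_x, origin_y, theta_s, defl_00..defl_NN (0/1),
    dir_00..dir_NN`` (empty where undeflected).
    """
    import csv

    events = list(events)
    if not events:
        raise ValueError("no events to write")
    n = events[0].deflected.size
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = (
            ["event", "origin_x", "origin_y", "theta_s"]
            + [f"defl_{i:02d}" for i in range(n)]
            + [f"dir_{i:02d}" for i in range(n)]
        )
        writer.writerow(header)
        for i, ev in enumerate(events):
            dirs = ["" if not d else f"{ev.deflection_dir[j]:.6f}"
                    for j, d in enumerate(ev.deflected)]
            writer.writerow(
                [i, f"{ev.origin[0]:.6f}", f"{ev.origin[1]:.6f}", f"{ev.theta_s:.6f}"]
                + [int(d) for d in ev.deflected] + dirs
            )
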
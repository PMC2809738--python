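"""The recurrent layer-2/3 sheet: architecture, settling, Hebbian learning.

The sheet is a square grid of neurons partitioned into supra-barrels, one per
whisker.  Each neuron receives

* an *afferent* connection field: one weight per direction-tuned unit of its
  own barrel (all-to-one barrel -> supra-barrel connectivity),
* a fixed *lateral excitatory* field from itself and its 8 immediate
  neighbours, and
* a plastic *lateral inhibitory* field from every neuron inside a window four
  supra-barrel widths across, centred on it and clipped at the sheet border.

Each field's weights are initialised to uniform random values normalised to
sum to 1, and divisive normalisation keeps that sum exactly 1 after every
Hebbian update, so learning redistributes synaptic resources instead of
saturating them.  A stimulus is processed by computing the afferent drive
(a weighted sum of barrel activity, held fixed), settling the lateral
dynamics through a piecewise-linear sigmoid for a fixed number of synchronous
steps, applying the Hebbian rule to the afferent and inhibitory fields of
active neurons, and resetting activity.

The sigmoid thresholds, lateral gains, and learning-rate numerators default
to values calibrated in pilot runs so that settled activity condenses into
bubbles smaller than one supra-barrel (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Callable, Iterator, Optional, Sequence

import numpy as np

from . import _kernels
from ._kernels import piecewise_sigmoid, settle_reference
from .l4 import L4Activity, MEDAssignment
from .stimulus import StimulusEvent

__all__ = [
    "Architecture",
    "CorticalState",
    "TrainingLog",
    "SettleResult",
    "piecewise_sigmoid",
    "init_network",
    "afferent_activation",
    "settle",
    "hebbian_update",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class Architecture:
    """Geometry and dynamics parameters of the cortical sheet.

    The sheet has ``barrel_rows * supra_size`` x ``barrel_cols * supra_size``
    neurons; the inhibitory window is always four supra-barrel widths across.
    ``delta``/``beta`` are the lower threshold and saturation point of the
    piecewise-linear sigmoid; ``gamma_E``/``gamma_I`` scale the lateral
    excitatory and inhibitory terms; ``c_A``/``c_I`` are learning-rate
    numerators, with the per-field rate ``alpha = c / N_CF`` for a field of
    ``N_CF`` connections.
    """

    barrel_rows: int = 5
    barrel_cols: int = 5
    supra_size: int = 21
    units_per_barrel: int = 25
    excitatory_radius: int = 1
    settling_steps: int = 9
    delta: float = 0.187
    beta: float = 1.015
    gamma_E: float = 1.31
    gamma_I: float = 3.68
    c_A: float = 0.35
    c_I: float = 0.1
    excit_init: str = "uniform"  # "uniform" (constant kernel) or "random" (then frozen)
    sparse_threshold: int = -1  # settle strategy switch; -1 = extent^2 / 8 (see _kernels)

    def __post_init__(self) -> None:
        if self.supra_size % 2 == 0:
            raise ValueError("supra_size must be odd (the template centre must be a neuron)")
        if not self.beta > self.delta >= 0.0:
            raise ValueError("require beta > delta >= 0")
        if self.excit_init not in ("random", "uniform"):
            raise ValueError(f"unknown excit_init {self.excit_init!r}")

    @property
    def sheet_rows(self) -> int:
        return self.barrel_rows * self.supra_size

    @property
    def sheet_cols(self) -> int:
        return self.barrel_cols * self.supra_size

    @property
    def n_neurons(self) -> int:
        return self.sheet_rows * self.sheet_cols

    @property
    def inhib_extent(self) -> int:
        return 4 * self.supra_size

    @property
    def excit_extent(self) -> int:
        return 2 * self.excitatory_radius + 1

    @property
    def n_barrels(self) -> int:
        return self.barrel_rows * self.barrel_cols

    def barrel_index_map(self) -> np.ndarray:
        """(rows, cols) int array mapping each neuron to its barrel index."""
        r = np.arange(self.sheet_rows) // self.supra_size
        c = np.arange(self.sheet_cols) // self.supra_size
        return (r[:, None] * self.barrel_cols + c[None, :]).astype(np.int64)


def _window_offsets(extent: int) -> int:
    """Lowest offset of a centred window; even extents lean one cell low."""
    return -(extent // 2)


def _valid_mask(rows: int, cols: int, extent: int) -> np.ndarray:
    """(rows, cols, extent, extent) bool: window entry lies on the sheet."""
    klo = _window_offsets(extent)
    r = np.arange(rows)[:, None] + klo + np.arange(extent)[None, :]
    c = np.arange(cols)[:, None] + klo + np.arange(extent)[None, :]
    rv = (r >= 0) & (r < rows)
    cv = (c >= 0) & (c < cols)
    return rv[:, None, :, None] & cv[None, :, None, :]


@dataclass
class CorticalState:
    """Weights and activity of one network instance."""

    arch: Architecture
    afferent_w: np.ndarray   # (rows, cols, units) float64
    excit_w: np.ndarray      # (rows, cols, Ke, Ke) float64, frozen
    inhib_w: np.ndarray      # (rows, cols, Ki, Ki) float64
    inhib_w32: np.ndarray    # float32 mirror used during settling
    inhib_n_cf: np.ndarray   # (rows, cols) in-sheet connection counts
    activity: np.ndarray     # (rows, cols) float64
    barrel_index: np.ndarray  # (rows, cols) int64

    def copy(self) -> "CorticalState":
        return CorticalState(
            arch=self.arch,
            afferent_w=self.afferent_w.copy(),
            excit_w=self.excit_w.copy(),
            inhib_w=self.inhib_w.copy(),
            inhib_w32=self.inhib_w32.copy(),
            inhib_n_cf=self.inhib_n_cf.copy(),
            activity=self.activity.copy(),
            barrel_index=self.barrel_index.copy(),
        )


def init_network(arch: Architecture, rng: np.random.Generator) -> CorticalState:
    """Initialise all connection fields to normalised uniform-random weights.

    Window entries falling off the sheet are zeroed before normalisation, so
    border fields are renormalised over their surviving connections and every
    field sums to exactly 1 (to float precision).
    """
    rows, cols = arch.sheet_rows, arch.sheet_cols

    aff = rng.random((rows, cols, arch.units_per_barrel))
    aff /= aff.sum(axis=2, keepdims=True)

    Ke = arch.excit_extent
    ev = _valid_mask(rows, cols, Ke)
    if arch.excit_init == "random":
        exc = rng.random((rows, cols, Ke, Ke))
    else:
        exc = np.ones((rows, cols, Ke, Ke))
    exc *= ev
    exc /= exc.sum(axis=(2, 3), keepdims=True)

    Ki = arch.inhib_extent
    iv = _valid_mask(rows, cols, Ki)
    inh = rng.random((rows, cols, Ki, Ki))
    inh *= iv
    inh /= inh.sum(axis=(2, 3), keepdims=True)

    return CorticalState(
        arch=arch,
        afferent_w=aff,
        excit_w=exc,
        inhib_w=inh,
        inhib_w32=inh.astype(np.float32),
        inhib_n_cf=iv.sum(axis=(2, 3)).astype(np.float64),
        activity=np.zeros((rows, cols)),
        barrel_index=arch.barrel_index_map(),
    )


def afferent_activation(state: CorticalState, l4: L4Activity) -> np.ndarray:
    """Feed-forward drive: each neuron's weighted sum of its own barrel's rates."""
    rates = l4.rate[state.barrel_index]          # (rows, cols, units)
    return np.einsum("rcu,rcu->rc", state.afferent_w, rates)


@dataclass
class SettleResult:
    activity: np.ndarray       # (rows, cols) final settled activity
    step_changes: np.ndarray   # (settling_steps,) max |activity change| per step
    history: Optional[np.ndarray] = None  # (settling_steps+1, rows, cols)


def settle(
    state: CorticalState,
    drive: np.ndarray,
    arch: Optional[Architecture] = None,
    record_history: bool = False,
) -> SettleResult:
    """Run the synchronous lateral settling dynamics on a fixed afferent drive."""
    arch = arch or state.arch
    n = arch.settling_steps
    rows, cols = drive.shape
    history = (
        np.zeros((n + 1, rows, cols))
        if record_history
        else np.zeros((0, 0, 0))
    )
    changes = np.zeros(n)
    act = _kernels.settle_kernel(
        np.ascontiguousarray(drive, dtype=np.float64),
        state.excit_w,
        state.inhib_w32,
        _window_offsets(arch.excit_extent),
        _window_offsets(arch.inhib_extent),
        arch.gamma_E,
        arch.gamma_I,
        arch.delta,
        arch.beta,
        n,
        history,
        changes,
        arch.sparse_threshold if arch.sparse_threshold >= 0
        else arch.inhib_extent**2 // 8,
    )
    return SettleResult(
        activity=act,
        step_changes=changes,
        history=history if record_history else None,
    )


def hebbian_update(
    state: CorticalState,
    final_activity: np.ndarray,
    l4: L4Activity,
    arch: Optional[Architecture] = None,
) -> None:
    """Hebbian step with divisive normalisation on the plastic fields.

    For every connection, ``w' = (w + alpha * pre * post) / sum_field(...)``;
    afferent and lateral-inhibitory fields are normalised separately, the
    excitatory field is frozen.  Neurons with zero settled activity keep
    their fields bit-for-bit unchanged.  Activity is reset to zero afterwards.
    """
    arch = arch or state.arch
    rr, cc = np.nonzero(final_activity)
    if rr.size:
        post = final_activity[rr, cc]

        # afferent fields (N_CF = units_per_barrel)
        alpha_a = arch.c_A / arch.units_per_barrel
        pre = l4.rate[state.barrel_index[rr, cc]]          # (n_active, units)
        block = state.afferent_w[rr, cc] + alpha_a * post[:, None] * pre
        block /= block.sum(axis=1, keepdims=True)
        state.afferent_w[rr, cc] = block

        # inhibitory fields (N_CF = per-neuron in-sheet connection count)
        alpha_i = arch.c_I / state.inhib_n_cf
        _kernels.inhib_update_kernel(
            state.inhib_w,
            state.inhib_w32,
            alpha_i,
            _window_offsets(arch.inhib_extent),
            rr.astype(np.int64),
            cc.astype(np.int64),
            post.astype(np.float64),
            rr.size,
        )
    state.activity[:] = 0.0


class TrainingLog:
    """Append-only per-pattern record of the training loop."""

    def __init__(self) -> None:
        self.pattern: list[int] = []
        self.n_deflected: list[int] = []
        self.n_active: list[int] = []
        self.first_step_change: list[float] = []
        self.last_step_change: list[float] = []

    def append(self, pattern: int, n_deflected: int, n_active: int,
               first_change: float, last_change: float) -> None:
        self.pattern.append(pattern)
        self.n_deflected.append(n_deflected)
        self.n_active.append(n_active)
        self.first_step_change.append(first_change)
        self.last_step_change.append(last_change)

    def to_dict(self) -> dict:
        return {
            "pattern": self.pattern,
            "n_deflected": self.n_deflected,
            "n_active": self.n_active,
            "first_step_change": self.first_step_change,
            "last_step_change": self.last_step_change,
        }


def train(
    state: CorticalState,
    stimulus_stream: Iterator[StimulusEvent],
    n_patterns: int,
    meds: MEDAssignment,
    arch: Optional[Architecture] = None,
    log: Optional[TrainingLog] = None,
    tuning_kind: str = "rectified_cosine",
    tuning_exponent: float = 1.0,
    checkpoint_iters: Sequence[int] = (),
    checkpoint_fn: Optional[Callable[[int, CorticalState], None]] = None,
) -> CorticalState:
    """Run the activate -> settle -> learn -> reset loop for ``n_patterns``.

    ``checkpoint_fn(iteration, state)`` is invoked at each iteration listed in
    ``checkpoint_iters`` (0 means before any learning) and, implicitly, after
    the final pattern.
    """
    from .l4 import l4_response

    arch = arch or state.arch
    checkpoints = set(int(i) for i in checkpoint_iters)

    def _maybe_checkpoint(it: int) -> None:
        if checkpoint_fn is not None and it in checkpoints:
            try:
                checkpoint_fn(it, state)
            except Exception as exc:  # surface the pattern index with the failure
                raise RuntimeError(f"checkpoint at pattern {it} failed: {exc}") from exc

    _maybe_checkpoint(0)
    for i in range(n_patterns):
        event = next(stimulus_stream)
        frame = l4_response(event, meds, kind=tuning_kind, exponent=tuning_exponent)
        drive = afferent_activation(state, frame)
        result = settle(state, drive, arch)
        state.activity[:] = result.activity
        if log is not None:
            log.append(
                i,
                event.n_deflected,
                int(np.count_nonzero(result.activity)),
                float(result.step_changes[0]),
                float(result.step_changes[-1]),
            )
        hebbian_update(state, result.activity, frame, arch)
        _maybe_checkpoint(i + 1)
    return state


# ---------------------------------------------------------------------------
# checkpoint container


def save_checkpoint(
    path,
    state: CorticalState,
    meds: MEDAssignment,
    pattern_index: int = 0,
    rng: Optional[np.random.Generator] = None,
    extra: Optional[dict] = None,
) -> None:
    """Write a bit-exact network snapshot (.npz).

    Datasets: ``afferent_w``, ``excit_w``, ``inhib_w``, ``inhib_n_cf``,
    ``activity``, ``meds``, ``pattern_index``, ``arch_json``, ``rng_state_json``,
    ``extra_json``.
    """
    payload = {
        "afferent_w": state.afferent_w,
        "excit_w": state.excit_w,
        "inhib_w": state.inhib_w,
        "inhib_n_cf": state.inhib_n_cf,
        "activity": state.activity,
        "meds": meds.med,
        "pattern_index": np.int64(pattern_index),
        "arch_json": np.bytes_(json.dumps(asdict(state.arch)).encode()),
        "rng_state_json": np.bytes_(
            json.dumps(rng.bit_generator.state if rng is not None else None, default=int).encode()
        ),
        "extra_json": np.bytes_(json.dumps(extra or {}).encode()),
    }
    np.savez(path, **payload)


def load_checkpoint(path) -> dict:
    """Load a snapshot; returns dict with 'state', 'meds', 'pattern_index', ...."""
    with np.load(path) as data:
        arch = Architecture(**json.loads(bytes(data["arch_json"]).decode()))
        inhib = data["inhib_w"]
        state = CorticalState(
            arch=arch,
            afferent_w=data["afferent_w"],
            excit_w=data["excit_w"],
            inhib_w=inhib,
            inhib_w32=inhib.astype(np.float32),
            inhib_n_cf=data["inhib_n_cf"],
            activity=data["activity"],
            barrel_index=arch.barrel_index_map(),
        )
        meds = MEDAssignment(med=data["meds"])
        rng_state = json.loads(bytes(data["rng_state_json"]).decode())
        extra = json.loads(bytes(data["extra_json"]).decode())
        pattern_index = int(data["pattern_index"])
    return {
        "state": state,
        "meds": meds,
        "pattern_index": pattern_index,
        "rng_state": rng_state,
        "extra": extra,
    }
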
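"""Direction-tuned layer-4 barrel encoding.

Each whisker maps to one barrel of direction-tuned units.  A unit is
pre-assigned a fixed maximally effective direction (MED), drawn once uniformly
on the circle and never changed during training.  When its principal whisker
is deflected in direction ``theta`` the unit fires at a half-wave-rectified
cosine of the angular distance between ``theta`` and its MED — a broad tuning
curve (half-height width 120 deg at exponent 1) matching the coarse direction
selectivity of barrel neurons.  Units of undeflected whiskers stay silent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimulus import StimulusEvent, TWO_PI

__all__ = ["MEDAssignment", "L4Activity", "assign_meds", "l4_response", "tuning_curve"]


@dataclass(frozen=True)
class MEDAssignment:
    """Fixed per-unit maximally effective directions, shape (n_barrels, units)."""

    med: np.ndarray

    @property
    def n_barrels(self) -> int:
        return self.med.shape[0]

    @property
    def units_per_barrel(self) -> int:
        return self.med.shape[1]


@dataclass(frozen=True)
class L4Activity:
    """One frame of barrel firing rates, shape (n_barrels, units), in [0, 1]."""

    rate: np.ndarray


def assign_meds(
    n_barrels: int = 25, units_per_barrel: int = 25, rng: np.random.Generator | None = None
) -> MEDAssignment:
    """Draw the fixed MED of every unit uniformly on [0, 2pi)."""
    if n_barrels < 1 or units_per_barrel < 1:
        raise ValueError("counts must be positive")
    if rng is None:
        rng = np.random.default_rng()
    med = rng.uniform(0.0, TWO_PI, size=(n_barrels, units_per_barrel))
    return MEDAssignment(med=med)


def tuning_curve(
    delta: np.ndarray, kind: str = "rectified_cosine", exponent: float = 1.0
) -> np.ndarray:
    """Firing rate as a function of the angle ``delta`` between deflection and MED.

    ``rectified_cosine`` (default): ``max(cos(delta), 0) ** exponent`` — units
    driven against their MED are exactly silent, which lets Hebbian learning
    separate directions.  ``raised_cosine``: ``((1 + cos(delta)) / 2) ** exponent``
    adds a graded baseline and never fully silences a unit; provided for
    sensitivity analysis.
    """
    c = np.cos(delta)
    if kind == "rectified_cosine":
        r = np.maximum(c, 0.0)
    elif kind == "raised_cosine":
        r = (1.0 + c) / 2.0
    else:
        raise ValueError(f"unknown tuning kind {kind!r}")
    if exponent != 1.0:
        r = r**exponent
    return r


def l4_response(
    event: StimulusEvent,
    meds: MEDAssignment,
    kind: str = "rectified_cosine",
    exponent: float = 1.0,
) -> L4Activity:
    """Encode a stimulus event as barrel firing rates.

    Barrel ``b`` is driven only if whisker ``b`` is deflected; unit ``u`` then
    fires at ``tuning_curve(theta_b - med[b, u])``.
    """
    if event.deflected.size != meds.n_barrels:
        raise ValueError(
            f"event has {event.deflected.size} whiskers but MEDs cover "
            f"{meds.n_barrels} barrels"
        )
    rate = np.zeros_like(meds.med)
    idx = np.flatnonzero(event.deflected)
    if idx.size:
        delta = event.deflection_dir[idx, None] - meds.med[idx, :]
        rate[idx, :] = tuning_curve(delta, kind=kind, exponent=exponent)
    return L4Activity(rate=rate)
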
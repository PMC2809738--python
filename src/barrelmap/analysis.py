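"""Direction-map measurement and circular map statistics.

Maps are measured feed-forward: each whisker is deflected through a set of
test directions with lateral interactions and learning off, and each neuron
is labelled with the direction evoking its largest afferent response.  The
map inside each supra-barrel is then compared to the ideal somatotopic
pinwheel template (the atan2 angle of each neuron's offset from the
supra-barrel centre) with the Fisher-Lee angular-angular correlation, whose
magnitude is the supra-barrel's *pinwheelness* and whose sign distinguishes
counter-clockwise (somatotopically correct) from clockwise (inverted)
rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _kernels
from .cortex import Architecture, CorticalState, _window_offsets
from .l4 import MEDAssignment, tuning_curve

__all__ = [
    "DirectionMap",
    "SupraBarrelScore",
    "UndefinedCorrelationError",
    "DEFAULT_CLASSIFICATION_THRESHOLD",
    "measure_direction_map",
    "pinwheel_template",
    "circular_correlation",
    "classify_supra_barrel",
    "score_all_supra_barrels",
    "circular_mean",
    "circular_std",
    "map_anisotropy",
    "mean_direction_map",
    "weight_direction_correlation",
    "map_to_csv",
    "plot_direction_map",
]

TWO_PI = 2.0 * math.pi

#: Pinwheelness threshold separating pinwheels from non-pinwheels, matching
#: the angular-angular correlation measured for the biological supra-barrel map.
DEFAULT_CLASSIFICATION_THRESHOLD = 0.33


class UndefinedCorrelationError(ValueError):
    """A correlation whose denominator vanishes (no angular/weight variance)."""


@dataclass
class DirectionMap:
    """Per-neuron preferred deflection direction and selectivity.

    ``preferred_dir`` is in [0, 2pi); ``selectivity`` is the resultant length
    of the response-weighted direction vectors (1 = responds to a single
    direction, 0 = unselective).  ``supra_size`` and the barrel grid shape
    tie the map back to the sheet geometry.
    """

    preferred_dir: np.ndarray   # (rows, cols) radians
    selectivity: np.ndarray     # (rows, cols) in [0, 1]
    supra_size: int
    barrel_rows: int
    barrel_cols: int
    n_ties: int = 0

    @property
    def n_barrels(self) -> int:
        return self.barrel_rows * self.barrel_cols

    def supra_block(self, b: int) -> tuple[np.ndarray, np.ndarray]:
        """(preferred_dir, selectivity) of supra-barrel ``b`` as (s, s) arrays."""
        br, bc = divmod(b, self.barrel_cols)
        s = self.supra_size
        sl = (slice(br * s, (br + 1) * s), slice(bc * s, (bc + 1) * s))
        return self.preferred_dir[sl], self.selectivity[sl]


def measure_direction_map(
    state: CorticalState,
    meds: MEDAssignment,
    n_dirs: int = 16,
    tuning_kind: str = "rectified_cosine",
    tuning_exponent: float = 1.0,
) -> DirectionMap:
    """Measure the feed-forward direction map.

    Single-whisker deflections at ``n_dirs`` evenly spaced directions are
    presented; a neuron's response to direction ``d`` is its afferent drive
    (no settling, no learning).  Argmax ties break toward the lowest
    direction index and are counted in ``n_ties``.
    """
    if n_dirs < 2:
        raise ValueError("need at least 2 test directions")
    arch = state.arch
    s = arch.supra_size
    dirs = TWO_PI * np.arange(n_dirs) / n_dirs
    pref = np.zeros((arch.sheet_rows, arch.sheet_cols))
    sel = np.zeros((arch.sheet_rows, arch.sheet_cols))
    n_ties = 0
    z_dirs = np.exp(1j * dirs)
    for b in range(arch.n_barrels):
        br, bc = divmod(b, arch.barrel_cols)
        sl = (slice(br * s, (br + 1) * s), slice(bc * s, (bc + 1) * s))
        # (n_dirs, units): rates of this barrel's units for each test direction
        rates = tuning_curve(
            dirs[:, None] - meds.med[b][None, :],
            kind=tuning_kind, exponent=tuning_exponent,
        )
        resp = state.afferent_w[sl] @ rates.T          # (s, s, n_dirs)
        best = np.argmax(resp, axis=2)
        n_ties += int(
            ((resp == resp.max(axis=2, keepdims=True)).sum(axis=2) > 1).sum()
        )
        pref[sl] = dirs[best]
        total = resp.sum(axis=2)
        vec = np.abs(resp @ z_dirs)
        with np.errstate(invalid="ignore", divide="ignore"):
            sel[sl] = np.where(total > 0, vec / np.where(total > 0, total, 1.0), 0.0)
    return DirectionMap(
        preferred_dir=pref,
        selectivity=sel,
        supra_size=s,
        barrel_rows=arch.barrel_rows,
        barrel_cols=arch.barrel_cols,
        n_ties=n_ties,
    )


def pinwheel_template(size: int = 21) -> np.ndarray:
    """Ideal somatotopic pinwheel: atan2 angle of each cell from the centre.

    Row index plays the role of y (consistent with the whisker-grid layout),
    column index of x.  The centre cell is NaN (undefined angle, excluded
    from analyses).
    """
    if size % 2 == 0:
        raise ValueError("template size must be odd")
    c = size // 2
    y = np.arange(size)[:, None] - c
    x = np.arange(size)[None, :] - c
    t = np.mod(np.arctan2(y, x), TWO_PI).astype(float)
    t = np.broadcast_to(t, (size, size)).copy()
    t[c, c] = np.nan
    return t


def circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher-Lee angular-angular correlation coefficient.

    ``r = sum_{i<j} sin(a_i - a_j) sin(b_i - b_j) /
    sqrt(sum_{i<j} sin^2(a_i - a_j) sum_{i<j} sin^2(b_i - b_j))``,
    computed via the O(n) trigonometric-moment identity.  Invariant to
    rotating either sample; flips sign if either is reflected.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length angle arrays of size >= 3")
    ua, va = np.cos(a), np.sin(a)
    ub, vb = np.cos(b), np.sin(b)
    num = (va @ vb) * (ua @ ub) - (va @ ub) * (ua @ vb)
    da = max((ua @ ua) * (va @ va) - (ua @ va) ** 2, 0.0)
    db = max((ub @ ub) * (vb @ vb) - (ub @ vb) ** 2, 0.0)
    denom = math.sqrt(da * db)
    # guard: near-constant samples have angular variance ~0 up to roundoff
    if denom <= 1e-9 * a.size**2 or not math.isfinite(denom):
        raise UndefinedCorrelationError("zero angular variance in one of the samples")
    return float(num / denom)


@dataclass(frozen=True)
class SupraBarrelScore:
    """Template comparison for one supra-barrel map.

    ``corr`` is the signed angular-angular correlation with the pinwheel
    template (|corr| is the pinwheelness), ``klass`` the threshold
    classification, ``offset`` the circular mean of (measured - template),
    and ``threshold`` the classification threshold used.
    """

    corr: float
    klass: str  # "ccw_somatotopic" | "cw_inverted" | "non_pinwheel"
    offset: float
    threshold: float


def circular_mean(angles: np.ndarray) -> float:
    """Circular mean in [0, 2pi); raises if the resultant vanishes."""
    z = np.exp(1j * np.asarray(angles, dtype=float)).mean()
    if np.abs(z) < 1e-12:
        raise UndefinedCorrelationError("circular mean undefined (zero resultant)")
    return float(np.mod(np.angle(z), TWO_PI))


def classify_supra_barrel(
    map_sb: np.ndarray,
    template: np.ndarray,
    threshold: float = DEFAULT_CLASSIFICATION_THRESHOLD,
) -> SupraBarrelScore:
    """Score one supra-barrel map against the pinwheel template.

    NaN template cells (the centre) are excluded.  ``corr > threshold`` is a
    counter-clockwise, somatotopically correct pinwheel; ``corr < -threshold``
    a clockwise, inverted one; anything between is not a pinwheel.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    map_sb = np.asarray(map_sb, dtype=float)
    mask = ~np.isnan(template)
    a = map_sb[mask]
    t = template[mask]
    corr = circular_correlation(a, t)
    if corr > threshold:
        klass = "ccw_somatotopic"
    elif corr < -threshold:
        klass = "cw_inverted"
    else:
        klass = "non_pinwheel"
    try:
        offset = circular_mean(np.mod(a - t, TWO_PI))
    except UndefinedCorrelationError:
        offset = math.nan  # offsets spread evenly around the circle
    return SupraBarrelScore(corr=corr, klass=klass, offset=offset, threshold=threshold)


def score_all_supra_barrels(
    dmap: DirectionMap,
    threshold: float = DEFAULT_CLASSIFICATION_THRESHOLD,
    exclude: Iterable[int] = (),
) -> list[Optional[SupraBarrelScore]]:
    """Score every supra-barrel; entries in ``exclude`` (e.g. deprived ones) are None."""
    template = pinwheel_template(dmap.supra_size)
    excluded = set(exclude)
    scores: list[Optional[SupraBarrelScore]] = []
    for b in range(dmap.n_barrels):
        if b in excluded:
            scores.append(None)
            continue
        pref, _ = dmap.supra_block(b)
        try:
            scores.append(classify_supra_barrel(pref, template, threshold))
        except UndefinedCorrelationError:
            scores.append(None)
    return scores


def circular_std(offsets: np.ndarray) -> float:
    """Circular standard deviation sqrt(-2 ln R) of a sample of angles.

    Returns ``inf`` when the mean resultant length R is (numerically) zero,
    i.e. when the angles are spread all the way around the circle.
    """
    offsets = np.asarray(offsets, dtype=float).ravel()
    if offsets.size < 1:
        raise ValueError("need at least one angle")
    r = float(np.abs(np.exp(1j * offsets).mean()))
    if r <= 1e-15:
        return math.inf
    return math.sqrt(-2.0 * math.log(min(r, 1.0)))


def map_anisotropy(dmap: DirectionMap | np.ndarray) -> float:
    """Mean resultant length of all neurons' preferred-direction unit vectors.

    0 means directions are represented isotropically; 1 means every neuron
    prefers the same direction.
    """
    pref = dmap.preferred_dir if isinstance(dmap, DirectionMap) else np.asarray(dmap)
    return float(np.abs(np.exp(1j * pref.ravel()).mean()))


def mean_direction_map(maps: Sequence[DirectionMap]) -> DirectionMap:
    """Per-location circular mean map over replicate networks.

    ``selectivity`` of the result is the per-location resultant length, i.e.
    the consistency of the preference across runs; locations with zero
    resultant get NaN direction.
    """
    if len(maps) < 1:
        raise ValueError("need at least one map")
    ref = maps[0]
    for m in maps[1:]:
        if m.preferred_dir.shape != ref.preferred_dir.shape or m.supra_size != ref.supra_size:
            raise ValueError("maps have mismatching geometry")
    z = np.mean([np.exp(1j * m.preferred_dir) for m in maps], axis=0)
    resultant = np.abs(z)
    pref = np.mod(np.angle(z), TWO_PI)
    pref[resultant < 1e-12] = np.nan
    return DirectionMap(
        preferred_dir=pref,
        selectivity=resultant,
        supra_size=ref.supra_size,
        barrel_rows=ref.barrel_rows,
        barrel_cols=ref.barrel_cols,
    )


def weight_direction_correlation(state: CorticalState, dmap: DirectionMap) -> float:
    """Pearson r between inhibitory weight and circular preferred-direction difference.

    Runs over every in-sheet lateral inhibitory connection; a negative value
    means similarly tuned neuron pairs are more strongly connected.
    """
    n, sx, sy, sxx, syy, sxy = _kernels.weight_dir_corr_accumulate(
        state.inhib_w,
        np.ascontiguousarray(dmap.preferred_dir),
        _window_offsets(state.arch.inhib_extent),
    )
    vx = sxx - sx * sx / n
    vy = syy - sy * sy / n
    if vx <= 0 or vy <= 0:
        raise UndefinedCorrelationError("degenerate variance of weights or directions")
    return float((sxy - sx * sy / n) / math.sqrt(vx * vy))


def map_to_csv(dmap: DirectionMap, path) -> None:
    """Per-neuron CSV: row, col, supra_barrel, preferred_dir_deg, selectivity."""
    import csv

    s = dmap.supra_size
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col", "supra_barrel", "preferred_dir_deg", "selectivity"])
        rows, cols = dmap.preferred_dir.shape
        for r in range(rows):
            for c in range(cols):
                b = (r // s) * dmap.barrel_cols + (c // s)
                writer.writerow([
                    r, c, b,
                    f"{math.degrees(dmap.preferred_dir[r, c]):.3f}",
                    f"{dmap.selectivity[r, c]:.4f}",
                ])


def plot_direction_map(dmap: DirectionMap, path=None, ax=None):
    """Render the map in HSV (hue = direction, saturation = selectivity).

    Supra-barrel borders are drawn in white.  Returns the matplotlib axes.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import hsv_to_rgb

    h = np.mod(dmap.preferred_dir, TWO_PI) / TWO_PI
    sat = np.clip(dmap.selectivity, 0.0, 1.0)
    v = np.ones_like(h)
    rgb = hsv_to_rgb(np.dstack([np.nan_to_num(h), np.nan_to_num(sat), v]))
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(rgb, origin="lower", interpolation="nearest")
    s = dmap.supra_size
    rows, cols = dmap.preferred_dir.shape
    for r in range(s, rows, s):
        ax.axhline(r - 0.5, color="white", lw=1.0)
    for c in range(s, cols, s):
        ax.axvline(c - 0.5, color="white", lw=1.0)
    ax.set_xticks([])
    ax.set_yticks([])
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
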
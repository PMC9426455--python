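"""Icosahedral capsid-lattice accounting and the spooled-genome model.

A T = n icosahedral capsid contains 60·n subunits arranged in n
quasi-equivalent positions per asymmetric unit. The partially spooled
genome layer is modeled as a single continuous solenoid: a helix of
constant radius whose pitch is the axial separation of adjacent turns.
Base-pair capacity converts helical arc length to base pairs at the ideal
B-form rise of 3.4 Å/bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor, pi, sqrt

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CapsidLattice",
    "SpoolSpec",
    "subunit_count",
    "asymmetric_unit_size",
    "spool_capacity",
    "radius_for_capacity",
    "generate_spool_trace",
    "measure_turn_spacing",
    "ds_region_coverage",
]


def _is_triangulation_number(t: int) -> bool:
    # T = h^2 + h*k + k^2 for non-negative integers h, k
    for h in range(int(sqrt(t)) + 2):
        for k in range(h + 1):
            if h * h + h * k + k * k == t:
                return True
    return False


@dataclass(frozen=True)
class CapsidLattice:
    """Icosahedral lattice class (triangulation number)."""

    t_number: int

    def __post_init__(self) -> None:
        t = int(self.t_number)
        if t < 1 or not _is_triangulation_number(t):
            raise ValueError(f"T = {self.t_number} is not an icosahedral class")
        object.__setattr__(self, "t_number", t)


def subunit_count(lattice: CapsidLattice) -> int:
    """Total capsid-protein subunits, 60·T (T = 3 gives 180 protomers)."""
    return 60 * lattice.t_number


def asymmetric_unit_size(lattice: CapsidLattice) -> int:
    """Quasi-equivalent positions per icosahedral asymmetric unit (= T)."""
    return lattice.t_number


@dataclass(frozen=True)
class SpoolSpec:
    """Parametric n-turn genome spool.

    radius : helix radius, Å.
    pitch : axial separation of adjacent turns, Å (0 = stacked rings limit).
    n_turns : number of turns (may be fractional).
    rise_per_bp : arc length per base pair, Å/bp; 3.4 for ideal B-form DNA.
    """

    radius: float
    pitch: float = 28.0
    n_turns: float = 3.0
    rise_per_bp: float = 3.4

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.pitch < 0:
            raise ValueError("pitch must be >= 0")
        if self.n_turns <= 0:
            raise ValueError("n_turns must be positive")
        if not (2.5 < self.rise_per_bp < 4.5):
            raise ValueError("rise_per_bp outside the (2.5, 4.5) Å sanity window")

    @property
    def turn_arc_length(self) -> float:
        """Arc length of one full turn, Å."""
        return sqrt((2 * pi * self.radius) ** 2 + self.pitch ** 2)


def spool_capacity(spec: SpoolSpec) -> int:
    """Complete base pairs fitting on the spool: floor(arc length / rise).

    A 1e-9 bp tolerance absorbs floating-point roundoff when the arc length
    is an exact multiple of the rise (as it is for radii produced by
    :func:`radius_for_capacity`).
    """
    return floor(spec.n_turns * spec.turn_arc_length / spec.rise_per_bp + 1e-9)


def radius_for_capacity(bp: int, pitch: float, n_turns: float,
                        rise_per_bp: float = 3.4) -> float:
    """Helix radius whose spool holds ``bp`` base pairs (inverse of capacity).

    Solves bp·rise = n_turns·sqrt((2πr)² + pitch²) for r; infeasible when
    the required per-turn arc is shorter than the pitch.
    """
    if bp <= 0 or n_turns <= 0 or rise_per_bp <= 0:
        raise ValueError("bp, n_turns and rise_per_bp must be positive")
    per_turn_arc = bp * rise_per_bp / n_turns
    if per_turn_arc <= pitch:
        raise ValueError(
            f"infeasible: per-turn arc {per_turn_arc:.2f} Å does not exceed "
            f"the pitch {pitch:.2f} Å"
        )
    return sqrt(per_turn_arc ** 2 - pitch ** 2) / (2 * pi)


def _frame_from_axis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("axis must be a non-zero vector")
    w = axis / norm
    helper = np.array([1.0, 0.0, 0.0])
    if abs(w @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(w, helper)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v, w


def generate_spool_trace(spec: SpoolSpec,
                         axis: np.ndarray = (0.0, 0.0, 1.0),
                         center: np.ndarray = (0.0, 0.0, 0.0)) -> np.ndarray:
    """Base-pair centers along the spool helix, one point per base pair.

    Returns ``spool_capacity(spec)`` points. The angular step is solved so
    that the chord between consecutive centers equals ``rise_per_bp``
    exactly (at this sampling the chord–arc difference is far below the
    coordinate precision of the density-fitting regime, but the constant
    chord makes inter-point spacing uniform to machine precision).
    """
    n_points = spool_capacity(spec)
    if n_points < 1:
        raise ValueError("spool capacity is zero; nothing to generate")
    u, v, w = _frame_from_axis(np.asarray(axis, dtype=float))
    center = np.asarray(center, dtype=float)
    r, p = spec.radius, spec.pitch

    # fraction of a turn per step such that the chord equals the rise
    def chord_minus_rise(f: float) -> float:
        return sqrt((2 * r * np.sin(pi * f)) ** 2 + (p * f) ** 2) - spec.rise_per_bp

    f_arc = spec.rise_per_bp / spec.turn_arc_length  # arc-length step, slight over-chord
    f_step = brentq(chord_minus_rise, f_arc, 2.0 * f_arc + 1e-9, xtol=1e-15)

    k = np.arange(n_points)
    theta = 2 * pi * f_step * k
    z = p * f_step * k
    pts = (center[None, :]
           + np.outer(r * np.cos(theta), u)
           + np.outer(r * np.sin(theta), v)
           + np.outer(z, w))
    return pts


def measure_turn_spacing(points: np.ndarray, axis: np.ndarray = (0.0, 0.0, 1.0)) -> float:
    """Mean axial separation of consecutive turns of a helical trace, Å.

    Projects the trace onto the axis and the normal plane, unwraps the
    azimuth, and interpolates the axial coordinate at each return to the
    starting azimuth; the mean difference of consecutive crossings is the
    pitch. Requires at least two full turns.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("points must be an (n >= 4, 3) array")
    u, v, w = _frame_from_axis(np.asarray(axis, dtype=float))
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    x, y, z = rel @ u, rel @ v, rel @ w
    theta = np.unwrap(np.arctan2(y, x))
    sweep = theta[-1] - theta[0]
    if abs(sweep) < 4 * pi - 1e-9:
        raise ValueError(
            f"fewer than 2 full turns present (sweep {abs(sweep) / (2 * pi):.2f} turns)"
        )
    if sweep < 0:  # normalize handedness
        theta = -theta
    theta = theta - theta[0]
    crossings = []
    targets = 2 * pi * np.arange(1, int(theta[-1] / (2 * pi)) + 1)
    ti = 0
    for target in targets:
        while ti + 1 < len(theta) and theta[ti + 1] < target:
            ti += 1
        if ti + 1 >= len(theta):
            break
        th0, th1 = theta[ti], theta[ti + 1]
        frac = 0.0 if th1 == th0 else (target - th0) / (th1 - th0)
        crossings.append(z[ti] + frac * (z[ti + 1] - z[ti]))
    if len(crossings) < 2:
        raise ValueError("fewer than 2 azimuth returns; cannot measure spacing")
    return float(np.mean(np.diff(crossings)))


def ds_region_coverage(model_bp: int, genome_ds_bp: int) -> float:
    """Fraction of the genome's double-stranded region covered by the model."""
    if genome_ds_bp <= 0:
        raise ValueError("genome_ds_bp must be positive")
    if model_bp < 0:
        raise ValueError("model_bp must be non-negative")
    return model_bp / genome_ds_bp
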
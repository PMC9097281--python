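"""Analytic model potentials and distance-based collective variables.

These potentials stand in for the molecular force field: a harmonic
single well models a stable "noise" degree of freedom, a quartic double
well models a decisive coordinate with two metastable basins (bound /
unbound), and the 2D pocket models a ligand particle held by attractive
anchor sites with a barrier on the escape route.

All energies are in units of kT unless stated otherwise; coordinates are
in "Å" (the toy length unit used throughout the package).
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Potential",
    "SingleWell",
    "DoubleWell",
    "Pocket2D",
    "IndependentWells",
    "CompositePotential",
    "CollectiveVariable",
    "CoordinateCV",
    "SumDistanceCV",
    "BiasTerm",
    "potential_from_dict",
    "potential_to_dict",
]


class Potential(ABC):
    """Energy function with an analytic gradient.

    ``energy`` maps an array of shape ``(..., dimension)`` to ``(...)``;
    ``gradient`` maps it to ``(..., dimension)``.
    """

    kind: str = "abstract"
    dimension: int = 1
    #: crest positions separating labelled basins (1D potentials only)
    basin_boundaries: tuple = ()

    @abstractmethod
    def energy(self, x: np.ndarray) -> np.ndarray: ...

    @abstractmethod
    def gradient(self, x: np.ndarray) -> np.ndarray: ...

    def __add__(self, other: "Potential") -> "CompositePotential":
        return CompositePotential([self, other])


@dataclass
class SingleWell(Potential):
    """Harmonic well ``V(x) = (stiffness/2)(x - center)^2``."""

    center: float = 0.0
    stiffness: float = 1.0

    kind = "single_well"
    dimension = 1

    def __post_init__(self):
        if self.stiffness <= 0:
            raise ValueError("stiffness must be positive")

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return 0.5 * self.stiffness * (x[..., 0] - self.center) ** 2

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        g[..., 0] = self.stiffness * (x[..., 0] - self.center)
        return g


@dataclass
class DoubleWell(Potential):
    """Quartic double well ``V(u) = h ((u/w)^2 - 1)^2`` with ``u = x - center``.

    Minima sit at ``center ± half_width``, the crest (barrier top, height
    ``barrier_height`` above the minima) at ``center``.  The basin at
    ``x < center`` is the "bound" basin by convention.
    """

    barrier_height: float = 7.0
    half_width: float = 1.0
    center: float = 0.0

    kind = "double_well"
    dimension = 1

    def __post_init__(self):
        if self.barrier_height <= 0 or self.half_width <= 0:
            raise ValueError("barrier_height and half_width must be positive")
        self.basin_boundaries = (self.center,)

    @property
    def minima(self) -> tuple:
        return (self.center - self.half_width, self.center + self.half_width)

    @property
    def crest(self) -> float:
        return self.center

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        u = (x[..., 0] - self.center) / self.half_width
        return self.barrier_height * (u**2 - 1.0) ** 2

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        u = (x[..., 0] - self.center) / self.half_width
        g = np.zeros_like(x)
        g[..., 0] = 4.0 * self.barrier_height * u * (u**2 - 1.0) / self.half_width
        return g


@dataclass
class Pocket2D(Potential):
    """2D binding pocket: attractive wells at fixed anchor sites, an
    optional Gaussian barrier on the escape route along +x, and a weak
    harmonic channel in y keeping the minimum-energy path on the x axis.

    With a single anchor at the origin and a barrier bump at
    ``barrier_center_x`` the minimum free-energy path is exactly the
    ``y = 0`` line (by symmetry), which makes the system a convenient
    string-method benchmark with a numerically known barrier.
    """

    anchors: tuple = ((0.0, 0.0),)
    well_depth: float = 5.0
    well_width: float = 0.8
    barrier_height: float = 0.0
    barrier_center_x: float = 2.5
    barrier_width: float = 0.8
    channel_stiffness: float = 1.0
    escape_slope: float = 0.0
    escape_radius: float = 4.0
    ring_barrier_height: float = 0.0
    ring_radius: float = 2.5
    ring_width: float = 0.5

    kind = "pocket2d"
    dimension = 2

    def __post_init__(self):
        self.anchors = tuple(tuple(map(float, a)) for a in self.anchors)
        if self.well_depth <= 0 or self.well_width <= 0:
            raise ValueError("well_depth and well_width must be positive")

    def _escape(self, x):
        # gentle downhill beyond the pocket rim: models the entropic drift
        # of a released ligand into bulk, so an unbound particle does not
        # linger at the rim of a bounded 2D domain
        r = np.sqrt(x[..., 0] ** 2 + x[..., 1] ** 2)
        return r, -self.escape_slope * np.maximum(r - self.escape_radius, 0.0)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        e = 0.5 * self.channel_stiffness * x[..., 1] ** 2
        for ax, ay in self.anchors:
            r2 = (x[..., 0] - ax) ** 2 + (x[..., 1] - ay) ** 2
            e = e - self.well_depth * np.exp(-r2 / (2.0 * self.well_width**2))
        if self.barrier_height > 0:
            r2 = (x[..., 0] - self.barrier_center_x) ** 2 + x[..., 1] ** 2
            e = e + self.barrier_height * np.exp(-r2 / (2.0 * self.barrier_width**2))
        if self.escape_slope > 0:
            e = e + self._escape(x)[1]
        if self.ring_barrier_height > 0:
            r = np.sqrt(x[..., 0] ** 2 + x[..., 1] ** 2)
            e = e + self.ring_barrier_height * np.exp(
                -((r - self.ring_radius) ** 2) / (2.0 * self.ring_width**2))
        return e

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        g[..., 1] = self.channel_stiffness * x[..., 1]
        if self.escape_slope > 0:
            r, _ = self._escape(x)
            outside = r > self.escape_radius
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = np.where(outside, -self.escape_slope / np.where(r > 0, r, 1.0), 0.0)
            g[..., 0] += scale * x[..., 0]
            g[..., 1] += scale * x[..., 1]
        if self.ring_barrier_height > 0:
            r = np.sqrt(x[..., 0] ** 2 + x[..., 1] ** 2)
            bump = self.ring_barrier_height * np.exp(
                -((r - self.ring_radius) ** 2) / (2.0 * self.ring_width**2))
            dEdr = -bump * (r - self.ring_radius) / self.ring_width**2
            safe_r = np.where(r > 0, r, 1.0)
            g[..., 0] += dEdr * x[..., 0] / safe_r
            g[..., 1] += dEdr * x[..., 1] / safe_r
        for ax, ay in self.anchors:
            dx = x[..., 0] - ax
            dy = x[..., 1] - ay
            w = self.well_depth / self.well_width**2 * np.exp(
                -(dx**2 + dy**2) / (2.0 * self.well_width**2)
            )
            g[..., 0] += w * dx
            g[..., 1] += w * dy
        if self.barrier_height > 0:
            dx = x[..., 0] - self.barrier_center_x
            dy = x[..., 1]
            w = self.barrier_height / self.barrier_width**2 * np.exp(
                -(dx**2 + dy**2) / (2.0 * self.barrier_width**2)
            )
            g[..., 0] -= w * dx
            g[..., 1] -= w * dy
        return g

    def profile_along_mep(self, x_grid: np.ndarray) -> np.ndarray:
        """Energy along the y=0 minimum-energy path (single-anchor case)."""
        pts = np.stack([np.asarray(x_grid, float), np.zeros_like(x_grid)], axis=-1)
        return self.energy(pts)


class IndependentWells(Potential):
    """Product potential of independent 1D wells, one per coordinate.

    This is the multidimensional construction behind the analytical
    benchmark: each latent coordinate evolves on its own 1D potential.
    """

    kind = "independent_wells"

    def __init__(self, potentials: Sequence[Potential]):
        for p in potentials:
            if p.dimension != 1:
                raise ValueError("IndependentWells requires 1D member potentials")
        self.potentials = list(potentials)
        self.dimension = len(self.potentials)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        e = np.zeros(x.shape[:-1])
        for i, p in enumerate(self.potentials):
            e = e + p.energy(x[..., i : i + 1])
        return e

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        g = np.empty_like(x)
        for i, p in enumerate(self.potentials):
            g[..., i : i + 1] = p.gradient(x[..., i : i + 1])
        return g


class CompositePotential(Potential):
    """Sum of potentials (and/or frozen bias terms) on shared coordinates."""

    kind = "composite"

    def __init__(self, terms: Sequence):
        if not terms:
            raise ValueError("CompositePotential needs at least one term")
        self.terms = list(terms)
        self.dimension = max(getattr(t, "dimension", 1) for t in terms)

    def energy(self, x):
        return sum(t.energy(x) for t in self.terms)

    def gradient(self, x):
        return sum(t.gradient(x) for t in self.terms)


# ---------------------------------------------------------------------------
# collective variables and harmonic bias
# ---------------------------------------------------------------------------


class CollectiveVariable(ABC):
    """Scalar function of particle coordinates, with gradient."""

    @abstractmethod
    def value(self, x: np.ndarray) -> np.ndarray:
        """``(..., dim) -> (...)``"""

    @abstractmethod
    def gradient(self, x: np.ndarray) -> np.ndarray:
        """``(..., dim) -> (..., dim)``"""


@dataclass
class CoordinateCV(CollectiveVariable):
    """A single Cartesian coordinate as the CV."""

    index: int = 0

    def value(self, x):
        return np.asarray(x, float)[..., self.index]

    def gradient(self, x):
        g = np.zeros_like(np.asarray(x, float))
        g[..., self.index] = 1.0
        return g


class SumDistanceCV(CollectiveVariable):
    """Sum of Euclidean distances from the particle to fixed anchor sites.

    This is the toy analogue of the protocol's main unbinding CV: the sum
    of the currently active ligand-protein contact distances.
    """

    def __init__(self, anchors):
        self.anchors = np.atleast_2d(np.asarray(anchors, dtype=float))
        if self.anchors.shape[0] < 1:
            raise ValueError("need at least one anchor")

    def value(self, x):
        x = np.asarray(x, dtype=float)
        d = np.linalg.norm(x[..., None, :] - self.anchors, axis=-1)
        return d.sum(axis=-1)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        diff = x[..., None, :] - self.anchors  # (..., m, dim)
        d = np.linalg.norm(diff, axis=-1, keepdims=True)
        d = np.where(d > 0, d, 1.0)  # zero-distance: force direction undefined, use 0
        return (diff / d).sum(axis=-2)


@dataclass
class BiasTerm:
    """Harmonic restraint ``(k/2) (CV(x) - D)^2`` on a collective variable.

    ``schedule="linear"`` ramps the restraint centre from ``start_center``
    (D0) at the first step of an iteration to ``center`` (D) at the last,
    which is how the unbinding protocol reaches its target progressively.
    ``force_constant`` is in kcal mol^-1 Å^-2 in protocol language; with
    kT-unit potentials it is simply in energy units per Å².
    """

    cv: CollectiveVariable
    center: float
    force_constant: float = 20.0
    schedule: str = "fixed"  # "fixed" | "linear"
    start_center: float | None = None

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if self.schedule not in ("fixed", "linear"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.schedule == "linear" and self.start_center is None:
            raise ValueError("linear schedule needs start_center")

    def center_at(self, progress: float) -> float:
        if self.schedule == "fixed":
            return self.center
        return self.start_center + progress * (self.center - self.start_center)

    def energy(self, x, progress: float = 1.0):
        d = self.cv.value(x) - self.center_at(progress)
        return 0.5 * self.force_constant * d**2

    def gradient(self, x, progress: float = 1.0):
        d = self.cv.value(x) - self.center_at(progress)
        return (self.force_constant * d)[..., None] * self.cv.gradient(x)

    def frozen(self, progress: float = 1.0) -> Potential:
        """The bias at fixed progress, as a plain Potential term."""
        return _FrozenBias(self, progress)


# ---------------------------------------------------------------------------
# JSON-friendly (de)serialisation of the closed-form potentials
# ---------------------------------------------------------------------------

_POTENTIAL_KINDS = {}


def _register(cls):
    _POTENTIAL_KINDS[cls.kind] = cls
    return cls


for _cls in (SingleWell, DoubleWell, Pocket2D):
    _register(_cls)


def potential_to_dict(potential: Potential) -> dict:
    """Serialisable description of a closed-form potential."""
    if isinstance(potential, IndependentWells):
        return {"kind": potential.kind,
                "potentials": [potential_to_dict(p) for p in potential.potentials]}
    if potential.kind not in _POTENTIAL_KINDS:
        raise ValueError(f"potential kind {potential.kind!r} is not serialisable")
    from dataclasses import asdict

    return {"kind": potential.kind, **asdict(potential)}


def potential_from_dict(data: dict) -> Potential:
    """Rebuild a potential from :func:`potential_to_dict` output."""
    data = dict(data)
    kind = data.pop("kind", None)
    if kind == "independent_wells":
        return IndependentWells([potential_from_dict(p) for p in data["potentials"]])
    if kind not in _POTENTIAL_KINDS:
        raise ValueError(f"unknown potential kind {kind!r}")
    return _POTENTIAL_KINDS[kind](**data)


class _FrozenBias(Potential):
    kind = "frozen_bias"

    def __init__(self, bias: BiasTerm, progress: float):
        self._bias = bias
        self._progress = progress
        self.dimension = 1

    def energy(self, x):
        return self._bias.energy(x, self._progress)

    def gradient(self, x):
        return self._bias.gradient(x, self._progress)
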
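"""Overdamped Langevin dynamics on analytic potentials.

The integrator is first-order Euler-Maruyama for the overdamped
(high-friction) Langevin equation

    x_{t+1} = x_t - (dt/gamma) * grad(V + bias)(x_t)
              + sqrt(2 kT dt / gamma) * xi_t,    xi_t ~ N(0, I)

which is the desk-scale stand-in for all molecular dynamics in this
package.  Ensembles are propagated as a batch, so a call with ``n_traj``
starting points runs all trajectories in lock-step vectorised numpy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .potentials import BiasTerm, Potential

__all__ = [
    "LangevinParams",
    "TrajectoryEnsemble",
    "DivergenceError",
    "simulate",
    "label_outcome",
]

IN, OUT = "IN", "OUT"


class DivergenceError(RuntimeError):
    """Raised when a coordinate exceeds the divergence guard.

    Almost always means the step size is too large for the stiffest part
    of the potential.
    """


@dataclass
class LangevinParams:
    """Integration constants for overdamped Langevin dynamics.

    step_size : dimensionless integrator time step dt
    friction  : gamma; mobility is dt/gamma.  A scalar, or one value per
                coordinate - a slow decisive mode coupled to a fast noise
                bath is modelled by giving it a larger friction.
    kT        : thermal energy, same units as the potential
    n_steps   : number of stored frames (the initial condition is frame 0)
    stride    : integrator substeps between stored frames (save interval,
                like an MD trajectory's output frequency)
    seed      : integer seed; identical seeds give bit-identical runs
    """

    step_size: float = 0.005
    friction: float | np.ndarray = 1.0
    kT: float = 1.0
    n_steps: int = 500
    stride: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if np.any(np.asarray(self.friction) <= 0):
            raise ValueError("friction must be > 0")
        if self.kT < 0:
            raise ValueError("kT must be >= 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class TrajectoryEnsemble:
    """Batch of trajectories: ``frames`` has shape (n_traj, n_steps, dim)."""

    frames: np.ndarray
    step_size: float
    labels: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_traj, n_steps, dim)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.n_trajectories:
                raise ValueError("labels must cover every trajectory")

    @property
    def n_trajectories(self) -> int:
        return self.frames.shape[0]

    @property
    def n_steps(self) -> int:
        return self.frames.shape[1]

    @property
    def dimension(self) -> int:
        return self.frames.shape[2]

    # -- plain-text serialization (one file per trajectory) ----------------
    def save(self, directory, prefix: str = "traj") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        header = "\t".join(f"dim{i}" for i in range(self.dimension))
        for i in range(self.n_trajectories):
            np.savetxt(directory / f"{prefix}{i:04d}.tsv", self.frames[i],
                       delimiter="\t", header=header, comments="")
        meta = {
            "step_size": self.step_size,
            "n_trajectories": self.n_trajectories,
            "labels": None if self.labels is None else list(map(str, self.labels)),
            "provenance": _jsonable(self.provenance),
            "prefix": prefix,
        }
        (directory / f"{prefix}_manifest.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory, prefix: str = "traj") -> "TrajectoryEnsemble":
        directory = Path(directory)
        meta = json.loads((directory / f"{prefix}_manifest.json").read_text())
        parts = []
        for i in range(meta["n_trajectories"]):
            arr = np.loadtxt(directory / f"{prefix}{i:04d}.tsv",
                             delimiter="\t", skiprows=1)
            parts.append(arr.reshape(arr.shape[0], -1) if arr.ndim > 1
                         else arr.reshape(-1, 1))
        frames = np.stack(parts)
        labels = meta["labels"]
        return cls(frames=frames, step_size=meta["step_size"],
                   labels=None if labels is None else np.array(labels),
                   provenance=meta.get("provenance", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def simulate(
    potential: Potential,
    params: LangevinParams,
    bias: BiasTerm | None = None,
    x0=None,
    divergence_guard: float = 1.0e3,
) -> TrajectoryEnsemble:
    """Propagate an ensemble of overdamped Langevin trajectories.

    ``x0`` is either one starting point of shape ``(dim,)`` or a batch
    ``(n_traj, dim)``.  A ramped bias (``schedule="linear"``) reaches its
    target at the final stored frame.  Frame 0 is the initial condition.
    """
    if x0 is None:
        raise ValueError("x0 is required")
    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    if x0.shape[1] != potential.dimension:
        raise ValueError(
            f"x0 dimension {x0.shape[1]} != potential dimension {potential.dimension}"
        )
    n_traj, dim = x0.shape
    rng = np.random.default_rng(params.seed)

    friction = np.broadcast_to(np.asarray(params.friction, dtype=float), (dim,))
    frames = np.empty((n_traj, params.n_steps, dim))
    x = x0.copy()
    frames[:, 0] = x
    mobility = params.step_size / friction
    noise_amp = np.sqrt(2.0 * params.kT * params.step_size / friction)
    denom = max((params.n_steps - 1) * params.stride, 1)
    noisy = params.kT > 0

    step = 0
    for t in range(1, params.n_steps):
        for _ in range(params.stride):
            step += 1
            progress = step / denom
            g = potential.gradient(x)
            if bias is not None:
                g = g + bias.gradient(x, progress)
            x = x - mobility * g
            if noisy:
                x = x + noise_amp * rng.standard_normal(x.shape)
        if np.max(np.abs(x)) > divergence_guard:
            raise DivergenceError(
                "coordinate exceeded divergence guard "
                f"({divergence_guard:g}); reduce step_size"
            )
        frames[:, t] = x

    return TrajectoryEnsemble(
        frames=frames,
        step_size=params.step_size,
        provenance={
            "potential": getattr(potential, "kind", "unknown"),
            "biased": bias is not None,
            "seed": params.seed,
            "kT": params.kT,
            "friction": params.friction,
        },
    )


def label_outcome(
    traj: TrajectoryEnsemble,
    decisive_dimension: int,
    crest: float,
    bound_side: str = "lower",
) -> np.ndarray:
    """Label each trajectory IN/OUT by its decisive coordinate's final basin.

    IN means the final frame of the decisive coordinate lies on the bound
    side of the crest; a final value exactly at the crest is assigned IN
    (deterministic tie rule for a measure-zero event).
    """
    if not 0 <= decisive_dimension < traj.dimension:
        raise ValueError("decisive_dimension out of range")
    if bound_side not in ("lower", "upper"):
        raise ValueError("bound_side must be 'lower' or 'upper'")
    final = traj.frames[:, -1, decisive_dimension]
    if bound_side == "lower":
        is_in = final <= crest
    else:
        is_in = final >= crest
    return np.where(is_in, IN, OUT)
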
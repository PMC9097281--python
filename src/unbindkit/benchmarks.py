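"""Shipped toy systems: the analytical MLTSA benchmarks and the 2D pocket.

The analytical benchmark emulates the downhill-trajectory construction:
25 independent 1D coordinates (one decisive double well started at its
crest, the rest noise wells), observed only through 180 L1-normalised
linear features of which a known subset carries the decisive coordinate.
Trajectory fate (IN/OUT) is the decisive coordinate's final basin, and
the classification window is frames 30-60 of 500 - early enough to be a
genuine prediction, late enough to be accurately solvable.

``pocket_system`` builds the 2D binding-pocket particle with fixed
anchor sites used by the unbinding protocol and the string method; its
minimum-energy path and barrier are known (the y=0 axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import mltsa
from .engine import LangevinParams, TrajectoryEnsemble, label_outcome, simulate
from .mixer import MixingMatrix, apply_mixing, make_mixing
from .potentials import DoubleWell, IndependentWells, Pocket2D, SingleWell

__all__ = [
    "AnalyticalBenchmark",
    "make_benchmark",
    "simulate_benchmark",
    "run_replica",
    "replica_study",
    "pocket_system",
    "PocketFixture",
]


@dataclass
class AnalyticalBenchmark:
    """Frozen construction of one analytical MLTSA benchmark."""

    potential: IndependentWells
    decisive_index: int
    mixing: MixingMatrix
    x0: np.ndarray  # starting point shared by all trajectories
    langevin: LangevinParams
    n_train: int = 180
    n_validation: int = 50
    window: tuple = (30, 60)

    @property
    def crest(self) -> float:
        return self.potential.potentials[self.decisive_index].crest

    @property
    def correlated_features(self) -> np.ndarray:
        return self.mixing.correlated_rows


def make_benchmark(
    n_coordinates: int = 25,
    n_features: int = 180,
    n_correlated: int = 11,
    n_noise_doublewells: int = 12,
    alpha_range: tuple = (0.35, 0.65),
    decisive_barrier: float = 6.0,
    decisive_half_width: float = 1.4,
    decisive_friction: float = 25.0,
    bath_friction: float = 0.1,
    n_slow_noise: int = 5,
    slow_noise_friction: float = 30.0,
    noise_dw_friction: float = 15.0,
    noise_dw_barrier_range: tuple = (0.8, 1.5),
    noise_dw_half_width_range: tuple = (1.0, 1.4),
    noise_sw_stiffness_range: tuple = (0.5, 2.0),
    window: tuple = (30, 60),
    n_train: int = 180,
    n_validation: int = 50,
    seed: int | None = None,
) -> AnalyticalBenchmark:
    """Construct the analytical benchmark (defaults: the 1-DW system).

    One decisive double well (barrier ``decisive_barrier`` kT, minima at
    ±``decisive_half_width``) plus ``n_noise_doublewells`` noise double
    wells (lower barriers, so they hop between basins on the window
    timescale) and harmonic noise wells fill the ``n_coordinates``
    latent coordinates.  All double wells start at their crest; only the
    decisive one defines the labels.  Noise wells are deliberately
    fast-mixing relative to the classification window so that observable
    features carry genuine per-frame noise rather than stable
    per-trajectory signatures.  The 5-DW variant of the benchmark is
    obtained with ``n_noise_doublewells=4, n_correlated=15``.
    """
    rng = np.random.default_rng(seed)
    decisive_index = int(rng.integers(n_coordinates))

    potentials, x0 = [], np.zeros(n_coordinates)
    dw_slots = set(
        rng.choice(
            [i for i in range(n_coordinates) if i != decisive_index],
            size=min(n_noise_doublewells, n_coordinates - 1),
            replace=False,
        ).tolist()
    )
    for i in range(n_coordinates):
        if i == decisive_index:
            potentials.append(
                DoubleWell(barrier_height=decisive_barrier,
                           half_width=decisive_half_width)
            )
            x0[i] = 0.0  # crest: fate decided by the dynamics
        elif i in dw_slots:
            potentials.append(
                DoubleWell(
                    barrier_height=float(rng.uniform(*noise_dw_barrier_range)),
                    half_width=float(rng.uniform(*noise_dw_half_width_range)),
                )
            )
            x0[i] = 0.0
        else:
            center = float(rng.uniform(-1.0, 1.0))
            potentials.append(
                SingleWell(center=center,
                           stiffness=float(rng.uniform(*noise_sw_stiffness_range)))
            )
            x0[i] = center

    friction = np.full(n_coordinates, bath_friction)
    for i in dw_slots:
        friction[i] = noise_dw_friction
    sw_slots = [i for i in range(n_coordinates)
                if i != decisive_index and i not in dw_slots]
    for i in sw_slots[:n_slow_noise]:
        friction[i] = slow_noise_friction
    friction[decisive_index] = decisive_friction

    # correlated features draw their noise from the fast bath wells with
    # amplitude-equalised weights, so alpha alone orders their information
    # content; fingerprint-like slow coordinates stay out of them
    fast_sw = sw_slots[n_slow_noise:]
    noise_scales = {i: float(np.sqrt(1.0 / potentials[i].stiffness))
                    for i in fast_sw}
    mixing = make_mixing(
        n_features=n_features,
        n_coordinates=n_coordinates,
        n_correlated=n_correlated,
        alpha_range=alpha_range,
        seed=int(rng.integers(2**31)),
        decisive_column=decisive_index,
        correlated_noise_pool=fast_sw if fast_sw else None,
        correlated_noise_scales=noise_scales if fast_sw else None,
    )
    return AnalyticalBenchmark(
        potential=IndependentWells(potentials),
        decisive_index=decisive_index,
        mixing=mixing,
        x0=x0,
        langevin=LangevinParams(step_size=0.005, friction=friction, kT=1.0,
                                n_steps=500, stride=40),
        n_train=n_train,
        n_validation=n_validation,
        window=window,
    )


def simulate_benchmark(bench: AnalyticalBenchmark, seed: int) -> mltsa.DownhillDataset:
    """Generate one replica's trajectories, features, and labels.

    Draws ``n_train + n_validation`` fresh trajectories from the frozen
    benchmark construction; the last ``n_validation`` trajectory ids form
    the held-out validation set.
    """
    n_total = bench.n_train + bench.n_validation
    params = LangevinParams(
        step_size=bench.langevin.step_size,
        friction=bench.langevin.friction,
        kT=bench.langevin.kT,
        n_steps=bench.langevin.n_steps,
        stride=bench.langevin.stride,
        seed=seed,
    )
    traj = simulate(bench.potential, params, x0=np.tile(bench.x0, (n_total, 1)))
    labels = label_outcome(traj, bench.decisive_index, bench.crest)
    features = apply_mixing(bench.mixing, traj)
    return mltsa.DownhillDataset(
        features=features,
        labels=labels,
        window=bench.window,
        validation_ids=np.arange(bench.n_train, n_total),
        seed=seed,
    )


@dataclass
class ReplicaResult:
    mlp: mltsa.MLTSAReport | None = None
    gbdt: mltsa.MLTSAReport | None = None


def run_replica(
    bench: AnalyticalBenchmark,
    seed: int,
    run_mlp: bool = True,
    run_gbdt: bool = True,
    compute_drops: bool = True,
) -> ReplicaResult:
    """One benchmark replica: simulate, mix, train, score, analyse."""
    dataset = simulate_benchmark(bench, seed)
    result = ReplicaResult()
    if run_mlp:
        model, rep = mltsa.train_and_score(dataset, mltsa.MLPConfig(seed=seed))
        if compute_drops:
            rep.accuracy_drops = mltsa.global_mean_drop(model, dataset,
                                                        on="validation")
        result.mlp = rep
    if run_gbdt:
        model, rep = mltsa.train_and_score(dataset, mltsa.GBDTConfig(seed=seed))
        rep.feature_importances = mltsa.gbdt_importances(model)
        result.gbdt = rep
    return result


def replica_study(
    bench: AnalyticalBenchmark,
    n_replicas: int = 10,
    seed: int | None = None,
    **kwargs,
) -> list:
    """Run ``n_replicas`` independent replicas with spawned seeds."""
    seeds = np.random.SeedSequence(seed).generate_state(n_replicas) % (2**31)
    return [run_replica(bench, int(s), **kwargs) for s in seeds]


# ---------------------------------------------------------------------------
# 2D pocket fixtures
# ---------------------------------------------------------------------------


@dataclass
class PocketFixture:
    """A Pocket2D with its anchors, bound state, and barrier metadata."""

    potential: Pocket2D
    anchors: dict
    x0: np.ndarray
    mep_x_range: tuple
    barrier: float
    barrier_x: float
    bound_x: float


def pocket_system(kind: str = "string", kT: float = 1.0) -> PocketFixture:
    """Build a toy 2D pocket.

    kind="string": a single anchor well plus a Gaussian barrier on the
    escape route; the minimum-energy path is exactly y=0 and the barrier
    height along it is known numerically, for string/WHAM benchmarks.

    kind="unbind": three anchor sites forming a pocket around the bound
    minimum, for exercising the contact-based unbinding protocol.
    """
    if kind == "string":
        # the stiff transverse channel keeps the post-convergence residual
        # (string moves below the 0.3 Å absolute rule stall refinement)
        # well inside one node spacing
        pot = Pocket2D(
            anchors=((0.0, 0.0),),
            well_depth=6.0,
            well_width=0.8,
            barrier_height=2.0,
            barrier_center_x=2.2,
            barrier_width=0.7,
            channel_stiffness=20.0,
        )
        xs = np.linspace(-1.0, 8.0, 4001)
        prof = pot.profile_along_mep(xs)
        bound_i = int(np.argmin(prof))
        crest_i = bound_i + int(np.argmax(prof[bound_i:]))
        return PocketFixture(
            potential=pot,
            anchors={"A0": np.array([0.0, 0.0])},
            x0=np.array([xs[bound_i], 0.0]),
            mep_x_range=(float(xs[bound_i]), 7.0),
            barrier=float(prof[crest_i] - prof[bound_i]),
            barrier_x=float(xs[crest_i]),
            bound_x=float(xs[bound_i]),
        )
    if kind == "unbind":
        anchors = {
            "A0": np.array([0.0, 0.5]),
            "A1": np.array([-0.43, -0.25]),
            "A2": np.array([0.43, -0.25]),
        }
        pot = Pocket2D(
            anchors=tuple(tuple(a) for a in anchors.values()),
            well_depth=3.0,
            well_width=0.9,
            channel_stiffness=0.0,
            escape_slope=0.6,
            escape_radius=4.0,
            ring_barrier_height=1.5,
            ring_radius=2.5,
            ring_width=0.5,
        )
        return PocketFixture(
            potential=pot,
            anchors=anchors,
            x0=np.array([0.0, 0.0]),
            mep_x_range=(0.0, 7.0),
            barrier=float("nan"),
            barrier_x=float("nan"),
            bound_x=0.0,
        )
    raise ValueError("kind must be 'string' or 'unbind'")
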
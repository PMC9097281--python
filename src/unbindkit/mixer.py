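"""Linear mixing of latent coordinates into observable features.

The analytical benchmark hides one decisive double-well coordinate among
noise coordinates and exposes only linear combinations of them, mimicking
how a physically decisive interatomic distance contributes, with some
coefficient, to several observable CVs.  Every mixing row is L1
normalised so coefficients read as percentages that sum to 100 per
feature; the "mixing coefficient" alpha of a correlated feature is the
share of its mass on the decisive column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .engine import TrajectoryEnsemble

__all__ = ["MixingMatrix", "make_mixing", "apply_mixing"]


@dataclass
class MixingMatrix:
    """Feature-by-coordinate coefficient matrix with decisive bookkeeping."""

    coefficients: np.ndarray  # (n_features, n_coordinates), rows unit L1
    decisive_column: int
    seed: int | None = None

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 2:
            raise ValueError("coefficients must be 2D")
        if not 0 <= self.decisive_column < self.coefficients.shape[1]:
            raise ValueError("decisive_column out of range")

    @property
    def n_features(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_coordinates(self) -> int:
        return self.coefficients.shape[1]

    @property
    def correlated_rows(self) -> np.ndarray:
        """Indices of features carrying the decisive coordinate."""
        return np.flatnonzero(self.coefficients[:, self.decisive_column] != 0.0)

    @property
    def alphas(self) -> np.ndarray:
        """Per-feature decisive share (fraction of L1 mass), in [0, 1]."""
        l1 = np.abs(self.coefficients).sum(axis=1)
        return np.abs(self.coefficients[:, self.decisive_column]) / l1

    # -- text round-trip ----------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        np.savetxt(path, self.coefficients, delimiter="\t")
        sidecar = {
            "decisive_column": int(self.decisive_column),
            "seed": self.seed,
            "correlated_rows": self.correlated_rows.tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "MixingMatrix":
        path = Path(path)
        coeff = np.loadtxt(path, delimiter="\t")
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(coefficients=coeff, decisive_column=meta["decisive_column"],
                   seed=meta.get("seed"))


def make_mixing(
    n_features: int,
    n_coordinates: int,
    n_correlated: int,
    alpha_range: tuple = (0.2, 1.0),
    seed: int | None = None,
    decisive_column: int = 0,
    max_noise_terms: int = 4,
    correlated_noise_pool=None,
    n_correlated_noise_terms: int = 3,
    correlated_noise_scales=None,
) -> MixingMatrix:
    """Draw a random L1-normalised mixing matrix.

    Exactly ``n_correlated`` rows carry the decisive column, with decisive
    share alpha drawn uniformly from ``alpha_range`` (fractions of L1
    mass).  Uncorrelated rows mix 1..``max_noise_terms`` randomly chosen
    noise coordinates with random positive weights.

    Correlated rows spread their residual mass over
    ``n_correlated_noise_terms`` near-equal noise terms drawn from
    ``correlated_noise_pool`` (default: all noise columns), so their
    noise backgrounds are statistically alike and the decisive share
    alpha is the sole parameter ordering how informative they are.
    The alphas themselves are stratified across ``alpha_range`` (evenly
    spaced with jitter, shuffled over rows) so every correlated feature
    has a distinct, identifiable correlation strength; order statistics
    of plain uniform draws produce near-ties that make rank-based
    comparisons ill-defined.
    """
    if not 0 <= n_correlated <= n_features:
        raise ValueError("need 0 <= n_correlated <= n_features")
    lo, hi = alpha_range
    if not (0 < lo <= hi <= 1):
        raise ValueError("alpha_range must satisfy 0 < lo <= hi <= 1")
    if n_coordinates < 2:
        raise ValueError("need at least 2 coordinates (decisive + noise)")

    rng = np.random.default_rng(seed)
    noise_cols = np.array([c for c in range(n_coordinates) if c != decisive_column])
    if correlated_noise_pool is None:
        pool = noise_cols
    else:
        pool = np.asarray([c for c in correlated_noise_pool
                           if c != decisive_column], dtype=int)
        if pool.size == 0:
            raise ValueError("correlated_noise_pool has no usable columns")
    coeff = np.zeros((n_features, n_coordinates))
    correlated = rng.choice(n_features, size=n_correlated, replace=False)
    correlated_set = set(correlated.tolist())

    if correlated_noise_scales is None:
        inv_scale = {int(c): 1.0 for c in pool}
    else:
        inv_scale = {int(c): 1.0 / float(s)
                     for c, s in correlated_noise_scales.items() if c in set(pool.tolist())}
    n_corr_terms = min(n_correlated_noise_terms, len(pool))
    if n_correlated > 0:
        if n_correlated > 1:
            base = np.linspace(lo, hi, n_correlated)
            spacing = (hi - lo) / (n_correlated - 1)
            alphas = base + rng.uniform(-0.2, 0.2, size=n_correlated) * spacing
            alphas = np.clip(alphas, lo, hi)
        else:
            alphas = np.array([rng.uniform(lo, hi)])
        rng.shuffle(alphas)
    alpha_iter = iter(alphas) if n_correlated else iter(())
    for row in range(n_features):
        if row in correlated_set:
            cols = rng.choice(pool, size=n_corr_terms, replace=False)
            # weight each noise term inversely to its coordinate's
            # fluctuation scale: every correlated row then carries the
            # same effective noise level and alpha alone sets its SNR
            weights = np.array([inv_scale[int(c)] for c in cols])
            weights = weights * rng.uniform(0.95, 1.05, size=n_corr_terms)
            weights /= weights.sum()
            alpha = float(next(alpha_iter))
            coeff[row, decisive_column] = alpha
            coeff[row, cols] = (1.0 - alpha) * weights
        else:
            k = rng.integers(1, min(max_noise_terms, len(noise_cols)) + 1)
            cols = rng.choice(noise_cols, size=k, replace=False)
            weights = rng.uniform(0.2, 1.0, size=k)
            weights /= weights.sum()
            coeff[row, cols] = weights

    return MixingMatrix(coefficients=coeff, decisive_column=decisive_column, seed=seed)


def apply_mixing(mix: MixingMatrix, traj) -> np.ndarray:
    """Project latent trajectories onto observable features.

    ``traj`` is a TrajectoryEnsemble or a frames array
    ``(n_traj, n_steps, n_coordinates)``; returns
    ``(n_traj, n_steps, n_features)``.
    """
    frames = traj.frames if isinstance(traj, TrajectoryEnsemble) else np.asarray(traj, float)
    if frames.shape[-1] != mix.n_coordinates:
        raise ValueError(
            f"trajectory dimension {frames.shape[-1]} != "
            f"mixing n_coordinates {mix.n_coordinates}"
        )
    return frames @ mix.coefficients.T
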
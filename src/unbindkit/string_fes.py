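"""Finite-temperature string refinement and binless-WHAM free energies.

A string is an ordered set of restraint centres (nodes) in CV space,
reparametrised to equal arc-length spacing.  Each refinement iteration
restrains one sampling window per node (harmonic, default force constant
20 energy units per Å²), refits an order-8 polynomial per CV through the
window means, and re-places the nodes equidistantly on the refitted
curve; the string has converged when every CV's maximal node change is
below 7% of that CV's path range or below 0.3 Å absolute.

The restrained windows are then unbiased with the binless weighted
histogram analysis method: the self-consistent equations

    f_i = -kT ln sum_n m_n exp(-u_i(x_n)/kT) / sum_j N_j exp((f_j - u_j(x_n))/kT)

are iterated (gauge f_0 = 0) to yield per-sample unbiased weights, from
which the potential of mean force along the normalised string coordinate
is estimated (binning is for display only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .engine import LangevinParams, simulate
from .potentials import Potential

__all__ = [
    "StringPath",
    "PMFProfile",
    "WHAMResult",
    "seed_string",
    "refit_string",
    "check_convergence",
    "binless_wham",
    "pmf_and_barrier",
    "pick_ts_candidates",
    "sample_windows",
    "run_string",
    "string_umbrella_energies",
]


# ---------------------------------------------------------------------------
# string geometry
# ---------------------------------------------------------------------------


def _resample_equidistant(points: np.ndarray, n_out: int) -> np.ndarray:
    """Place ``n_out`` points equidistantly in arc length along a polyline."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate (constant) curve: zero arc length")
    s /= s[-1]
    targets = np.linspace(0.0, 1.0, n_out)
    return np.column_stack(
        [np.interp(targets, s, points[:, c]) for c in range(points.shape[1])]
    )


@dataclass
class StringPath:
    """Ordered restraint centres in CV space, equidistant in arc length."""

    nodes: np.ndarray  # (n_windows, n_cvs), Å
    force_constant: float = 20.0
    iteration: int = 0
    ensembles: list | None = None  # per-node sampled frames, filled by sampling

    def __post_init__(self):
        self.nodes = np.atleast_2d(np.asarray(self.nodes, dtype=float))

    @property
    def n_windows(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_cvs(self) -> int:
        return self.nodes.shape[1]

    @property
    def arc_parameter(self) -> np.ndarray:
        """Normalised cumulative arc length per node, in [0, 1]."""
        seg = np.linalg.norm(np.diff(self.nodes, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        return s / s[-1] if s[-1] > 0 else s

    @property
    def node_spacing(self) -> float:
        """Mean Euclidean arc gap between neighbouring nodes."""
        seg = np.linalg.norm(np.diff(self.nodes, axis=0), axis=1)
        return float(seg.mean())

    def save(self, path) -> None:
        header = "\t".join(f"cv{i}" for i in range(self.n_cvs))
        np.savetxt(path, self.nodes, delimiter="\t", header=header, comments="")

    @classmethod
    def load(cls, path, **kwargs) -> "StringPath":
        return cls(nodes=np.loadtxt(path, delimiter="\t", skiprows=1), **kwargs)


def seed_string(
    cv_series: np.ndarray,
    n_windows: int = 100,
    force_constant: float = 20.0,
    smooth: int | None = None,
) -> StringPath:
    """Initial string from an unbinding CV trajectory.

    The per-frame CV series (n_frames, n_cvs) is lightly smoothed with a
    moving average (default window: n_frames // n_windows) and resampled
    to ``n_windows`` nodes equidistant in arc length.
    """
    series = np.atleast_2d(np.asarray(cv_series, dtype=float))
    if series.shape[0] < 2:
        raise ValueError("cv_series needs at least two frames")
    if np.allclose(series, series[0]):
        raise ValueError("degenerate (constant) CV series")
    if n_windows < 2:
        raise ValueError("need at least 2 windows")
    if smooth is None:
        smooth = max(1, series.shape[0] // n_windows)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        series = np.column_stack(
            [np.convolve(series[:, c], kernel, mode="valid")
             for c in range(series.shape[1])]
        )
    nodes = _resample_equidistant(series, n_windows)
    return StringPath(nodes=nodes, force_constant=force_constant, iteration=0)


def refit_string(
    path: StringPath,
    window_means: np.ndarray,
    order: int = 8,
    dense: int = 2001,
) -> StringPath:
    """One string refinement: polynomial refit through window means.

    Fits an ``order``-degree polynomial per CV against the current arc
    parameter, evaluates it densely, and re-places the nodes
    equidistantly along the refitted curve.
    """
    means = np.atleast_2d(np.asarray(window_means, dtype=float))
    if means.shape != path.nodes.shape:
        raise ValueError("window_means must match the string shape")
    if order >= path.n_windows:
        raise ValueError("polynomial order must be below n_windows")
    t = path.arc_parameter
    t_dense = np.linspace(0.0, 1.0, dense)
    curve = np.column_stack(
        [
            np.polynomial.Polynomial.fit(t, means[:, c], deg=order)(t_dense)
            for c in range(path.n_cvs)
        ]
    )
    nodes = _resample_equidistant(curve, path.n_windows)
    return StringPath(nodes=nodes, force_constant=path.force_constant,
                      iteration=path.iteration + 1)


def check_convergence(
    prev: StringPath,
    curr: StringPath,
    rel_tol: float = 0.07,
    abs_tol: float = 0.3,
):
    """String convergence test: per-CV max node change below 7% of the
    CV's path range, or below 0.3 Å absolute.

    Returns ``(converged, per_cv_max_change)``.
    """
    if prev.nodes.shape != curr.nodes.shape:
        raise ValueError("paths differ in shape")
    delta = np.abs(curr.nodes - prev.nodes).max(axis=0)
    cv_range = np.ptp(prev.nodes, axis=0)
    ok = (delta < rel_tol * cv_range) | (delta < abs_tol)
    return bool(np.all(ok)), delta


# ---------------------------------------------------------------------------
# restrained window sampling
# ---------------------------------------------------------------------------


class _PerWindowRestraint:
    """Batch bias: window i's trajectory is restrained to node i."""

    def __init__(self, centers: np.ndarray, force_constant: float):
        self.centers = np.asarray(centers, dtype=float)
        self.k = float(force_constant)

    def gradient(self, x, progress=1.0):
        return self.k * (x - self.centers)

    def energy(self, x, progress=1.0):
        return 0.5 * self.k * np.sum((x - self.centers) ** 2, axis=-1)


def sample_windows(
    potential: Potential,
    path: StringPath,
    params: LangevinParams,
    equilibration_fraction: float = 0.5,
    subsample: int = 5,
) -> list:
    """Restrained sampling of every window, propagated as one batch.

    Starts each window at its node, discards the first
    ``equilibration_fraction`` of frames, and keeps every ``subsample``-th
    remaining frame.  Returns a list of (n_samples, n_cvs) arrays.
    """
    bias = _PerWindowRestraint(path.nodes, path.force_constant)
    traj = simulate(potential, params, bias=bias, x0=path.nodes.copy())
    start = int(equilibration_fraction * traj.n_steps)
    kept = traj.frames[:, start::subsample, :]
    return [kept[i] for i in range(path.n_windows)]


def run_string(
    potential: Potential,
    path: StringPath,
    params: LangevinParams,
    max_iterations: int = 30,
    order: int = 8,
    rel_tol: float = 0.07,
    abs_tol: float = 0.3,
    seed: int | None = None,
):
    """Iterate restrained sampling + refit until string convergence.

    Returns ``(path, history)`` where history records per-iteration
    convergence diagnostics; the returned path carries the final
    iteration's sampled ensembles.
    """
    seeds = np.random.SeedSequence(seed).generate_state(max_iterations + 1)
    seeds = seeds % (2**31)

    def _params(s):
        return LangevinParams(step_size=params.step_size,
                              friction=params.friction, kT=params.kT,
                              n_steps=params.n_steps, stride=params.stride,
                              seed=int(s))

    history = []
    for it in range(max_iterations):
        # ensembles belong to the path they were restrained to: keep them
        # attached to *this* path, never to the refitted one
        path.ensembles = sample_windows(potential, path, _params(seeds[it]))
        means = np.array([e.mean(axis=0) for e in path.ensembles])
        new_path = refit_string(path, means, order=order)
        converged, delta = check_convergence(path, new_path, rel_tol, abs_tol)
        history.append({"iteration": it, "max_change": delta.tolist(),
                        "converged": converged})
        path = new_path
        if converged:
            break
    # the final path (refitted, or loop-exhausted) gets its own sampling so
    # downstream WHAM sees bias energies consistent with its nodes
    path.ensembles = sample_windows(potential, path, _params(seeds[max_iterations]))
    return path, history


def string_umbrella_energies(path: StringPath, kT: float):
    """Bias-energy matrix u[i, n] of every sample under every window.

    Uses the path's attached ensembles; returns ``(u, counts, samples)``
    where samples is the concatenated (N, n_cvs) array.
    """
    if not path.ensembles:
        raise ValueError("path carries no sampled ensembles")
    samples = np.concatenate(path.ensembles, axis=0)
    counts = np.array([len(e) for e in path.ensembles])
    diff = samples[None, :, :] - path.nodes[:, None, :]
    u = 0.5 * path.force_constant * np.sum(diff**2, axis=-1)
    return u, counts, samples


# ---------------------------------------------------------------------------
# binless WHAM
# ---------------------------------------------------------------------------


@dataclass
class WHAMResult:
    window_free_energies: np.ndarray  # f_i, gauge f_0 = 0
    weights: np.ndarray  # normalised unbiased per-sample weights
    n_iterations: int
    converged: bool
    max_residual: float


def _wham_log_denominator(u, f, log_counts, kT):
    # d_n = ln sum_j N_j exp((f_j - u_jn)/kT)
    return logsumexp((f[:, None] - u) / kT + log_counts[:, None], axis=0)


def binless_wham(
    bias_energies: np.ndarray,
    counts: np.ndarray,
    kT: float = 1.0,
    tol: float = 1.0e-7,
    max_iterations: int = 100000,
    multiplicities: np.ndarray | None = None,
    method: str = "scf",
) -> WHAMResult:
    """Solve the binless WHAM equations for window free energies and weights.

    ``bias_energies[i, n]`` is the bias energy of sample n under window i,
    ``counts[i]`` the number of samples contributed by window i.
    Optional ``multiplicities`` weight each sample (quadrature use).
    ``method`` is "scf" (self-consistent iteration, default) or "ml"
    (direct maximisation of the WHAM log-likelihood).  Gauge: f_0 = 0.

    Raises on non-convergence with overlap diagnostics in the message
    (typically non-overlapping windows).
    """
    u = np.asarray(bias_energies, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if u.ndim != 2 or u.shape[0] != counts.shape[0]:
        raise ValueError("bias_energies must be (n_windows, n_samples)")
    if multiplicities is None:
        log_m = np.zeros(u.shape[1])
    else:
        log_m = np.log(np.asarray(multiplicities, dtype=float))
    log_counts = np.log(counts)

    f = np.zeros(len(counts))
    scf_tol = tol
    if method == "ml":
        f = _wham_ml(u, f, log_counts, log_m, kT)
        # the optimiser already sits at the stationary point; the SCF pass
        # below just polishes and certifies the residual
        scf_tol = max(tol, 1e-5)
    elif method != "scf":
        raise ValueError("method must be 'scf' or 'ml'")

    converged, it, resid = False, 0, np.inf
    for it in range(1, max_iterations + 1):
        d = _wham_log_denominator(u, f, log_counts, kT)
        f_new = -kT * logsumexp(-u / kT + log_m - d, axis=1)
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid < scf_tol:
            converged = True
            break
    if not converged:
        overlap = _overlap_diagnostics(u, f, log_counts, kT)
        raise RuntimeError(
            "binless WHAM did not converge "
            f"(max |df| = {resid:.3e} after {it} iterations); "
            f"minimal window overlap = {overlap:.3e} - "
            "windows may not overlap"
        )
    if len(counts) > 1:
        overlap = _overlap_diagnostics(u, f, log_counts, kT)
        if overlap < 1e-6:
            raise RuntimeError(
                "binless WHAM: adjacent windows share essentially no "
                f"configuration-space overlap (min overlap {overlap:.3e}); "
                "the stitched free energies are unreliable"
            )
    d = _wham_log_denominator(u, f, log_counts, kT)
    log_w = log_m - d
    log_w -= logsumexp(log_w)
    return WHAMResult(
        window_free_energies=f,
        weights=np.exp(log_w),
        n_iterations=it,
        converged=True,
        max_residual=resid,
    )


def _wham_ml(u, f0, log_counts, log_m, kT):
    """Direct minimisation of the WHAM negative log-likelihood over f[1:]."""
    counts = np.exp(log_counts)
    m = np.exp(log_m)

    def objective(f_tail):
        f = np.concatenate([[0.0], f_tail])
        d = _wham_log_denominator(u, f, log_counts, kT)
        # negative log-likelihood (up to constants), gradient wrt f/kT
        val = np.sum(m * d) - np.sum(counts * f) / kT
        p = np.exp((f[:, None] - u) / kT + log_counts[:, None] - d[None, :])
        grad = (p * m).sum(axis=1) / kT - counts / kT
        return val, grad[1:]

    res = minimize(objective, np.asarray(f0[1:]), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    return np.concatenate([[0.0], res.x])


def _overlap_diagnostics(u, f, log_counts, kT):
    d = _wham_log_denominator(u, f, log_counts, kT)
    p = np.exp((f[:, None] - u) / kT + log_counts[:, None] - d[None, :])
    p /= p.sum(axis=1, keepdims=True)
    # smallest nearest-neighbour overlap between window sample distributions
    overlaps = [
        np.minimum(p[i], p[i + 1]).sum() for i in range(len(f) - 1)
    ]
    return min(overlaps) if overlaps else 0.0


# ---------------------------------------------------------------------------
# PMF, barrier, TS windows
# ---------------------------------------------------------------------------


@dataclass
class PMFProfile:
    """Free energy along the normalised string coordinate.

    The profile is shifted so its minimum is zero; ``barrier`` is the
    global maximum minus the bound-side (left of the maximum) minimum.
    """

    arc: np.ndarray
    free_energy: np.ndarray  # kT units unless stated otherwise
    standard_error: np.ndarray
    barrier: float
    ts_windows: np.ndarray

    def save(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.arc, self.free_energy, self.standard_error]),
            delimiter="\t",
            header="arc\tfree_energy\tstderr",
            comments="",
        )


def _profile_from_weights(weights, arcs, n_bins, kT):
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(arcs, edges) - 1, 0, n_bins - 1)
    mass = np.bincount(idx, weights=weights, minlength=n_bins)
    with np.errstate(divide="ignore"):
        fe = -kT * np.log(mass)
    return fe - np.nanmin(fe[np.isfinite(fe)])


def pmf_and_barrier(
    wham: WHAMResult,
    sample_arcs: np.ndarray,
    counts: np.ndarray | None = None,
    n_bins: int | None = None,
    kT: float = 1.0,
    n_ts_windows: int = 5,
    bias_energies: np.ndarray | None = None,
    method: str = "scf",
) -> PMFProfile:
    """PMF along the normalised string coordinate from WHAM weights.

    ``sample_arcs`` assigns each sample an arc coordinate in [0, 1]
    (projection onto the string).  The standard error is estimated by
    re-solving WHAM on a contiguous 4-way split of every window's samples
    when ``counts``/``bias_energies`` are provided, else left at zero.
    """
    arcs = np.asarray(sample_arcs, dtype=float)
    if n_bins is None:
        n_bins = 100 if counts is None else len(counts)
    fe = _profile_from_weights(wham.weights, arcs, n_bins, kT)
    stderr = np.zeros(n_bins)

    if counts is not None and bias_energies is not None:
        profiles = []
        for part in range(4):
            keep = np.zeros(arcs.shape[0], dtype=bool)
            start = 0
            for n in counts:
                n = int(n)
                lo = start + (part * n) // 4
                hi = start + ((part + 1) * n) // 4
                keep[lo:hi] = True
                start += n
            sub = binless_wham(bias_energies[:, keep],
                               np.maximum(1, [(keep[s:s + int(n)]).sum()
                                              for s, n in zip(
                                                  np.cumsum([0, *counts[:-1]]),
                                                  counts)]),
                               kT=kT, method=method)
            profiles.append(_profile_from_weights(sub.weights, arcs[keep],
                                                  n_bins, kT))
        profiles = np.array(profiles)
        with np.errstate(invalid="ignore"):
            stderr = np.nanstd(profiles, axis=0, ddof=1) / np.sqrt(4)
        stderr = np.nan_to_num(stderr)

    finite = np.isfinite(fe)
    fe_f = np.where(finite, fe, np.inf)
    imax = int(np.argmax(np.where(finite, fe, -np.inf)))
    bound_min = float(fe_f[: imax + 1].min()) if imax > 0 else float(fe_f.min())
    barrier = float(fe[imax] - bound_min)
    arc_centers = (np.arange(n_bins) + 0.5) / n_bins
    ts = pick_ts_candidates_from_profile(fe, n=min(n_ts_windows, n_bins))
    return PMFProfile(arc=arc_centers, free_energy=fe, standard_error=stderr,
                      barrier=barrier, ts_windows=ts)


def pick_ts_candidates_from_profile(free_energy: np.ndarray, n: int = 5) -> np.ndarray:
    """Indices of the n highest-free-energy windows, preferring a
    contiguous block around the global maximum.

    Ties are resolved toward the bound state (lower index), so a flat
    profile yields the first n windows.
    """
    fe = np.asarray(free_energy, dtype=float)
    fe = np.where(np.isfinite(fe), fe, -np.inf)
    if n > fe.shape[0]:
        raise ValueError("n exceeds the number of windows")
    peak = int(np.argmax(fe))  # argmax takes the first (bound-side) of ties
    chosen = [peak]
    left, right = peak - 1, peak + 1
    while len(chosen) < n:
        left_fe = fe[left] if left >= 0 else -np.inf
        right_fe = fe[right] if right < fe.shape[0] else -np.inf
        if left_fe >= right_fe:  # tie toward the bound side
            chosen.append(left)
            left -= 1
        else:
            chosen.append(right)
            right += 1
    return np.array(sorted(chosen))


def pick_ts_candidates(profile: PMFProfile, n: int = 5) -> np.ndarray:
    """TS candidate windows of a computed PMF (highest-energy block)."""
    return pick_ts_candidates_from_profile(profile.free_energy, n=n)


def project_onto_path(path: StringPath, samples: np.ndarray) -> np.ndarray:
    """Arc coordinate in [0, 1] of each sample: arc of the nearest node."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    d2 = ((samples[:, None, :] - path.nodes[None, :, :]) ** 2).sum(axis=-1)
    nearest = np.argmin(d2, axis=1)
    return path.arc_parameter[nearest]
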
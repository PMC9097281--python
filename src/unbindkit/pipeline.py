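"""End-to-end runs binding all modules, with manifests and fixtures.

Two pipelines are provided.  The "benchmark" pipeline runs the
analytical MLTSA benchmark (simulate latent wells -> mix into features
-> train/score classifiers -> feature analysis).  The "pocket" pipeline
exercises the full unbinding methodology on the toy 2D pocket:
iterative contact-based unbinding -> string seeding and refinement ->
binless WHAM PMF and barrier -> TS-candidate selection -> downhill
trajectories -> MLTSA.  Every run directory receives a JSON manifest
with the configuration, package version, derived seeds, and sha256
hashes of all artifacts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__, benchmarks, mltsa, string_fes
from .config import RunConfig
from .cvselect import AnchoredParticleSystem, ProtocolParams, run_unbinding
from .engine import LangevinParams

__all__ = ["run_pipeline", "make_fixtures"]

_POCKET_STAGES = ("unbind", "string", "wham", "downhill", "mltsa")


def make_fixtures(seed: int = 0) -> dict:
    """The shipped toy systems, as a name -> fixture mapping.

    * ``benchmark_1dw``: 180 features, 11 correlated, one decisive
      double well among 25 latent coordinates.
    * ``benchmark_5dw``: the harder variant with 5 double-well
      potentials and 15 correlated features.
    * ``pocket_string``: single-anchor 2D pocket with known
      minimum-energy path and barrier metadata.
    * ``pocket_unbind``: three-anchor 2D pocket for the unbinding
      protocol.
    """
    return {
        "benchmark_1dw": benchmarks.make_benchmark(seed=seed),
        "benchmark_5dw": benchmarks.make_benchmark(
            n_noise_doublewells=4, n_correlated=15, seed=seed
        ),
        "pocket_string": benchmarks.pocket_system("string"),
        "pocket_unbind": benchmarks.pocket_system("unbind"),
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured pipeline (or any stage prefix).

    Returns the run directory; artifacts are delimited text or JSON, and
    ``manifest.json`` records what was run and the hash of every output.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    if not stages:
        stages = ["benchmark"] if config.mode == "benchmark" else list(_POCKET_STAGES)
    _check_prefix(config.mode, stages)

    seeds = np.random.SeedSequence(config.seed).generate_state(len(stages)) % (2**31)
    results: dict = {}
    for stage, seed in zip(stages, seeds):
        _STAGE_RUNNERS[stage](config, int(seed), out, results)

    manifest = {
        "unbindkit_version": __version__,
        "config": config.to_dict(),
        "stages_run": stages,
        "stage_seeds": [int(s) for s in seeds],
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _check_prefix(mode: str, stages: list) -> None:
    if mode == "benchmark":
        if stages != ["benchmark"]:
            raise ValueError("benchmark mode runs the single stage ['benchmark']")
        return
    if tuple(stages) != tuple(_POCKET_STAGES[: len(stages)]):
        raise ValueError(
            f"pocket stages must be a prefix of {list(_POCKET_STAGES)}, got {stages}"
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------


def _stage_benchmark(config: RunConfig, seed: int, out: Path, results: dict):
    bench = benchmarks.make_benchmark(seed=seed, **config.benchmark)
    n_replicas = config.ml.get("n_replicas", 3)
    classifiers = config.ml.get("classifiers", ["mlp", "gbdt"])
    study = benchmarks.replica_study(
        bench, n_replicas=n_replicas, seed=seed,
        run_mlp="mlp" in classifiers, run_gbdt="gbdt" in classifiers,
    )
    report = {
        "n_replicas": n_replicas,
        "correlated_features": bench.correlated_features.tolist(),
        "alphas": bench.mixing.alphas[bench.correlated_features].tolist(),
        "replicas": [
            {"mlp": r.mlp.to_dict() if r.mlp else None,
             "gbdt": r.gbdt.to_dict() if r.gbdt else None}
            for r in study
        ],
    }
    (out / "benchmark_report.json").write_text(json.dumps(report, indent=1))
    results["benchmark"] = study


def _pocket_system(config: RunConfig) -> tuple:
    fixture = benchmarks.pocket_system("unbind")
    langevin = LangevinParams(step_size=0.005, kT=1.0, n_steps=1)
    system = AnchoredParticleSystem(fixture.potential, fixture.anchors, langevin)
    return fixture, system


def _stage_unbind(config: RunConfig, seed: int, out: Path, results: dict):
    fixture, system = _pocket_system(config)
    defaults = {"iteration_length": 4000, "evaluation_window": 2000}
    params = ProtocolParams(**{**defaults, **config.protocol})
    result = run_unbinding(system, params, seed=seed, x0=fixture.x0)
    np.savetxt(out / "unbind_cv_series.tsv", result.cv_series[:, None],
               delimiter="\t", header="cv_sum", comments="")
    (out / "unbind_iterations.json").write_text(
        json.dumps({"terminated": result.terminated,
                    "iterations": result.iteration_log}, indent=1))
    results["unbind"] = (fixture, system, result, params)


def _stage_string(config: RunConfig, seed: int, out: Path, results: dict):
    fixture, system, unbind, _ = results["unbind"]
    n_windows = config.string.get("n_windows", 50)
    path = string_fes.seed_string(unbind.frames, n_windows=n_windows)
    params = LangevinParams(
        step_size=0.005,
        n_steps=config.string.get("steps_per_window", 2000),
        kT=1.0,
    )
    path, history = string_fes.run_string(
        system.potential, path, params,
        max_iterations=config.string.get("max_iterations", 10), seed=seed,
    )
    path.save(out / "string_nodes.tsv")
    (out / "string_history.json").write_text(json.dumps(history, indent=1))
    results["string"] = path


def _stage_wham(config: RunConfig, seed: int, out: Path, results: dict):
    path = results["string"]
    u, counts, samples = string_fes.string_umbrella_energies(path, kT=1.0)
    # direct likelihood maximisation: many overlapping windows make the
    # plain self-consistent iteration diffusively slow
    wham = string_fes.binless_wham(u, counts, kT=1.0, method="ml")
    arcs = string_fes.project_onto_path(path, samples)
    profile = string_fes.pmf_and_barrier(
        wham, arcs, counts=counts, kT=1.0, bias_energies=u,
        n_bins=min(path.n_windows, 50), method="ml",
    )
    profile.save(out / "pmf.tsv")
    results["wham"] = (wham, profile)


def _stage_downhill(config: RunConfig, seed: int, out: Path, results: dict):
    fixture, system, _, _ = results["unbind"]
    path = results["string"]
    _, profile = results["wham"]
    # map TS bins back to nearest string nodes
    arc_nodes = path.arc_parameter
    ts_arcs = profile.arc[profile.ts_windows]
    node_idx = np.unique([int(np.argmin(np.abs(arc_nodes - a))) for a in ts_arcs])
    candidates = path.nodes[node_idx]
    params = LangevinParams(step_size=0.005,
                            n_steps=config.ml.get("downhill_steps", 400), kT=1.0)
    bundles = mltsa.generate_downhill(system.potential, candidates,
                                      n_runs=config.ml.get("downhill_runs", 20),
                                      params=params, seed=seed)
    labelled = []
    fractions = []
    for bundle in bundles:
        dists = np.stack([system.distance_table(bundle.frames[i]).to_numpy()
                          for i in range(bundle.n_trajectories)])
        labels, resolved = mltsa.label_downhill(dists)
        fractions.append(float(np.mean(labels[resolved] == "IN")))
        labelled.append((dists, labels, resolved))
    chosen = mltsa.select_ts(fractions,
                             pmf_values=profile.free_energy[profile.ts_windows[:len(fractions)]])
    (out / "downhill_committors.json").write_text(json.dumps(
        {"in_fractions": fractions, "chosen_candidate": int(chosen)}, indent=1))
    results["downhill"] = (labelled, chosen)


def _stage_mltsa(config: RunConfig, seed: int, out: Path, results: dict):
    labelled, chosen = results["downhill"]
    dists, labels, resolved = labelled[chosen]
    n_steps = dists.shape[1]
    window = tuple(config.ml.get("window", (n_steps // 10, n_steps // 4)))
    keep = np.flatnonzero(resolved)
    n_val = max(2, len(keep) // 5)
    dataset = mltsa.DownhillDataset(
        features=dists[keep], labels=labels[keep], window=window,
        validation_ids=np.arange(len(keep) - n_val, len(keep)), seed=seed,
    )
    model, report = mltsa.train_and_score(dataset, mltsa.MLPConfig(seed=seed))
    report.accuracy_drops = mltsa.global_mean_drop(model, dataset)
    (out / "mltsa_report.json").write_text(json.dumps(report.to_dict(), indent=1))
    results["mltsa"] = report


_STAGE_RUNNERS = {
    "benchmark": _stage_benchmark,
    "unbind": _stage_unbind,
    "string": _stage_string,
    "wham": _stage_wham,
    "downhill": _stage_downhill,
    "mltsa": _stage_mltsa,
}
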
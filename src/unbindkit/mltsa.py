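"""Machine Learning Transition State Analysis (MLTSA).

Downhill (unbiased) trajectories launched from transition-state
candidates either rebind (IN) or dissociate (OUT).  A classifier trained
on an early-time window of per-frame features learns to predict that
fate; the features whose removal (replacement by their training-set
global mean) degrades the prediction are the ones that decide the
outcome at the transition state.

Two backends are supported with fixed, deliberately simple
hyperparameters: a single-hidden-layer perceptron (100 ReLU units, Adam,
lr 1e-3, <=500 epochs, tol 1e-4 with 10-epoch patience) and gradient
boosted decision trees (500 estimators, lr 0.1, Friedman-MSE splits,
depth 3, validation fraction 0.1).  The global-mean swap analysis is
model agnostic; the GBDT additionally exposes split-gain feature
importances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.neural_network import MLPClassifier

from .engine import IN, OUT, LangevinParams, TrajectoryEnsemble, simulate

__all__ = [
    "MLPConfig",
    "GBDTConfig",
    "DownhillDataset",
    "MLTSAReport",
    "generate_downhill",
    "select_ts",
    "label_downhill",
    "train_and_score",
    "accuracy_sweep",
    "global_mean_drop",
    "gbdt_importances",
]


@dataclass
class MLPConfig:
    hidden_units: int = 100
    activation: str = "relu"
    learning_rate: float = 0.001
    max_epochs: int = 500
    tolerance: float = 1e-4
    patience: int = 10
    seed: int | None = None

    def build(self):
        return MLPClassifier(
            hidden_layer_sizes=(self.hidden_units,),
            activation=self.activation,
            solver="adam",
            learning_rate_init=self.learning_rate,
            max_iter=self.max_epochs,
            tol=self.tolerance,
            n_iter_no_change=self.patience,
            random_state=self.seed,
        )


@dataclass
class GBDTConfig:
    """Gradient-boosted trees with logistic loss.

    ``validation_fraction`` only has an effect together with
    ``patience`` (scikit-learn's ``n_iter_no_change``): boosting stops
    once the held-out 0.1 split stops improving, typically well before
    the 500-estimator ceiling.  Set ``patience=None`` to always fit the
    full ensemble.
    """

    n_estimators: int = 500
    learning_rate: float = 0.1
    max_depth: int = 3
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    validation_fraction: float = 0.1
    patience: int | None = 20
    seed: int | None = None

    def build(self):
        # split criterion: Friedman MSE (scikit-learn's default and, since
        # 1.9, its only supported criterion)
        return GradientBoostingClassifier(
            loss="log_loss",
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            validation_fraction=self.validation_fraction,
            n_iter_no_change=self.patience,
            random_state=self.seed,
        )


@dataclass
class DownhillDataset:
    """Windowed per-frame feature dataset with a trajectory-level holdout.

    ``features`` is (n_traj, n_steps, n_features); ``labels`` one IN/OUT
    string per trajectory.  ``window = (start, end)`` selects frames
    start..end inclusive.  Frames from non-validation trajectories are
    concatenated, shuffled and split (1 - test_fraction)/test_fraction;
    validation trajectories never contribute frames to training.
    """

    features: np.ndarray
    labels: np.ndarray
    window: tuple = (30, 60)
    test_fraction: float = 0.3
    validation_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    seed: int | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 3:
            raise ValueError("features must be (n_traj, n_steps, n_features)")
        if self.labels.shape[0] != self.features.shape[0]:
            raise ValueError("one label per trajectory required")
        if not set(np.unique(self.labels)) <= {IN, OUT}:
            raise ValueError("labels must be IN/OUT")
        self.validation_ids = np.asarray(self.validation_ids, dtype=int)
        lo, hi = self.window
        if not (0 <= lo <= hi < self.features.shape[1]):
            raise ValueError("window out of trajectory range")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")

    @property
    def n_features(self) -> int:
        return self.features.shape[2]

    @property
    def training_ids(self) -> np.ndarray:
        mask = np.ones(self.features.shape[0], dtype=bool)
        mask[self.validation_ids] = False
        return np.flatnonzero(mask)

    def _window_frames(self, traj_ids):
        lo, hi = self.window
        X = self.features[traj_ids, lo : hi + 1].reshape(-1, self.n_features)
        y = np.repeat(self.labels[traj_ids], hi - lo + 1)
        return X, y

    def frame_split(self):
        """Shuffled train/test frame matrices from non-validation trajectories."""
        X, y = self._window_frames(self.training_ids)
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(len(y))
        X, y = X[order], y[order]
        n_test = int(round(self.test_fraction * len(y)))
        return X[n_test:], y[n_test:], X[:n_test], y[:n_test]

    def validation_frames(self):
        """Window frames of held-out trajectories, grouped per trajectory."""
        lo, hi = self.window
        return [
            (self.features[i, lo : hi + 1], self.labels[i])
            for i in self.validation_ids
        ]

    # -- packed container with a JSON manifest ------------------------------
    def save(self, path) -> None:
        """Write the dataset as a .npz container plus a JSON sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        np.savez_compressed(path, features=self.features,
                            labels=self.labels.astype("U3"),
                            validation_ids=self.validation_ids)
        manifest = {
            "window": list(self.window),
            "test_fraction": self.test_fraction,
            "seed": self.seed,
            "shape": list(self.features.shape),
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path) -> "DownhillDataset":
        import json
        from pathlib import Path

        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as data:
            return cls(
                features=data["features"],
                labels=data["labels"],
                validation_ids=data["validation_ids"],
                window=tuple(manifest["window"]),
                test_fraction=manifest["test_fraction"],
                seed=manifest["seed"],
            )


@dataclass
class MLTSAReport:
    """Results of one MLTSA run: accuracies, drops, importances, rankings."""

    train_accuracy: float
    test_accuracy: float
    validation_accuracy: float | None = None
    validation_frame_accuracy: float | None = None
    accuracy_drops: np.ndarray | None = None
    feature_importances: np.ndarray | None = None
    window: tuple = (30, 60)
    model_kind: str = ""

    def ranked_by_drop(self) -> np.ndarray:
        if self.accuracy_drops is None:
            raise ValueError("no accuracy drops computed")
        return np.argsort(self.accuracy_drops)[::-1]

    def ranked_by_importance(self) -> np.ndarray:
        if self.feature_importances is None:
            raise ValueError("no feature importances available")
        return np.argsort(self.feature_importances)[::-1]

    def to_dict(self) -> dict:
        d = {
            "model_kind": self.model_kind,
            "window": list(self.window),
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
            "validation_accuracy": self.validation_accuracy,
            "validation_frame_accuracy": self.validation_frame_accuracy,
        }
        if self.accuracy_drops is not None:
            d["accuracy_drops"] = np.asarray(self.accuracy_drops).tolist()
        if self.feature_importances is not None:
            d["feature_importances"] = np.asarray(self.feature_importances).tolist()
        return d


# ---------------------------------------------------------------------------
# downhill trajectory generation and TS selection
# ---------------------------------------------------------------------------


def generate_downhill(
    potential,
    candidates,
    n_runs: int,
    params: LangevinParams,
    seed: int | None = None,
) -> list:
    """Unbiased trajectory bundles from each TS candidate starting point.

    Returns one TrajectoryEnsemble per candidate; each bundle's ``n_runs``
    trajectories use distinct child seeds spawned from ``seed``.
    """
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    seeds = np.random.SeedSequence(seed).generate_state(len(candidates)) % (2**31)
    out = []
    for cand, s in zip(candidates, seeds):
        p = LangevinParams(step_size=params.step_size, friction=params.friction,
                           kT=params.kT, n_steps=params.n_steps, seed=int(s))
        x0 = np.tile(cand, (n_runs, 1))
        out.append(simulate(potential, p, bias=None, x0=x0))
    return out


def select_ts(in_fractions, pmf_values=None) -> int:
    """Pick the TS candidate whose committor is closest to 1:1 IN/OUT.

    Ties are broken toward the candidate with the higher free energy
    (when ``pmf_values`` is given), else the lowest index.
    """
    fr = np.asarray(in_fractions, dtype=float)
    if fr.size == 0:
        raise ValueError("no candidates")
    dist = np.abs(fr - 0.5)
    best = np.flatnonzero(np.isclose(dist, dist.min()))
    if len(best) > 1 and pmf_values is not None:
        pmf = np.asarray(pmf_values, dtype=float)
        best = best[np.argsort(-pmf[best], kind="stable")]
    return int(best[0])


def label_downhill(
    distances: np.ndarray,
    pair_indices: tuple = (0, 1),
    bound_threshold: float = 3.5,
    unbound_threshold: float = 6.0,
    final_fraction: float = 0.1,
):
    """Label downhill trajectories from two monitored key distances.

    ``distances`` is (n_traj, n_steps, n_pairs).  A trajectory is IN when
    both key distances' means over the final ``final_fraction`` of frames
    are below ``bound_threshold``; OUT when either exceeds
    ``unbound_threshold``; otherwise unresolved (flagged, to be excluded).

    Returns ``(labels, resolved_mask)``.
    """
    distances = np.asarray(distances, dtype=float)
    i, j = pair_indices
    n_last = max(1, int(round(final_fraction * distances.shape[1])))
    tail = distances[:, -n_last:, :]
    mi = tail[..., i].mean(axis=1)
    mj = tail[..., j].mean(axis=1)
    is_in = (mi < bound_threshold) & (mj < bound_threshold)
    is_out = (mi > unbound_threshold) | (mj > unbound_threshold)
    resolved = is_in | is_out
    if not resolved.any():
        raise ValueError("all trajectories unresolved; adjust thresholds")
    labels = np.where(is_in, IN, OUT)
    return labels, resolved


# ---------------------------------------------------------------------------
# training, scoring, and feature analysis
# ---------------------------------------------------------------------------


def train_and_score(dataset: DownhillDataset, config) -> tuple:
    """Fit a classifier on the frame split and score it.

    Returns ``(model, report)`` where the report holds train/test frame
    accuracies plus, when the dataset has held-out trajectories, the
    per-trajectory majority-vote validation accuracy and the per-frame
    validation accuracy.
    """
    X_train, y_train, X_test, y_test = dataset.frame_split()
    if len(np.unique(y_train)) < 2:
        raise ValueError("training frames contain a single class")
    model = config.build()
    model.fit(X_train, y_train)

    report = MLTSAReport(
        train_accuracy=float(model.score(X_train, y_train)),
        test_accuracy=float(model.score(X_test, y_test)),
        window=dataset.window,
        model_kind=type(model).__name__,
    )
    if len(dataset.validation_ids):
        votes, frame_hits, n_frames = [], 0, 0
        for frames, label in dataset.validation_frames():
            pred = model.predict(frames)
            votes.append(_majority(pred) == label)
            frame_hits += int(np.sum(pred == label))
            n_frames += len(pred)
        report.validation_accuracy = float(np.mean(votes))
        report.validation_frame_accuracy = frame_hits / n_frames
    return model, report


def _majority(pred: np.ndarray) -> str:
    vals, counts = np.unique(pred, return_counts=True)
    return vals[np.argmax(counts)]


def accuracy_sweep(dataset: DownhillDataset, config, windows) -> list:
    """Train/score once per candidate window; returns list of reports.

    Used to locate the regime where the classification problem is
    accurately solvable but not trivially so (late windows approach the
    labels themselves; very early windows carry no information).
    """
    reports = []
    for lo, hi in windows:
        d = DownhillDataset(
            features=dataset.features, labels=dataset.labels, window=(lo, hi),
            test_fraction=dataset.test_fraction,
            validation_ids=dataset.validation_ids, seed=dataset.seed,
        )
        _, rep = train_and_score(d, config)
        reports.append(rep)
    return reports


def global_mean_drop(model, dataset: DownhillDataset, on: str = "test") -> np.ndarray:
    """Per-feature accuracy drop under the global-mean swap.

    One feature at a time is replaced everywhere with its mean over all
    frames used for training (train split); the model re-predicts and the
    drop is baseline accuracy minus swapped accuracy.  ``on`` selects the
    evaluation frames: "test" (default), "train", or "validation".
    """
    X_train, y_train, X_test, y_test = dataset.frame_split()
    means = X_train.mean(axis=0)
    if on == "test":
        X_eval, y_eval = X_test, y_test
    elif on == "train":
        X_eval, y_eval = X_train, y_train
    elif on == "validation":
        pairs = dataset.validation_frames()
        if not pairs:
            raise ValueError("dataset has no validation trajectories")
        X_eval = np.concatenate([f for f, _ in pairs])
        y_eval = np.concatenate(
            [np.repeat(lbl, len(f)) for f, lbl in pairs]
        )
    else:
        raise ValueError("on must be 'test', 'train', or 'validation'")

    baseline = float(np.mean(model.predict(X_eval) == y_eval))
    drops = np.empty(X_eval.shape[1])
    X_swap = X_eval.copy()
    for j in range(X_eval.shape[1]):
        original = X_swap[:, j].copy()
        X_swap[:, j] = means[j]
        drops[j] = baseline - float(np.mean(model.predict(X_swap) == y_eval))
        X_swap[:, j] = original
    return drops


def gbdt_importances(model) -> np.ndarray:
    """Normalised split-gain feature importances of a fitted GBDT."""
    if not hasattr(model, "feature_importances_"):
        raise ValueError("model exposes no feature importances")
    fi = np.asarray(model.feature_importances_, dtype=float)
    total = fi.sum()
    return fi / total if total > 0 else fi
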
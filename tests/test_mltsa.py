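"""MLTSA: dataset mechanics, TS selection, training, feature analysis."""

import hashlib

import numpy as np
import pytest

from unbindkit.benchmarks import pocket_system
from unbindkit.engine import IN, OUT, LangevinParams, label_outcome
from unbindkit.mltsa import (
    DownhillDataset,
    GBDTConfig,
    MLPConfig,
    accuracy_sweep,
    generate_downhill,
    global_mean_drop,
    gbdt_importances,
    label_downhill,
    select_ts,
    train_and_score,
)
from unbindkit.potentials import DoubleWell


def _separable_dataset(n_traj=40, n_steps=20, n_feat=5, seed=0, informative=2):
    """One feature encodes the label exactly; the rest are noise."""
    rng = np.random.default_rng(seed)
    labels = np.where(rng.random(n_traj) < 0.5, IN, OUT)
    feats = rng.normal(size=(n_traj, n_steps, n_feat))
    feats[:, :, informative] = np.where(labels == IN, 1.0, -1.0)[:, None]
    return feats, labels


class TestDownhillDataset:
    def test_split_sizes_and_shuffling(self):
        feats, labels = _separable_dataset()
        ds = DownhillDataset(features=feats, labels=labels, window=(5, 14),
                             test_fraction=0.3, seed=1)
        X_train, y_train, X_test, y_test = ds.frame_split()
        n_frames = 40 * 10
        assert len(y_train) + len(y_test) == n_frames
        assert len(y_test) == round(0.3 * n_frames)

    def test_validation_trajectories_never_reach_training(self):
        """Hash check: training frames identical with/without holdout rows."""
        feats, labels = _separable_dataset(n_traj=30)
        ds_all = DownhillDataset(features=feats, labels=labels, window=(2, 9),
                                 validation_ids=np.arange(25, 30), seed=3)
        ds_trimmed = DownhillDataset(features=feats[:25], labels=labels[:25],
                                     window=(2, 9), seed=3)
        h = lambda arr: hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()
        assert h(ds_all.frame_split()[0]) == h(ds_trimmed.frame_split()[0])

    def test_window_bounds_validated(self):
        feats, labels = _separable_dataset(n_steps=10)
        with pytest.raises(ValueError, match="window"):
            DownhillDataset(features=feats, labels=labels, window=(5, 10))

    def test_foreign_labels_rejected(self):
        feats, _ = _separable_dataset(n_traj=4)
        with pytest.raises(ValueError, match="IN/OUT"):
            DownhillDataset(features=feats,
                            labels=np.array(["YES", "NO", "YES", "NO"]))


class TestSelectTs:
    def test_closest_to_half_wins(self):
        assert select_ts([0.9, 0.7, 0.55, 0.2]) == 2

    def test_tie_broken_by_higher_pmf(self):
        assert select_ts([0.4, 0.6], pmf_values=[1.0, 2.0]) == 1
        assert select_ts([0.4, 0.6], pmf_values=[2.0, 1.0]) == 0

    def test_single_candidate(self):
        assert select_ts([0.8]) == 0


class TestLabelDownhill:
    def test_bound_and_unbound_extremes(self):
        d = np.zeros((2, 10, 2))
        d[0] = 1.0   # both key distances bound
        d[1] = 7.0   # both beyond the unbound cutoff
        labels, resolved = label_downhill(d)
        assert list(labels) == [IN, OUT]
        assert resolved.all()

    def test_intermediate_trajectories_flagged_unresolved(self):
        d = np.full((2, 10, 2), 5.0)  # between the cutoffs
        d[1] = 1.0
        labels, resolved = label_downhill(d)
        assert not resolved[0] and resolved[1]

    def test_all_unresolved_rejected(self):
        with pytest.raises(ValueError, match="unresolved"):
            label_downhill(np.full((3, 10, 2), 5.0))

    def test_agrees_with_basin_labelling_on_pocket(self):
        """Distance-rule labels match the engine's basin labels."""
        fx = pocket_system("unbind")
        params = LangevinParams(step_size=0.005, kT=1.0, n_steps=2500)
        bundles = generate_downhill(fx.potential, [np.array([2.2, 0.0])],
                                    n_runs=40, params=params, seed=5)
        traj = bundles[0]
        anchors = np.array(list(fx.anchors.values()))
        dists = np.linalg.norm(traj.frames[:, :, None, :] - anchors, axis=-1)
        labels, resolved = label_downhill(dists, pair_indices=(0, 1),
                                          bound_threshold=3.5,
                                          unbound_threshold=6.0)
        # oracle: radial basin test on the final frame
        radius = np.linalg.norm(traj.frames[:, -1, :] - anchors.mean(axis=0),
                                axis=1)
        basin = np.where(radius < 3.5, IN, OUT)
        agree = np.mean(labels[resolved] == basin[resolved])
        assert agree > 0.9


class TestGenerateDownhill:
    def test_barrier_top_produces_both_outcomes(self):
        dw = DoubleWell(barrier_height=4.0)
        params = LangevinParams(step_size=0.01, kT=1.0, n_steps=1500)
        bundles = generate_downhill(dw, [[0.0]], n_runs=50, params=params, seed=1)
        labels = label_outcome(bundles[0], 0, crest=0.0)
        assert {IN, OUT} <= set(labels)

    def test_deep_bound_start_stays_in(self):
        dw = DoubleWell(barrier_height=8.0)
        params = LangevinParams(step_size=0.01, kT=0.5, n_steps=500)
        bundles = generate_downhill(dw, [[-1.0]], n_runs=30, params=params, seed=2)
        labels = label_outcome(bundles[0], 0, crest=0.0)
        assert np.mean(labels == IN) > 0.95

    def test_fixed_seed_reproducible(self):
        dw = DoubleWell(barrier_height=3.0)
        params = LangevinParams(step_size=0.01, n_steps=300)
        a = generate_downhill(dw, [[0.0], [0.5]], 10, params, seed=9)
        b = generate_downhill(dw, [[0.0], [0.5]], 10, params, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.frames, y.frames)


class TestTrainAndScore:
    def test_label_encoding_feature_is_perfectly_learnable(self):
        feats, labels = _separable_dataset()
        ds = DownhillDataset(features=feats, labels=labels, window=(5, 14),
                             validation_ids=np.arange(35, 40), seed=0)
        _, rep = train_and_score(ds, MLPConfig(seed=0))
        assert rep.test_accuracy > 0.99
        assert rep.validation_accuracy == 1.0

    def test_permuted_labels_score_at_majority_fraction(self):
        rng = np.random.default_rng(7)
        feats, labels = _separable_dataset(n_traj=60, seed=7)
        shuffled = labels.copy()
        rng.shuffle(shuffled)  # labels decoupled from every feature
        ds = DownhillDataset(features=feats, labels=shuffled, window=(5, 14),
                             seed=7)
        _, rep = train_and_score(ds, MLPConfig(seed=7, max_epochs=100))
        _, _, X_test, y_test = ds.frame_split()
        majority = max(np.mean(y_test == IN), np.mean(y_test == OUT))
        # permutation null: accuracy within binomial noise of majority class
        assert rep.test_accuracy < majority + 4 * np.sqrt(0.25 / len(y_test))

    def test_single_class_training_rejected(self):
        feats, _ = _separable_dataset(n_traj=10)
        ds = DownhillDataset(features=feats, labels=np.array([IN] * 10),
                             window=(5, 14))
        with pytest.raises(ValueError, match="single class"):
            train_and_score(ds, MLPConfig(seed=0))


def test_accuracy_sweep_late_windows_beat_early(rng):
    """Labels come from final frames: late windows carry more information."""
    n_traj, n_steps = 60, 40
    sig = np.cumsum(rng.standard_normal((n_traj, n_steps)), axis=1)
    labels = np.where(sig[:, -1] > 0, IN, OUT)
    feats = sig[:, :, None] + 0.3 * rng.standard_normal((n_traj, n_steps, 1))
    ds = DownhillDataset(features=feats, labels=labels, window=(0, 1), seed=0)
    reps = accuracy_sweep(ds, MLPConfig(seed=0, max_epochs=150),
                          windows=[(0, 4), (17, 21), (35, 39)])
    accs = [r.test_accuracy for r in reps]
    assert accs[2] > accs[0]
    assert accs[2] > 0.9


class TestFeatureAnalysis:
    def test_constant_feature_swap_is_identity(self):
        feats, labels = _separable_dataset()
        feats[:, :, 4] = 2.5  # constant: its global mean equals its value
        ds = DownhillDataset(features=feats, labels=labels, window=(5, 14),
                             seed=0)
        model, _ = train_and_score(ds, MLPConfig(seed=0))
        drops = global_mean_drop(model, ds)
        assert drops[4] == 0.0

    def test_sole_informative_feature_drop_to_majority(self):
        feats, labels = _separable_dataset(seed=3)
        ds = DownhillDataset(features=feats, labels=labels, window=(5, 14),
                             seed=3)
        model, rep = train_and_score(ds, MLPConfig(seed=3))
        drops = global_mean_drop(model, ds)
        _, _, X_test, y_test = ds.frame_split()
        majority = max(np.mean(y_test == IN), np.mean(y_test == OUT))
        assert drops[2] == pytest.approx(rep.test_accuracy - majority, abs=0.06)
        assert drops[2] > 3 * np.abs(np.delete(drops, 2)).max() - 1e-12

    def test_gbdt_importances_normalised_and_concentrated(self):
        feats, labels = _separable_dataset(seed=5)
        ds = DownhillDataset(features=feats, labels=labels, window=(5, 14),
                             seed=5)
        model, _ = train_and_score(ds, GBDTConfig(n_estimators=50, seed=5))
        fi = gbdt_importances(model)
        assert fi.sum() == pytest.approx(1.0)
        assert fi[2] > 0.95  # the sole informative feature dominates

    def test_drop_analysis_is_model_agnostic(self):
        feats, labels = _separable_dataset(seed=8)
        ds = DownhillDataset(features=feats, labels=labels, window=(5, 14),
                             seed=8)
        for config in (MLPConfig(seed=8), GBDTConfig(n_estimators=30, seed=8)):
            model, _ = train_and_score(ds, config)
            drops = global_mean_drop(model, ds)
            assert np.argmax(drops) == 2


def test_dataset_packed_roundtrip(tmp_path):
    feats, labels = _separable_dataset(n_traj=12)
    ds = DownhillDataset(features=feats, labels=labels, window=(5, 14),
                         validation_ids=np.arange(10, 12), seed=4)
    ds.save(tmp_path / "ds")
    back = DownhillDataset.load(tmp_path / "ds")
    assert np.allclose(back.features, ds.features)
    assert list(back.labels) == list(ds.labels)
    assert back.window == ds.window
    # identical splits after the round trip
    a = ds.frame_split()[0]
    b = back.frame_split()[0]
    assert np.allclose(a, b)
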
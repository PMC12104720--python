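"""Folds, augmentation, early stopping, grid-search selection rules."""

import numpy as np
import pandas as pd
import pytest

import collascore as cs
from collascore.train_harness import EarlyStopper, early_stop_epoch


class TestMakeFolds:
    def test_exact_stratification_two_strata(self):
        ids = [f"c{i}" for i in range(10)]
        labels = [0] * 5 + [1] * 5
        folds = cs.make_folds(ids, labels, n_folds=5, seed=0)
        for f in range(5):
            members = [i for i in ids if folds[i] == f]
            assert len(members) == 2
            assert sorted(labels[ids.index(m)] for m in members) == [0, 1]

    def test_deterministic_for_fixed_seed(self):
        ids = [f"c{i}" for i in range(20)]
        labels = [i % 3 for i in range(20)]
        a = cs.make_folds(ids, labels, 5, seed=4)
        b = cs.make_folds(ids, labels, 5, seed=4)
        assert a == b

    def test_94_cases_5_folds_pigeonhole_sizes(self):
        ids = [f"c{i}" for i in range(94)]
        labels = [i % 4 for i in range(94)]  # grade strata
        folds = cs.make_folds(ids, labels, 5, seed=1)
        sizes = pd.Series(list(folds.values())).value_counts()
        assert set(sizes) <= {18, 19}
        # per-fold stratum proportions within one case of the global share
        df = pd.DataFrame({"fold": [folds[i] for i in ids], "label": labels})
        for lab, grp in df.groupby("label"):
            per_fold = grp["fold"].value_counts()
            assert per_fold.max() - per_fold.min() <= 1

    def test_tiny_stratum_round_robin_with_warning(self):
        ids = [f"c{i}" for i in range(12)]
        labels = [0] * 10 + [1] * 2
        with pytest.warns(UserWarning, match="round-robin"):
            folds = cs.make_folds(ids, labels, 5, seed=0)
        assert set(folds.values()) == set(range(5))


class TestAugmentPair:
    def test_identity_spec_bit_exact(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (32, 32))
        msk = rng.uniform(0, 1, (32, 32)) > 0.8
        out_img, out_msk = cs.augment_pair(img, msk, cs.AugmentSpec.identity(), seed=5)
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_msk, msk)

    def test_brightness_is_multiplicative(self):
        # collapse everything except brightness
        spec = cs.AugmentSpec(0.0, 0.2, (1.0, 1.0), 0.0, (1.0, 1.0))
        img = np.full((16, 16), 0.5)
        msk = np.zeros((16, 16), bool)
        rng = np.random.default_rng(123)
        rng.uniform(); rng.uniform()  # flips
        rng.uniform(-0.0, 0.0); rng.uniform(1.0, 1.0)  # rotation, zoom
        factor = rng.uniform(0.8, 1.2)
        out_img, _ = cs.augment_pair(img, msk, spec, seed=123)
        assert np.allclose(out_img, np.clip(0.5 * factor, 0, 1))

    def test_flip_only_is_an_involution(self):
        spec = cs.AugmentSpec(1.0, 0.0, (1.0, 1.0), 0.0, (1.0, 1.0))
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (24, 24))
        msk = rng.uniform(0, 1, (24, 24)) > 0.7
        out_img, out_msk = cs.augment_pair(img, msk, spec, seed=9)
        # flip_prob=1: both flips applied; undo them
        back = out_img[::-1, :][:, ::-1]
        assert np.array_equal(back, img)
        assert np.array_equal(out_msk[::-1, :][:, ::-1], msk)

    def test_geometry_shared_mask_stays_binary(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, (32, 32))
        msk = np.zeros((32, 32), bool)
        msk[10:20, 12:25] = True
        out_img, out_msk = cs.augment_pair(img, msk, cs.AugmentSpec(), seed=77)
        assert out_msk.dtype == bool
        assert out_img.min() >= 0 and out_img.max() <= 1

    def test_unnormalized_image_rejected(self):
        with pytest.raises(ValueError):
            cs.augment_pair(np.full((8, 8), 50.0), np.zeros((8, 8)), cs.AugmentSpec(), 0)


class TestEarlyStopping:
    def test_plateau_after_improvement_stops_at_patience(self):
        history = [0.1 + 0.02 * i for i in range(30)] + [0.5] * 40
        stop, best = early_stop_epoch(history, patience=20)
        assert stop == 50
        assert best == 30

    def test_max_epochs_cap_when_patience_never_reached(self):
        history = [0.1 * i for i in range(5)]
        stop, best = early_stop_epoch(history, patience=20)
        assert stop == 5
        assert best == 5

    def test_best_epoch_never_below_running_maximum(self):
        rng = np.random.default_rng(0)
        history = list(rng.uniform(0, 1, 60))
        _, best = early_stop_epoch(history, patience=10)
        seen = history[: best if best else len(history)]
        assert history[best - 1] == max(seen)

    def test_min_delta_requires_strict_improvement_beyond_it(self):
        stopper = EarlyStopper(patience=2, min_delta=0.05)
        assert not stopper.update(1, 0.5)
        assert not stopper.update(2, 0.54)  # within delta: stale
        assert stopper.update(3, 0.54)
        assert stopper.best_epoch == 1


@pytest.fixture(scope="module")
def two_cases():
    shape = (48, 48, 16)
    a = cs.generate_phantom(cs.PhantomSpec(grid_shape=shape, seed=21, true_ratio=0.7))
    b = cs.generate_phantom(cs.PhantomSpec(grid_shape=shape, seed=22, true_ratio=0.9))
    a.case_id, b.case_id = "train_a", "val_b"
    return a, b


class TestTrainOne:

    def test_leakage_rejected(self, two_cases):
        a, _ = two_cases
        model = cs.build_model(cs.ModelConfig.scaled(), seed=0)
        cfg = cs.TrainConfig(max_epochs=2, patience_epochs=1, seed=0)
        with pytest.raises(ValueError, match="leakage"):
            cs.train_one(model, cs.slice_dataset([a]), [a], cfg)

    def test_empty_validation_rejected(self, two_cases):
        a, _ = two_cases
        model = cs.build_model(cs.ModelConfig.scaled(), seed=0)
        cfg = cs.TrainConfig(max_epochs=2, patience_epochs=1, seed=0)
        with pytest.raises(ValueError, match="empty"):
            cs.train_one(model, cs.slice_dataset([a]), [], cfg)

    def test_short_run_history_and_determinism(self, two_cases):
        a, b = two_cases
        slices = cs.slice_dataset([a])[:6]
        cfg = cs.TrainConfig(
            learning_rate=1e-2, batch_size=4, max_epochs=3, patience_epochs=2,
            augmentation=cs.AugmentSpec.identity(), seed=0,
        )
        m1 = cs.build_model(cs.ModelConfig.scaled(), seed=0)
        m1, h1 = cs.train_one(m1, slices, [b], cfg)
        m2 = cs.build_model(cs.ModelConfig.scaled(), seed=0)
        m2, h2 = cs.train_one(m2, slices, [b], cfg)
        assert list(h1.columns) == ["epoch", "train_loss", "val_dsc"]
        assert len(h1) == 3
        pd.testing.assert_frame_equal(h1, h2)
        assert h1.attrs["best_val_dsc"] == h1["val_dsc"].max()


class TestGridSearchSelectionRules:
    """The argmax / tie-break rules, exercised on constructed histories via a
    stubbed trainer."""

    @pytest.fixture()
    def stubbed(self, monkeypatch):
        import collascore.train_harness as th

        outcomes = {}

        def fake_train_one(model, slices, val_cases, cfg):
            key = (cfg.learning_rate, cfg.batch_size)
            fold_scores = outcomes[key]
            fold = fake_train_one.calls.setdefault(key, 0)
            fake_train_one.calls[key] = fold + 1
            hist = pd.DataFrame(
                {"epoch": [1], "train_loss": [1.0], "val_dsc": [fold_scores[fold]]}
            )
            hist.attrs["best_epoch"] = 1
            hist.attrs["best_val_dsc"] = fold_scores[fold]
            return model, hist

        fake_train_one.calls = {}
        monkeypatch.setattr(th, "train_one", fake_train_one)
        return outcomes

    @staticmethod
    def _mini_cases():
        shape = (48, 48, 16)
        cases = []
        for i, r in enumerate((0.3, 0.6, 0.8, 1.0)):
            c = cs.generate_phantom(cs.PhantomSpec(grid_shape=shape, seed=30 + i, true_ratio=r))
            c.case_id = f"g{i}"
            cases.append(c)
        return cases

    def test_selected_fold_is_argmax_within_winning_cell(self, stubbed):
        stubbed[(1e-3, 8)] = [0.6, 0.8]
        cases = self._mini_cases()
        cfg = cs.TrainConfig(max_epochs=2, patience_epochs=1, n_folds=2, seed=0)
        model, report = cs.grid_search_cv(
            cases, cs.ModelConfig.scaled(), cfg, grid=((1e-3, 8),), labels=[0, 1, 0, 1]
        )
        assert report.selected_fold == 1
        assert report.winning_mean_dsc == pytest.approx(0.7)

    def test_mean_tie_broken_by_smaller_lr_then_batch(self, stubbed):
        stubbed[(1e-3, 8)] = [0.7, 0.7]
        stubbed[(1e-4, 16)] = [0.6, 0.8]
        stubbed[(1e-4, 8)] = [0.8, 0.6]
        cases = self._mini_cases()
        cfg = cs.TrainConfig(max_epochs=2, patience_epochs=1, n_folds=2, seed=0)
        _, report = cs.grid_search_cv(
            cases,
            cs.ModelConfig.scaled(),
            cfg,
            grid=((1e-3, 8), (1e-4, 16), (1e-4, 8)),
            labels=[0, 1, 0, 1],
        )
        assert report.winning_cell == (1e-4, 8)

    def test_winning_mean_recomputable_from_report(self, stubbed):
        stubbed[(1e-3, 8)] = [0.55, 0.85]
        cases = self._mini_cases()
        cfg = cs.TrainConfig(max_epochs=2, patience_epochs=1, n_folds=2, seed=0)
        _, report = cs.grid_search_cv(
            cases, cs.ModelConfig.scaled(), cfg, grid=((1e-3, 8),), labels=[0, 1, 0, 1]
        )
        ok = report.table[~report.table["failed"]]
        assert report.winning_mean_dsc == pytest.approx(ok["best_val_dsc"].mean())
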
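"""Training-set construction, the ensemble regressor, bank selection and the
illuminant mismatch experiment."""

import numpy as np
import pytest

from specalib import (
    BankEntry,
    ConfigurationError,
    ExperimentDesign,
    IlluminantSpectrum,
    LabeledSpectra,
    NoiseModel,
    RegressorBank,
    TissueRanges,
    build_training_set,
    evaluate_oxygenation,
    run_illuminant_mismatch_experiment,
    sample_tissue,
    select_regressor,
    train_regressor,
)
from specalib.oxygenation import OxygenationRegressor


@pytest.fixture(scope="session")
def band_pair(grid, camera, band_truths):
    return (
        IlluminantSpectrum(band_truths["ls1_xenon"], normalized=True),
        IlluminantSpectrum(band_truths["ls3_fluorescent"], normalized=True),
    )


class TestBuildTrainingSet:
    def test_same_samples_share_labels_across_illuminants(self, grid, camera, band_pair, chromophores):
        samples = sample_tissue(50, 0)
        a = build_training_set(samples, band_pair[0], grid, camera, NoiseModel(0.1), 1, table=chromophores)
        b = build_training_set(samples, band_pair[1], grid, camera, NoiseModel(0.1), 2, table=chromophores)
        np.testing.assert_array_equal(a.y, b.y)
        assert not np.allclose(a.X, b.X)

    def test_identical_illuminants_and_seed_give_identical_features(self, grid, camera, band_pair, chromophores):
        samples = sample_tissue(30, 0)
        a = build_training_set(samples, band_pair[0], grid, camera, NoiseModel(0.1), 7, table=chromophores)
        b = build_training_set(samples, band_pair[0], grid, camera, NoiseModel(0.1), 7, table=chromophores)
        np.testing.assert_array_equal(a.X, b.X)

    def test_gain_randomization_cancels_under_normalization(self, grid, camera, band_pair, chromophores):
        samples = sample_tissue(30, 0)
        narrow = build_training_set(
            samples, band_pair[0], grid, camera, NoiseModel(0.0), 3,
            table=chromophores, alpha_range=(1.0, 1.0),
        )
        wide = build_training_set(
            samples, band_pair[0], grid, camera, NoiseModel(0.0), 4,
            table=chromophores, alpha_range=(0.01, 100.0),
        )
        np.testing.assert_allclose(narrow.X, wide.X, atol=1e-12)

    def test_rows_are_normalized(self, grid, camera, band_pair, chromophores):
        ts = build_training_set(
            sample_tissue(20, 5), band_pair[1], grid, camera, NoiseModel(0.1), 6,
            table=chromophores,
        )
        np.testing.assert_allclose(ts.X.sum(axis=1), 1.0, atol=1e-12)


class TestRegressor:
    def test_constant_labels_predict_constant(self):
        X = np.random.default_rng(0).dirichlet(np.ones(6), size=200)
        train = LabeledSpectra(X=X, y=np.full(200, 0.7))
        reg = train_regressor(train, n_estimators=20)
        np.testing.assert_allclose(reg.predict(X[:10]), 0.7, atol=1e-12)

    def test_deterministic_for_fixed_seed(self):
        r = np.random.default_rng(1)
        X = r.dirichlet(np.ones(6), size=300)
        y = np.clip(X[:, 0] * 2, 0, 1)
        train = LabeledSpectra(X=X, y=y)
        p1 = train_regressor(train, n_estimators=20, seed=3).predict(X[:20])
        p2 = train_regressor(train, n_estimators=20, seed=3).predict(X[:20])
        np.testing.assert_array_equal(p1, p2)

    def test_too_few_rows_rejected(self):
        X = np.full((10, 4), 0.25)
        with pytest.raises(ConfigurationError):
            train_regressor(LabeledSpectra(X=X, y=np.zeros(10)))

    def test_predictions_clipped_to_unit_interval(self):
        r = np.random.default_rng(2)
        X = r.dirichlet(np.ones(4), size=150)
        train = LabeledSpectra(X=X, y=np.clip(4 * X[:, 0], 0, 1))
        reg = train_regressor(train, n_estimators=10)
        p = reg.predict(r.dirichlet(np.ones(4), size=50))
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_single_layer_noiseless_recovery(self, grid, camera, chromophores, band_pair):
        """Thick first layer, no noise: oxygenation is recoverable to a few pp."""
        ranges = TissueRanges(thickness_um=(1800.0, 2000.0))
        samples = sample_tissue(2000, 42, ranges)
        test_samples = sample_tissue(500, 43, ranges)
        train = build_training_set(
            samples, band_pair[0], grid, camera, NoiseModel(0.0), 44, table=chromophores
        )
        test = build_training_set(
            test_samples, band_pair[0], grid, camera, NoiseModel(0.0), 45, table=chromophores
        )
        reg = train_regressor(train, seed=46)
        assert evaluate_oxygenation(reg, test) < 5.0


class _ConstantRegressor(OxygenationRegressor):
    def __init__(self, value):
        self._value = value

    def predict(self, X):
        return np.full(len(X), self._value)


class TestEvaluate:
    def test_perfect_predictions_zero_error(self):
        X = np.full((50, 4), 0.25)
        test = LabeledSpectra(X=X, y=np.full(50, 0.3))
        assert evaluate_oxygenation(_ConstantRegressor(0.3), test) == 0.0

    def test_constant_half_against_uniform_labels(self):
        r = np.random.default_rng(0)
        n = 5000
        test = LabeledSpectra(X=np.full((n, 4), 0.25), y=r.uniform(0, 1, n))
        mae = evaluate_oxygenation(_ConstantRegressor(0.5), test)
        se = 100 * np.std(np.abs(test.y - 0.5)) / np.sqrt(n)
        assert mae == pytest.approx(25.0, abs=3 * se + 0.5)

    def test_row_order_invariance(self):
        r = np.random.default_rng(3)
        X = r.dirichlet(np.ones(4), size=100)
        y = r.uniform(0, 1, 100)
        perm = r.permutation(100)
        a = evaluate_oxygenation(_ConstantRegressor(0.4), LabeledSpectra(X=X, y=y))
        b = evaluate_oxygenation(
            _ConstantRegressor(0.4), LabeledSpectra(X=X[perm], y=y[perm])
        )
        assert a == pytest.approx(b)


class TestSelectRegressor:
    def _bank(self, spectra_ids):
        entries = tuple(
            BankEntry(i, IlluminantSpectrum.from_values(v), _ConstantRegressor(0.5))
            for i, v in spectra_ids
        )
        return RegressorBank(entries)

    def test_exact_match_selected(self):
        bank = self._bank([("a", [1, 0, 0]), ("b", [0, 1, 0])])
        est = IlluminantSpectrum.from_values([0, 1, 0])
        assert select_regressor(bank, est).illuminant_id == "b"

    def test_nearest_by_angle_selected(self):
        bank = self._bank([("a", [1.0, 0.9]), ("b", [1.0, 0.2])])
        est = IlluminantSpectrum.from_values([1.0, 0.85])
        assert select_regressor(bank, est).illuminant_id == "a"

    def test_tie_resolves_to_lowest_id(self):
        bank = self._bank([("b", [1, 0]), ("a", [0, 1])])
        est = IlluminantSpectrum.from_values([1, 1])
        assert select_regressor(bank, est).illuminant_id == "a"

    def test_empty_bank_rejected(self):
        with pytest.raises(ConfigurationError):
            select_regressor(RegressorBank(()), IlluminantSpectrum.from_values([1, 1]))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ConfigurationError):
            self._bank([("a", [1, 0]), ("a", [0, 1])])


class TestBankSerialization:
    def test_roundtrip_preserves_spectra_and_predictions(
        self, grid, camera, band_truths, tmp_path, chromophores
    ):
        from specalib import load_bank, save_bank, train_bank

        bands = {
            k: IlluminantSpectrum(band_truths[k], normalized=True)
            for k in ("ls1_xenon", "ls3_fluorescent")
        }
        bank = train_bank(
            bands, grid, camera, n_train=300, seed=4, table=chromophores,
            n_estimators=10,
        )
        save_bank(bank, tmp_path / "bank")
        loaded = load_bank(tmp_path / "bank")
        assert [e.illuminant_id for e in loaded.entries] == [
            e.illuminant_id for e in bank.entries
        ]
        X = np.random.default_rng(0).dirichlet(np.ones(16), size=20)
        for orig, back in zip(bank.entries, loaded.entries):
            np.testing.assert_allclose(orig.spectrum.values, back.spectrum.values)
            np.testing.assert_array_equal(orig.regressor.predict(X), back.regressor.predict(X))
        est = IlluminantSpectrum(band_truths["ls3_fluorescent"], normalized=True)
        assert select_regressor(loaded, est).illuminant_id == "ls3_fluorescent"


@pytest.fixture(scope="module")
def small_experiment(grid, camera, band_truths):
    bands = {
        k: IlluminantSpectrum(band_truths[k], normalized=True)
        for k in ("ls1_xenon", "ls2_halogen", "ls3_fluorescent")
    }
    perfect = tuple((k, bands[k]) for k in bands)
    design = ExperimentDesign(
        illuminants=bands, estimates=perfect, n_train=600, n_test=200,
        seed=5, n_estimators=30,
    )
    return design, run_illuminant_mismatch_experiment(design, grid=grid, camera=camera)


class TestMismatchExperiment:
    def test_perfect_estimates_collapse_to_matched(self, small_experiment):
        """When the calibration estimate equals the true illuminant, the
        calibrated condition reproduces the matched condition exactly."""
        _, result = small_experiment
        t = result.table
        for ls in t.test_ls.unique():
            matched = t[(t.test_ls == ls) & (t.condition == "matched")].mae_pp.iloc[0]
            calibrated = t[(t.test_ls == ls) & (t.condition == "calibrated")].mae_pp.iloc[0]
            assert calibrated == pytest.approx(matched, abs=1e-12)

    def test_matched_beats_strongly_mismatched_pairs(self, small_experiment, band_truths):
        from specalib import angular_error

        _, result = small_experiment
        t = result.table
        for ls_a in t.test_ls.unique():
            matched = t[(t.test_ls == ls_a) & (t.condition == "matched")].mae_pp.iloc[0]
            for _, row in t[(t.test_ls == ls_a) & (t.condition == "mismatched")].iterrows():
                if angular_error(band_truths[ls_a], band_truths[row.train_ls]) > 5.0:
                    assert matched < row.mae_pp

    def test_summary_fields_present(self, small_experiment):
        _, result = small_experiment
        s = result.summary
        assert {"matched_mean_pp", "mismatched_mean_pp", "calibrated_mean_pp"} <= set(s)
        assert "mean_reduction_pct" in s

    def test_single_illuminant_design_degenerates(self, grid, camera, band_truths):
        bands = {"ls1_xenon": IlluminantSpectrum(band_truths["ls1_xenon"], normalized=True)}
        design = ExperimentDesign(
            illuminants=bands,
            estimates=(("ls1_xenon", bands["ls1_xenon"]),),
            n_train=300, n_test=100, seed=1, n_estimators=10,
        )
        result = run_illuminant_mismatch_experiment(design, grid=grid, camera=camera)
        conditions = set(result.table.condition)
        assert conditions == {"matched", "calibrated"}

    def test_noise_degrades_matched_accuracy(self, grid, camera, band_truths):
        maes = []
        for sigma in (0.0, 0.3):
            bands = {"ls1_xenon": IlluminantSpectrum(band_truths["ls1_xenon"], normalized=True)}
            design = ExperimentDesign(
                illuminants=bands, n_train=800, n_test=300, seed=2,
                noise=NoiseModel(sigma), n_estimators=30,
            )
            result = run_illuminant_mismatch_experiment(design, grid=grid, camera=camera)
            maes.append(result.summary["matched_mean_pp"])
        assert maes[0] < maes[1]
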
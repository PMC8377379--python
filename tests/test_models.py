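import numpy as np
import pytest

import epiforest as ef
from epiforest.models import DEFAULT_THRESHOLDS, FUSION_ORDER
from epiforest.selection import SelectionMask


def gaussian_fm(n_per_class, d=20, shift=3.0, seed=0, encoding="AFC"):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(2 * n_per_class, d))
    values[:n_per_class] += shift
    labels = np.array([1] * n_per_class + [0] * n_per_class)
    return ef.FeatureMatrix(
        encoding=encoding,
        values=values,
        columns=tuple(f"f{j}" for j in range(d)),
        ids=tuple(f"p{i}" for i in range(2 * n_per_class)),
        labels=labels,
    )


def full_mask(fm):
    return SelectionMask(encoding=fm.encoding, indices=tuple(range(fm.d)), k=fm.d)


class TestTrainRf:
    def test_separated_clouds_training_auc(self):
        fm = gaussian_fm(200, seed=1)
        model = ef.train_rf(fm, full_mask(fm), ef.RfConfig(n_trees=100, seed=0))
        scores = model.scores(fm.values)
        assert ef.roc_auc(scores, fm.labels)[2] >= 0.99

    def test_permuted_labels_oof_auc_near_half(self):
        rng = np.random.default_rng(2)
        fm = gaussian_fm(200, shift=3.0, seed=2)
        permuted = rng.permutation(fm.labels)
        fm_null = ef.FeatureMatrix(
            encoding=fm.encoding, values=fm.values, columns=fm.columns,
            ids=fm.ids, labels=permuted,
        )
        oof = ef.oof_scores(fm_null, full_mask(fm), ef.RfConfig(n_trees=100, seed=0),
                            folds=5, fold_seed=3)
        auc = ef.roc_auc(oof, permuted)[2]
        assert 0.40 <= auc <= 0.60

    def test_same_seed_bitwise_identical(self):
        fm = gaussian_fm(50, seed=3)
        cfg = ef.RfConfig(n_trees=50, seed=7)
        s1 = ef.train_rf(fm, full_mask(fm), cfg).scores(fm.values)
        s2 = ef.train_rf(fm, full_mask(fm), cfg).scores(fm.values)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_rejected(self):
        fm = gaussian_fm(10, seed=4)
        bad = ef.FeatureMatrix(
            encoding=fm.encoding, values=fm.values, columns=fm.columns,
            ids=fm.ids, labels=np.ones(20, dtype=int),
        )
        with pytest.raises(ValueError, match="class"):
            ef.train_rf(bad, full_mask(fm), ef.RfConfig(n_trees=10))

    def test_scores_are_vote_fractions(self):
        fm = gaussian_fm(30, seed=5)
        cfg = ef.RfConfig(n_trees=40, seed=0)
        model = ef.train_rf(fm, full_mask(fm), cfg)
        s = model.scores(fm.values)
        # vote fractions are multiples of 1/n_trees in [0, 1]
        assert np.allclose(s * cfg.n_trees, np.round(s * cfg.n_trees))
        assert s.min() >= 0.0 and s.max() <= 1.0


class TestOofScores:
    def test_every_example_scored_once(self):
        fm = gaussian_fm(40, seed=6)
        oof = ef.oof_scores(fm, full_mask(fm), ef.RfConfig(n_trees=20), folds=5,
                            fold_seed=1)
        assert oof.shape == (80,) and np.isfinite(oof).all()

    def test_folds_stratified_and_reproducible(self):
        from epiforest.models import stratified_folds

        labels = np.array([1] * 33 + [0] * 47)
        folds_a = stratified_folds(labels, 10, 5)
        folds_b = stratified_folds(labels, 10, 5)
        for (_, ta), (_, tb) in zip(folds_a, folds_b):
            np.testing.assert_array_equal(ta, tb)
        for _, te in folds_a:
            n_pos = labels[te].sum()
            assert abs(n_pos - 3.3) <= 1  # class ratio within one example
        covered = np.concatenate([te for _, te in folds_a])
        assert sorted(covered) == list(range(80))

    def test_oof_auc_consistent_with_holdout(self):
        fm = gaussian_fm(250, d=10, shift=1.0, seed=7)
        holdout = gaussian_fm(250, d=10, shift=1.0, seed=8)
        cfg = ef.RfConfig(n_trees=100, seed=0)
        oof = ef.oof_scores(fm, full_mask(fm), cfg, folds=5, fold_seed=2)
        oof_auc = ef.roc_auc(oof, fm.labels)[2]
        model = ef.train_rf(fm, full_mask(fm), cfg)
        held_auc = ef.roc_auc(model.scores(holdout.values), holdout.labels)[2]
        assert abs(oof_auc - held_auc) <= 0.05


class TestFitFusion:
    BETAS = np.array([0.435, 0.102, 1.337, 0.465])  # PSSM, AIP, PKAF, AFC

    def test_parameter_recovery(self):
        scores, labels = ef.simulate_fusion_scores(
            50_000, self.BETAS, alpha=-1.0, seed=42
        )
        model = ef.fit_fusion(scores, labels)
        np.testing.assert_allclose(model.betas, self.BETAS, atol=0.10)
        assert abs(model.alpha - (-1.0)) <= 0.10

    def test_null_scores_give_small_betas(self):
        rng = np.random.default_rng(9)
        scores = rng.uniform(size=(50_000, 4))
        labels = rng.integers(0, 2, size=50_000)
        model = ef.fit_fusion(scores, labels)
        assert np.abs(model.betas).max() <= 0.1

    def test_duplicated_column_terminates_and_is_stable(self):
        scores, labels = ef.simulate_fusion_scores(2_000, self.BETAS, -1.0, seed=1)
        dup = scores.copy()
        dup[:, 1] = dup[:, 0]
        m1 = ef.fit_fusion(dup, labels)
        swapped = dup[:, [1, 0, 2, 3]]  # identical data, columns swapped
        m2 = ef.fit_fusion(swapped, labels)
        p1 = ef.predict_fusion(m1, dup)
        p2 = ef.predict_fusion(m2, swapped)
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_separable_scores_fall_back_to_ridge(self):
        labels = np.array([0] * 50 + [1] * 50)
        scores = np.column_stack(
            [labels * 0.8 + 0.1, np.full(100, 0.5), np.full(100, 0.5), np.full(100, 0.5)]
        )
        with pytest.warns(RuntimeWarning, match="separation"):
            model = ef.fit_fusion(scores, labels)
        assert np.isfinite(model.betas).all() and np.isfinite(model.alpha)

    def test_matches_glm_oracle(self):
        import statsmodels.api as sm

        scores, labels = ef.simulate_fusion_scores(5_000, self.BETAS, -1.0, seed=3)
        model = ef.fit_fusion(scores, labels)
        glm = sm.GLM(
            labels, sm.add_constant(scores), family=sm.families.Binomial()
        ).fit()
        np.testing.assert_allclose(model.alpha, glm.params[0], atol=1e-5)
        np.testing.assert_allclose(model.betas, glm.params[1:], atol=1e-5)


class TestPredictFusion:
    def test_zero_model_gives_half(self):
        model = ef.FusionModel(betas=np.zeros(4), alpha=0.0)
        assert ef.predict_fusion(model, np.array([0.1, 0.9, 0.4, 0.7])) == 0.5

    def test_logit_ln3_gives_three_quarters(self):
        model = ef.FusionModel(betas=np.array([np.log(3), 0, 0, 0]), alpha=0.0)
        assert ef.predict_fusion(model, np.array([1.0, 0, 0, 0])) == pytest.approx(0.75)

    def test_closed_form_evaluation(self):
        model = ef.FusionModel(
            betas=np.array([0.435, 0.102, 1.337, 0.465]), alpha=-1.5
        )
        p = ef.predict_fusion(model, np.ones(4))
        assert p == pytest.approx(1 / (1 + np.exp(-0.839)), abs=1e-9)
        assert p == pytest.approx(0.6983, abs=2e-4)

    def test_strictly_increasing_in_positive_beta_scores(self):
        model = ef.FusionModel(betas=np.array([0.5, 0.1, 1.0, 0.4]), alpha=-1.0)
        rng = np.random.default_rng(10)
        base = rng.uniform(size=4)
        p0 = ef.predict_fusion(model, base)
        for j in range(4):
            bumped = base.copy()
            bumped[j] = min(bumped[j] + 0.1, 1.0)
            assert ef.predict_fusion(model, bumped) > p0 or bumped[j] == base[j]

    def test_out_of_range_scores_rejected(self):
        model = ef.FusionModel(betas=np.zeros(4), alpha=0.0)
        with pytest.raises(ValueError):
            ef.predict_fusion(model, np.array([0.2, 0.4, 1.4, 0.0]))


class TestClassifyAndThresholds:
    def test_tier_calls_at_default_thresholds(self):
        model = ef.FusionModel(betas=np.zeros(4), alpha=0.0)
        assert not ef.classify(0.45, "high", model)
        assert ef.classify(0.45, "moderate", model)
        assert ef.classify(0.45, "low", model)
        assert all(ef.classify(1.0, t, model) for t in ("high", "moderate", "low"))

    def test_threshold_tie_is_positive(self):
        model = ef.FusionModel(betas=np.zeros(4), alpha=0.0)
        for tier, t in DEFAULT_THRESHOLDS.items():
            assert ef.classify(t, tier, model)

    def test_unknown_tier_rejected(self):
        model = ef.FusionModel(betas=np.zeros(4), alpha=0.0)
        with pytest.raises(ValueError, match="tier"):
            ef.classify(0.5, "extreme", model)

    def test_tier_monotonicity(self):
        model = ef.FusionModel(betas=np.zeros(4), alpha=0.0)
        p = np.linspace(0, 1, 101)
        high = ef.classify(p, "high", model)
        mod = ef.classify(p, "moderate", model)
        low = ef.classify(p, "low", model)
        assert (~high | mod).all() and (~mod | low).all()

    def test_calibration_counting_oracle(self):
        neg_scores = np.arange(0.05, 1.0, 0.10)  # 0.05, 0.15, ..., 0.95
        pos_scores = np.full(5, 0.99)
        p = np.concatenate([pos_scores, neg_scores])
        y = np.array([1] * 5 + [0] * 10)
        thresholds = ef.calibrate_thresholds(p, y, target_sp=(0.9, 0.8, 0.5))
        # Sp 0.8 needs 8 negatives below: just above the 8th smallest (0.75)
        assert thresholds["moderate"] > 0.75
        assert thresholds["moderate"] <= 0.7500001
        sp = ((neg_scores < thresholds["moderate"]).mean())
        assert sp >= 0.8

    def test_raising_target_never_lowers_threshold(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=200)
        y = rng.integers(0, 2, size=200)
        t1 = ef.calibrate_thresholds(p, y, target_sp=(0.9, 0.6, 0.3))
        t2 = ef.calibrate_thresholds(p, y, target_sp=(0.95, 0.7, 0.4))
        for tier in ("high", "moderate", "low"):
            assert t2[tier] >= t1[tier]

    def test_perfect_scores_keep_strict_ordering(self):
        y = np.array([1] * 20 + [0] * 20)
        p = y.astype(float) * 0.98 + 0.01
        t = ef.calibrate_thresholds(p, y)
        assert t["high"] > t["moderate"] > t["low"] > 0

    def test_unattainable_target_errors(self):
        y = np.array([1] * 5 + [0] * 5)
        p = np.array([1.0] * 10)  # negatives all at the ceiling
        with pytest.raises(ValueError, match="unattainable"):
            ef.calibrate_thresholds(p, y, target_sp=(0.9, 0.5, 0.2))


class TestFullPipeline:
    def test_fused_oof_auc_beats_singles(self, small_fixture):
        ds, profiles, _ = small_fixture
        pred = ef.train_predictor(
            ds, profiles, cfg=ef.RfConfig(n_trees=60, seed=2), folds=5
        )
        rep = ef.oof_report(pred)
        fused = float(rep.loc[rep.method == "fused", "AUC"].iloc[0])
        singles = rep.loc[rep.method != "fused", "AUC"]
        assert (fused >= singles - 0.02).all()

    def test_retraining_reproduces_scores_bitwise(self, small_fixture):
        ds, profiles, _ = small_fixture
        kw = dict(cfg=ef.RfConfig(n_trees=30, seed=4), folds=5)
        p1 = ef.train_predictor(ds, profiles, **kw)
        p2 = ef.train_predictor(ds, profiles, **kw)
        np.testing.assert_array_equal(p1.report.fused_p, p2.report.fused_p)
        for enc in FUSION_ORDER:
            np.testing.assert_array_equal(
                p1.report.oof_scores[enc], p2.report.oof_scores[enc]
            )
        np.testing.assert_array_equal(p1.fusion.betas, p2.fusion.betas)

    def test_no_signal_data_gives_null_auc(self):
        # n large enough that the fusion layer's in-sample optimism
        # (5 fitted parameters) cannot lift a pure-noise AUC past the band
        cfg = ef.SimulationConfig(n_pos=200, n_neg=200, effect_size=0.0, seed=13)
        ds = ef.generate_peptides(cfg)
        profiles = ef.generate_profiles(ds, cfg)
        pred = ef.train_predictor(
            ds, profiles, cfg=ef.RfConfig(n_trees=60, seed=1), folds=5,
            calibrate=False,
        )
        auc = ef.roc_auc(pred.report.fused_p, pred.report.labels)[2]
        assert 0.40 <= auc <= 0.60

    def test_sequential_concatenation_width(self, small_fixture):
        ds, profiles, _ = small_fixture
        seq = ef.train_sequential(
            ds, profiles, cfg=ef.RfConfig(n_trees=20, seed=0), top_k=50, folds=5
        )
        assert len(seq.columns) == 800 + 192 + 480 + 800  # 2272
        assert seq.columns[0].startswith("afc.")
        assert seq.model.mask.k == 50

    def test_archive_round_trip(self, small_fixture, tmp_path):
        ds, profiles, _ = small_fixture
        pred = ef.train_predictor(
            ds, profiles, cfg=ef.RfConfig(n_trees=30, seed=6), folds=5
        )
        pred.save(tmp_path / "model")
        back = ef.EpitopePredictor.load(tmp_path / "model")
        np.testing.assert_array_equal(back.fusion.betas, pred.fusion.betas)
        assert back.fusion.thresholds == pred.fusion.thresholds
        df_a = pred.predict(ds, profiles)
        df_b = back.predict(ds, profiles)
        np.testing.assert_array_equal(df_a["P"].values, df_b["P"].values)

    def test_archive_version_mismatch_rejected(self, small_fixture, tmp_path):
        import json

        ds, profiles, _ = small_fixture
        pred = ef.train_predictor(
            ds, profiles, cfg=ef.RfConfig(n_trees=10, seed=6), folds=3
        )
        pred.save(tmp_path / "model")
        manifest = json.loads((tmp_path / "model" / "manifest.json").read_text())
        manifest["format_version"] = 99
        (tmp_path / "model" / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(ValueError, match="version"):
            ef.EpitopePredictor.load(tmp_path / "model")
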
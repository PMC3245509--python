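"""Training, scoring, smoothing, combination and region extraction."""

import numpy as np
import pytest

import flexmotion as fm
from flexmotion.dataset import ClassStats
from flexmotion.features import N_PAIRS
from flexmotion.predictor import PredictionResult


def _stats(cells):
    return ClassStats(stats=cells, counts={k: 10 for k in cells})


class TestClassToScore:
    def test_published_worked_example(self):
        stats = _stats({("CS", "flexible"): (-0.248, 0.919)})
        assert fm.class_to_score(stats, "CS", "flexible", z=3) == pytest.approx(
            2.509
        )

    def test_z_zero_returns_cell_average(self):
        stats = _stats({("PS", "rigid"): (-0.7, 0.3)})
        assert fm.class_to_score(stats, "PS", "rigid") == pytest.approx(-0.7)

    def test_zero_sd_cell(self):
        stats = _stats({("RS", "flexible"): (1.2, 0.0)})
        for z in (0, 1, 3):
            assert fm.class_to_score(stats, "RS", "flexible", z) == 1.2

    def test_missing_cell_raises(self):
        with pytest.raises(KeyError):
            fm.class_to_score(_stats({}), "CS", "flexible")


def _separable_training_set(seed=0, n_per_cell=30, p=920):
    """Class is a deterministic function of variable 0."""
    rng = np.random.default_rng(seed)
    xs, cats, clss = [], [], []
    for cat in ("CS", "PS", "RS"):
        for cls, val in [("flexible", 2), ("rigid", 0)]:
            x = rng.integers(0, 3, size=(n_per_cell, p))
            x[:, 0] = val
            xs.append(x)
            cats.extend([cat] * n_per_cell)
            clss.extend([cls] * n_per_cell)
    stats = _stats(
        {(c, "flexible"): (2.0, 0.5) for c in ("CS", "PS", "RS")}
        | {(c, "rigid"): (-1.0, 0.2) for c in ("CS", "PS", "RS")}
    )
    seqs = [fm.dataset.AMINO_ACIDS]
    grps = [np.array(["normal_mob"] * 20)]
    table = fm.build_feature_table(fm.compute_mobility_propensity(seqs, grps))
    return (
        np.concatenate(xs),
        np.array(cats),
        np.array(clss),
        stats,
        table,
    )


class TestTrainMotionModel:
    def test_separable_corpus_trains_perfectly(self):
        x, cats, clss, stats, table = _separable_training_set()
        model = fm.train_motion_model(
            x, cats, clss, "internal", stats, table,
            config=fm.TrainConfig(seed=3, ntree=50),
        )
        for cat in ("CS", "PS", "RS"):
            sel = cats == cat
            assert (model.classifiers[cat].predict(x[sel]) == clss[sel]).all()

    def test_separable_variable_ranks_first(self):
        x, cats, clss, stats, table = _separable_training_set()
        model = fm.train_motion_model(
            x, cats, clss, "internal", stats, table,
            config=fm.TrainConfig(seed=3, ntree=50),
        )
        ranked = fm.variable_importance(model, top_k=1)
        assert ranked[0][0] == model.variable_names[0]
        all_imp = fm.variable_importance(model)
        assert all(np.isfinite(v) and v >= 0 for _, v in all_imp)

    def test_determinism_under_fixed_seed(self):
        x, cats, clss, stats, table = _separable_training_set()
        cfg = fm.TrainConfig(seed=11, ntree=50)
        m1 = fm.train_motion_model(x, cats, clss, "internal", stats, table, config=cfg)
        m2 = fm.train_motion_model(x, cats, clss, "internal", stats, table, config=cfg)
        for cat in ("CS", "PS", "RS"):
            assert (
                m1.classifiers[cat].predict(x) == m2.classifiers[cat].predict(x)
            ).all()

    def test_missing_class_coverage_raises(self):
        x, cats, clss, stats, table = _separable_training_set(n_per_cell=30)
        clss[:] = "flexible"  # only one class everywhere
        with pytest.raises(ValueError, match="fewer than 2 classes"):
            fm.train_motion_model(x, cats, clss, "internal", stats, table)

    def test_external_split_filters_flexible_runs(self):
        x, cats, clss, stats, table = _separable_training_set(n_per_cell=40)
        rng = np.random.default_rng(5)
        runs = np.where(
            clss == "flexible", rng.choice([4, 12], size=len(clss)), 0
        )
        short = fm.train_motion_model(
            x, cats, clss, "external_short", stats, table,
            config=fm.TrainConfig(seed=1, ntree=20), run_lengths=runs,
        )
        long = fm.train_motion_model(
            x, cats, clss, "external_long", stats, table,
            config=fm.TrainConfig(seed=1, ntree=20), run_lengths=runs,
        )
        assert short.motion_type == "external_short"
        assert long.motion_type == "external_long"
        with pytest.raises(ValueError, match="run_lengths"):
            fm.train_motion_model(
                x, cats, clss, "external_short", stats, table
            )


class TestSmoothScores:
    def test_constant_unchanged(self):
        x = np.full(10, 2.5)
        np.testing.assert_allclose(fm.smooth_scores(x), x)

    def test_center_spike(self):
        out = fm.smooth_scores(np.array([0.0, 0, 5, 0, 0]), window=5)
        assert out[2] == pytest.approx(1.0)

    def test_masked_residues_excluded(self):
        x = np.array([1.0, 1.0, 100.0, 1.0, 1.0])
        mask = np.array([True, True, False, True, True])
        out = fm.smooth_scores(x, window=5, mask=mask)
        np.testing.assert_allclose(out[[0, 1, 3, 4]], 1.0)
        assert np.isnan(out[2])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            fm.smooth_scores(np.zeros(5), window=4)

    def test_smoothed_within_window_envelope(self, corpus16, internal_model):
        chain = corpus16.chains[1]
        res = fm.predict_profile(chain.annotated, internal_model)
        valid = np.nonzero(res.mask)[0]
        for i in valid:
            lo, hi = max(0, i - 2), min(len(res), i + 3)
            window = res.raw[lo:hi][res.mask[lo:hi]]
            assert window.min() - 1e-12 <= res.smoothed[i] <= window.max() + 1e-12


def _result(classes, scores=None, model_id="m"):
    n = len(classes)
    scores = np.arange(n, dtype=float) if scores is None else np.asarray(scores, float)
    return PredictionResult(
        residue_ids=np.arange(1, n + 1),
        categories=np.full(n, "PS"),
        classes=np.asarray(classes, dtype="U12"),
        raw=scores,
        smoothed=scores.copy(),
        mask=np.ones(n, bool),
        model_id=model_id,
    )


class TestCombineExternal:
    def test_no_long_run_is_noop(self):
        short = _result(["intermediate"] * 15)
        long = _result(["flexible"] * 8 + ["intermediate"] * 7)
        out = fm.combine_external(short, long)
        np.testing.assert_array_equal(out.raw, short.raw)
        np.testing.assert_array_equal(out.classes, short.classes)

    def test_long_run_overrides(self):
        short = _result(["intermediate"] * 20, np.zeros(20))
        long = _result(
            ["intermediate"] * 4 + ["flexible"] * 12 + ["intermediate"] * 4,
            np.full(20, 3.0),
        )
        out = fm.combine_external(short, long)
        np.testing.assert_allclose(out.raw[4:16], 3.0)
        np.testing.assert_allclose(out.raw[:4], 0.0)
        np.testing.assert_allclose(out.raw[16:], 0.0)

    def test_idempotent(self):
        short = _result(["intermediate"] * 20, np.zeros(20))
        long = _result(
            ["flexible"] * 12 + ["intermediate"] * 8, np.full(20, 2.0)
        )
        once = fm.combine_external(short, long)
        twice = fm.combine_external(once, long)
        np.testing.assert_array_equal(once.raw, twice.raw)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            fm.combine_external(_result(["rigid"] * 5), _result(["rigid"] * 6))


class TestExtractFlexibleRegions:
    def test_short_second_run_dropped(self):
        regions = fm.extract_flexible_regions(
            np.array([2.0, 2, 2, 0, 2, 2])
        )
        assert [(r.start, r.end) for r in regions] == [(1, 3)]

    def test_all_low_scores(self):
        assert fm.extract_flexible_regions(np.array([1.0, 0.5, -1])) == []

    def test_accepts_prediction_result(self):
        res = _result(["flexible"] * 6, np.array([2.0, 2, 2, 0, 2, 2]))
        regions = fm.extract_flexible_regions(res)
        assert [(r.start, r.end) for r in regions] == [(1, 3)]
        assert regions[0].mean_score == pytest.approx(2.0)


class TestPredictProfile:
    def test_uniform_input_gives_constant_score(self, uniform_annotated, internal_model):
        res = fm.predict_profile(uniform_annotated, internal_model)
        vals = res.smoothed[res.mask]
        assert np.ptp(vals) < 1e-12

    def test_raw_scores_come_from_cell_values(self, corpus16, internal_model):
        chain = corpus16.chains[2]
        res = fm.predict_profile(chain.annotated, internal_model)
        cells = np.array(
            [avg for (avg, sd) in internal_model.class_stats.stats.values()]
        )
        for v in res.raw[res.mask]:
            assert np.min(np.abs(cells - v)) < 1e-12

    def test_coil_scores_exceed_helix_scores(self, corpus16, internal_model):
        chain = corpus16.chains[3]
        res = fm.predict_profile(chain.annotated, internal_model)
        ss = np.array(list(chain.annotated.ss))
        coil = res.smoothed[res.mask & (ss == "C")]
        helix = res.smoothed[res.mask & (ss == "H")]
        assert coil.mean() > helix.mean()

    def test_serialization_round_trip(self, tmp_path, corpus16, internal_model):
        path = tmp_path / "model.fmx"
        fm.save_models({"internal": internal_model}, path)
        loaded = fm.load_models(path)["internal"]
        chain = corpus16.chains[0]
        r1 = fm.predict_profile(chain.annotated, internal_model)
        r2 = fm.predict_profile(chain.annotated, loaded)
        np.testing.assert_array_equal(
            np.nan_to_num(r1.raw, nan=-999), np.nan_to_num(r2.raw, nan=-999)
        )
        np.testing.assert_array_equal(r1.classes, r2.classes)

    def test_expected_score_policy_blends_cells(self, corpus16):
        model = fm.train_from_corpus(
            corpus16, "internal",
            config=fm.TrainConfig(seed=7, ntree=50, z_policy="expected"),
        )
        chain = corpus16.chains[0]
        res = fm.predict_profile(chain.annotated, model)
        cell_means = [avg for avg, _ in model.class_stats.stats.values()]
        assert np.nanmin(res.raw) >= min(cell_means) - 1e-9
        assert np.nanmax(res.raw) <= max(cell_means) + 1e-9
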
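import numpy as np
import pytest
from scipy.stats import pearsonr

from framepool.interpret_eval import bootstrap_compare
from framepool.model_zoo import ModelConfig, build_model
from framepool.synthetic_mpra import ScanningParams, scan_annotate, simulate_dataset
from framepool.training import (
    TrainConfig,
    predict_dataset,
    split_validation,
    train,
    train_combined,
)

TINY_CONFIG = ModelConfig(
    conv_layers=((16, 7, 1), (16, 7, 1), (16, 7, 1)), dense_units=16, dropout_rate=0.2
)


class TestSplitValidation:
    def test_sizes_and_disjointness(self):
        ds = simulate_dataset(500, 50, seed=0)
        tr, val = split_validation(ds, 100, seed=1)
        assert len(tr) == 400 and len(val) == 100
        assert set(str(s) for s in tr.sequences).isdisjoint(str(s) for s in val.sequences)

    def test_seeded_determinism(self):
        ds = simulate_dataset(200, 50, seed=0)
        tr1, val1 = split_validation(ds, 50, seed=9)
        tr2, val2 = split_validation(ds, 50, seed=9)
        assert val1.sequences == val2.sequences

    def test_zero_val_count_no_split(self):
        ds = simulate_dataset(50, 50, seed=0)
        tr, val = split_validation(ds, 0, seed=0)
        assert val is None and len(tr) == 50

    def test_val_count_too_large(self):
        ds = simulate_dataset(50, 50, seed=0)
        with pytest.raises(ValueError):
            split_validation(ds, 50, seed=0)


class TestTrain:
    def test_fixed_epoch_mode_runs_exactly_max_epochs(self):
        ds = simulate_dataset(400, 50, seed=3)
        model = build_model(TINY_CONFIG, seed=0)
        _, hist = train(model, ds, TrainConfig(max_epochs=6, patience=None, val_count=0,
                                               batch_size=64, seed=1))
        assert len(hist) == 6

    def test_loss_decreases_over_first_epochs(self):
        ds = simulate_dataset(1200, 50, seed=4)
        model = build_model(TINY_CONFIG, seed=1)
        _, hist = train(model, ds, TrainConfig(max_epochs=4, patience=None, val_count=0,
                                               batch_size=64, seed=2))
        assert hist.train_loss.iloc[-1] < hist.train_loss.iloc[0]

    def test_early_stopping_restores_best_weights(self):
        ds = simulate_dataset(1200, 50, seed=5)
        model = build_model(TINY_CONFIG, seed=2)
        cfg = TrainConfig(max_epochs=30, patience=2, val_count=300, batch_size=64, seed=3)
        model, hist = train(model, ds, cfg)
        _, val = split_validation(ds, 300, seed=3)
        final_val = np.mean((predict_dataset(model, val) - val.mrl) ** 2)
        assert final_val == pytest.approx(hist.val_loss.min(), rel=1e-6)
        # stopped before exhausting the epoch budget
        best_epoch = int(hist.val_loss.idxmin())
        assert len(hist) <= best_epoch + 1 + cfg.patience

    def test_run_directory_artifacts(self, tmp_path):
        ds = simulate_dataset(200, 50, seed=6)
        model = build_model(TINY_CONFIG, seed=3)
        train(model, ds, TrainConfig(max_epochs=1, patience=None, val_count=0,
                                     batch_size=64, seed=4), run_dir=tmp_path / "run")
        assert (tmp_path / "run" / "train_config.json").exists()
        assert (tmp_path / "run" / "history.csv").exists()
        assert (tmp_path / "run" / "model.zip").exists()

    def test_bucketed_batching_matches_plain_at_inference(self):
        ds = simulate_dataset(300, (25, 100), seed=7)
        model = build_model(TINY_CONFIG, seed=4)
        train(model, ds, TrainConfig(max_epochs=1, patience=None, val_count=0,
                                     batch_size=32, seed=5, bucket_by_length=True))
        p_sorted = predict_dataset(model, ds, batch_size=64)
        alone = np.array([model.predict_sequences([s])[0] for s in ds.sequences])
        np.testing.assert_allclose(p_sorted, alone, rtol=1e-5)


class TestCombinedTraining:
    def test_affine_recovery_between_libraries(self):
        # two libraries identical except MRL_b = 1.5 * MRL_a + 0.5; the
        # learned relative (scale, bias) must recover the generating affine
        params = ScanningParams(library_affines=((1.0, 0.0), (1.5, 0.5)))
        ds_a = simulate_dataset(4000, 50, params=params, library=0, seed=8)
        ds_b = simulate_dataset(4000, 50, params=params, library=1, seed=8)
        model = build_model(
            ModelConfig(conv_layers=((16, 7, 1), (16, 7, 1), (16, 7, 1)),
                        dense_units=16, dropout_rate=0.2, n_libraries=2),
            seed=5,
        )
        cfg = TrainConfig(max_epochs=6, patience=None, val_count=0, batch_size=64, seed=6)
        train_combined(model, ds_a, ds_b, cfg)
        s0, s1 = model.params["lib_scale"]
        b0, b1 = model.params["lib_bias"]
        rel_scale = s1 / s0
        rel_bias = b1 - rel_scale * b0
        assert rel_scale == pytest.approx(1.5, rel=0.10)
        assert rel_bias == pytest.approx(0.5, rel=0.10)

    def test_single_library_degenerate_call_equals_train(self):
        ds = simulate_dataset(200, 50, seed=10)
        cfg = TrainConfig(max_epochs=1, patience=None, val_count=0, batch_size=64, seed=7)
        m1 = build_model(TINY_CONFIG, seed=6)
        train_combined(m1, ds, None, cfg)
        m2 = build_model(TINY_CONFIG, seed=6)
        train(m2, ds, cfg)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_mixed_length_batches_from_both_libraries(self):
        params = ScanningParams(library_affines=((1.0, 0.0), (2.0, 0.0)))
        ds_a = simulate_dataset(120, 50, params=params, library=0, seed=11)
        ds_b = simulate_dataset(120, (25, 100), params=params, library=1, seed=12)
        model = build_model(
            ModelConfig(conv_layers=((8, 7, 1),), dense_units=8, n_libraries=2), seed=7
        )
        cfg = TrainConfig(max_epochs=1, patience=None, val_count=0, batch_size=32, seed=8)
        train_combined(model, ds_a, ds_b, cfg)  # must not raise

    def test_missing_library_capacity_rejected(self):
        ds = simulate_dataset(50, 50, seed=13)
        model = build_model(TINY_CONFIG, seed=8)
        with pytest.raises(ValueError, match="n_libraries"):
            train_combined(model, ds, ds, TrainConfig(max_epochs=1, patience=None,
                                                      val_count=0, seed=0))


class TestSimStudyProperties:
    """Properties of the full-size simulator recovery study (session fixture)."""

    def test_frame_pooling_beats_global_pooling_beyond_bootstrap_noise(self, sim_study):
        obs = sim_study["test"].mrl
        res = bootstrap_compare(
            sim_study["preds"]["framepool"], sim_study["preds"]["global_pool"],
            obs, n_boot=100, multiplier=3.54, seed=0,
        )
        assert res.metric_a > res.metric_b
        assert res.significant

    def test_frame_sensitivity_of_trained_model(self, sim_study):
        """Making a lone out-of-frame uAUG in-frame (one base inserted just
        3' of it) raises the trained frame-pooling model's prediction in
        >= 80% of 100 cases, as the scanning oracle dictates; the
        global-pooling baseline shows no such preference."""
        rng = np.random.default_rng(77)
        cases = []
        while len(cases) < 100:
            seq = "".join(rng.choice(list("ACGU"), 50))
            ann = scan_annotate(seq)
            if len(ann.candidates) != 1:
                continue
            c = ann.candidates[0]
            if c.codon != "AUG" or c.frame != 2 or c.is_uorf:
                continue
            ins = c.position + 3
            mod = seq[:ins] + "C" + seq[ins:]
            ann2 = scan_annotate(mod)
            if [x.position for x in ann2.candidates] != [c.position] or ann2.candidates[0].is_uorf:
                continue
            cases.append((seq, mod))
        frac = {}
        for preset in ("framepool", "global_pool"):
            model = sim_study["models"][preset]
            before = model.predict_sequences([s for s, _ in cases])
            after = model.predict_sequences([m for _, m in cases])
            frac[preset] = float(np.mean(after > before))
        assert frac["framepool"] >= 0.8
        assert frac["global_pool"] < frac["framepool"]

    def test_heldout_correlation_above_simulator_floor(self, sim_study):
        r = pearsonr(sim_study["preds"]["framepool"], sim_study["test"].mrl)[0]
        assert r >= 0.8
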
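import numpy as np
import pytest

from framepool.fixtures import ORACLE_TEST_PARAMS, make_fixtures
from framepool.model_zoo import ModelConfig, build_model, get_preset
from framepool.synthetic_mpra import OraclePredictor, simulate_dataset
from framepool.training import TrainConfig, predict_dataset, train


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Toy genome FASTA + BED + VCF + TIS context CSV."""
    d = tmp_path_factory.mktemp("toyfix")
    return make_fixtures(d)


@pytest.fixture(scope="session")
def oracle_predictor():
    """Simulator oracle with analytically clean parameters (p(uAUG) = 0.9,
    CUG/GUG inert, mu_main 6, mu_oof 2)."""
    return OraclePredictor(ORACLE_TEST_PARAMS)


@pytest.fixture(scope="session")
def tiny_trained_model():
    """A small frame-pooling model trained in float64 on a small simulated
    set; used for gradient and interpretation tests."""
    config = ModelConfig(
        conv_layers=((16, 7, 1), (16, 7, 1), (16, 7, 1)),
        dense_units=16,
        dropout_rate=0.2,
    )
    model = build_model(config, seed=11, dtype=np.float64)
    ds = simulate_dataset(1500, 50, seed=31)
    cfg = TrainConfig(max_epochs=4, patience=None, val_count=0, batch_size=128, seed=5)
    train(model, ds, cfg)
    return model


@pytest.fixture(scope="session")
def sim_study():
    """The simulator recovery study: frame-pooling vs global-pooling models
    trained on 20,000 simulated 50 nt sequences (label noise sd 0.3), with
    a 4,000-sequence held-out set.

    Trained once per session; shared by the training-property and
    acceptance tests.
    """
    train_ds = simulate_dataset(20000, 50, seed=101)
    test_ds = simulate_dataset(4000, 50, seed=202)
    cfg = TrainConfig(max_epochs=12, patience=3, val_count=2000, batch_size=128, seed=7)
    models = {}
    preds = {}
    for preset in ("framepool", "global_pool"):
        model = build_model(get_preset(preset), seed=7)
        train(model, train_ds, cfg)
        models[preset] = model
        preds[preset] = predict_dataset(model, test_ds)
    return {
        "train": train_ds,
        "test": test_ds,
        "models": models,
        "preds": preds,
    }


@pytest.fixture(scope="session")
def rf_study(sim_study):
    """Framed vs unframed 4-mer random-forest baselines on the same study
    data (100 trees, library defaults)."""
    from sklearn.ensemble import RandomForestRegressor

    from framepool.seq_core import kmer_feature_matrix

    train_ds = sim_study["train"]
    test_ds = sim_study["test"]
    preds = {}
    for framed in (False, True):
        X = kmer_feature_matrix(train_ds.sequences, 4, framed)
        Xt = kmer_feature_matrix(test_ds.sequences, 4, framed)
        rf = RandomForestRegressor(n_estimators=100, random_state=7, n_jobs=1)
        rf.fit(X, train_ds.mrl)
        preds[framed] = rf.predict(Xt)
    return preds
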
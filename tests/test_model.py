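"""Same-gene pair classifier: training table, CV, importances, contracts."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from ncgene.errors import ConfigError, ContractError, DegenerateTrainingError, InputError
from ncgene.features import FEATURE_NAMES, PairFeatures
from ncgene.model import (
    SameGenePairClassifier,
    build_training_set,
    cross_validate,
    feature_importances,
    load_model,
    predict_pair,
    save_model,
    train_classifier,
)

from conftest import make_set, make_transcript


def _two_gene_reference():
    """Two genes, two transcripts each, all four 5' starts within 1 kb."""
    return make_set(
        [
            make_transcript("t1", [(100, 300)], gene_id="gA"),
            make_transcript("t2", [(150, 350)], gene_id="gA"),
            make_transcript("t3", [(600, 800)], gene_id="gB", strand="-", so_type="SO:0000253"),
            make_transcript("t4", [(650, 850)], gene_id="gB", strand="-", so_type="SO:0000253"),
        ]
    )


def test_build_training_set_counts(mini_emb):
    table = build_training_set(_two_gene_reference(), mini_emb)
    assert len(table) == 6  # all C(4,2) pairs fall in the window
    assert int(table["label"].sum()) == 2
    assert table.attrs["class_counts"] == {"positive": 2, "negative": 4}
    assert list(table.columns) == ["id_a", "id_b", *FEATURE_NAMES, "label"]


def test_single_gene_reference_is_degenerate(mini_emb):
    ref = make_set(
        [
            make_transcript("t1", [(100, 300)], gene_id="gA"),
            make_transcript("t2", [(150, 350)], gene_id="gA"),
        ]
    )
    with pytest.raises(DegenerateTrainingError):
        build_training_set(ref, mini_emb)


def test_distant_genes_yield_no_cross_rows(mini_emb):
    ref = make_set(
        [
            make_transcript("t1", [(100, 300)], gene_id="gA"),
            make_transcript("t2", [(150, 350)], gene_id="gA"),
            make_transcript("t3", [(9_000, 9_200)], gene_id="gB"),
            make_transcript("t4", [(9_050, 9_250)], gene_id="gB"),
        ]
    )
    # positives only -> single class -> degenerate by the spec'd contract
    with pytest.raises(DegenerateTrainingError):
        build_training_set(ref, mini_emb)


def test_missing_gene_ids_rejected(mini_emb):
    ref = make_set([make_transcript("t1", [(100, 300)])])
    with pytest.raises(InputError, match="gene id"):
        build_training_set(ref, mini_emb)


def _separable_table(n_per_class: int = 50, seed: int = 0) -> pd.DataFrame:
    """Positives all d_start5 < 10, negatives all > 500; other features noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(2 * n_per_class):
        label = int(i < n_per_class)
        d = rng.uniform(0, 10) if label else rng.uniform(500, 1000)
        rows.append(
            (f"a{i}", f"b{i}", d, rng.uniform(0, 1000), rng.uniform(0, 1),
             float(rng.integers(0, 3)), float(rng.integers(0, 2)), rng.uniform(-1, 1), label)
        )
    return pd.DataFrame(rows, columns=["id_a", "id_b", *FEATURE_NAMES, "label"])


def test_separable_table_reaches_perfect_auc():
    """Any threshold on d_start5 separates the classes (one-feature oracle),
    so the forest must reach AUC = AP = 1 in CV."""
    table = _separable_table()
    x = table["d_start5"].to_numpy()
    y = table["label"].to_numpy()
    assert x[y == 1].max() < x[y == 0].min()  # threshold oracle: separable
    cv = cross_validate(table, k=5, seed=1)
    assert cv.averages["auc"] == pytest.approx(1.0)
    assert cv.averages["ap"] == pytest.approx(1.0)


def test_training_is_deterministic():
    table = _separable_table(seed=3)
    probe = _separable_table(n_per_class=10, seed=9)[list(FEATURE_NAMES)].to_numpy()
    m1 = train_classifier(table, seed=7)
    m2 = train_classifier(table, seed=7)
    assert np.array_equal(m1.same_gene_probability(probe), m2.same_gene_probability(probe))
    assert m1.data_fingerprint_ == m2.data_fingerprint_


def test_one_row_per_class_trains():
    table = _separable_table(n_per_class=1)
    model = train_classifier(table, seed=0)
    p = predict_pair(model, PairFeatures(5.0, 1.0, 0.5, 1.0, 1.0, 0.5))
    assert np.isfinite(p) and 0.0 <= p <= 1.0


def test_permuted_labels_give_chance_auc():
    table = _separable_table(n_per_class=150, seed=4)
    rng = np.random.default_rng(123)
    table = table.assign(label=rng.permutation(table["label"].to_numpy()))
    cv = cross_validate(table, k=5, seed=5)
    assert 0.4 <= cv.averages["auc"] <= 0.6


def test_cv_averages_equal_fold_means_and_config_errors():
    table = _separable_table()
    cv = cross_validate(table, k=5, seed=0)
    assert len(cv.folds) == 5
    pd.testing.assert_series_equal(cv.averages, cv.folds[["accuracy", "f1", "auc", "ap"]].mean())
    with pytest.raises(ConfigError):
        cross_validate(table, k=1)
    with pytest.raises(InputError):
        cross_validate(_separable_table(n_per_class=3), k=5)


def test_nan_features_are_contract_error():
    model = train_classifier(_separable_table(), seed=0)
    with pytest.raises(ContractError, match="non-finite"):
        predict_pair(model, PairFeatures(np.nan, 0, 0, 0, 1, 0))


def test_wrong_feature_count_is_contract_error():
    model = train_classifier(_separable_table(), seed=0)
    with pytest.raises(ContractError):
        model.predict_proba(np.zeros((3, 4)))


def test_unfitted_importances_is_state_error():
    from sklearn.exceptions import NotFittedError

    with pytest.raises(NotFittedError):
        feature_importances(SameGenePairClassifier())


def test_importances_normalized_and_signal_feature_wins():
    table = _separable_table(n_per_class=100, seed=2)
    cv = cross_validate(table, k=5, seed=2)
    model = train_classifier(table, seed=2)
    imp = feature_importances(model, cv.models)
    assert imp["importance"].sum() == pytest.approx(1.0, abs=1e-9)
    assert (imp["importance"] >= 0).all()
    assert imp["importance"].idxmax() == "d_start5"  # the only informative feature
    assert (imp["std"] >= 0).all()


def test_monotone_sanity_shrinking_separation_cannot_raise_auc():
    """Moving positive-class d_start5 toward the negative range never
    improves CV AUC on the one-signal table."""
    base = _separable_table(n_per_class=60, seed=6)
    degraded = base.copy()
    pos = degraded["label"] == 1
    degraded.loc[pos, "d_start5"] = degraded.loc[pos, "d_start5"] + 495  # overlap the classes
    auc_base = cross_validate(base, k=5, seed=1).averages["auc"]
    auc_degraded = cross_validate(degraded, k=5, seed=1).averages["auc"]
    assert auc_degraded <= auc_base + 1e-9


def test_model_archive_round_trip(tmp_path):
    table = _separable_table()
    model = train_classifier(table, seed=0, embedding_fingerprint="abc123")
    path = tmp_path / "model.joblib"
    save_model(model, path)
    back = load_model(path)
    probe = table[list(FEATURE_NAMES)].to_numpy()
    assert np.array_equal(back.same_gene_probability(probe), model.same_gene_probability(probe))
    assert back.embedding_fingerprint_ == "abc123"
    assert tuple(back.feature_names_) == FEATURE_NAMES


def test_estimator_is_sklearn_compatible():
    est = SameGenePairClassifier(n_estimators=10, random_state=1)
    assert clone(est).get_params() == est.get_params()
    est.set_params(n_estimators=20)
    assert est.n_estimators == 20
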
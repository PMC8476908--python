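"""Feature filtering, patient-level splitting, grids and tuning."""

import numpy as np
import pandas as pd
import pytest

from epidfluence.classifiers import (
    GridSpec,
    default_grid,
    pearson_filter,
    run_experiment,
    split_by_patient,
    tune_and_train,
)


def _toy_matrix(n_patients=6, seed=0):
    """Small feature matrix with one informative and several junk columns."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        for s in range(9):
            label = 1 if s < 5 else 2
            rows.append(
                {
                    "patient_id": f"P{p}",
                    "serial": s,
                    "type1": label,
                    "dd_signal": label * 10 + rng.normal(0, 0.5),
                    "dd_noise1": rng.normal(),
                    "dd_noise2": rng.normal(),
                    "dd_constant": 3.0,
                }
            )
    return pd.DataFrame(rows)


def test_pearson_filter_keeps_correlated_drops_constant():
    x = pd.DataFrame(
        {
            "exact": [1.0, 1, 2, 2],
            "constant": [5.0, 5, 5, 5],
            "weak": [1.0, 2, 3, 4],
        }
    )
    labels = [1, 1, 2, 2]
    kept = pearson_filter(x, labels, threshold=0.3)
    assert "exact" in kept and "constant" not in kept
    # r((1,2,3,4), (1,1,2,2)) = 0.8944 -> kept at 0.3
    assert "weak" in kept
    r = np.corrcoef([1, 2, 3, 4], [1, 1, 2, 2])[0, 1]
    assert r == pytest.approx(0.8944, abs=1e-4)


def test_pearson_filter_raises_when_nothing_survives():
    x = pd.DataFrame({"c": [1.0, 1, 1, 1]})
    with pytest.raises(ValueError, match="threshold"):
        pearson_filter(x, [1, 1, 2, 2], threshold=0.5)


@pytest.mark.parametrize("n, expected", [(40, (32, 8)), (10, (8, 2)), (5, (4, 1))])
def test_split_by_patient_sizes(n, expected):
    ids = [f"P{i}" for i in range(n) for _ in range(3)]
    train, test = split_by_patient(ids, seed=1)
    assert (len(train), len(test)) == expected
    assert not set(train) & set(test)
    assert set(train) | set(test) == set(ids)


def test_split_deterministic_and_rejects_single_patient():
    ids = [f"P{i}" for i in range(10)]
    assert split_by_patient(ids, 3) == split_by_patient(ids, 3)
    assert split_by_patient(ids, 3) != split_by_patient(ids, 4)
    with pytest.raises(ValueError):
        split_by_patient(["P0"], 0)


def test_default_grids_reproduce_search_spaces():
    knn = default_grid("knn", "type1")
    assert knn.grid[0]["clf__n_neighbors"] == list(range(1, 11))

    svm = default_grid("svm", "type1")
    linear, rbf = svm.grid
    assert linear["clf__kernel"] == ["linear"]
    assert linear["clf__C"] == [0.01, 0.1, 1, 10]
    assert rbf["clf__gamma"] == [0.001, 0.01, 0.1, 1]
    assert "clf__gamma" not in linear  # gamma applies to the RBF kernel only

    ldc = default_grid("ldc", "type1")
    assert ldc.grid[0]["clf__solver"] == ["svd", "lsqr", "eigen"]

    xgb12 = default_grid("xgboost", "type2_si")
    assert xgb12.grid[0]["clf__n_estimators"] == list(range(10, 101, 10))
    assert xgb12.grid[0]["clf__max_depth"] == list(range(3, 11))
    xgb3 = default_grid("xgboost", "type3")
    assert xgb3.grid[0]["clf__n_estimators"] == list(range(100, 251, 10))


def test_gridspec_rejects_empty_candidates():
    with pytest.raises(ValueError):
        GridSpec("knn", [{"clf__n_neighbors": []}])


def test_tune_and_train_selects_from_grid_and_rejects_single_class():
    df = _toy_matrix()
    x = df[["dd_signal", "dd_noise1"]]
    model = tune_and_train(
        x, df["type1"], df["patient_id"], "type1", "knn",
        grid=GridSpec("knn", [{"clf__n_neighbors": [1, 3, 5]}]),
    )
    assert model.selected_params["clf__n_neighbors"] in (1, 3, 5)
    assert 0 <= model.cv_accuracy <= 1
    with pytest.raises(ValueError, match="single-class"):
        tune_and_train(
            x, np.ones(len(x)), df["patient_id"], "type1", "knn",
        )


def test_one_nearest_neighbour_memorizes_training_data():
    df = _toy_matrix()
    model = tune_and_train(
        df[["dd_signal", "dd_noise1", "dd_noise2"]],
        df["type1"], df["patient_id"], "type1", "knn",
        grid=GridSpec("knn", [{"clf__n_neighbors": [1]}]),
    )
    pred = model.estimator.predict(
        df[["dd_signal", "dd_noise1", "dd_noise2"]].to_numpy()
    ) + 1
    assert np.mean(pred == df["type1"].to_numpy()) == 1.0


def test_run_experiment_end_to_end_filters_on_train_only():
    df = _toy_matrix(n_patients=8)
    res = run_experiment(
        df, "ml1", "type1", "ldc", seed=0,
        grid=GridSpec("ldc", [{"clf__solver": ["svd"]}]),
    )
    # held-out patients only: 2 of 8 patients x 9 samples
    assert len(res.y_true) == 18
    assert set(res.patient_ids) <= {f"P{i}" for i in range(8)}
    assert len(set(res.patient_ids)) == 2
    assert "dd_constant" not in res.selected_features
    # separable toy signal: the classifier recovers the labels
    assert np.mean(res.y_true == res.y_pred) == 1.0
    assert res.scores.shape == (18, 2)


def test_run_experiment_permuted_labels_near_chance():
    rng = np.random.default_rng(5)
    df = _toy_matrix(n_patients=10, seed=2)
    df["type1"] = rng.permutation(df["type1"].to_numpy())
    res = run_experiment(
        df, "ml1", "type1", "knn", seed=1,
        grid=GridSpec("knn", [{"clf__n_neighbors": [3]}]),
    )
    acc = np.mean(res.y_true == res.y_pred)
    # majority class is 5/9; binomial noise at n=27 keeps chance-level
    # accuracy well below 0.85
    assert acc < 0.85


def test_unknown_task_and_empty_config_rejected():
    df = _toy_matrix()
    with pytest.raises(ValueError, match="task"):
        run_experiment(df, "ml1", "type9", "ldc")
    with pytest.raises(KeyError):
        run_experiment(df, "ml9", "type1", "ldc")
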
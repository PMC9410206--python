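"""Feature scoring, hybrid and LASSO selection, radscore."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radpipe import (
    SelectionResult,
    TableSpec,
    compute_radscore,
    generate_feature_table,
    hybrid_select,
    lasso_select,
    score_features,
)
from radpipe.tables import feature_columns


def small_table():
    return pd.DataFrame(
        {
            "patient_id": ["a", "b", "c", "d"],
            "label": [0, 0, 1, 1],
            "feat_x": [1.0, 2.0, 3.0, 4.0],
        }
    )


def test_pbc_equals_pearson_with_dummy_label():
    """The point-biserial score is the Pearson r against the 0/1 label."""
    table = small_table()
    scores = score_features(table, "pbc")
    expected = stats.pearsonr([1, 2, 3, 4], [0, 0, 1, 1]).statistic
    assert scores.scores["feat_x"] == pytest.approx(expected, abs=1e-12)
    assert scores.scores["feat_x"] == pytest.approx(0.8944271909999159)


def test_welch_t_statistic():
    """(3.5 - 1.5) / sqrt(0.5/2 + 0.5/2) = 2.828..."""
    table = small_table()
    scores = score_features(table, "ttest")
    assert abs(scores.scores["feat_x"]) == pytest.approx(2.8284271247461903)


def test_zero_variance_feature_scored_zero_with_warning():
    table = small_table()
    table["flat"] = 1.0
    for method in ("pbc", "ttest", "relieff"):
        with pytest.warns(UserWarning, match="zero-variance"):
            scores = score_features(table, method)
        assert scores.scores["flat"] == 0.0


def test_single_class_rejected():
    table = small_table()
    table["label"] = 1
    with pytest.raises(ValueError, match="both classes"):
        score_features(table, "pbc")


def test_scores_invariant_to_row_permutation():
    spec = TableSpec(
        n_per_class=(30, 30), n_features=8, batch_sizes=(60,),
        effects=((2, 1.0),), seed=3,
    )
    table, _ = generate_feature_table(spec)
    rng = np.random.default_rng(0)
    shuffled = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
    for method in ("pbc", "ttest", "relieff"):
        a = score_features(table, method).scores
        b = score_features(shuffled, method).scores
        pd.testing.assert_series_equal(a, b, atol=1e-12)


def test_relieff_prefers_informative_feature():
    spec = TableSpec(
        n_per_class=(50, 50), n_features=10, batch_sizes=(100,),
        effects=((4, 2.0),), seed=1,
    )
    table, _ = generate_feature_table(spec)
    scores = score_features(table, "relieff")
    assert scores.order[0] == "feat_004"


def test_tied_scores_break_lexicographically():
    table = pd.DataFrame(
        {
            "patient_id": list("abcdef"),
            "label": [0, 0, 0, 1, 1, 1],
            "zeta": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "alpha": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        }
    )
    scores = score_features(table, "pbc")
    assert scores.order == ["alpha", "zeta"]


def test_hybrid_selects_the_informative_feature():
    spec = TableSpec(
        n_per_class=(50, 50), n_features=10, batch_sizes=(100,),
        effects=((3, 2.0),), seed=7,
    )
    table, _ = generate_feature_table(spec)
    scores = score_features(table, "pbc")
    result = hybrid_select(table, scores)
    assert result.selected == ["feat_003"]
    assert len(result.p_trajectory) == 1
    # independent check: the 2-feature model's LRT p exceeds the 1-feature one
    assert np.all(np.diff(result.p_trajectory) < 0)


def test_hybrid_on_pure_noise_keeps_exactly_one():
    spec = TableSpec(
        n_per_class=(40, 40), n_features=8, batch_sizes=(80,), seed=12
    )
    table, _ = generate_feature_table(spec)
    result = hybrid_select(table, score_features(table, "pbc"))
    assert len(result.selected) >= 1  # the procedure floor: cycle 1 always kept
    assert sorted(result.p_trajectory, reverse=True) == result.p_trajectory


def test_hybrid_trajectory_strictly_decreasing():
    spec = TableSpec(
        n_per_class=(60, 60), n_features=12, batch_sizes=(120,),
        effects=((0, 1.0), (1, 0.8), (2, 0.6)), seed=2,
    )
    table, _ = generate_feature_table(spec)
    result = hybrid_select(table, score_features(table, "pbc"))
    traj = result.p_trajectory
    assert all(b < a for a, b in zip(traj, traj[1:]))
    assert len(result.selected) == len(traj)


def test_lasso_full_shrinkage_at_high_lambda():
    spec = TableSpec(
        n_per_class=(40, 40), n_features=6, batch_sizes=(80,),
        effects=((0, 1.5),), seed=4,
    )
    table, _ = generate_feature_table(spec)
    result = lasso_select(table, k_folds=5, lambda_grid=np.array([10.0]))
    assert result.selected == []
    assert result.coefficients == {}


def test_lasso_recovers_strong_features():
    spec = TableSpec(
        n_per_class=(100, 100), n_features=20, batch_sizes=(200,),
        effects=((0, 1.5), (1, 1.5)), seed=8,
    )
    table, _ = generate_feature_table(spec)
    result = lasso_select(table, k_folds=10, seed=0)
    assert {"feat_000", "feat_001"} <= set(result.selected)
    assert result.lambda_chosen is not None
    assert len(result.lambda_path) == 100


def test_lasso_fold_bounds():
    table = small_table()
    with pytest.raises(ValueError, match="k_folds"):
        lasso_select(table, k_folds=1)
    with pytest.raises(ValueError, match="k_folds"):
        lasso_select(table, k_folds=50)


def test_radscore_arithmetic_and_linearity():
    result = SelectionResult(
        method="manual",
        selected=["f1", "f2"],
        coefficients={"f1": 2.0, "f2": -1.0},
        intercept=0.5,
    )
    table = pd.DataFrame(
        {"patient_id": ["a"], "label": [0], "f1": [3.0], "f2": [4.0]}
    )
    assert compute_radscore(result, table).iloc[0] == pytest.approx(2.5)
    doubled = table.assign(f1=table["f1"] * 2)
    assert compute_radscore(result, doubled).iloc[0] == pytest.approx(
        2.5 + 2.0 * 3.0
    )
    # zero coefficients -> constant intercept
    const = SelectionResult("manual", ["f1"], {"f1": 0.0}, intercept=0.5)
    assert (compute_radscore(const, table) == 0.5).all()
    with pytest.raises(KeyError, match="f9"):
        compute_radscore(
            SelectionResult("manual", ["f9"], {"f9": 1.0}, 0.0), table
        )


def test_hybrid_agrees_between_raw_and_harmonized():
    """Same injected structure -> same top feature either way."""
    from radpipe import combat_harmonize

    spec = TableSpec(
        n_per_class=(60, 60), n_features=10, batch_sizes=(60, 60),
        batch_shifts=(2.0, 0.0), effects=((5, 1.5),), seed=21,
    )
    table, _ = generate_feature_table(spec)
    harmonized = combat_harmonize(table).table
    sel_raw = hybrid_select(table, score_features(table, "pbc"))
    sel_harm = hybrid_select(harmonized, score_features(harmonized, "pbc"))
    assert sel_raw.selected[0] == sel_harm.selected[0] == "feat_005"
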
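"""Feature gating, RF proximity clustering, BIC selection, 2x2 readout."""

import numpy as np
import pandas as pd
import pytest

from dialhrv import (bic_select_k, contingency, pam, relative_risk,
                     rf_cluster, select_features)

from reference_data import (BF10_BY_FEATURE, CLUSTER1_HS_PCT, CLUSTER_COUNTS,
                            RR_CI_PRINTED, RR_PRINTED)


# --- BF gate ---------------------------------------------------------------

def test_select_features_reference_bf_column():
    selected = select_features(BF10_BY_FEATURE, 3.0)
    assert selected == (
        [f"MSE{t}" for t in range(3, 21)] + ["MSE_1_20", "MSE_1_5", "MSE_6_20"]
    )
    for excluded in ("MSE1", "MSE2", "LFnu", "HFnu", "FuzzyEn"):
        assert excluded not in selected


def test_select_features_threshold_zero_keeps_all():
    assert select_features(BF10_BY_FEATURE, 0.0) == list(BF10_BY_FEATURE)


def test_select_features_empty_selection_errors():
    with pytest.raises(ValueError, match="threshold"):
        select_features({"a": 0.5, "b": 2.9}, 3.0)


# --- clustering ------------------------------------------------------------

def _two_blobs(seed, n=20, d=4, sep=6.0):
    r = np.random.default_rng(seed)
    a = r.standard_normal((n, d))
    b = r.standard_normal((n, d)) + sep / np.sqrt(d)
    x = np.vstack([a, b])
    truth = np.array([0] * n + [1] * n)
    return x, truth


def test_two_blobs_recovered_exactly():
    x, truth = _two_blobs(seed=1)
    asg = rf_cluster(x, k_max=5, n_trees=500, seed=1)
    assert asg.k == 2
    # agreement up to label swap
    agree = (asg.labels - 1 == truth).mean()
    assert max(agree, 1 - agree) == 1.0


def test_proximity_symmetric_unit_diagonal():
    x, _ = _two_blobs(seed=2, n=12)
    asg = rf_cluster(x, k_max=3, n_trees=100, seed=2)
    p = asg.proximity
    np.testing.assert_allclose(p, p.T)
    np.testing.assert_allclose(np.diag(p), 1.0)
    assert p.min() >= 0.0 and p.max() <= 1.0


def test_single_blob_prefers_smallest_k():
    hits = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        x = r.standard_normal((40, 2))
        asg = rf_cluster(x, k_max=4, n_trees=200, seed=seed)
        if asg.k == 2:
            hits += 1
    assert hits >= 16  # >= 80% of seeds


def test_constant_columns_dropped_with_warning():
    x, _ = _two_blobs(seed=3, n=12)
    x = np.column_stack([x, np.full(x.shape[0], 7.0)])
    with pytest.warns(UserWarning, match="constant"):
        asg = rf_cluster(x, k_max=3, n_trees=100, seed=3)
    assert len(asg.feature_names) == x.shape[1] - 1


def test_rf_cluster_deterministic():
    x, _ = _two_blobs(seed=4, n=15)
    a = rf_cluster(x, k_max=4, n_trees=200, seed=9)
    b = rf_cluster(x, k_max=4, n_trees=200, seed=9)
    np.testing.assert_array_equal(a.labels, b.labels)
    np.testing.assert_allclose(a.proximity, b.proximity)


# --- PAM and BIC -----------------------------------------------------------

def test_pam_separates_two_clusters_on_clean_distances():
    x, truth = _two_blobs(seed=5, n=15, d=2)
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
    labels = pam(d, 2)
    agree = (labels == truth).mean()
    assert max(agree, 1 - agree) == 1.0


def test_bic_ordering_on_two_blob_fixture():
    x, truth = _two_blobs(seed=6, n=20, d=2)
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
    labels_by_k = {k: pam(d, k) for k in (2, 3, 5)}
    _, bics = bic_select_k(x, labels_by_k)
    assert bics[2] < bics[3] < bics[5]


def test_bic_duplicate_partitions_equal_and_penalty_monotone():
    x, _ = _two_blobs(seed=7, n=10, d=2)
    lab = np.array([0] * 10 + [1] * 10)
    # identical partitions give identical scores on repeated evaluation
    _, a = bic_select_k(x, {2: lab, 3: pam(
        np.linalg.norm(x[:, None] - x[None, :], axis=2), 3)})
    _, b = bic_select_k(x, {2: lab.copy(), 3: pam(
        np.linalg.norm(x[:, None] - x[None, :], axis=2), 3)})
    assert a == b
    # an empty extra cluster (same partition declared as k+1) only pays
    # penalty, so its score strictly increases
    best, bics = bic_select_k(x, {2: lab, 3: lab.copy()})
    assert bics[3] > bics[2]
    assert best == 2


# --- contingency and relative risk ----------------------------------------

def _reference_table():
    return pd.DataFrame(CLUSTER_COUNTS, index=[1, 2], columns=["HS", "HU"])


def test_contingency_from_labels():
    clusters = np.array([1] * 17 + [2] * 4 + [1] * 11 + [2] * 14)
    groups = np.array(["HS"] * 21 + ["HU"] * 25)
    table = contingency(clusters, groups)
    pd.testing.assert_frame_equal(
        table, _reference_table(), check_names=False, check_dtype=False)
    hs_in_c1 = 100.0 * table.loc[1, "HS"] / table["HS"].sum()
    assert round(hs_in_c1, 1) == CLUSTER1_HS_PCT


def test_contingency_rejects_single_or_many_clusters():
    groups = np.array(["HS", "HU"] * 5)
    with pytest.raises(ValueError, match="two clusters"):
        contingency(np.ones(10, int), groups)
    with pytest.raises(ValueError, match="two clusters"):
        contingency(np.array([1, 2, 3] * 3 + [1]), groups)


def test_relative_risk_reference_counts():
    res = relative_risk(_reference_table())
    assert round(res.rr, 2) == RR_PRINTED
    assert round(res.ci95[0], 2) == RR_CI_PRINTED[0]
    assert round(res.ci95[1], 2) == RR_CI_PRINTED[1]
    assert res.p_value == pytest.approx(0.025, abs=0.005)


def test_relative_risk_equal_rates_is_one():
    tab = pd.DataFrame([[10, 12], [5, 6]], index=[1, 2], columns=["HS", "HU"])
    assert relative_risk(tab).rr == pytest.approx(1.0)


def test_relative_risk_matches_probability_ratio_oracle(rng):
    for _ in range(100):
        t = rng.integers(1, 30, size=(2, 2)).astype(float)
        res = relative_risk(pd.DataFrame(t, index=[1, 2],
                                         columns=["HS", "HU"]))
        p_exposed = t[1, 1] / (t[0, 1] + t[1, 1])  # P(C2 | HU)
        p_unexposed = t[1, 0] / (t[0, 0] + t[1, 0])  # P(C2 | HS)
        assert res.rr == pytest.approx(p_exposed / p_unexposed, rel=1e-12)
        assert res.ci95[0] <= res.rr <= res.ci95[1]


def test_relative_risk_zero_cell_continuity_corrected():
    tab = pd.DataFrame([[10, 12], [0, 6]], index=[1, 2], columns=["HS", "HU"])
    res = relative_risk(tab)
    assert res.continuity_corrected_cells
    assert np.isfinite(res.rr) and res.rr > 1.0
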
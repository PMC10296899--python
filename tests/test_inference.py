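"""JZS Bayes factors, evidence classes and the adjusted group comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dialhrv import (adjusted_group_difference, bayes_ttest,
                     bf_to_probability, classify_bf, jzs_bf10, pooled_t)

from reference_data import LFNU_HS, LFNU_HU


# --- JZS Bayes factor ------------------------------------------------------

def bf10_grid_oracle(t, n1, n2, rscale):
    """Dense-grid trapezoid over g, independent of the quadrature path."""
    nu = n1 + n2 - 2
    neff = n1 * n2 / (n1 + n2)
    g = np.exp(np.linspace(math.log(1e-6), math.log(1e6), 400_001))
    a = 1.0 + neff * g * rscale ** 2
    integrand = (a ** -0.5 * (1 + t * t / (nu * a)) ** (-(nu + 1) / 2)
                 * (2 * np.pi) ** -0.5 * g ** -1.5 * np.exp(-1 / (2 * g)))
    num = np.trapezoid(integrand, g)
    den = (1 + t * t / nu) ** (-(nu + 1) / 2)
    return num / den


@pytest.mark.parametrize("t", [0.5, 2.0, 4.0])
@pytest.mark.parametrize("n1", [10, 21])
@pytest.mark.parametrize("n2", [12, 25])
def test_bf_matches_grid_oracle(t, n1, n2):
    got = jzs_bf10(t, n1, n2)
    want = bf10_grid_oracle(t, n1, n2, math.sqrt(2) / 2)
    assert got == pytest.approx(want, rel=1e-5)


def test_bf_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    for t, n1, n2 in [(2.18, 21, 25), (0.7, 15, 18), (3.5, 21, 25)]:
        want = float(pingouin.bayesfactor_ttest(t, n1, n2))
        assert jzs_bf10(t, n1, n2) == pytest.approx(want, rel=1e-3)


def test_bf_null_favoured_at_t_zero():
    assert jzs_bf10(0.0, 21, 25) < 1.0


def test_bf_monotone_in_abs_t_and_symmetric():
    ts = [0.0, 0.5, 1.0, 2.0, 3.0, 5.0]
    bfs = [jzs_bf10(t, 21, 25) for t in ts]
    assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))
    assert jzs_bf10(-2.5, 21, 25) == pytest.approx(jzs_bf10(2.5, 21, 25),
                                                   rel=1e-10)


def test_bf_rejects_nonfinite_t():
    with pytest.raises(ValueError):
        jzs_bf10(float("nan"), 10, 10)


def test_pooled_t_from_spectral_summaries():
    t = pooled_t(*LFNU_HS, *LFNU_HU)
    assert t == pytest.approx(2.18, abs=0.01)


# --- BF -> probability and evidence classes --------------------------------

@given(st.floats(0.01, 100.0))
def test_probability_complement_identity(b):
    p = bf_to_probability(b)
    assert 0.0 < p < 100.0
    assert bf_to_probability(1.0 / b) == pytest.approx(100.0 - p, abs=1e-9)


def test_probability_monotone():
    bs = [0.1, 0.5, 1.0, 2.0, 10.0, 1e6]
    ps = [bf_to_probability(b) for b in bs]
    assert ps == sorted(ps)
    assert bf_to_probability(1.0) == 50.0


@pytest.mark.parametrize("bf,expected", [
    (15.8, "strong evidence for H1"),
    (3.86, "moderate evidence for H1"),
    (1.93, "anecdotal evidence for H1"),
    (150.0, "extreme evidence for H1"),
    (45.0, "very strong evidence for H1"),
    (0.37, "anecdotal evidence for H0"),
    (0.2, "moderate evidence for H0"),
    (0.05, "strong evidence for H0"),
    (0.005, "extreme evidence for H0"),
])
def test_evidence_classification(bf, expected):
    assert classify_bf(bf) == expected


def test_evidence_classification_boundary_bf1():
    assert "no evidence" in classify_bf(1.0)


# --- adjusted comparison ---------------------------------------------------

def _fake_cohort(seed, shift=0.0):
    r = np.random.default_rng(seed)
    idx = [f"s{i:02d}" for i in range(46)]
    labels = pd.Series(["HS"] * 21 + ["HU"] * 25, index=idx)
    cov = pd.DataFrame({
        "filtered_volume_ml": r.normal(2600, 950, 46),
        "urea_mg_dl": r.normal(133, 33, 46),
    }, index=idx)
    y = pd.Series(r.normal(1.33, 0.26, 46), index=idx)
    y[labels == "HS"] += shift
    return y, labels, cov


def test_recovery_of_injected_shift():
    """CI covers the injected 0.25 shift in >=90% of 50 simulated cohorts."""
    hits = 0
    for seed in range(50):
        y, labels, cov = _fake_cohort(seed, shift=0.25)
        res = adjusted_group_difference(y, labels, cov)
        if res.ci95[0] <= 0.25 <= res.ci95[1]:
            hits += 1
    assert hits >= 45


def test_adjusted_close_to_unadjusted_when_covariates_inert():
    diffs = []
    for seed in range(20):
        y, labels, cov = _fake_cohort(seed, shift=0.3)
        adj = adjusted_group_difference(y, labels, cov, mode="fixed")
        raw = y[labels == "HS"].mean() - y[labels == "HU"].mean()
        diffs.append(adj.mean_diff - raw)
    assert abs(np.mean(diffs)) < 0.05


def test_adjusted_requires_min_group_size():
    y, labels, cov = _fake_cohort(0)
    small = labels.copy()
    small[:] = "HU"
    small[:2] = "HS"
    with pytest.raises(ValueError, match="3 subjects"):
        adjusted_group_difference(y, small, cov)


def test_bayes_ttest_end_to_end(rng):
    hs = rng.normal(1.5, 0.2, 21)
    hu = rng.normal(1.1, 0.25, 25)
    res = bayes_ttest(hs, hu)
    assert res.bf10 > 10
    assert res.replication_prob == pytest.approx(
        bf_to_probability(res.bf10))
    assert "H1" in res.evidence_class
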
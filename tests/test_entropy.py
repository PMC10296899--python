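"""Entropy metrics against brute-force oracles and algebraic identities."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dialhrv import (EntropyConfig, auc_mse, coarse_grain, fuzzy_entropy,
                     fuzzy_membership, mse_profile, sample_entropy)


# --- independent O(N^2) oracles (pure python, no shared code paths) --------

def sampen_oracle(x, m, r):
    n = len(x)
    nt = n - m
    a = b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return -math.log(a / b)


def fuzzyen_oracle(x, m, r, n_exp):
    def phi(mlen, nt):
        tot = 0.0
        cnt = 0
        for i in range(nt - 1):
            ti = [x[i + k] for k in range(mlen)]
            mi = sum(ti) / mlen
            for j in range(i + 1, nt):
                tj = [x[j + k] for k in range(mlen)]
                mj = sum(tj) / mlen
                d = max(abs((a - mi) - (b - mj)) for a, b in zip(ti, tj))
                tot += math.exp(-math.log(2.0) * (d / r) ** n_exp)
                cnt += 1
        return tot / cnt

    nt = len(x) - m
    return -math.log(phi(m + 1, nt - 1) / phi(m, nt))


# --- coarse graining -------------------------------------------------------

@pytest.mark.parametrize("x,tau,expected", [
    ([1, 2, 3, 4, 5, 6], 2, [1.5, 3.5, 5.5]),
    ([1, 2, 3, 4, 5, 6, 7], 3, [2.0, 5.0]),
])
def test_coarse_grain_examples(x, tau, expected):
    np.testing.assert_allclose(coarse_grain(np.array(x, float), tau), expected)


def test_coarse_grain_tau1_identity(rng):
    x = rng.standard_normal(100)
    np.testing.assert_array_equal(coarse_grain(x, 1), x)


def test_coarse_grain_rejects_bad_tau():
    with pytest.raises(ValueError):
        coarse_grain(np.arange(10.0), 0)


# --- sample entropy --------------------------------------------------------

def test_sampen_constant_series_is_zero():
    assert sample_entropy(np.full(50, 5.0), 2, 0.1) == 0.0


def test_sampen_matches_bruteforce_oracle(rng):
    x = rng.standard_normal(120)
    r = 0.2 * x.std()
    got = sample_entropy(x, 2, r)
    assert got == pytest.approx(sampen_oracle(x.tolist(), 2, r), abs=1e-12)


def test_sampen_m3_matches_oracle(rng):
    x = rng.standard_normal(150)
    r = 0.3 * x.std()
    got = sample_entropy(x, 3, r)
    assert got == pytest.approx(sampen_oracle(x.tolist(), 3, r), abs=1e-12)


def test_sampen_shift_invariant(rng):
    x = rng.standard_normal(200)
    r = 0.2 * x.std()
    assert sample_entropy(x + 1000.0, 2, r) == \
        pytest.approx(sample_entropy(x, 2, r), abs=1e-12)


def test_sampen_undefined_flagged_nan():
    x = np.arange(30.0)  # monotone ramp: no (m+1)-matches at tiny r
    with pytest.warns(UserWarning, match="undefined"):
        out = sample_entropy(x, 2, 1e-6)
    assert math.isnan(out)


# --- fuzzy entropy ---------------------------------------------------------

@pytest.mark.parametrize("d,r,n,expected", [
    (0.5, 0.5, 2.0, 0.5),
    (0.5, 0.5, 1.0, 0.5),
    (0.0, 0.3, 2.0, 1.0),
    (1.0, 0.5, 2.0, 1.0 / 16.0),
])
def test_fuzzy_membership_values(d, r, n, expected):
    assert fuzzy_membership(d, r, n) == pytest.approx(expected, abs=1e-4)


def test_fuzzyen_constant_series_is_zero():
    assert fuzzy_entropy(np.full(60, 3.0), 2, 0.1, 2.0) == pytest.approx(0.0)


def test_fuzzyen_matches_bruteforce_oracle(rng):
    x = rng.standard_normal(120)
    r = 0.2 * x.std()
    got = fuzzy_entropy(x, 2, r, 2.0)
    assert got == pytest.approx(fuzzyen_oracle(x.tolist(), 2, r, 2.0),
                                abs=1e-12)


def test_fuzzyen_scale_and_shift_invariance(rng):
    x = rng.standard_normal(150)
    r = 0.2 * x.std()
    ref = fuzzy_entropy(x, 2, r, 2.0)
    assert fuzzy_entropy(5.0 * x, 2, 5.0 * r, 2.0) == pytest.approx(ref, abs=1e-10)
    assert fuzzy_entropy(x + 77.0, 2, r, 2.0) == pytest.approx(ref, abs=1e-10)


# --- AUC indices -----------------------------------------------------------

def test_auc_constant_profile():
    prof = {t: 1.3 for t in range(1, 21)}
    assert auc_mse(prof, 6, 20) == pytest.approx(1.3 * 14)
    assert auc_mse(prof, 1, 20) == pytest.approx(1.3 * 19)


def test_auc_additivity_identity(rng):
    vals = rng.uniform(0.5, 2.0, 20)
    prof = {t + 1: vals[t] for t in range(20)}
    bridge = (prof[5] + prof[6]) / 2.0
    assert auc_mse(prof, 1, 20) == pytest.approx(
        auc_mse(prof, 1, 5) + bridge + auc_mse(prof, 6, 20), abs=1e-12)


@given(st.integers(0, 1000))
def test_auc_linearity(seed):
    r = np.random.default_rng(seed)
    a = {t: float(v) for t, v in enumerate(r.uniform(0, 2, 20), start=1)}
    b = {t: float(v) for t, v in enumerate(r.uniform(0, 2, 20), start=1)}
    mixed = {t: 0.3 * a[t] + 0.7 * b[t] for t in a}
    assert auc_mse(mixed, 1, 20) == pytest.approx(
        0.3 * auc_mse(a, 1, 20) + 0.7 * auc_mse(b, 1, 20), abs=1e-9)


def test_auc_rejects_bad_range():
    prof = {t: 1.0 for t in range(1, 21)}
    with pytest.raises(ValueError):
        auc_mse(prof, 6, 6)


# --- profile ---------------------------------------------------------------

def test_profile_scale1_equals_plain_sampen(rng):
    x = rng.standard_normal(2500)
    prof = mse_profile(x, EntropyConfig(max_scale=5))
    r = 0.2 * np.std(x)
    assert prof.sampen_by_scale[1] == sample_entropy(x, 2, r)


def test_profile_auc_consistency(rng):
    x = 800 + 50 * rng.standard_normal(3000)
    prof = mse_profile(x)
    assert prof.defined
    assert prof.auc_1_20 == pytest.approx(
        auc_mse(prof.sampen_by_scale, 1, 20))
    bridge = (prof.sampen_by_scale[5] + prof.sampen_by_scale[6]) / 2.0
    assert prof.auc_1_20 == pytest.approx(
        prof.auc_1_5 + bridge + prof.auc_6_20, abs=1e-10)


def test_profile_warns_on_short_series(rng):
    x = rng.standard_normal(1200)
    with pytest.warns(UserWarning, match="short"):
        mse_profile(x, EntropyConfig(max_scale=5))


def test_profile_rejects_constant_series():
    with pytest.raises(ValueError, match="constant"):
        mse_profile(np.full(3000, 800.0))
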
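"""Skellam statistics against brute-force oracles, and the calling rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tssatlas.core import EndProfile
from tssatlas.tss_detection import (
    DetectionParams,
    RateEstimate,
    call_tss,
    estimate_rates,
    skellam_pmf,
    skellam_sf,
)


def convolution_sf(d, lam1, lam2, trunc=400):
    """Independent oracle: P(N1 - N2 >= d) by truncated double-Poisson convolution."""
    k = np.arange(trunc)
    p1 = stats.poisson.pmf(k, lam1)
    p2 = stats.poisson.pmf(k, lam2)
    tail1 = np.concatenate([np.cumsum(p1[::-1])[::-1], [0.0]])  # tail1[i] = P(N1 >= i)
    return float(sum(p2[j] * tail1[min(max(d + j, 0), trunc)] for j in range(trunc)))


def test_poisson_limit_and_degenerate_masses():
    assert skellam_sf(1, 1.0, 0.0) == pytest.approx(1 - np.exp(-1), abs=1e-9)
    assert skellam_sf(1, 0.0, 0.0) == 0.0
    assert skellam_sf(0, 0.0, 0.0) == 1.0
    assert skellam_sf(0, 5.0, 5.0) == pytest.approx(0.563917, abs=1e-6)
    assert skellam_pmf(0, 0.0, 0.0) == 1.0
    # difference of nothing minus Poisson is never positive
    assert skellam_sf(1, 0.0, 3.0) == 0.0
    assert skellam_sf(-2, 0.0, 3.0) == pytest.approx(stats.poisson.cdf(2, 3.0))


def test_negative_rate_rejected():
    with pytest.raises(ValueError, match="negative rate"):
        skellam_sf(0, -1.0, 2.0)


@pytest.mark.parametrize("lam1", [0.1, 1.0, 5.0, 20.0])
@pytest.mark.parametrize("lam2", [0.1, 5.0])
def test_sf_matches_convolution_oracle(lam1, lam2):
    for d in range(-30, 31, 5):
        assert skellam_sf(d, lam1, lam2) == pytest.approx(
            convolution_sf(d, lam1, lam2), abs=1e-9
        )


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    lam1=st.floats(0.0, 50.0),
    lam2=st.floats(0.0, 50.0),
    d=st.integers(-60, 60),
)
def test_sf_monotone_and_complements_lower_mass(lam1, lam2, d):
    assert skellam_sf(d, lam1, lam2) >= skellam_sf(d + 1, lam1, lam2) - 1e-12
    below = np.arange(d - 300, d)
    mass_below = float(np.sum(skellam_pmf(below, lam1, lam2)))
    assert skellam_sf(d, lam1, lam2) + mass_below == pytest.approx(1.0, abs=1e-7)


# ---------------------------------------------------------------------------
# rate estimation
# ---------------------------------------------------------------------------

def _profile(counts, strand="+", kind="plus_lib"):
    return EndProfile(replicon="chr", strand=strand, counts=counts, library_kind=kind)


def test_rate_is_mean_over_nonzero_union():
    plus = _profile({10: 10, 20: 20, 30: 30})
    minus = _profile({}, kind="minus_lib")
    est = estimate_rates(plus, minus)
    assert est.lambda_plus == 20.0
    assert est.lambda_minus == 0.0
    assert not est.flagged


def test_empty_profiles_flagged_zero_rates():
    est = estimate_rates(_profile({}), _profile({}, kind="minus_lib"))
    assert (est.lambda_plus, est.lambda_minus, est.flagged) == (0.0, 0.0, True)


def test_rate_recovers_poisson_parameter():
    rng = np.random.default_rng(0)
    n = 10_000
    draws_p = rng.poisson(5.0, n)
    draws_m = rng.poisson(5.0, n)
    either = (draws_p > 0) | (draws_m > 0)
    plus = _profile({i + 1: int(c) for i, c in enumerate(draws_p) if c > 0})
    minus = _profile(
        {i + 1: int(c) for i, c in enumerate(draws_m) if c > 0}, kind="minus_lib"
    )
    est = estimate_rates(plus, minus)
    # oracle: mean over union of nonzero positions; at lambda=5 virtually all
    # positions are transcribed, so the estimate approaches the true rate
    se = np.sqrt(5.0 / either.sum())
    assert abs(est.lambda_plus - draws_p[either].mean()) < 1e-12
    assert abs(est.lambda_plus - 5.0) <= 4 * se


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def test_empty_profiles_no_calls():
    assert call_tss(_profile({}), _profile({}, kind="minus_lib")) == []


def test_single_strong_site_called():
    plus = _profile({500: 50})
    minus = _profile({500: 2}, kind="minus_lib")
    calls = call_tss(plus, minus, DetectionParams(), rates=RateEstimate(0.5, 0.4))
    assert len(calls) == 1
    c = calls[0]
    assert (c.position, c.k_plus, c.k_minus) == (500, 50, 2)
    assert c.p_value <= 1e-6


def test_merge_keeps_largest_diff():
    plus = _profile({100: 40, 101: 30})
    minus = _profile({}, kind="minus_lib")
    calls = call_tss(plus, minus, DetectionParams(merge=1), rates=RateEstimate(0.5, 0.4))
    assert [c.position for c in calls] == [100]
    assert calls[0].k_plus == 40


def test_merge_tie_resolves_five_prime_most():
    rates = RateEstimate(0.5, 0.4)
    plus_f = _profile({100: 40, 101: 40})
    calls = call_tss(plus_f, _profile({}, kind="minus_lib"), DetectionParams(), rates=rates)
    assert [c.position for c in calls] == [100]
    plus_r = _profile({100: 40, 101: 40}, strand="-")
    minus_r = _profile({}, strand="-", kind="minus_lib")
    calls = call_tss(plus_r, minus_r, DetectionParams(), rates=rates)
    assert [c.position for c in calls] == [101]


def test_below_noise_or_nonpositive_diff_never_candidates():
    plus = _profile({100: 9, 200: 50})
    minus = _profile({200: 60}, kind="minus_lib")
    calls = call_tss(plus, minus, DetectionParams(), rates=RateEstimate(0.1, 0.1))
    assert calls == []


def test_fold_gate_blocks_balanced_high_coverage_site():
    """Equal "+"/"−" counts (a processed 5' end) must not be called even when
    Poisson jitter makes the count difference nominally significant."""
    plus = _profile({300: 520})
    minus = _profile({300: 480}, kind="minus_lib")
    rates = RateEstimate(2.0, 1.5)
    assert call_tss(plus, minus, DetectionParams(), rates=rates) == []
    # the literal Skellam rule alone would call it
    literal = call_tss(plus, minus, DetectionParams(min_fold=None), rates=rates)
    assert [c.position for c in literal] == [300]


def test_mismatched_tracks_rejected():
    with pytest.raises(ValueError, match="mismatched"):
        call_tss(_profile({1: 10}), _profile({}, strand="-", kind="minus_lib"))


def test_windowed_policy_calls_isolated_peak():
    rng = np.random.default_rng(1)
    bg = {int(p): 1 for p in rng.choice(np.arange(1, 5000), 400, replace=False)}
    plus_counts = dict(bg)
    plus_counts[2500] = plus_counts.get(2500, 0) + 200
    plus = _profile(plus_counts)
    minus = _profile(dict(bg), kind="minus_lib")
    calls = call_tss(plus, minus, DetectionParams(rate_policy="windowed", window=500))
    assert 2500 in [c.position for c in calls]
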
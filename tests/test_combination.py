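"""Inverse-normal combination, multiplicity adjustments and closed testing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from asrt.combination import (inverse_normal_combine, dunnett_adjusted_p,
                              stage1_intersection_p, friede_decision,
                              PClampWarning)
from asrt.selection import SelectionResult
from asrt.survival import ScoreResult

W = (np.sqrt(0.5), np.sqrt(0.5))


def _score(z, V=100.0):
    return ScoreResult(u=z * np.sqrt(V), V=V)


def test_neutral_pvalues_combine_to_half():
    assert inverse_normal_combine(0.5, 0.5, 0.543, np.sqrt(1 - 0.543 ** 2)) \
        == pytest.approx(0.5, abs=1e-12)


def test_equal_weights_borderline_pair():
    got = inverse_normal_combine(0.025, 0.025, *W)
    assert got == pytest.approx(norm.sf(norm.isf(0.025) * np.sqrt(2)),
                                abs=1e-12)
    assert got == pytest.approx(0.002787, abs=5e-6)


def test_combination_strictly_monotone():
    grid = np.linspace(0.01, 0.99, 25)
    vals = [inverse_normal_combine(0.3, p2, *W) for p2 in grid]
    assert np.all(np.diff(vals) > 0)


def test_boundary_pvalue_clamped_with_warning():
    with pytest.warns(PClampWarning):
        v = inverse_normal_combine(1.0, 0.5, *W)
    assert 0 < v < 1


def test_invalid_weights_rejected():
    with pytest.raises(ValueError):
        inverse_normal_combine(0.5, 0.5, 0.9, 0.9)


# --- Dunnett-type adjustment ---------------------------------------------

def test_dunnett_reduces_to_univariate():
    assert dunnett_adjusted_p(norm.isf(0.05), 1, 0.5) == pytest.approx(
        0.05, abs=1e-10)


def test_dunnett_independent_pair_factorizes():
    z = norm.isf(0.05)
    assert dunnett_adjusted_p(z, 2, 0.0) == pytest.approx(1 - 0.95 ** 2,
                                                          abs=1e-10)


def test_dunnett_matches_monte_carlo():
    z, k, rho = 1.95996, 2, 0.5
    rng = np.random.default_rng(5)
    n = 2_000_000
    shared = rng.standard_normal(n)
    own = rng.standard_normal((k, n))
    zs = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
    p_mc = (zs.max(axis=0) > z).mean()
    se = np.sqrt(p_mc * (1 - p_mc) / n)
    assert abs(dunnett_adjusted_p(z, k, rho) - p_mc) < 3 * se


def test_dunnett_decreasing_in_rho():
    vals = [dunnett_adjusted_p(1.8, 3, r) for r in (0.0, 0.2, 0.5, 0.8)]
    assert np.all(np.diff(vals) < 0)


# --- Stage-1 intersection p-values ---------------------------------------

def test_singleton_intersection_definitions():
    z = 1.3
    assert stage1_intersection_p([z], "holm") == pytest.approx(norm.sf(z))
    assert stage1_intersection_p([z], "dunnett", rho=0.5) == pytest.approx(
        norm.sf(z), abs=1e-10)
    assert stage1_intersection_p([z], "bonferroni", n_arms_total=2) == \
        pytest.approx(min(1, 2 * norm.sf(z)))


def test_holm_two_arm_example():
    assert stage1_intersection_p([2.0, 1.0], "holm") == pytest.approx(
        min(1, 2 * norm.sf(2.0)), abs=1e-12)
    assert stage1_intersection_p([2.0, 1.0], "holm") == pytest.approx(
        0.0455, abs=5e-5)


@settings(max_examples=40, derandomize=True)
@given(z=st.lists(st.floats(-3, 4), min_size=1, max_size=4),
       rho=st.floats(0.0, 0.9))
def test_dunnett_never_exceeds_holm(z, rho):
    assert stage1_intersection_p(z, "dunnett", rho=rho) <= \
        stage1_intersection_p(z, "holm") + 1e-12


def test_combined_p_is_uniform_under_null():
    """p-clud calibration: independent U(0,1) stagewise p's give P(C<=a)=a."""
    rng = np.random.default_rng(11)
    n = 200_000
    c = norm.sf(W[0] * norm.isf(rng.random(n)) + W[1] * norm.isf(rng.random(n)))
    for a in (0.01, 0.05, 0.2):
        assert (c <= a).mean() == pytest.approx(a, abs=3 * np.sqrt(a / n) + 1e-3)


# --- closed testing -------------------------------------------------------

def _selection(arm, G):
    rates = tuple(0.5 if g != arm else 0.6 for g in range(1, G + 1))
    return SelectionResult(selected=frozenset({arm}), response_rates=rates,
                           response_counts=tuple(int(r * 50) for r in rates))


def test_single_hypothesis_reduces_to_plain_combination():
    s1 = {1: _score(1.8)}
    s2 = _score(2.0)
    dec = friede_decision(s1, s2, _selection(1, 1), W, alpha=0.05,
                          method="holm")
    direct = inverse_normal_combine(norm.sf(1.8), norm.sf(2.0), *W)
    assert len(dec.intersections) == 1
    assert dec.intersections[0].combined_p == pytest.approx(direct)
    assert dec.reject_selected == (direct <= 0.05)


def test_stage1_dominance_can_carry_rejection():
    # overwhelming Stage-1 evidence with neutral Stage 2 still rejects
    s1 = {1: _score(8.0), 2: _score(7.5)}
    dec = friede_decision(s1, _score(0.0), _selection(1, 2),
                          (0.543, np.sqrt(1 - 0.543 ** 2)), method="dunnett")
    assert dec.reject_selected


def test_closed_test_requires_all_intersections():
    # strong elementary evidence but a poor partner arm cannot unreject H_S;
    # a *weak* elementary z must block rejection even if the max is large
    s1 = {1: _score(0.2), 2: _score(3.5)}
    s2 = _score(1.8)
    dec = friede_decision(s1, s2, _selection(1, 2), W, method="holm")
    elementary = [t for t in dec.intersections if t.index_set == {1}][0]
    full = [t for t in dec.intersections if t.index_set == {1, 2}][0]
    assert full.rejected  # the joint evidence alone would reject
    assert not elementary.rejected
    assert not dec.reject_selected


@pytest.mark.filterwarnings("ignore::asrt.combination.PClampWarning")
def test_method_rejection_ordering_on_random_data():
    """Per dataset: Dunnett rejects whenever Holm does, Holm whenever Bonferroni."""
    rng = np.random.default_rng(17)
    order = []
    for _ in range(300):
        s1 = {g: _score(rng.normal(1.5, 1)) for g in (1, 2)}
        s2 = _score(rng.normal(1.5, 1))
        sel = _selection(int(rng.integers(1, 3)), 2)
        dec = {m: friede_decision(s1, s2, sel, W, method=m).reject_selected
               for m in ("bonferroni", "holm", "dunnett")}
        assert dec["holm"] >= dec["bonferroni"]
        assert dec["dunnett"] >= dec["holm"]
        order.append(dec)
    assert any(d["dunnett"] for d in order)  # the comparison was exercised


def test_missing_stage2_score_is_an_error():
    with pytest.raises(ValueError):
        friede_decision({1: _score(1.0)}, None, _selection(1, 1), W)
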
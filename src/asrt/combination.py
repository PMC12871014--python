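"""Inverse-normal combination test and closed testing for the comparator method.

This is the conventional analysis of a two-stage adaptive seamless design with
treatment selection (Friede-style): stagewise one-sided p-values for each
intersection hypothesis are merged with the weighted inverse-normal rule

    C(p1, p2) = 1 - Phi(w1 * Phi^{-1}(1 - p1) + w2 * Phi^{-1}(1 - p2)),

and the elementary hypothesis of the selected arm is rejected only if every
intersection hypothesis containing it is rejected at level alpha (closed
testing, strong FWER control).  Stage-1 intersection p-values adjust for the
many-to-one multiplicity with a Bonferroni, Holm or Dunnett-type rule on the
maximum standardized statistic; the Stage-2 p-value of an intersection is the
selected arm's Stage-2 p-value.

The Dunnett adjustment uses the exact equicoordinate probability of ``k``
equicorrelated standard normals, evaluated by deterministic one-dimensional
Gauss-Hermite-style quadrature over the shared latent factor.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm

from .survival import ScoreResult
from .selection import SelectionResult

__all__ = [
    "IntersectionTest",
    "ClosedTestDecision",
    "inverse_normal_combine",
    "dunnett_adjusted_p",
    "stage1_intersection_p",
    "friede_decision",
    "friede_decision_multi",
    "PClampWarning",
]

#: clamp for Phi^{-1} stability; invisible at any practical alpha
_P_CLAMP = 1e-12


class PClampWarning(UserWarning):
    """A stagewise p-value of exactly 0 or 1 was clamped before Phi^{-1}."""


@dataclass(frozen=True)
class IntersectionTest:
    index_set: frozenset
    stage1_p: float
    stage2_p: float
    combined_p: float
    rejected: bool


@dataclass(frozen=True)
class ClosedTestDecision:
    selected_arm: int
    intersections: tuple
    reject_selected: bool


def _clamp_p(p):
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn(
            "p-value at or beyond the open interval (0,1); clamped for Phi^{-1}",
            PClampWarning,
            stacklevel=3,
        )
    return float(np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP))


def inverse_normal_combine(p1, p2, w1, w2):
    """Weighted inverse-normal combination of two stagewise one-sided p-values."""
    if not np.isclose(w1 * w1 + w2 * w2, 1.0, atol=1e-9):
        raise ValueError("weights must satisfy w1**2 + w2**2 = 1")
    if not (0 < w1 < 1 and 0 < w2 < 1):
        raise ValueError("weights must lie strictly in (0, 1)")
    z = w1 * norm.isf(_clamp_p(p1)) + w2 * norm.isf(_clamp_p(p2))
    return float(norm.sf(z))


def dunnett_adjusted_p(z_max, k, rho=0.5):
    """One-sided Dunnett-type p-value for the max of k equicorrelated normals.

    ``1 - P(max(Z_1..Z_k) <= z_max)`` with common pairwise correlation
    ``rho``; the equicoordinate probability is the 1-D integral
    ``int phi(x) Phi((z - sqrt(rho) x)/sqrt(1-rho))^k dx``.
    """
    k = int(k)
    if k < 1:
        raise ValueError("k must be a positive integer")
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    if k == 1:
        return float(norm.sf(z_max))
    if rho == 0:
        return float(1.0 - norm.cdf(z_max) ** k)
    sr, sc = np.sqrt(rho), np.sqrt(1.0 - rho)

    def integrand(x):
        return norm.pdf(x) * norm.cdf((z_max - sr * x) / sc) ** k

    prob, _ = quad(integrand, -9.0, 9.0, epsabs=1e-11, epsrel=1e-11, limit=200)
    return float(min(max(1.0 - prob, 0.0), 1.0))


def stage1_intersection_p(z_values, method, rho=0.5, n_arms_total=None):
    """Adjusted Stage-1 p-value for the intersection hypothesis over ``z_values``.

    ``dunnett``: equicoordinate adjustment of max z at the intersection size.
    ``holm``: closed-test shortcut factor |I| on the max-z p-value.
    ``bonferroni``: the single-step factor G (total arm count) for every I.
    """
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise ValueError("empty intersection")
    k = z.size
    zmax = float(z.max())
    if method == "dunnett":
        return dunnett_adjusted_p(zmax, k, rho)
    if method == "holm":
        return float(min(1.0, k * norm.sf(zmax)))
    if method == "bonferroni":
        G = n_arms_total if n_arms_total is not None else k
        return float(min(1.0, G * norm.sf(zmax)))
    raise ValueError(f"unknown multiplicity method {method!r}")


def friede_decision(stage1_scores, stage2_score, selected, weights,
                    alpha=0.05, method="dunnett", rho=0.5) -> ClosedTestDecision:
    """Closed combination test for the single selected arm.

    Parameters
    ----------
    stage1_scores : dict arm -> ScoreResult (Stage-1 data, all G arms).
    stage2_score : ScoreResult of the selected arm on Stage-2 data only.
    selected : SelectionResult with exactly one arm.
    weights : (w1, w2).
    """
    if isinstance(selected, SelectionResult):
        sel = selected.selected
    else:
        sel = frozenset(selected)
    if len(sel) != 1:
        raise ValueError("closed-test path requires exactly one selected arm")
    (s,) = sel
    if stage2_score is None:
        raise ValueError("Stage-2 score for the selected arm is required")
    G = len(stage1_scores)
    arms = sorted(stage1_scores)
    others = [a for a in arms if a != s]
    w1, w2 = weights
    p2 = stage2_score.p_one_sided
    tests = []
    reject_all = True
    for r in range(len(others) + 1):
        for extra in itertools.combinations(others, r):
            index_set = frozenset({s, *extra})
            z_I = [stage1_scores[a].z for a in index_set]
            p1 = stage1_intersection_p(z_I, method, rho=rho, n_arms_total=G)
            cp = inverse_normal_combine(p1, p2, w1, w2)
            rej = cp <= alpha
            reject_all &= rej
            tests.append(IntersectionTest(index_set, p1, p2, cp, rej))
    return ClosedTestDecision(selected_arm=s, intersections=tuple(tests),
                              reject_selected=reject_all)


def _stage2_intersection_p(z_sel, method, rho):
    """Stage-2 p for an intersection: adjustment over its selected arms."""
    z = np.asarray(z_sel, dtype=float)
    k = z.size
    zmax = float(z.max())
    if method == "dunnett":
        return dunnett_adjusted_p(zmax, k, rho)
    # Bonferroni and Holm both reduce to the |I ∩ l| factor here: Stage 2
    # only ever tests the selected arms.
    return float(min(1.0, k * norm.sf(zmax)))


def friede_decision_multi(stage1_scores, stage2_scores, selected, weights,
                          alpha=0.05, method="dunnett", rho=0.5):
    """Closed combination test when more than one arm was selected.

    Extension of the single-selection comparator: for each intersection I the
    Stage-2 p-value applies the same adjustment family to the Stage-2
    statistics of the selected arms in I.  Returns ``{arm: rejected}`` for
    every selected arm.
    """
    sel = selected.selected if isinstance(selected, SelectionResult) else frozenset(selected)
    G = len(stage1_scores)
    arms = sorted(stage1_scores)
    w1, w2 = weights
    combined = {}
    for r in range(1, G + 1):
        for index_set in itertools.combinations(arms, r):
            I = frozenset(index_set)
            overlap = sorted(I & sel)
            if not overlap:
                continue
            z_I = [stage1_scores[a].z for a in I]
            p1 = stage1_intersection_p(z_I, method, rho=rho, n_arms_total=G)
            p2 = _stage2_intersection_p([stage2_scores[a].z for a in overlap],
                                        method, rho)
            combined[I] = inverse_normal_combine(p1, p2, w1, w2) <= alpha
    return {
        a: all(rej for I, rej in combined.items() if a in I)
        for a in sorted(sel)
    }
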
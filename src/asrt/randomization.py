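"""Conditional randomization inference for the adaptive seamless design.

The Stage-1 evidence of the selected arm enters the final combination test as
a p-value *conditional on the selection event*, computed from the
rerandomization distribution of the Stage-1 log-rank statistic: subjects'
(response, survival) outcomes are frozen and their group labels are repeatedly
reallocated at the fixed Stage-1 group sizes; in each reallocation the
pre-specified selection rule is re-applied, and only reallocations that
reproduce the observed selection event contribute.  The conditional p-value is

    p = #{reallocations i : Z^(i) >= z_obs and selection event matches}
        / #{reallocations i : selection event matches}

with the inclusive tie convention.  When the number of distinct allocations M
is small the sum runs over all of them (exact mode); otherwise it is
approximated by M* Monte-Carlo draws.  Conditioning restores the uniform null
distribution of the Stage-1 p-value that marginal post-selection p-values
lack, which is what removes the conservatism of the unconditional
combination-test analysis.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .survival import SortedSurvival
from .selection import SelectionRule, SelectionResult, select_batch
from .combination import inverse_normal_combine, dunnett_adjusted_p, PClampWarning

__all__ = [
    "Stage1Dataset",
    "RandomizationResult",
    "AsrtDecision",
    "rerandomize",
    "enumerate_allocations",
    "count_allocations",
    "conditional_p",
    "asrt_decision",
    "ZeroNumeratorWarning",
    "LowSelectionCountWarning",
    "SelectionEventError",
]

#: hard cap on exhaustive enumeration
ENUMERATION_GUARD = 10**6
#: warn when fewer matching rerandomizations than this support the p-value
MIN_SELECTING = 50
#: slack for the inclusive >= comparison of recomputed floats
_Z_TIE_EPS = 1e-12


class ZeroNumeratorWarning(UserWarning):
    """No rerandomized statistic reached the observed one; p = 0 reported."""


class LowSelectionCountWarning(UserWarning):
    """Few rerandomizations matched the selection event; p-value is coarse."""


class SelectionEventError(RuntimeError):
    """No rerandomization reproduced the selection event."""


@dataclass(frozen=True)
class Stage1Dataset:
    """Stage-1 subject outcomes with their observed allocation.

    ``assignment`` holds labels 0 (control) .. G; ``group_sizes`` is
    ``(N_{0,1}, N_{1,1}, ..., N_{G,1})`` and must match the assignment counts.
    """

    response: np.ndarray
    surv_time: np.ndarray
    event: np.ndarray
    assignment: np.ndarray
    group_sizes: tuple

    def __post_init__(self):
        r = np.asarray(self.response, dtype=np.int64)
        t = np.asarray(self.surv_time, dtype=float)
        e = np.asarray(self.event, dtype=np.int64)
        a = np.asarray(self.assignment, dtype=np.int64)
        n = r.size
        if not (t.size == e.size == a.size == n):
            raise ValueError("all subject-level arrays must have equal length")
        if not np.isin(r, (0, 1)).all():
            raise ValueError("Stage-1 responses must be observed and binary")
        sizes = tuple(int(s) for s in self.group_sizes)
        counts = np.bincount(a, minlength=len(sizes))
        if counts.size != len(sizes) or tuple(counts) != sizes:
            raise ValueError("assignment counts do not match group_sizes")
        for name, arr in (("response", r), ("surv_time", t),
                          ("event", e), ("assignment", a)):
            object.__setattr__(self, name if name != "surv_time" else "surv_time", arr)
        object.__setattr__(self, "group_sizes", sizes)

    @property
    def n_subjects(self) -> int:
        return int(self.response.size)

    @property
    def n_arms(self) -> int:
        return len(self.group_sizes) - 1


@dataclass(frozen=True)
class RandomizationResult:
    z_observed: float
    n_rerandomizations: int
    n_selecting: int
    n_at_least: int
    conditional_p: float
    exhaustive: bool


@dataclass(frozen=True)
class AsrtDecision:
    """Per-arm outcome of the conditional randomization analysis."""

    conditional_p: dict
    stage2_p: dict
    combined_p: dict
    reject: dict
    n_selecting: int
    n_rerandomizations: int
    exhaustive: bool


def rerandomize(data: Stage1Dataset, rng) -> np.ndarray:
    """One uniformly random reallocation of subjects at the fixed group sizes."""
    template = np.repeat(np.arange(len(data.group_sizes)), data.group_sizes)
    return template[rng.permutation(data.n_subjects)]


def count_allocations(group_sizes) -> int:
    """Multinomial number of distinct allocations, N! / prod(N_g!)."""
    sizes = [int(s) for s in group_sizes]
    if any(s < 0 for s in sizes):
        raise ValueError("group sizes must be nonnegative")
    M = math.factorial(sum(sizes))
    for s in sizes:
        M //= math.factorial(s)
    return M


def enumerate_allocations(group_sizes, guard=ENUMERATION_GUARD) -> np.ndarray:
    """All distinct allocations as an (M, N) label matrix, each exactly once."""
    sizes = [int(s) for s in group_sizes]
    N = sum(sizes)
    M = count_allocations(sizes)
    if M > guard:
        raise ValueError(
            f"{M} allocation patterns exceed the enumeration guard ({guard}); "
            "use Monte-Carlo mode"
        )
    out = np.empty((M, N), dtype=np.int8)
    row = 0

    def fill(remaining, g, partial):
        nonlocal row
        if g == len(sizes) - 1:
            pattern = partial.copy()
            pattern[list(remaining)] = g
            out[row] = pattern
            row += 1
            return
        for chosen in itertools.combinations(remaining, sizes[g]):
            nxt = partial.copy()
            nxt[list(chosen)] = g
            fill([i for i in remaining if i not in set(chosen)], g + 1, nxt)

    fill(list(range(N)), 0, np.empty(N, dtype=np.int8))
    assert row == M
    return out


def _batch_assignments_mc(data, b, rng):
    template = np.repeat(
        np.arange(len(data.group_sizes), dtype=np.int8), data.group_sizes
    )
    keys = rng.random((b, data.n_subjects))
    perm = np.argsort(keys, axis=1)
    A = np.empty((b, data.n_subjects), dtype=np.int8)
    np.put_along_axis(A, perm, np.broadcast_to(template, (b, data.n_subjects)), axis=1)
    return A


def _response_counts(A, responses, n_arms):
    """(B, G) response counts of the treatment arms under each assignment row."""
    counts = np.empty((A.shape[0], n_arms), dtype=np.int64)
    r = responses.astype(np.int64)
    for g in range(1, n_arms + 1):
        counts[:, g - 1] = ((A == g) * r).sum(axis=1)
    return counts


def _z_for_arm(ss: SortedSurvival, A, arm):
    inc = (A == arm) | (A == 0)
    trt = A == arm
    u, V = ss.score(inc, trt)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(V > 0, u / np.sqrt(np.where(V > 0, V, 1.0)), 0.0)


def _run(data, rule, targets, event_set, mode, n_iter, rng, batch_size=1000):
    """Shared rerandomization pass; returns per-target (n_at_least,), n_match, total."""
    ss = SortedSurvival(data.surv_time, data.event)
    sizes = np.asarray(data.group_sizes)
    G = data.n_arms
    event_mask = np.zeros(G, dtype=bool)
    event_mask[[t - 1 for t in event_set]] = True

    # observed statistic per target, through the identical numeric path
    A_obs = data.assignment[None, :]
    z_obs = {k: float(_z_for_arm(ss, A_obs, k)[0]) for k in targets}

    exhaustive = mode == "exact"
    if exhaustive:
        patterns = enumerate_allocations(data.group_sizes)
        total = patterns.shape[0]
    else:
        total = int(n_iter)

    n_match = 0
    n_ge = {k: 0 for k in targets}
    done = 0
    while done < total:
        b = min(batch_size, total - done)
        if exhaustive:
            A = patterns[done: done + b]
        else:
            A = _batch_assignments_mc(data, b, rng)
        counts = _response_counts(A, data.response, G)
        mask = select_batch(counts, sizes[1:], rule, rng)
        match = (mask == event_mask[None, :]).all(axis=1)
        rows = np.flatnonzero(match)
        n_match += rows.size
        if rows.size:
            A_m = A[rows]
            for k in targets:
                z = _z_for_arm(ss, A_m, k)
                n_ge[k] += int((z >= z_obs[k] - _Z_TIE_EPS).sum())
        done += b
    return z_obs, n_ge, n_match, total, exhaustive


def conditional_p(data: Stage1Dataset, selection_rule: SelectionRule, target: int,
                  z_observed=None, selected_set=None, mode="monte_carlo",
                  n_iter=5000, rng=None,
                  min_selecting=MIN_SELECTING) -> RandomizationResult:
    """Conditional p-value of arm ``target`` given the observed selection event.

    Under the single rule the event is ``{selection} == {target}``; under the
    multi rule it is exact equality of the selected *set* with
    ``selected_set`` (which must contain ``target``).  ``mode='exact'``
    enumerates every allocation (guarded); ``mode='monte_carlo'`` samples
    ``n_iter`` reallocations.  The selection tie-break is re-drawn per
    rerandomization from ``rng``, so exact mode marginalises ties only
    empirically, one realisation per pattern.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if selection_rule.rule == "single":
        event_set = frozenset({int(target)})
    else:
        if selected_set is None:
            raise ValueError("multi rule needs the observed selected_set")
        event_set = frozenset(int(a) for a in selected_set)
        if target not in event_set:
            raise ValueError("target must belong to the observed selected set")
    if mode not in ("exact", "monte_carlo"):
        raise ValueError(f"unknown mode {mode!r}")

    z_obs_map, n_ge, n_match, total, exhaustive = _run(
        data, selection_rule, (int(target),), event_set, mode, n_iter, rng
    )
    z_obs = z_obs_map[int(target)] if z_observed is None else float(z_observed)
    if z_observed is not None and not np.isclose(z_obs, z_obs_map[int(target)],
                                                 atol=1e-9):
        raise ValueError(
            "z_observed does not match the statistic recomputed from the "
            "observed assignment"
        )
    return _to_result(z_obs, n_ge[int(target)], n_match, total, exhaustive,
                      min_selecting)


def _to_result(z_obs, n_ge, n_match, total, exhaustive, min_selecting):
    if n_match == 0:
        raise SelectionEventError(
            f"selection event matched in 0 of {total} rerandomizations; "
            "increase M* or reconsider the conditioning event"
        )
    if n_match < min_selecting:
        warnings.warn(
            f"only {n_match} of {total} rerandomizations matched the selection "
            "event; conditional p-value is coarse",
            LowSelectionCountWarning,
            stacklevel=3,
        )
    if n_ge == 0:
        warnings.warn(
            "no rerandomized statistic reached the observed value; reporting "
            "conditional p = 0 (consider a larger M*)",
            ZeroNumeratorWarning,
            stacklevel=3,
        )
    return RandomizationResult(
        z_observed=float(z_obs),
        n_rerandomizations=int(total),
        n_selecting=int(n_match),
        n_at_least=int(n_ge),
        conditional_p=n_ge / n_match,
        exhaustive=bool(exhaustive),
    )


def _holm_reject(pvals, alpha):
    """Step-down Holm decisions for a dict arm -> p."""
    arms = sorted(pvals, key=lambda a: pvals[a])
    m = len(arms)
    reject = {}
    alive = True
    for j, a in enumerate(arms):
        alive = alive and pvals[a] <= alpha / (m - j)
        reject[a] = alive
    return reject


def asrt_decision(stage1: Stage1Dataset, stage2_scores, selection: SelectionResult,
                  weights, alpha=0.05, n_iter=5000, multi_method="dunnett",
                  rng=None, mode="monte_carlo", dunnett_rho=0.5,
                  min_selecting=MIN_SELECTING) -> AsrtDecision:
    """Final-analysis decision of the adaptive seamless randomization test.

    Single selection: reject H_k iff ``C(p_cond, p_{k,2}) <= alpha``.  Multiple
    selection: the per-arm combination p-values (conditional on the exact
    selected set) are tested with the chosen multiplicity rule at level
    ``alpha``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sel = tuple(sorted(selection.selected))
    rule = _rule_from_selection(selection)
    for k in sel:
        if stage2_scores.get(k) is None:
            raise ValueError(f"missing Stage-2 score for selected arm {k}")
    w1, w2 = weights
    event_set = frozenset(sel)
    z_obs, n_ge, n_match, total, exhaustive = _run(
        stage1, rule, sel, event_set, mode, n_iter, rng
    )
    if n_match == 0:
        raise SelectionEventError(
            f"selection event matched in 0 of {total} rerandomizations"
        )
    cond = {k: n_ge[k] / n_match for k in sel}
    p2 = {k: stage2_scores[k].p_one_sided for k in sel}
    with warnings.catch_warnings():
        # a conditional p of exactly 0 is legitimate here (see module notes)
        warnings.simplefilter("ignore", PClampWarning)
        comb = {k: inverse_normal_combine(cond[k], p2[k], w1, w2) for k in sel}
    if len(sel) == 1:
        reject = {sel[0]: comb[sel[0]] <= alpha}
    elif multi_method == "bonferroni":
        reject = {k: comb[k] <= alpha / len(sel) for k in sel}
    elif multi_method == "holm":
        reject = _holm_reject(comb, alpha)
    elif multi_method == "dunnett":
        reject = {
            k: dunnett_adjusted_p(norm.isf(max(comb[k], 1e-12)), len(sel),
                                  dunnett_rho) <= alpha
            for k in sel
        }
    else:
        raise ValueError(f"unknown multiplicity method {multi_method!r}")
    if n_match < min_selecting:
        warnings.warn(
            f"only {n_match} of {total} rerandomizations matched the selection "
            "event",
            LowSelectionCountWarning,
            stacklevel=2,
        )
    return AsrtDecision(conditional_p=cond, stage2_p=p2, combined_p=comb,
                        reject=reject, n_selecting=n_match,
                        n_rerandomizations=total, exhaustive=exhaustive)


def _rule_from_selection(selection: SelectionResult) -> SelectionRule:
    if selection.rule == "single":
        return SelectionRule("single")
    # the rerandomized rule keeps the design's cap, not the realized set size
    return SelectionRule("multi", margin=selection.margin,
                         max_selected=selection.max_selected)
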
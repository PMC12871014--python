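"""Interim treatment-arm selection rules on Stage-1 binary response rates.

Two pre-specified rules are implemented:

* *single* — select the arm with the highest observed response rate; exact
  ties are broken uniformly at random (argmax rule).
* *multi* — select every arm whose response rate is within a clinical-
  equivalence margin ``Delta`` of the best, capped at ``max_selected`` arms
  (kept by highest rate, boundary ties broken uniformly at random).

Both rules are pure functions of the Stage-1 response counts plus a seeded
random stream for tie-breaks, which is what lets the rerandomization test
replay them deterministically on permuted data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["SelectionRule", "SelectionResult", "select_single", "select_multi",
           "select_batch"]


@dataclass(frozen=True)
class SelectionRule:
    """Config-level description of the pre-specified selection rule.

    ``rule='single'`` is the argmax rule; ``rule='multi'`` keeps all arms
    within ``margin`` of the best rate, at most ``max_selected`` of them.
    """

    rule: str = "single"
    margin: float = 0.0
    max_selected: int = 1

    def __post_init__(self):
        if self.rule not in ("single", "multi"):
            raise ValueError(f"unknown selection rule {self.rule!r}")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.max_selected < 1:
            raise ValueError("max_selected must be >= 1")
        if self.rule == "single" and (self.margin != 0 or self.max_selected != 1):
            raise ValueError("single rule takes margin=0, max_selected=1")


@dataclass(frozen=True)
class SelectionResult:
    selected: frozenset          # arm labels in 1..G
    response_rates: tuple
    response_counts: tuple
    rule: str = "single"
    margin: float = 0.0
    max_selected: int = 1        # the design cap, not the realized set size

    @property
    def selected_sorted(self):
        return tuple(sorted(self.selected))


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def _validate(counts, sizes):
    counts = np.asarray(counts, dtype=np.int64)
    sizes = np.asarray(sizes, dtype=np.int64)
    if counts.shape != sizes.shape or counts.ndim != 1 or counts.size < 1:
        raise ValueError("counts and sizes must be equal-length 1-d arrays")
    if np.any(sizes <= 0):
        raise ValueError("every arm must have at least one subject")
    if np.any((counts < 0) | (counts > sizes)):
        raise ValueError("response counts must lie in [0, arm size]")
    return counts, sizes


def select_single(response_counts, n_per_arm, rng_seed=None) -> SelectionResult:
    """Argmax selection: the treatment arm with the highest response rate.

    Exact ties for the maximum are broken by a single uniform draw from the
    seeded generator.
    """
    counts, sizes = _validate(response_counts, n_per_arm)
    rng = _as_rng(rng_seed)
    rates = counts / sizes
    tied = np.flatnonzero(rates == rates.max())
    pick = tied[int(rng.integers(tied.size))] if tied.size > 1 else tied[0]
    return SelectionResult(
        selected=frozenset({int(pick) + 1}),
        response_rates=tuple(rates),
        response_counts=tuple(int(c) for c in counts),
        rule="single",
        margin=0.0,
    )


def select_multi(response_counts, n_per_arm, margin, max_selected,
                 rng_seed=None) -> SelectionResult:
    """Margin selection: arms within ``margin`` of the best rate, capped.

    Candidates are ``{m : max(rate) - rate_m <= margin}``.  If more than
    ``max_selected`` qualify, the highest rates are kept; arms tied exactly at
    the cut are chosen uniformly at random among themselves.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if max_selected < 1:
        raise ValueError("max_selected must be >= 1")
    counts, sizes = _validate(response_counts, n_per_arm)
    rng = _as_rng(rng_seed)
    rates = counts / sizes
    cand = np.flatnonzero(rates.max() - rates <= margin)
    if cand.size > max_selected:
        cut = np.sort(rates[cand])[::-1][max_selected - 1]
        sure = cand[rates[cand] > cut]
        border = cand[rates[cand] == cut]
        extra = rng.choice(border, size=max_selected - sure.size, replace=False)
        cand = np.concatenate([sure, extra])
    return SelectionResult(
        selected=frozenset(int(m) + 1 for m in cand),
        response_rates=tuple(rates),
        response_counts=tuple(int(c) for c in counts),
        rule="multi",
        margin=float(margin),
        max_selected=int(max_selected),
    )


def select(response_counts, n_per_arm, rule: SelectionRule,
           rng_seed=None) -> SelectionResult:
    """Apply a :class:`SelectionRule` (dispatch helper)."""
    if rule.rule == "single":
        return select_single(response_counts, n_per_arm, rng_seed)
    return select_multi(response_counts, n_per_arm, rule.margin,
                        rule.max_selected, rng_seed)


def select_batch(counts, sizes, rule: SelectionRule,
                 rng: np.random.Generator) -> np.ndarray:
    """Vectorized selection over many response-count vectors at once.

    Parameters
    ----------
    counts : (B, G) int array of per-arm response counts.
    sizes : (G,) arm sizes.
    rule : the pre-specified rule.
    rng : generator supplying the per-row tie-break keys.

    Returns
    -------
    (B, G) boolean membership matrix of the selected set per row.  Tie-breaks
    are uniform and independent across rows.
    """
    counts = np.asarray(counts, dtype=np.float64)
    sizes = np.asarray(sizes, dtype=np.float64)
    B, G = counts.shape
    rates = counts / sizes
    keys = rng.random((B, G))
    # per-row order: rate descending, random among exact ties
    order = np.lexsort((keys, -rates), axis=1)
    sorted_rates = np.take_along_axis(rates, order, axis=1)
    within = sorted_rates[:, :1] - sorted_rates <= rule.margin
    n_keep = np.minimum(within.sum(axis=1), rule.max_selected)
    keep_sorted = np.arange(G)[None, :] < n_keep[:, None]
    mask = np.zeros((B, G), dtype=bool)
    np.put_along_axis(mask, order, keep_sorted, axis=1)
    return mask
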
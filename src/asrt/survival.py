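"""Log-rank score statistics and stagewise quantities for survival comparisons.

The confirmatory endpoint of the two-stage design is overall survival, compared
between a treatment arm and the shared control arm with the (unstratified)
log-rank test.  The test is expressed in score form: ``u`` is the sum over
distinct event times of observed-minus-expected control-arm deaths under the
hypergeometric null, ``V`` the corresponding variance (Fisher information), and
``z = u / sqrt(V)`` the standardized statistic whose one-sided p-value is
``1 - Phi(z)``.

Sign convention
---------------
``u`` counts control-arm *excess* deaths, so treatment superiority (fewer
deaths on treatment than expected) yields ``u > 0``, large ``z`` and a small
one-sided p-value.  Swapping the two arm labels negates ``u`` and ``z``
exactly.

A batched implementation (:func:`logrank_score_batch`) evaluates the same
statistic simultaneously for many alternative group assignments of one fixed
set of subjects; this is the hot path of the rerandomization test, where the
survival data are frozen and only the allocation labels vary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "SurvivalSample",
    "ScoreResult",
    "StageDesign",
    "logrank_score",
    "logrank_score_batch",
    "SortedSurvival",
    "expected_event_count",
    "combination_weights",
]


class DegenerateInformationWarning(UserWarning):
    """Raised when a comparison carries no events (V = 0): uninformative, not invalid."""


@dataclass(frozen=True)
class SurvivalSample:
    """Survival outcomes of the subjects in one arm.

    Attributes
    ----------
    times : ndarray
        Nonnegative follow-up durations in years.
    events : ndarray
        1 where death was observed, 0 where administratively censored.
    group : str
        Arm label (informational).
    """

    times: np.ndarray
    events: np.ndarray
    group: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and events must be 1-d arrays of equal length")
        if np.any(t < 0):
            raise ValueError("survival times must be nonnegative")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ScoreResult:
    """Log-rank score statistic for one treatment-vs-control comparison.

    ``u`` is oriented so positive values favour the treatment arm;
    ``theta_hat = u / V`` estimates the negative log hazard ratio scale and is
    exposed for completeness only — no test decision uses it.
    """

    u: float
    V: float

    @property
    def z(self) -> float:
        return 0.0 if self.V <= 0 else self.u / np.sqrt(self.V)

    @property
    def p_one_sided(self) -> float:
        return 0.5 if self.V <= 0 else float(norm.sf(self.z))

    @property
    def theta_hat(self) -> float:
        return np.nan if self.V <= 0 else self.u / self.V


@dataclass(frozen=True)
class StageDesign:
    """Calendar geometry and sample sizes of one accrual stage."""

    accrual_start: float
    accrual_end: float
    analysis_time: float
    n_per_group: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if not (self.accrual_start < self.accrual_end <= self.analysis_time):
            raise ValueError(
                "require accrual_start < accrual_end <= analysis_time"
            )
        if any(int(n) != n or n <= 0 for n in self.n_per_group):
            raise ValueError("group sizes must be positive integers")


# ---------------------------------------------------------------------------
# sorted-event-table cache and the batched statistic
# ---------------------------------------------------------------------------

class SortedSurvival:
    """Pre-sorted event table of a fixed subject set, reused across permutations.

    Sorting is by time ascending with deaths preceding censorings at equal
    times (the conventional risk-set rule).  ``tie_starts`` marks the first
    index of each distinct time; when all times are distinct the per-position
    fast path is used.
    """

    def __init__(self, times, events):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=np.int64)
        order = np.lexsort((1 - events, times))
        self.order = order
        self.times = times[order]
        self.events = events[order]
        self.n = times.size
        distinct = np.ones(self.n, dtype=bool)
        distinct[1:] = self.times[1:] != self.times[:-1]
        self.has_ties = not distinct.all()
        self.tie_starts = np.flatnonzero(distinct)

    def score(self, in_comparison, in_treatment):
        """Batched log-rank score over rows of alternative assignments.

        Parameters
        ----------
        in_comparison : (B, n) bool, subject order = original (unsorted)
            True for subjects contributing to the comparison (treatment or
            control arm under that assignment).
        in_treatment : (B, n) bool
            True for subjects on the treatment arm.

        Returns
        -------
        u, V : (B,) float arrays
        """
        inc = np.asarray(in_comparison)[:, self.order].astype(np.float64)
        trt = np.asarray(in_treatment)[:, self.order].astype(np.float64)
        ev = self.events.astype(np.float64)

        # at-risk counts at each sorted position: reverse cumulative sums
        n_at = np.cumsum(inc[:, ::-1], axis=1)[:, ::-1]
        n1_at = np.cumsum(trt[:, ::-1], axis=1)[:, ::-1]

        if self.has_ties:
            s = self.tie_starts
            n_at = n_at[:, s]
            n1_at = n1_at[:, s]
            d = np.add.reduceat(inc * ev, s, axis=1)
            d1 = np.add.reduceat(trt * ev, s, axis=1)
        else:
            d = inc * ev
            d1 = trt * ev

        n0_at = n_at - n1_at
        d0 = d - d1
        with np.errstate(divide="ignore", invalid="ignore"):
            e0 = np.where(n_at > 0, d * n0_at / n_at, 0.0)
            v = np.where(
                n_at > 1,
                d * (n_at - d) / np.maximum(n_at - 1.0, 1.0)
                * n0_at * n1_at / np.maximum(n_at, 1.0) ** 2,
                0.0,
            )
        u = np.sum(d0 - e0, axis=1)
        V = np.sum(v, axis=1)
        return u, V


def logrank_score_batch(times, events, in_comparison, in_treatment):
    """Vectorized log-rank ``(u, V)`` for many assignments of one subject set."""
    return SortedSurvival(times, events).score(in_comparison, in_treatment)


def logrank_score(treatment: SurvivalSample, control: SurvivalSample) -> ScoreResult:
    """Log-rank score statistic for one treatment arm against control.

    Returns the observed-minus-expected control-arm death count ``u``, the
    hypergeometric variance sum ``V`` (with the multiple-death tie
    correction), and through :class:`ScoreResult` the standardized ``z`` and
    one-sided p-value.  A comparison with zero events is degenerate: ``u = 0``,
    ``V = 0``, ``z = 0``, ``p = 0.5``, with a warning.
    """
    if len(treatment) == 0 or len(control) == 0:
        raise ValueError("each arm needs at least one subject")
    times = np.concatenate([treatment.times, control.times])
    events = np.concatenate([treatment.events, control.events])
    is_trt = np.zeros(times.size, dtype=bool)
    is_trt[: len(treatment)] = True
    u, V = logrank_score_batch(
        times, events, np.ones((1, times.size), bool), is_trt[None, :]
    )
    u, V = float(u[0]), float(V[0])
    if V <= 0:
        warnings.warn(
            "no events in either arm: log-rank information is zero",
            DegenerateInformationWarning,
            stacklevel=2,
        )
        return ScoreResult(u=0.0, V=0.0)
    return ScoreResult(u=u, V=V)


# ---------------------------------------------------------------------------
# expected events and combination weights
# ---------------------------------------------------------------------------

def expected_event_count(n, hazard, accrual_start, accrual_end, analysis_time):
    """Expected number of deaths among ``n`` subjects at the analysis date.

    Subjects enter uniformly on ``[accrual_start, accrual_end]``, survival is
    exponential with the given hazard (per year), and everyone still alive is
    administratively censored at ``analysis_time``.  Closed form::

        n * (1 - (1/a) * integral_{accrual window} exp(-hazard*(analysis - s)) ds)

    with ``a`` the accrual-window length.
    """
    if hazard <= 0:
        raise ValueError("hazard must be positive")
    if not accrual_start < accrual_end:
        raise ValueError("empty accrual window")
    if analysis_time < accrual_end:
        raise ValueError("analysis before end of accrual: not all subjects enrolled")
    a = accrual_end - accrual_start
    t0 = analysis_time - accrual_end    # shortest follow-up
    t1 = analysis_time - accrual_start  # longest follow-up
    p_censored = (np.exp(-hazard * t0) - np.exp(-hazard * t1)) / (hazard * a)
    return n * (1.0 - p_censored)


def combination_weights(expected_events_stage1, expected_events_stage2):
    """Inverse-normal combination weights, proportional to sqrt expected events.

    ``w1 = sqrt(e1/(e1+e2))``, ``w2 = sqrt(e2/(e1+e2))``; ``w1**2 + w2**2 = 1``.
    """
    e1, e2 = float(expected_events_stage1), float(expected_events_stage2)
    if e1 <= 0 or e2 <= 0:
        raise ValueError("expected event counts must be positive")
    tot = e1 + e2
    return np.sqrt(e1 / tot), np.sqrt(e2 / tot)
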
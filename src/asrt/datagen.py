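"""Synthetic two-stage trial generator with Clayton-dependent outcomes.

Each subject carries a latent *response time* R and an *overall survival* time
D, both exponential, coupled by a Clayton copula so that the joint survivor
function is

    S(t_R, t_D) = ( S_R(t_R)^(-theta) + S_D(t_D)^(-theta) - 1 )^(-1/theta),

with Kendall's tau = theta / (theta + 2).  The short-term binary response is
the landmark indicator R > 0.5 years, so the true response rate equals
S_R(0.5) by construction; arm hazards are parameterized from the design's
3-year survivor probability, lambda_D = -ln(S_D(3))/3, and response rate,
lambda_R = -ln(S_R(0.5))/0.5.

Trial calendar (defaults): Stage-1 subjects enter uniformly on [0, 1.7] years,
the interim selection happens 0.5 years after Stage-1 accrual closes (every
Stage-1 response status is then known), Stage-2 subjects enter uniformly on
(1.7, 5.0], and the final analysis at calendar year 8.0 administratively
censors everyone still alive — giving the last Stage-1 entrant at least 6.3
years of follow-up and the last Stage-2 entrant 3.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .survival import expected_event_count, combination_weights

__all__ = [
    "ArmModel",
    "TrialDesignConfig",
    "TrialData",
    "theta_from_tau",
    "tau_from_theta",
    "sample_clayton_pair",
    "response_indicator",
    "simulate_trial",
    "simulate_stage1",
    "simulate_stage2",
    "assemble_trial",
    "simulate_fixed_trial_data",
    "experiment1_config",
    "experiment2_config",
]


def theta_from_tau(tau):
    """Clayton dependence parameter from Kendall's tau: theta = 2 tau/(1-tau)."""
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    return 2.0 * tau / (1.0 - tau)


def tau_from_theta(theta):
    if theta <= 0:
        raise ValueError("theta must be positive")
    return theta / (theta + 2.0)


@dataclass(frozen=True)
class ArmModel:
    """Outcome model of one arm: exponential marginals + Clayton dependence."""

    hazard_response: float
    hazard_death: float
    copula_theta: float

    def __post_init__(self):
        if self.hazard_response <= 0 or self.hazard_death <= 0:
            raise ValueError("hazards must be positive")
        if self.copula_theta <= 0:
            raise ValueError("copula_theta must be positive")

    @property
    def kendall_tau(self):
        return tau_from_theta(self.copula_theta)

    @classmethod
    def from_design(cls, surv3, resp_rate, tau):
        """Build from the design quantities S_D(3), S_R(0.5) and Kendall tau."""
        if not 0 < surv3 < 1 or not 0 < resp_rate < 1:
            raise ValueError("survivor probabilities must lie in (0, 1)")
        return cls(
            hazard_response=-np.log(resp_rate) / 0.5,
            hazard_death=-np.log(surv3) / 3.0,
            copula_theta=theta_from_tau(tau),
        )


def sample_clayton_pair(arm: ArmModel, n, rng):
    """Draw ``n`` (response_time, death_time) pairs via the gamma-frailty route.

    A shared Gamma(1/theta) frailty W mixes two unit exponentials E_j into
    Clayton-coupled uniforms U_j = (1 + E_j/W)^(-1/theta); times follow by
    inverting the exponential survivors, t = -ln(U)/lambda.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    th = arm.copula_theta
    w = rng.gamma(1.0 / th, size=n)
    e = rng.exponential(size=(2, n))
    u = (1.0 + e / w) ** (-1.0 / th)
    t_resp = -np.log(u[0]) / arm.hazard_response
    t_death = -np.log(u[1]) / arm.hazard_death
    return t_resp, t_death


def sample_clayton_pair_inversion(arm: ArmModel, n, rng):
    """Conditional-inversion Clayton sampler (cross-check for the frailty route)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    th = arm.copula_theta
    u1 = rng.random(n)
    q = rng.random(n)
    # invert the conditional survivor C_{2|1}: u2 = ((q^(-th/(1+th)) - 1) u1^(-th) + 1)^(-1/th)
    u2 = ((q ** (-th / (1.0 + th)) - 1.0) * u1 ** (-th) + 1.0) ** (-1.0 / th)
    return -np.log(u1) / arm.hazard_response, -np.log(u2) / arm.hazard_death


def response_indicator(response_time, landmark=0.5):
    """Landmark binary response: 1 iff the response time strictly exceeds it."""
    return (np.asarray(response_time, dtype=float) > landmark).astype(np.int64)


@dataclass(frozen=True)
class TrialDesignConfig:
    """Design and outcome-model configuration of the two-stage trial.

    ``surv3`` and ``resp_rate`` list per-group values with the control at
    index 0 and treatment arms 1..G.  Stage-2 sizes may depend on the realized
    number of selected arms through ``n_stage2_by_count`` (e.g. 204 if one arm
    proceeds, 136 if two).
    """

    surv3: tuple
    resp_rate: tuple
    tau: float = 0.5
    n_stage1_per_group: int = 50
    n_stage2_per_group: int = 150
    n_stage2_by_count: dict = field(default_factory=dict)
    accrual_years_stage1: float = 1.7
    accrual_years_stage2: float = 3.3
    followup_years_final: float = 3.0
    response_landmark: float = 0.5
    selection_rule: str = "single"
    selection_margin: float = 0.0
    max_selected: int = 1
    weights_mode: str = "fixed"          # "fixed" | "expected_events"
    w1: float = 0.543
    w2: float = 0.839
    n_fixed_per_group: int = 100

    def __post_init__(self):
        if len(self.surv3) != len(self.resp_rate) or len(self.surv3) < 2:
            raise ValueError("surv3 and resp_rate must list control + >=1 arm")
        for p in (*self.surv3, *self.resp_rate):
            if not 0 < p < 1:
                raise ValueError("probabilities must lie in (0, 1)")
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")

    @property
    def n_arms(self):
        return len(self.surv3) - 1

    @property
    def final_analysis_time(self):
        return (self.accrual_years_stage1 + self.accrual_years_stage2
                + self.followup_years_final)

    def arm_model(self, g) -> ArmModel:
        return ArmModel.from_design(self.surv3[g], self.resp_rate[g], self.tau)

    def stage2_size(self, n_selected):
        return self.n_stage2_by_count.get(n_selected, self.n_stage2_per_group)

    def weights(self, n_selected=1):
        """Combination weights: fixed, or from expected events at final analysis.

        Fixed weights are renormalized to satisfy ``w1**2 + w2**2 = 1``
        exactly, so rounded design values (e.g. 0.543/0.839) are accepted.
        """
        if self.weights_mode == "fixed":
            nrm = np.sqrt(self.w1 ** 2 + self.w2 ** 2)
            return self.w1 / nrm, self.w2 / nrm
        hz = self.arm_model(0).hazard_death  # design-stage (null) hazard
        a1 = self.accrual_years_stage1
        a2 = self.accrual_years_stage2
        T = self.final_analysis_time
        n1 = (1 + n_selected) * self.n_stage1_per_group
        n2 = (1 + n_selected) * self.stage2_size(n_selected)
        e1 = expected_event_count(n1, hz, 0.0, a1, T)
        e2 = expected_event_count(n2, hz, a1, a1 + a2, T)
        return combination_weights(e1, e2)


@dataclass(frozen=True)
class TrialData:
    """Subject-level dataset of one simulated trial (arrays over subjects)."""

    group: np.ndarray       # 0 = control
    stage: np.ndarray       # 1 or 2
    entry_time: np.ndarray  # calendar years
    response: np.ndarray    # -1 for Stage-2 subjects (not used by the analysis)
    surv_time: np.ndarray   # observed follow-up, years
    event: np.ndarray       # 1 = death observed

    def to_frame(self):
        import pandas as pd

        resp = self.response.astype(object)
        resp[self.response < 0] = pd.NA
        return pd.DataFrame(
            {
                "id": np.arange(self.group.size),
                "group": self.group,
                "stage": self.stage,
                "entry_time": self.entry_time,
                "response": resp,
                "surv_time": self.surv_time,
                "event": self.event,
            }
        )


def _censor(death_time, entry, analysis_time):
    horizon = analysis_time - entry
    surv = np.minimum(death_time, horizon)
    event = (death_time <= horizon).astype(np.int64)
    return surv, event


def _sample_arm_block(cfg, g, n, entry_lo, entry_hi, rng):
    t_resp, t_death = sample_clayton_pair(cfg.arm_model(g), n, rng)
    entry = rng.uniform(entry_lo, entry_hi, size=n)
    return t_resp, t_death, entry


def simulate_trial(cfg: TrialDesignConfig, rng, analysis=None):
    """Generate one complete two-stage trial (and optionally analyse it).

    Stage-1 subjects are generated for every group; the pre-specified rule is
    applied to the observed Stage-1 responses (tie-breaks drawn from ``rng``)
    and Stage-2 subjects are generated for control plus the selected arm(s).
    Returns ``(TrialData, SelectionResult)``, or
    ``(TrialData, SelectionResult, decisions)`` when ``analysis`` — a callable
    ``analysis(trial, selection, cfg, rng)`` — is supplied.
    """
    from .selection import SelectionRule, select

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    stage1 = simulate_stage1(cfg, rng)
    g1, r1 = stage1[0], stage1[1]
    resp1 = response_indicator(r1, cfg.response_landmark)
    counts = np.array(
        [resp1[g1 == g].sum() for g in range(1, cfg.n_arms + 1)], dtype=np.int64
    )
    sizes = np.full(cfg.n_arms, cfg.n_stage1_per_group, dtype=np.int64)
    rule = SelectionRule(cfg.selection_rule, cfg.selection_margin,
                         cfg.max_selected)
    selection = select(counts, sizes, rule, rng)
    stage2 = simulate_stage2(cfg, selection.selected, rng)
    trial = assemble_trial(cfg, stage1, stage2)
    if analysis is None:
        return trial, selection
    return trial, selection, analysis(trial, selection, cfg, rng)


def simulate_stage1(cfg: TrialDesignConfig, rng):
    """Stage-1 subject outcomes for all groups (control = 0 first)."""
    G = cfg.n_arms
    n1 = cfg.n_stage1_per_group
    a1 = cfg.accrual_years_stage1
    groups, resp_t, death_t, entry = [], [], [], []
    for g in range(G + 1):
        tr, td, en = _sample_arm_block(cfg, g, n1, 0.0, a1, rng)
        groups.append(np.full(n1, g))
        resp_t.append(tr)
        death_t.append(td)
        entry.append(en)
    return (np.concatenate(groups), np.concatenate(resp_t),
            np.concatenate(death_t), np.concatenate(entry))


def simulate_stage2(cfg: TrialDesignConfig, selected, rng):
    """Stage-2 subjects for control + the selected arms."""
    sel = tuple(sorted(selected))
    n2 = cfg.stage2_size(len(sel))
    a1 = cfg.accrual_years_stage1
    a2 = cfg.accrual_years_stage2
    groups, resp_t, death_t, entry = [], [], [], []
    for g in (0, *sel):
        tr, td, en = _sample_arm_block(cfg, g, n2, a1, a1 + a2, rng)
        groups.append(np.full(n2, g))
        resp_t.append(tr)
        death_t.append(td)
        entry.append(en)
    return (np.concatenate(groups), np.concatenate(resp_t),
            np.concatenate(death_t), np.concatenate(entry))


def assemble_trial(cfg, stage1_block, stage2_block) -> TrialData:
    """Apply landmark response and administrative censoring; stack both stages."""
    T = cfg.final_analysis_time
    g1, r1, d1, e1 = stage1_block
    g2, r2, d2, e2 = stage2_block
    surv1, ev1 = _censor(d1, e1, T)
    surv2, ev2 = _censor(d2, e2, T)
    resp1 = response_indicator(r1, cfg.response_landmark)
    resp2 = np.full(g2.size, -1, dtype=np.int64)  # not observed pre-selection
    return TrialData(
        group=np.concatenate([g1, g2]),
        stage=np.concatenate([np.ones(g1.size, int), np.full(g2.size, 2)]),
        entry_time=np.concatenate([e1, e2]),
        response=np.concatenate([resp1, resp2]),
        surv_time=np.concatenate([surv1, surv2]),
        event=np.concatenate([ev1, ev2]),
    )


def simulate_fixed_trial_data(cfg: TrialDesignConfig, rng) -> TrialData:
    """Conventional fixed design: every arm enrols ``n_fixed_per_group`` over
    the whole accrual window, no selection, analysis at the same calendar time."""
    G = cfg.n_arms
    n = cfg.n_fixed_per_group
    a_total = cfg.accrual_years_stage1 + cfg.accrual_years_stage2
    T = cfg.final_analysis_time
    groups, death_t, entry, resp_t = [], [], [], []
    for g in range(G + 1):
        tr, td, en = _sample_arm_block(cfg, g, n, 0.0, a_total, rng)
        groups.append(np.full(n, g))
        death_t.append(td)
        entry.append(en)
        resp_t.append(tr)
    g_all = np.concatenate(groups)
    surv, ev = _censor(np.concatenate(death_t), np.concatenate(entry), T)
    return TrialData(
        group=g_all,
        stage=np.ones(g_all.size, int),
        entry_time=np.concatenate(entry),
        response=response_indicator(np.concatenate(resp_t), cfg.response_landmark),
        surv_time=surv,
        event=ev,
    )


# ---------------------------------------------------------------------------
# canonical experiment configurations
# ---------------------------------------------------------------------------

def experiment1_config(tau=0.5, surv3=(0.5, 0.5, 0.5),
                       resp_rate=(0.5, 0.5, 0.5)) -> TrialDesignConfig:
    """Two treatment arms + control, single selection, N1=50/N2=150 per group."""
    return TrialDesignConfig(surv3=surv3, resp_rate=resp_rate, tau=tau)


def experiment2_config(tau=0.5, surv3=(0.5, 0.5, 0.5, 0.5),
                       resp_rate=(0.5, 0.5, 0.5, 0.5)) -> TrialDesignConfig:
    """Three treatment arms + control; up to two selected within margin 0.05;
    Stage-2 size 204 (one selected) or 136 (two selected); weights from
    expected events."""
    return TrialDesignConfig(
        surv3=surv3,
        resp_rate=resp_rate,
        tau=tau,
        n_stage2_per_group=204,
        n_stage2_by_count={1: 204, 2: 136},
        selection_rule="multi",
        selection_margin=0.05,
        max_selected=2,
        weights_mode="expected_events",
    )
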
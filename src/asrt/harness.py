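"""Monte-Carlo experiment orchestration: type I error and power per method.

Batches of simulated two-stage trials are generated on a grid of Kendall-tau
values and outcome scenarios; every requested analysis method is applied to
the *identical* datasets within a cell (paired comparison), so method
differences carry no between-dataset Monte-Carlo noise.  Replicates are
independently seeded from ``(master_seed, cell index, replicate index)`` and
results are invariant to execution order.

Rates reported per cell: rejection of any hypothesis (the family-wise error
under a global null), rejection of arm 1 (the Scenario-1 power target), and
rejection of arm 1 or arm 2 (the Scenario-2 power target).
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import binomtest, norm

from . import __version__ as _pkg_version
from .survival import SurvivalSample, logrank_score, DegenerateInformationWarning
from .selection import SelectionResult
from .combination import (friede_decision, friede_decision_multi,
                          dunnett_adjusted_p, PClampWarning)
from .randomization import (Stage1Dataset, asrt_decision,
                            LowSelectionCountWarning, ZeroNumeratorWarning)
from .datagen import (TrialDesignConfig, simulate_trial,
                      simulate_fixed_trial_data, experiment1_config,
                      experiment2_config)

__all__ = ["ExperimentSpec", "SimResult", "run_experiment", "summarize",
           "analyze_trial", "analyze_fixed_trial"]

FRIEDE_METHODS = {"friede_bonferroni": "bonferroni", "friede_holm": "holm",
                  "friede_dunnett": "dunnett"}
ALL_METHODS = ("asrt", *FRIEDE_METHODS, "fixed_design")


# ---------------------------------------------------------------------------
# per-trial analysis
# ---------------------------------------------------------------------------

def _stage_scores(trial, cfg, selection):
    """Stage-1 scores for every arm and Stage-2 scores for the selected arms."""
    s1 = trial.stage == 1
    scores1 = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateInformationWarning)
        for g in range(1, cfg.n_arms + 1):
            trt = SurvivalSample(trial.surv_time[s1 & (trial.group == g)],
                                 trial.event[s1 & (trial.group == g)])
            ctl = SurvivalSample(trial.surv_time[s1 & (trial.group == 0)],
                                 trial.event[s1 & (trial.group == 0)])
            scores1[g] = logrank_score(trt, ctl)
        s2 = trial.stage == 2
        scores2 = {}
        for g in sorted(selection.selected):
            trt = SurvivalSample(trial.surv_time[s2 & (trial.group == g)],
                                 trial.event[s2 & (trial.group == g)])
            ctl = SurvivalSample(trial.surv_time[s2 & (trial.group == 0)],
                                 trial.event[s2 & (trial.group == 0)])
            scores2[g] = logrank_score(trt, ctl)
    return scores1, scores2


def _stage1_dataset(trial, cfg) -> Stage1Dataset:
    s1 = trial.stage == 1
    order = np.argsort(trial.group[s1], kind="stable")
    sizes = tuple([cfg.n_stage1_per_group] * (cfg.n_arms + 1))
    return Stage1Dataset(
        response=trial.response[s1][order],
        surv_time=trial.surv_time[s1][order],
        event=trial.event[s1][order],
        assignment=trial.group[s1][order],
        group_sizes=sizes,
    )


def analyze_trial(trial, selection: SelectionResult, cfg: TrialDesignConfig,
                  rng, methods=("asrt", "friede_bonferroni", "friede_holm",
                                "friede_dunnett"),
                  alpha=0.05, n_rerandomizations=5000, multi_method="dunnett",
                  dunnett_rho=0.5):
    """Apply every requested method to one simulated trial.

    Returns ``{method: frozenset(rejected arm labels)}``.
    """
    scores1, scores2 = _stage_scores(trial, cfg, selection)
    sel = tuple(sorted(selection.selected))
    weights = cfg.weights(len(sel))
    out = {}
    for m in methods:
        if m in FRIEDE_METHODS:
            adj = FRIEDE_METHODS[m]
            with warnings.catch_warnings():
                # a Bonferroni/Holm p capped at 1.0 is routine in batch runs
                warnings.simplefilter("ignore", PClampWarning)
                if len(sel) == 1:
                    dec = friede_decision(scores1, scores2[sel[0]], selection,
                                          weights, alpha=alpha, method=adj,
                                          rho=dunnett_rho)
                    out[m] = (frozenset(sel) if dec.reject_selected
                              else frozenset())
                else:
                    rej = friede_decision_multi(scores1, scores2, selection,
                                                weights, alpha=alpha,
                                                method=adj, rho=dunnett_rho)
                    out[m] = frozenset(a for a, r in rej.items() if r)
        elif m == "asrt":
            stage1 = _stage1_dataset(trial, cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", LowSelectionCountWarning)
                warnings.simplefilter("ignore", ZeroNumeratorWarning)
                dec = asrt_decision(stage1, scores2, selection, weights,
                                    alpha=alpha, n_iter=n_rerandomizations,
                                    multi_method=multi_method, rng=rng,
                                    dunnett_rho=dunnett_rho)
            out[m] = frozenset(a for a, r in dec.reject.items() if r)
        else:
            raise ValueError(f"unknown method {m!r} for a two-stage trial")
    return out


def analyze_fixed_trial(trial, cfg, alpha=0.05, method="dunnett",
                        dunnett_rho=0.5):
    """Pairwise log-rank comparisons of the fixed design with multiplicity."""
    z = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateInformationWarning)
        for g in range(1, cfg.n_arms + 1):
            trt = SurvivalSample(trial.surv_time[trial.group == g],
                                 trial.event[trial.group == g])
            ctl = SurvivalSample(trial.surv_time[trial.group == 0],
                                 trial.event[trial.group == 0])
            z[g] = logrank_score(trt, ctl).z
    G = len(z)
    p = {g: float(norm.sf(zz)) for g, zz in z.items()}
    if method == "bonferroni":
        rej = {g: G * p[g] <= alpha for g in z}
    elif method == "holm":
        order = sorted(z, key=lambda g: p[g])
        rej, alive = {}, True
        for j, g in enumerate(order):
            alive = alive and p[g] <= alpha / (G - j)
            rej[g] = alive
    elif method == "dunnett":
        rej = {g: dunnett_adjusted_p(z[g], G, dunnett_rho) <= alpha for g in z}
    else:
        raise ValueError(f"unknown multiplicity method {method!r}")
    return frozenset(g for g, r in rej.items() if r)


# ---------------------------------------------------------------------------
# experiment specification and execution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    name: str
    surv3: tuple
    resp_rate: tuple


@dataclass(frozen=True)
class ExperimentSpec:
    experiment_id: int
    scenarios: tuple                 # of Scenario
    taus: tuple = (0.2, 0.5, 0.8)
    n_replicates: int = 1000
    n_rerandomizations: int = 500
    methods: tuple = ("asrt", "friede_bonferroni", "friede_holm",
                      "friede_dunnett")
    alpha: float = 0.05
    master_seed: int = 0
    fixed_multiplicity: str = "dunnett"
    asrt_multi_method: str = "dunnett"

    def __post_init__(self):
        if self.experiment_id not in (1, 2, 3):
            raise ValueError("experiment_id must be 1, 2 or 3")
        if not self.scenarios or not self.taus:
            raise ValueError("scenario grid must be nonempty")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.experiment_id == 3 and "fixed_design" not in self.methods:
            raise ValueError("experiment 3 compares against fixed_design")
        if self.experiment_id != 3 and "fixed_design" in self.methods:
            raise ValueError("fixed_design has no selection stage; "
                             "only experiment 3 runs it")

    def config(self, scenario: Scenario, tau: float) -> TrialDesignConfig:
        if self.experiment_id == 2:
            return experiment2_config(tau=tau, surv3=scenario.surv3,
                                      resp_rate=scenario.resp_rate)
        return experiment1_config(tau=tau, surv3=scenario.surv3,
                                  resp_rate=scenario.resp_rate)


@dataclass
class SimResult:
    spec: ExperimentSpec
    cells: list = field(default_factory=list)
    runtime_s: float = 0.0

    def rate(self, scenario, tau, method, which="any"):
        for c in self.cells:
            if (c["scenario"] == scenario and c["tau"] == tau
                    and c["method"] == method):
                return c[f"rate_{which}"]
        raise KeyError((scenario, tau, method, which))

    def to_json(self, path=None):
        payload = {
            "spec": {**asdict(self.spec),
                     "scenarios": [asdict(s) for s in self.spec.scenarios]},
            "cells": self.cells,
            "runtime_s": self.runtime_s,
            "package_version": _pkg_version,
        }
        text = json.dumps(payload, indent=2, default=list)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _ci(k, n):
    lo, hi = binomtest(k, n).proportion_ci(0.95)
    return float(lo), float(hi)


def run_experiment(spec: ExperimentSpec) -> SimResult:
    """Run the full scenario grid; deterministic given ``spec.master_seed``."""
    t0 = time.time()
    result = SimResult(spec=spec)
    two_stage_methods = tuple(m for m in spec.methods if m != "fixed_design")
    run_fixed = "fixed_design" in spec.methods
    cell_idx = 0
    for scenario in spec.scenarios:
        for tau in spec.taus:
            cfg = spec.config(scenario, tau)
            counts = {m: {"any": 0, "arm1": 0, "arm1or2": 0}
                      for m in spec.methods}
            for rep in range(spec.n_replicates):
                rng = np.random.default_rng(
                    [spec.master_seed, spec.experiment_id, cell_idx, rep]
                )
                if two_stage_methods:
                    trial, selection = simulate_trial(cfg, rng)
                    rejected = analyze_trial(
                        trial, selection, cfg, rng,
                        methods=two_stage_methods, alpha=spec.alpha,
                        n_rerandomizations=spec.n_rerandomizations,
                        multi_method=spec.asrt_multi_method,
                    )
                else:
                    rejected = {}
                if run_fixed:
                    ftrial = simulate_fixed_trial_data(cfg, rng)
                    rejected["fixed_design"] = analyze_fixed_trial(
                        ftrial, cfg, alpha=spec.alpha,
                        method=spec.fixed_multiplicity,
                    )
                for m, rej in rejected.items():
                    counts[m]["any"] += bool(rej)
                    counts[m]["arm1"] += 1 in rej
                    counts[m]["arm1or2"] += bool(rej & {1, 2})
            n = spec.n_replicates
            for m in spec.methods:
                cell = {"scenario": scenario.name, "tau": tau, "method": m,
                        "n_replicates": n}
                for which, k in counts[m].items():
                    cell[f"rate_{which}"] = k / n
                    cell[f"n_{which}"] = k
                    cell[f"ci_{which}"] = _ci(k, n)
                result.cells.append(cell)
            cell_idx += 1
    result.runtime_s = time.time() - t0
    return result


def summarize(results, power_key="rate_arm1"):
    """Winner-per-cell and method-difference tables across result sets.

    Accepts one ``SimResult`` or a list sharing the same scenario/tau grid;
    returns ``{"winners": {...}, "differences": {...}}`` where winners name
    the method with the highest power per cell and differences give pairwise
    rate gaps with Monte-Carlo standard errors.
    """
    if isinstance(results, SimResult):
        results = [results]
    cells = [c for r in results for c in r.cells]
    grid = sorted({(c["scenario"], c["tau"]) for c in cells})
    grids = [sorted({(c["scenario"], c["tau"]) for c in r.cells})
             for r in results]
    if any(g != grids[0] for g in grids[1:]):
        raise ValueError("result sets do not share a scenario/tau grid")
    winners, diffs = {}, {}
    for key in grid:
        here = [c for c in cells if (c["scenario"], c["tau"]) == key]
        best = max(here, key=lambda c: c[power_key])
        winners[key] = best["method"]
        for a in here:
            for b in here:
                if a["method"] >= b["method"]:
                    continue
                n = a["n_replicates"]
                pa, pb = a[power_key], b[power_key]
                se = float(np.sqrt((pa * (1 - pa) + pb * (1 - pb)) / n))
                diffs[(key, a["method"], b["method"])] = (pa - pb, se)
    return {"winners": winners, "differences": diffs}
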
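"""Subject-level CSV and design-configuration file handling.

CSV schema (times in years): ``id, group, stage, entry_time, response,
surv_time, event`` with ``group`` 0 for control, ``response`` in {0, 1} or
empty for Stage-2 subjects (their short-term outcome plays no role in the
analysis).

YAML/JSON configuration mirrors :class:`~asrt.datagen.TrialDesignConfig`
under a ``design:`` block, plus analysis keys ``alpha``, ``multiplicity``,
``dunnett_rho``, ``weights: {mode, w1, w2}`` and
``selection: {rule, margin, max_selected}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datagen import TrialData, TrialDesignConfig

__all__ = ["read_subjects_csv", "write_subjects_csv", "trial_from_frame",
           "load_config"]

_COLUMNS = ["id", "group", "stage", "entry_time", "response", "surv_time",
            "event"]


def write_subjects_csv(trial: TrialData, path):
    # %.17g keeps float64 round-trips exact
    trial.to_frame().to_csv(path, index=False, float_format="%.17g")


def trial_from_frame(df: pd.DataFrame) -> TrialData:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    group = df["group"].to_numpy(dtype=np.int64)
    stage = df["stage"].to_numpy(dtype=np.int64)
    entry = df["entry_time"].to_numpy(dtype=float)
    surv = df["surv_time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=np.int64)
    resp_raw = df["response"]
    response = np.where(resp_raw.isna(), -1, resp_raw.fillna(-1)).astype(np.int64)
    if np.any(group < 0):
        raise ValueError("group labels must be nonnegative (0 = control)")
    if not np.isin(stage, (1, 2)).all():
        raise ValueError("stage must be 1 or 2")
    if np.any(surv < 0) or np.any(entry < 0):
        raise ValueError("times must be nonnegative")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event must be 0 or 1")
    if not np.isin(response, (-1, 0, 1)).all():
        raise ValueError("response must be 0, 1 or missing")
    if np.any((stage == 1) & (response < 0)):
        raise ValueError("Stage-1 subjects need an observed binary response")
    return TrialData(group=group, stage=stage, entry_time=entry,
                     response=response, surv_time=surv, event=event)


def read_subjects_csv(path) -> TrialData:
    # round_trip parsing keeps written float64 values bit-exact
    return trial_from_frame(pd.read_csv(path, float_precision="round_trip"))


def load_config(path):
    """Load a YAML or JSON design/analysis configuration.

    Returns ``(TrialDesignConfig, analysis_options_dict)``.
    """
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    design = dict(raw.get("design", {}))
    sel = raw.get("selection", {})
    weights = raw.get("weights", {})
    kwargs = {
        "surv3": tuple(design.pop("surv3")),
        "resp_rate": tuple(design.pop("resp_rate")),
    }
    for key in ("tau", "n_stage1_per_group", "n_stage2_per_group",
                "accrual_years_stage1", "accrual_years_stage2",
                "followup_years_final", "response_landmark",
                "n_fixed_per_group"):
        if key in design:
            kwargs[key] = design.pop(key)
    if "n_stage2_by_count" in design:
        kwargs["n_stage2_by_count"] = {
            int(k): int(v) for k, v in design.pop("n_stage2_by_count").items()
        }
    if design:
        raise ValueError(f"unknown design keys: {sorted(design)}")
    if sel:
        kwargs["selection_rule"] = sel.get("rule", "single")
        kwargs["selection_margin"] = float(sel.get("margin", 0.0))
        kwargs["max_selected"] = int(sel.get("max_selected", 1))
    if weights:
        kwargs["weights_mode"] = weights.get("mode", "fixed")
        if "w1" in weights:
            kwargs["w1"] = float(weights["w1"])
            kwargs["w2"] = float(weights["w2"])
    cfg = TrialDesignConfig(**kwargs)
    analysis = {
        "alpha": float(raw.get("alpha", 0.05)),
        "multiplicity": raw.get("multiplicity", "dunnett"),
        "dunnett_rho": float(raw.get("dunnett_rho", 0.5)),
    }
    return cfg, analysis
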
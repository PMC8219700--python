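"""Trial-table and session-metadata serialization, plus YAML configs.

The trial table is one row per trial with the fixed column set
``subject_id, timepoint, trial_index, phase, agent, amount_now,
amount_delayed, delay_days, option_chosen, feedback_correct`` (CSV or
TSV). Session-level metadata (partner spec, phase-2 stopping trial,
seed, generative parameters when simulated) goes to JSON lines, one
object per session.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .adaptive import DesignConfig
from .cohort import CohortSpec, SubjectParams
from .discounting import ChoiceRecord, OfferPair
from .social import PartnerSpec, SessionRecord, TaskConfig

__all__ = [
    "TRIAL_COLUMNS",
    "pairs_to_table",
    "sessions_to_trials",
    "trials_to_sessions",
    "write_trials",
    "read_trials",
    "write_session_meta",
    "read_session_meta",
    "load_cohort_spec",
    "load_task_config",
]

TRIAL_COLUMNS = [
    "subject_id",
    "timepoint",
    "trial_index",
    "phase",
    "agent",
    "amount_now",
    "amount_delayed",
    "delay_days",
    "option_chosen",
    "feedback_correct",
]


def pairs_to_table(pairs: Sequence[OfferPair]) -> pd.DataFrame:
    """Offer pairs (e.g. the standard set) as a table with their
    indifference log-k values."""
    from .discounting import indifference_logk

    return pd.DataFrame(
        {
            "amount_now": [p.amount_now for p in pairs],
            "amount_delayed": [p.amount_delayed for p in pairs],
            "delay_days": [p.delay_days for p in pairs],
            "indifference_logk": [indifference_logk(p) for p in pairs],
        }
    )


def sessions_to_trials(sessions: Sequence[SessionRecord]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for c in s.choices:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "timepoint": s.timepoint,
                    "trial_index": c.trial_index,
                    "phase": c.phase,
                    "agent": c.agent,
                    "amount_now": c.offer.amount_now,
                    "amount_delayed": c.offer.amount_delayed,
                    "delay_days": c.offer.delay_days,
                    "option_chosen": c.option_chosen,
                    "feedback_correct": c.feedback_correct,
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _session_meta(s: SessionRecord) -> dict:
    meta = {
        "subject_id": s.subject_id,
        "timepoint": s.timepoint,
        "partner": dataclasses.asdict(s.partner),
        "logk_hat_phase1": s.logk_hat_phase1,
        "other_posterior_mean": s.other_posterior_mean,
        "other_posterior_var": s.other_posterior_var,
        "phase2_stop_trial": s.phase2_stop_trial,
        "seed": s.seed,
        "sigma_pref_session": s.sigma_pref_session,
    }
    if s.params is not None:
        meta["params"] = dataclasses.asdict(s.params)
    return meta


def trials_to_sessions(
    trials: pd.DataFrame, meta: Iterable[dict] | None = None
) -> list[SessionRecord]:
    """Rebuild :class:`SessionRecord` objects from a trial table.

    Without metadata, partner parameters are unknown (filled with NaN
    placeholders) — sufficient for per-phase fitting but not for shift
    direction or relevance estimation.
    """
    meta_by_key = {}
    for m in meta or []:
        meta_by_key[(m["subject_id"], m["timepoint"])] = m
    sessions = []
    for (sid, tp), g in trials.groupby(["subject_id", "timepoint"], sort=False):
        g = g.sort_values("trial_index")
        choices = [
            ChoiceRecord(
                trial_index=int(r.trial_index),
                phase=int(r.phase),
                agent=r.agent,
                option_chosen=r.option_chosen,
                offer=OfferPair(
                    amount_now=float(r.amount_now),
                    amount_delayed=float(r.amount_delayed),
                    delay_days=float(r.delay_days),
                ),
                feedback_correct=(
                    None if pd.isna(r.feedback_correct) else bool(r.feedback_correct)
                ),
            )
            for r in g.itertuples()
        ]
        m = meta_by_key.get((sid, tp), {})
        partner = m.get("partner", {})
        params = m.get("params")
        sessions.append(
            SessionRecord(
                subject_id=str(sid),
                timepoint=str(tp),
                choices=choices,
                partner=PartnerSpec(
                    logk_other=partner.get("logk_other", float("nan")),
                    direction=partner.get("direction", "unknown"),
                ),
                logk_hat_phase1=m.get("logk_hat_phase1", float("nan")),
                other_posterior_mean=m.get("other_posterior_mean", float("nan")),
                other_posterior_var=m.get("other_posterior_var", float("nan")),
                phase2_stop_trial=m.get(
                    "phase2_stop_trial", sum(1 for c in choices if c.phase == 2)
                ),
                seed=m.get("seed"),
                params=SubjectParams(**params) if params else None,
                sigma_pref_session=m.get("sigma_pref_session"),
            )
        )
    return sessions


def write_trials(sessions: Sequence[SessionRecord], path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    sessions_to_trials(sessions).to_csv(path, sep=sep, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def write_session_meta(sessions: Sequence[SessionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sessions:
            fh.write(json.dumps(_session_meta(s)) + "\n")


def read_session_meta(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def _build(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Cohort spec from a YAML mapping of :class:`CohortSpec` fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "followup_bounds" in data:
        data["followup_bounds"] = tuple(data["followup_bounds"])
    return _build(CohortSpec, data)


def load_task_config(path: str | Path) -> TaskConfig:
    """Task config from YAML; an optional ``design`` sub-mapping holds
    :class:`DesignConfig` fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "design" in data:
        design = data.pop("design")
        for key in ("delays", "standard_delays"):
            if key in design:
                design[key] = tuple(design[key])
        data["design"] = _build(DesignConfig, design)
    return _build(TaskConfig, data)
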
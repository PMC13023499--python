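"""End-to-end convenience: cohort generation through LOTO-CV evaluation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .classify import CVReport, loto_cv
from .features import (build_feature_table, mi_feature_ranking,
                       select_top_features)
from .synthetic import SessionConfig, SyntheticSession, generate_session

__all__ = ["PipelineResult", "run_cohort_pipeline"]


@dataclass(frozen=True)
class PipelineResult:
    session: SyntheticSession
    table: pd.DataFrame
    ranking: pd.DataFrame
    selected: list[str]
    report: CVReport


def run_cohort_pipeline(seed: int, *, n_participants: int = 5,
                        tasks=("EAT", "SHIP", "NBACK", "PVT"),
                        n_trials: int = 12,
                        trial_duration_s: float | None = 120.0,
                        coupling_kappa: float = 0.9,
                        top_k: int = 6,
                        target: str = "P_Asym",
                        linkage: str = "average",
                        ranking_group_by=("participant", "task")
                        ) -> PipelineResult:
    """Generate a cohort and run the full analysis chain.

    Feature extraction uses the default windowing (13,000 samples, 325-sample
    step at 200 Hz).  The MI ranking pools each participant's trials (the
    per-trial default needs longer trials than the scaled-down 120 s to
    populate 12 bins); classification is leave-one-trial-out per task.
    """
    config = SessionConfig(n_participants=n_participants, tasks=tuple(tasks),
                           n_trials=n_trials,
                           trial_duration_s=trial_duration_s,
                           coupling_kappa=coupling_kappa, seed=seed)
    session = generate_session(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = build_feature_table(session)
    ranking = mi_feature_ranking(table, target=target,
                                 group_by=ranking_group_by)
    selected = select_top_features(ranking, top_k)
    report = loto_cv(table, selected, target=target, linkage=linkage)
    return PipelineResult(session=session, table=table, ranking=ranking,
                          selected=selected, report=report)
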
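"""Glue: run both arms of a study configuration through trace + economics."""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import CohortTrace, run_trace
from .config import StudyConfig
from .economics import CEOutcome, ICERResult, evaluate_strategy, icer


@dataclass
class BaseCaseResult:
    config: StudyConfig
    trace_intervention: CohortTrace
    trace_comparator: CohortTrace
    outcome_intervention: CEOutcome
    outcome_comparator: CEOutcome
    icer: ICERResult


def run_base_case(config: StudyConfig, traces=None) -> BaseCaseResult:
    """Evaluate both arms and their incremental comparison.

    ``traces`` may carry precomputed (intervention, comparator) traces;
    sensitivity analyses that only perturb economic parameters reuse them,
    since state membership depends on the survival curves alone.
    """
    if traces is None:
        ti = run_trace(config.survival.intervention.os,
                       config.survival.intervention.pfs, config.settings)
        tc = run_trace(config.survival.comparator.os,
                       config.survival.comparator.pfs, config.settings)
    else:
        ti, tc = traces
    oi = evaluate_strategy(ti, config.intervention, config.costs,
                           config.utilities, config.population,
                           config.settings)
    oc = evaluate_strategy(tc, config.comparator, config.costs,
                           config.utilities, config.population,
                           config.settings)
    return BaseCaseResult(config=config, trace_intervention=ti,
                          trace_comparator=tc, outcome_intervention=oi,
                          outcome_comparator=oc, icer=icer(oi, oc))
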
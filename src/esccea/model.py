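"""Model/Results front door for the cost-effectiveness analysis.

``CostEffectivenessModel`` wraps a validated :class:`~esccea.config.StudyConfig`
and, statsmodels-style, ``fit()`` returns a :class:`CEAResults` carrying
the discounted totals per strategy, the incremental comparison, and a
``summary()`` table.  Sensitivity analyses hang off the model.

>>> from esccea import CostEffectivenessModel
>>> res = CostEffectivenessModel.from_tables("overall").fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sensitivity
from .config import StudyConfig, load_config
from .economics import net_monetary_benefit
from .engine import BaseCaseResult, run_base_case


class CostEffectivenessModel:
    """Markov cohort cost-effectiveness model for one study configuration."""

    def __init__(self, config: StudyConfig):
        self.config = config.validate()

    @classmethod
    def from_yaml(cls, path) -> "CostEffectivenessModel":
        return cls(load_config(path))

    @classmethod
    def from_tables(cls, stratum: str = "overall") -> "CostEffectivenessModel":
        """Model built from the published input tables for one PD-L1 stratum."""
        from .synthetic import make_config_fixture
        return cls(make_config_fixture(stratum))

    def fit(self) -> "CEAResults":
        """Run the cohort trace and economic accrual for both arms."""
        return CEAResults(self, run_base_case(self.config))

    # -- sensitivity front ends ----------------------------------------

    def one_way(self, ranges=None) -> pd.DataFrame:
        """One-way (tornado) sensitivity analysis; see :func:`esccea.sensitivity.one_way_sa`."""
        return sensitivity.one_way_sa(self.config, ranges)

    def psa(self, n: int = 10000, seed: int = 0) -> sensitivity.PSAResult:
        """Probabilistic sensitivity analysis with ``n`` seeded draws."""
        return sensitivity.run_psa(self.config, n=n, seed=seed)

    def threshold_price(self, wtp: float | None = None,
                        **kwargs) -> sensitivity.ThresholdResult:
        """Drug-price multiplier at which the ICER meets the WTP."""
        return sensitivity.threshold_price(self.config, wtp, **kwargs)

    def subgroup(self, spec: sensitivity.SubgroupSpec) -> BaseCaseResult:
        """Hazard-ratio subgroup re-analysis."""
        return sensitivity.subgroup_analysis(self.config, spec)


class CEAResults:
    """Fitted base-case results: discounted totals and the ICER."""

    def __init__(self, model: CostEffectivenessModel, base: BaseCaseResult):
        self.model = model
        self.config = base.config
        self._base = base
        self.outcome_intervention = base.outcome_intervention
        self.outcome_comparator = base.outcome_comparator
        self.icer_result = base.icer
        self.trace_intervention = base.trace_intervention
        self.trace_comparator = base.trace_comparator

    # -- tabular views --------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Base-case table: one row per strategy plus incremental columns."""
        inc = self.icer_result
        rows = []
        for oc, is_int in ((self.outcome_intervention, True),
                           (self.outcome_comparator, False)):
            rows.append({
                "strategy": oc.strategy,
                "total_cost": oc.total_cost,
                "total_ly": oc.total_ly,
                "total_qaly": oc.total_qaly,
                "icer_per_ly": inc.icer_per_ly if is_int else np.nan,
                "icer_per_qaly": inc.icer_per_qaly if is_int else np.nan,
            })
        return pd.DataFrame(rows)

    def incremental_nmb(self, wtp: float | None = None) -> float:
        """Incremental net monetary benefit at ``wtp`` (default: configured WTP)."""
        wtp = self.config.settings.wtp_per_qaly if wtp is None else wtp
        return (net_monetary_benefit(self.outcome_intervention, wtp)
                - net_monetary_benefit(self.outcome_comparator, wtp))

    def summary(self) -> str:
        inc = self.icer_result
        s = self.config.settings
        lines = [
            "Cost-effectiveness analysis (Markov cohort model)",
            "=" * 58,
            f"study:            {self.config.label}",
            f"stratum:          {self.config.population.stratum}",
            f"cycles:           {s.n_cycles} x {s.cycle_length_days:g} days, "
            f"horizon {s.horizon_years:g} y",
            f"discount rate:    {s.annual_discount_rate:.1%} per year",
            f"WTP threshold:    ${s.wtp_per_qaly:,.0f}/QALY",
            "-" * 58,
            f"{'strategy':<20}{'cost ($)':>12}{'LY':>9}{'QALY':>9}",
        ]
        for oc in (self.outcome_intervention, self.outcome_comparator):
            lines.append(f"{oc.strategy:<20}{oc.total_cost:>12,.0f}"
                         f"{oc.total_ly:>9.3f}{oc.total_qaly:>9.3f}")
        lines.append("-" * 58)
        lines.append(f"incremental cost: ${inc.delta_cost:,.0f}")
        lines.append(f"incremental LY:   {inc.delta_ly:.4f}")
        lines.append(f"incremental QALY: {inc.delta_qaly:.4f}")
        if inc.status == "ok":
            lines.append(f"ICER:             ${inc.icer_per_qaly:,.0f}/QALY "
                         f"(${inc.icer_per_ly:,.0f}/LY)")
        else:
            lines.append(f"ICER:             {inc.status}")
        lines.append(f"incremental NMB:  ${self.incremental_nmb():,.0f} "
                     f"at configured WTP")
        return "\n".join(lines)

    def __repr__(self):  # pragma: no cover
        return f"<CEAResults {self.config.label}: " \
               f"ICER={self.icer_result.icer_per_qaly}>"
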
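"""Three-state cohort trace: progression-free, progressed, dead.

The cohort starts entirely progression-free.  Each cycle, the per-cycle
death probability derived from the overall-survival (OS) curve applies to
both alive states, and the excess of the PFS-exit probability over the
death probability moves patients from PFS to the progressed (PD) state.
With that construction the Markov trace coincides, cycle by cycle, with
partitioned-survival membership (PFS = S_pfs, PD = S_os - S_pfs,
dead = 1 - S_os) whenever the curves do not cross, which is the behaviour
a model parameterized directly from OS and PFS curves should have.

Time-scale convention
---------------------
The cycle grid is laid out in calendar months (``cycle_length_days``,
default 14 days), and life-years/discounting always use calendar time.
The time fed into the survival curves is controlled by
``transition_time_scale``:

* ``"cycle"`` (default) - the curve is evaluated at the cycle *index*
  (t = k, u = 1).  This is the convention under which the published
  results of the analysis this package reproduces were generated (the
  TreeAge ``_stage`` convention), with Weibull parameters on a monthly
  axis.
* ``"months"`` - the curve is evaluated at calendar months
  (t = k*u_months), the literal reading of a monthly parameterization.

Both are supported so the consequences of the convention can be examined;
see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import ParametricSurvival

DAYS_PER_MONTH = 30.4375  # 365.25 / 12


@dataclass
class EconSettings:
    """Global model settings: cycle grid, horizon, discounting, WTP."""

    cycle_length_days: float = 14.0
    horizon_years: float = 10.0
    annual_discount_rate: float = 0.05
    wtp_per_qaly: float = 36438.0
    half_cycle_correction: bool = False
    transition_time_scale: str = "cycle"  # "cycle" | "months"
    monitoring_in_pd: bool = False  # charge lab+imaging while progressed

    @property
    def cycle_length_months(self) -> float:
        return self.cycle_length_days / DAYS_PER_MONTH

    @property
    def horizon_months(self) -> float:
        return self.horizon_years * 12.0

    @property
    def n_cycles(self) -> int:
        return int(math.ceil(self.horizon_months / self.cycle_length_months))

    def validate(self) -> list:
        problems = []
        if self.cycle_length_days <= 0:
            problems.append("settings.cycle_length_days must be > 0")
        if self.horizon_years <= 0:
            problems.append("settings.horizon_years must be > 0")
        if not 0.0 <= self.annual_discount_rate <= 0.08:
            problems.append("settings.annual_discount_rate outside [0, 0.08]")
        if self.wtp_per_qaly < 0:
            problems.append("settings.wtp_per_qaly must be >= 0")
        if self.transition_time_scale not in ("cycle", "months"):
            problems.append("settings.transition_time_scale must be 'cycle' or 'months'")
        return problems


@dataclass
class CohortTrace:
    """Per-cycle state membership.

    ``data`` has one row per cycle boundary (row 0 = model start) with
    columns cycle_index, time_start (months), membership_pfs,
    membership_pd, membership_dead, new_deaths (deaths during the cycle
    ending at this boundary).
    """

    data: pd.DataFrame
    clamped_cycles: int = 0  # cycles where PFS-exit < death prob (curves crossing)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "CohortTrace":
        return cls(pd.read_csv(path))


def partitioned_membership(os_model: ParametricSurvival,
                           pfs_model: ParametricSurvival, t):
    """Partitioned-survival state membership at time ``t``.

    Returns ``(pfs, pd, dead) = (S_pfs, max(0, S_os - S_pfs), 1 - S_os)``.
    Serves as the independent oracle for :func:`run_trace`.
    """
    s_os = np.asarray(os_model.survival(t), dtype=float)
    s_pfs = np.asarray(pfs_model.survival(t), dtype=float)
    pfs = s_pfs
    pd_ = np.maximum(0.0, s_os - s_pfs)
    dead = 1.0 - s_os
    if pfs.ndim == 0:
        return float(pfs), float(pd_), float(dead)
    return pfs, pd_, dead


def run_trace(os_model: ParametricSurvival, pfs_model: ParametricSurvival,
              settings: EconSettings) -> CohortTrace:
    """Run the three-state Markov cohort over the model horizon.

    Death is absorbing; the per-cycle death probability from the OS curve
    applies equally to the PFS and PD states; PFS->PD receives the excess
    of the PFS-exit probability over the death probability, clamped at
    zero (clamped cycles are counted on the returned trace).
    """
    problems = settings.validate()
    if problems:
        raise ValueError("; ".join(problems))
    n = settings.n_cycles
    u_model = 1.0 if settings.transition_time_scale == "cycle" \
        else settings.cycle_length_months

    pfs = np.empty(n + 1)
    pd_ = np.empty(n + 1)
    dead = np.empty(n + 1)
    new_deaths = np.zeros(n + 1)
    pfs[0], pd_[0], dead[0] = 1.0, 0.0, 0.0
    clamped = 0
    for k in range(1, n + 1):
        t = k * u_model
        tp_death = os_model.transition_probability(t, u_model)
        tp_pfs_exit = pfs_model.transition_probability(t, u_model)
        tp_progress = tp_pfs_exit - tp_death
        if tp_progress < 0:
            tp_progress = 0.0
            clamped += 1
        deaths = (pfs[k - 1] + pd_[k - 1]) * tp_death
        pfs[k] = pfs[k - 1] * (1.0 - tp_death - tp_progress)
        pd_[k] = pd_[k - 1] * (1.0 - tp_death) + pfs[k - 1] * tp_progress
        dead[k] = dead[k - 1] + deaths
        new_deaths[k] = deaths
        # guard tiny negative round-off
        if pfs[k] < 0.0:
            pfs[k] = 0.0
        if pd_[k] < 0.0:
            pd_[k] = 0.0

    u_months = settings.cycle_length_months
    data = pd.DataFrame({
        "cycle_index": np.arange(n + 1),
        "time_start": np.arange(n + 1) * u_months,
        "membership_pfs": pfs,
        "membership_pd": pd_,
        "membership_dead": dead,
        "new_deaths": new_deaths,
    })
    return CohortTrace(data, clamped_cycles=clamped)
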
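"""Cost, utility, discounting and ICER computation over a cohort trace.

Costing conventions (all configurable where noted):

* First-line drugs are charged per cycle while in the progression-free
  state, until each drug's cycle cap is exhausted (immunotherapy capped at
  2 years = 52 two-week cycles, cisplatin at 8 cycles, 5-FU at 12 cycles).
* Administration is charged in any cycle in which an intravenous drug is
  actually given (first line within caps; the second-line fraction while
  progressed).
* Routine monitoring (laboratory + imaging) is charged per cycle in the
  progression-free state; charging it in the progressed state as well is
  available via ``EconSettings.monitoring_in_pd``.
* While progressed, the second-line proportion of the cohort receives the
  second-line drug plus administration and the remainder receives best
  supportive care, with no duration cap.
* PD-L1 testing and the lump adverse-event cost are charged once at model
  start; terminal care is charged per death in the cycle it occurs.
* Drug costs scale linearly with body weight (per-kg dosing) or body
  surface area (per-m2 dosing) relative to the reference patient
  (65 kg, 1.72 m2); at the reference the printed per-cycle prices apply
  unchanged.
* Adverse-event disutility (sum of incidence x decrement) is a one-time
  QALY subtraction at model start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortTrace, EconSettings

REF_WEIGHT_KG = 65.0
REF_BSA_M2 = 1.72


@dataclass
class DrugSchedule:
    """One drug line: per-cycle price, cycle cap, and dose-scaling rule."""

    name: str
    cost_per_cycle: float
    max_cycles: int | None = None  # None = no cap
    scaling: str = "none"  # per_weight | per_bsa | none

    def validate(self, prefix: str) -> list:
        problems = []
        if self.cost_per_cycle < 0:
            problems.append(f"{prefix}.cost_per_cycle must be >= 0")
        if self.max_cycles is not None and self.max_cycles < 1:
            problems.append(f"{prefix}.max_cycles must be >= 1 when finite")
        if self.scaling not in ("per_weight", "per_bsa", "none"):
            problems.append(f"{prefix}.scaling must be per_weight|per_bsa|none")
        return problems


@dataclass
class AdverseEvent:
    """Grade >=3 adverse event with incidence and utility decrement."""

    event: str
    incidence: float
    disutility: float

    def validate(self, prefix: str) -> list:
        problems = []
        if not 0.0 <= self.incidence <= 1.0:
            problems.append(f"{prefix}.incidence outside [0, 1]")
        if not 0.0 <= self.disutility <= 1.0:
            problems.append(f"{prefix}.disutility outside [0, 1]")
        return problems


@dataclass
class StrategySpec:
    """One treatment arm: schedule, caps, AE profile, second-line use."""

    name: str
    first_line_drugs: list
    second_line_proportion: float
    second_line_drug: DrugSchedule
    ae_profile: list
    ae_lump_cost: float

    def validate(self, prefix: str) -> list:
        problems = []
        if not 0.0 <= self.second_line_proportion <= 1.0:
            problems.append(f"{prefix}.second_line_proportion outside [0, 1]")
        if self.ae_lump_cost < 0:
            problems.append(f"{prefix}.ae_lump_cost must be >= 0")
        for d in self.first_line_drugs:
            problems += d.validate(f"{prefix}.first_line_drugs[{d.name}]")
        problems += self.second_line_drug.validate(f"{prefix}.second_line_drug")
        for ae in self.ae_profile:
            problems += ae.validate(f"{prefix}.ae_profile[{ae.event}]")
        return problems


@dataclass
class CostTable:
    """Shared per-cycle and per-event costs (US dollars)."""

    laboratory_per_cycle: float
    imaging_per_cycle: float
    administration_per_cycle: float
    bsc_per_cycle: float
    terminal_care_per_patient: float
    pdl1_test_per_patient: float

    def validate(self) -> list:
        return [f"costs.{k} must be >= 0"
                for k, v in vars(self).items() if v < 0]


@dataclass
class UtilitySet:
    """Health-state utilities (0 = dead, 1 = perfect health)."""

    pfs: float
    pd: float

    def validate(self) -> list:
        problems = []
        if not 0.0 <= self.pd:
            problems.append("utilities.pd must be >= 0")
        if self.pd > self.pfs:
            problems.append("utilities.pd must not exceed utilities.pfs "
                            f"(pd={self.pd}, pfs={self.pfs})")
        if self.pfs > 1.0:
            problems.append("utilities.pfs must be <= 1")
        return problems


@dataclass
class PopulationSpec:
    """Modelled patient characteristics."""

    body_weight_kg: float = REF_WEIGHT_KG
    body_surface_area_m2: float = REF_BSA_M2
    stratum: str = "overall"

    def validate(self) -> list:
        problems = []
        if self.body_weight_kg <= 0:
            problems.append("population.body_weight_kg must be > 0")
        if self.body_surface_area_m2 <= 0:
            problems.append("population.body_surface_area_m2 must be > 0")
        return problems


@dataclass
class CEOutcome:
    """Discounted totals for one strategy."""

    strategy: str
    total_cost: float
    total_ly: float
    total_qaly: float


@dataclass
class ICERResult:
    """Incremental comparison of two strategies."""

    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_qaly: float | None
    icer_per_ly: float | None
    status: str  # "ok" | "dominant" | "dominated" | "undefined"


def discount_factor(annual_rate: float, time_years):
    """Discrete annual discounting, 1/(1+r)**t."""
    if annual_rate < 0:
        raise ValueError("discount rate must be >= 0")
    t = np.asarray(time_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    d = (1.0 + annual_rate) ** (-t)
    return d if d.ndim else float(d)


def _drug_scale(drug: DrugSchedule, population: PopulationSpec) -> float:
    if drug.scaling == "per_weight":
        return population.body_weight_kg / REF_WEIGHT_KG
    if drug.scaling == "per_bsa":
        return population.body_surface_area_m2 / REF_BSA_M2
    return 1.0


def cycle_cost(strategy: StrategySpec, costs: CostTable, state: str,
               cycle_index: int, population: PopulationSpec,
               monitoring_in_pd: bool = False) -> float:
    """Recurring cost for one cycle spent in ``state``.

    ``cycle_index`` is the 1-based treatment cycle number; a drug with
    ``max_cycles = m`` is charged for cycles 1..m.  One-time costs
    (PD-L1 test, AE lump, terminal care) are handled by
    :func:`one_time_costs`.
    """
    if state == "dead":
        return 0.0
    if state == "pfs":
        total, any_drug = 0.0, False
        for d in strategy.first_line_drugs:
            if d.max_cycles is None or cycle_index <= d.max_cycles:
                total += d.cost_per_cycle * _drug_scale(d, population)
                any_drug = True
        if any_drug:
            total += costs.administration_per_cycle
        total += costs.laboratory_per_cycle + costs.imaging_per_cycle
        return total
    if state == "pd":
        sl = strategy.second_line_drug
        on_sl = sl.max_cycles is None or cycle_index <= sl.max_cycles
        p = strategy.second_line_proportion if on_sl else 0.0
        total = p * (sl.cost_per_cycle * _drug_scale(sl, population)
                     + costs.administration_per_cycle)
        total += (1.0 - strategy.second_line_proportion) * costs.bsc_per_cycle
        if monitoring_in_pd:
            total += costs.laboratory_per_cycle + costs.imaging_per_cycle
        return total
    raise ValueError(f"unknown state {state!r}")


def _cost_vectors(strategy: StrategySpec, costs: CostTable,
                  population: PopulationSpec, monitoring_in_pd: bool,
                  cyc: np.ndarray):
    """Vectorized per-cycle state costs; agrees with :func:`cycle_cost`."""
    pfs_costs = np.zeros_like(cyc, dtype=float)
    any_drug = np.zeros_like(cyc, dtype=bool)
    for d in strategy.first_line_drugs:
        active = np.ones_like(cyc, dtype=bool) if d.max_cycles is None \
            else cyc <= d.max_cycles
        pfs_costs += np.where(active, d.cost_per_cycle * _drug_scale(d, population), 0.0)
        any_drug |= active
    pfs_costs += np.where(any_drug, costs.administration_per_cycle, 0.0)
    pfs_costs += costs.laboratory_per_cycle + costs.imaging_per_cycle

    sl = strategy.second_line_drug
    on_sl = np.ones_like(cyc, dtype=bool) if sl.max_cycles is None \
        else cyc <= sl.max_cycles
    p = strategy.second_line_proportion
    pd_costs = np.where(on_sl, p * (sl.cost_per_cycle * _drug_scale(sl, population)
                                    + costs.administration_per_cycle), 0.0)
    pd_costs = pd_costs + (1.0 - p) * costs.bsc_per_cycle
    if monitoring_in_pd:
        pd_costs = pd_costs + costs.laboratory_per_cycle + costs.imaging_per_cycle
    return pfs_costs, pd_costs


def one_time_costs(strategy: StrategySpec, costs: CostTable,
                   trace: CohortTrace, settings: EconSettings) -> np.ndarray:
    """Per-row stream of one-time costs (undiscounted).

    PD-L1 testing and the lump AE cost fall on row 0; terminal care falls
    on each row in proportion to the deaths occurring in the cycle ending
    there.
    """
    stream = np.zeros(trace.n_rows)
    stream[0] = costs.pdl1_test_per_patient + strategy.ae_lump_cost
    stream += costs.terminal_care_per_patient * trace.data["new_deaths"].to_numpy()
    return stream


def ae_disutility(profile) -> float:
    """One-time QALY decrement: sum of incidence x disutility."""
    return float(sum(ae.incidence * ae.disutility for ae in profile))


def evaluate_strategy(trace: CohortTrace, strategy: StrategySpec,
                      costs: CostTable, utilities: UtilitySet,
                      population: PopulationSpec,
                      settings: EconSettings) -> CEOutcome:
    """Accrue discounted cost, life-years and QALYs over a trace."""
    if trace.n_rows != settings.n_cycles + 1:
        raise ValueError(
            f"trace has {trace.n_rows} rows but settings imply "
            f"{settings.n_cycles + 1}")
    u_months = settings.cycle_length_months
    cycle_years = u_months / 12.0
    n = settings.n_cycles

    m_pfs = trace.data["membership_pfs"].to_numpy()
    m_pd = trace.data["membership_pd"].to_numpy()
    if settings.half_cycle_correction:
        occ_pfs = 0.5 * (m_pfs[:-1] + m_pfs[1:])
        occ_pd = 0.5 * (m_pd[:-1] + m_pd[1:])
    else:
        occ_pfs = m_pfs[:-1]
        occ_pd = m_pd[:-1]

    t_start_years = trace.data["time_start"].to_numpy()[:-1] / 12.0
    df_start = discount_factor(settings.annual_discount_rate, t_start_years)

    cyc = np.arange(1, n + 1)
    pfs_costs, pd_costs = _cost_vectors(strategy, costs, population,
                                        settings.monitoring_in_pd, cyc)

    recurring = np.sum((occ_pfs * pfs_costs + occ_pd * pd_costs) * df_start)
    stream = one_time_costs(strategy, costs, trace, settings)
    df_rows = discount_factor(settings.annual_discount_rate,
                              trace.data["time_start"].to_numpy() / 12.0)
    total_cost = recurring + float(np.sum(stream * df_rows))

    total_ly = float(np.sum((occ_pfs + occ_pd) * cycle_years * df_start))
    total_qaly = float(np.sum(
        (occ_pfs * utilities.pfs + occ_pd * utilities.pd)
        * cycle_years * df_start))
    total_qaly -= ae_disutility(strategy.ae_profile)
    return CEOutcome(strategy=strategy.name, total_cost=total_cost,
                     total_ly=total_ly, total_qaly=max(total_qaly, 0.0))


def icer(intervention: CEOutcome, comparator: CEOutcome) -> ICERResult:
    """Incremental cost-effectiveness of intervention vs comparator."""
    dc = intervention.total_cost - comparator.total_cost
    dly = intervention.total_ly - comparator.total_ly
    dq = intervention.total_qaly - comparator.total_qaly
    if dq > 0 and dc < 0:
        status, per_qaly = "dominant", None
    elif dq < 0 and dc > 0:
        status, per_qaly = "dominated", None
    elif dq == 0:
        status = "ok" if dc == 0 else "undefined"
        per_qaly = 0.0 if dc == 0 else None
    else:
        status, per_qaly = "ok", dc / dq
    per_ly = dc / dly if dly != 0 else None
    return ICERResult(delta_cost=dc, delta_ly=dly, delta_qaly=dq,
                      icer_per_qaly=per_qaly, icer_per_ly=per_ly,
                      status=status)


def net_monetary_benefit(outcome: CEOutcome, wtp: float) -> float:
    """NMB = WTP x QALY - cost; higher is better."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * outcome.total_qaly - outcome.total_cost
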
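"""Synthetic inputs: digitized-KM emulation and complete study fixtures.

Two jobs live here.  ``generate_km_points`` emulates the (time, survival)
point sets produced by digitizing published Kaplan-Meier figures - truth
curves plus additive Gaussian digitization error, monotonized - so the
fitting stage can be exercised end to end without any external file.
``make_config_fixture`` builds the complete, validated study configuration
for the serplulimab + cisplatin/5-fluorouracil (CF) versus CF comparison
in PD-L1-positive advanced esophageal squamous cell carcinoma: Weibull
OS/PFS curves per arm and PD-L1 stratum, drug schedules and caps, adverse
event profiles, utilities, unit costs, and the uncertainty ranges and
distributions driving the sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import EconSettings
from .config import ArmCurves, ParamRange, StudyConfig, SurvivalSet
from .economics import (AdverseEvent, CostTable, DrugSchedule,
                        PopulationSpec, StrategySpec, UtilitySet)
from .survival import KMPoints, ParametricSurvival

STRATA = ("overall", "cps_1_to_10", "cps_ge_10")

# Weibull (scale, shape) per stratum, monthly time axis
WEIBULL_PARAMETERS = {
    "overall": {
        "intervention": {"os": (0.02617, 1.16846), "pfs": (0.10927, 0.97361)},
        "comparator": {"os": (0.020542, 1.404457), "pfs": (0.0931, 1.32774)},
    },
    "cps_1_to_10": {
        "intervention": {"os": (0.029888, 1.176584), "pfs": (0.10943, 1.05893)},
        "comparator": {"os": (0.0127079, 1.6243877), "pfs": (0.06808, 1.50072)},
    },
    "cps_ge_10": {
        "intervention": {"os": (0.016952, 1.254789), "pfs": (0.087778, 0.989156)},
        "comparator": {"os": (0.030741, 1.212235), "pfs": (0.06808, 1.524542)},
    },
}

# 2-week dosing: immunotherapy capped at 2 years, cisplatin at 8 cycles,
# 5-FU at 12 cycles
_SERPLULIMAB_MAX_CYCLES = 52
_CISPLATIN_MAX_CYCLES = 8
_FLUOROURACIL_MAX_CYCLES = 12


@dataclass
class SyntheticScenario:
    """Known truth curves plus a digitization-noise model."""

    os_truth: ParametricSurvival
    pfs_truth: ParametricSurvival
    grid: np.ndarray  # months, strictly increasing
    digitization_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.digitization_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def _noisy_curve(truth, grid, sd, rng):
    s = np.asarray(truth.survival(grid), dtype=float)
    if sd > 0:
        s = s + rng.normal(0.0, sd, size=len(grid))
    s = np.clip(s, 1e-6, 1.0)
    return np.minimum.accumulate(s)  # digitized curves cannot rise


def generate_km_points(scenario: SyntheticScenario):
    """Emit (OS, PFS) digitized-KM point sets for a scenario.

    Survival values are the truth curves plus independent Gaussian noise,
    clipped to (0, 1] and monotonized by running minimum; PFS is then
    clipped to never exceed OS at the same time.  Reproducible by seed.
    """
    rng = np.random.default_rng(scenario.seed)
    s_os = _noisy_curve(scenario.os_truth, scenario.grid,
                        scenario.digitization_noise_sd, rng)
    s_pfs = _noisy_curve(scenario.pfs_truth, scenario.grid,
                         scenario.digitization_noise_sd, rng)
    s_pfs = np.minimum(s_pfs, s_os)
    os_pts = KMPoints(list(zip(scenario.grid, s_os)), label="OS")
    pfs_pts = KMPoints(list(zip(scenario.grid, s_pfs)), label="PFS")
    return os_pts, pfs_pts


def _curves(stratum: str) -> SurvivalSet:
    w = WEIBULL_PARAMETERS[stratum]

    def arm(name):
        return ArmCurves(os=ParametricSurvival("weibull", w[name]["os"]),
                         pfs=ParametricSurvival("weibull", w[name]["pfs"]))

    return SurvivalSet(intervention=arm("intervention"),
                       comparator=arm("comparator"))


def _intervention_strategy() -> StrategySpec:
    return StrategySpec(
        name="serplulimab_cf",
        first_line_drugs=[
            DrugSchedule("serplulimab", 198.0, _SERPLULIMAB_MAX_CYCLES, "per_weight"),
            DrugSchedule("cisplatin", 12.0, _CISPLATIN_MAX_CYCLES, "per_bsa"),
            DrugSchedule("fluorouracil", 127.0, _FLUOROURACIL_MAX_CYCLES, "per_bsa"),
        ],
        # trial-reported share receiving active second-line therapy
        second_line_proportion=0.38,
        second_line_drug=DrugSchedule("paclitaxel", 180.0, None, "per_bsa"),
        ae_profile=[
            AdverseEvent("anemia", 0.18, 0.074),
            AdverseEvent("hyponatremia", 0.05, 0.0),
            AdverseEvent("neutrophil_count_decreased", 0.19, 0.09),
            AdverseEvent("white_blood_cell_count_decreased", 0.11, 0.09),
        ],
        ae_lump_cost=65.0,
    )


def _comparator_strategy() -> StrategySpec:
    return StrategySpec(
        name="cf",
        first_line_drugs=[
            DrugSchedule("cisplatin", 12.0, _CISPLATIN_MAX_CYCLES, "per_bsa"),
            DrugSchedule("fluorouracil", 127.0, _FLUOROURACIL_MAX_CYCLES, "per_bsa"),
        ],
        second_line_proportion=0.52,
        second_line_drug=DrugSchedule("paclitaxel", 180.0, None, "per_bsa"),
        ae_profile=[
            AdverseEvent("anemia", 0.20, 0.074),
            AdverseEvent("neutrophil_count_decreased", 0.17, 0.09),
            AdverseEvent("white_blood_cell_count_decreased", 0.07, 0.09),
        ],
        ae_lump_cost=60.0,
    )


def _uncertainty() -> list:
    """Published ranges (+/-20% of baseline) and assigned distributions.

    Order is the canonical sampling order of the probabilistic analysis:
    costs, AE incidences, utilities, disutilities, weight, body surface
    area, discount rate, second-line proportions.
    """
    both = ["intervention", "comparator"]

    def fl(drug):
        return [f"{arm}.first_line_drugs[{drug}].cost_per_cycle" for arm in both]

    def ae(event, leaf, arms=both):
        return [f"{arm}.ae_profile[{event}].{leaf}" for arm in arms]

    P = ParamRange
    return [
        # costs (gamma)
        P("cost_serplulimab", 158, 238, "gamma",
          ["intervention.first_line_drugs[serplulimab].cost_per_cycle"]),
        P("cost_cisplatin", 10, 14, "gamma", fl("cisplatin")),
        P("cost_fluorouracil", 102, 152, "gamma", fl("fluorouracil")),
        P("cost_paclitaxel", 144, 216, "gamma",
          [f"{arm}.second_line_drug.cost_per_cycle" for arm in both]),
        P("cost_ae_intervention", 52, 78, "gamma", ["intervention.ae_lump_cost"]),
        P("cost_ae_comparator", 48, 72, "gamma", ["comparator.ae_lump_cost"]),
        P("cost_laboratory", 42, 64, "gamma", ["costs.laboratory_per_cycle"]),
        P("cost_imaging", 130, 194, "gamma", ["costs.imaging_per_cycle"]),
        P("cost_administration", 10, 14, "gamma", ["costs.administration_per_cycle"]),
        P("cost_pdl1_test", 69, 103, "gamma", ["costs.pdl1_test_per_patient"]),
        P("cost_bsc", 56, 84, "gamma", ["costs.bsc_per_cycle"]),
        P("cost_terminal_care", 1122, 1682, "gamma",
          ["costs.terminal_care_per_patient"]),
        # AE incidences (beta)
        P("inc_anemia_intervention", 0.144, 0.216, "beta",
          ae("anemia", "incidence", ["intervention"])),
        P("inc_hyponatremia_intervention", 0.040, 0.060, "beta",
          ae("hyponatremia", "incidence", ["intervention"])),
        P("inc_neutropenia_intervention", 0.152, 0.228, "beta",
          ae("neutrophil_count_decreased", "incidence", ["intervention"])),
        P("inc_leukopenia_intervention", 0.088, 0.132, "beta",
          ae("white_blood_cell_count_decreased", "incidence", ["intervention"])),
        P("inc_anemia_comparator", 0.160, 0.240, "beta",
          ae("anemia", "incidence", ["comparator"])),
        P("inc_neutropenia_comparator", 0.136, 0.204, "beta",
          ae("neutrophil_count_decreased", "incidence", ["comparator"])),
        P("inc_leukopenia_comparator", 0.056, 0.084, "beta",
          ae("white_blood_cell_count_decreased", "incidence", ["comparator"])),
        # utilities (beta)
        P("utility_pfs", 0.544, 0.816, "beta", ["utilities.pfs"]),
        P("utility_pd", 0.336, 0.504, "beta", ["utilities.pd"]),
        # disutilities (beta), shared across arms
        P("disutility_anemia", 0.059, 0.089, "beta", ae("anemia", "disutility")),
        P("disutility_neutropenia", 0.072, 0.108, "beta",
          ae("neutrophil_count_decreased", "disutility")),
        P("disutility_leukopenia", 0.072, 0.108, "beta",
          ae("white_blood_cell_count_decreased", "disutility")),
        # population (normal)
        P("body_weight", 52, 78, "normal", ["population.body_weight_kg"]),
        P("body_surface_area", 1.38, 2.06, "normal",
          ["population.body_surface_area_m2"]),
        # discount (uniform)
        P("discount_rate", 0.0, 0.08, "uniform", ["settings.annual_discount_rate"]),
        # second-line proportions (beta)
        P("secondline_intervention", 0.304, 0.456, "beta",
          ["intervention.second_line_proportion"]),
        P("secondline_comparator", 0.416, 0.624, "beta",
          ["comparator.second_line_proportion"]),
    ]


def make_config_fixture(stratum: str = "overall") -> StudyConfig:
    """Complete validated study configuration for one PD-L1 stratum."""
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
    cfg = StudyConfig(
        label=f"serplulimab_cf_vs_cf_{stratum}",
        settings=EconSettings(),
        population=PopulationSpec(stratum=stratum),
        utilities=UtilitySet(pfs=0.68, pd=0.42),
        costs=CostTable(
            laboratory_per_cycle=53.0,
            imaging_per_cycle=162.0,
            administration_per_cycle=12.0,
            bsc_per_cycle=70.0,
            terminal_care_per_patient=1402.0,
            pdl1_test_per_patient=86.0,
        ),
        survival=_curves(stratum),
        intervention=_intervention_strategy(),
        comparator=_comparator_strategy(),
        uncertainty=_uncertainty(),
    )
    return cfg.validate()
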
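"""Deterministic and probabilistic sensitivity analyses.

One-way analysis re-runs the model at the low/high bound of each uncertain
parameter (all others at baseline) and orders the resulting ICER spreads
for a tornado diagram.  The probabilistic analysis draws every uncertain
parameter from its assigned distribution - beta for probabilities and
utilities, gamma for costs, normal for weight and body surface area,
uniform for the discount rate - parameterized by method of moments with
SE = (max - min) / (2 * 1.96), evaluates the model per draw, and summarizes
acceptance probabilities and the cost-effectiveness acceptability curve.
A bisection on the intervention drug price finds the multiplier at which
the ICER meets the willingness-to-pay threshold, and hazard-ratio-based
subgroups rescale the comparator's curves by proportional hazards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ParamRange, StudyConfig, get_path
from .engine import run_base_case
from .survival import proportional_hazards

log = logging.getLogger(__name__)

_Z95 = 1.96  # conventional two-sided 95% multiplier


# -- distribution parameterization -------------------------------------


def beta_from_mean_range(mean: float, low: float, high: float):
    """Method-of-moments beta parameters from mean and 95% range.

    SE = (high - low) / (2 * 1.96); alpha = mean*(mean(1-mean)/SE^2 - 1),
    beta = alpha*(1-mean)/mean.  Returns None when the implied variance is
    infeasible for a beta (SE^2 >= mean(1-mean)); the caller falls back to
    a uniform draw on [low, high].
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("beta mean must lie strictly inside (0, 1)")
    if low >= high:
        raise ValueError("need low < high")
    se = (high - low) / (2.0 * _Z95)
    var = se * se
    if var >= mean * (1.0 - mean):
        return None
    alpha = mean * (mean * (1.0 - mean) / var - 1.0)
    beta = alpha * (1.0 - mean) / mean
    return alpha, beta


def gamma_from_mean_range(mean: float, low: float, high: float):
    """Method-of-moments gamma (shape, scale) from mean and 95% range."""
    if mean <= 0:
        raise ValueError("gamma mean must be positive")
    if low >= high:
        raise ValueError("need low < high")
    se = (high - low) / (2.0 * _Z95)
    var = se * se
    return mean * mean / var, var / mean


# -- one-way sensitivity -----------------------------------------------


def _clamped_assignments(config: StudyConfig, pr: ParamRange, value):
    """Assignments for one parameter end, clamped to a valid model."""
    assignments = {p: value for p in pr.paths}
    note = ""
    # utility ordering is the one pairwise constraint a +/-20% range can break
    u_pfs = assignments.get("utilities.pfs", config.utilities.pfs)
    u_pd = assignments.get("utilities.pd", config.utilities.pd)
    if u_pd > u_pfs:
        if "utilities.pd" in assignments:
            assignments["utilities.pd"] = u_pfs
        else:
            assignments["utilities.pfs"] = u_pd
        note = "clamped to keep utility_pd <= utility_pfs"
    return assignments, note


def one_way_sa(config: StudyConfig, ranges=None) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's low/high bound.

    Returns a DataFrame with columns (parameter, base, low, high,
    icer_low, icer_high, spread, note), sorted by descending spread.
    """
    ranges = config.uncertainty if ranges is None else ranges
    base = run_base_case(config)
    traces = (base.trace_intervention, base.trace_comparator)
    rows = []
    for pr in ranges:
        base_value = get_path(config, pr.paths[0])
        icers = {}
        notes = []
        for end, value in (("low", pr.low), ("high", pr.high)):
            if value == base_value:
                icers[end] = base.icer.icer_per_qaly
                continue
            assignments, note = _clamped_assignments(config, pr, value)
            if note:
                notes.append(f"{end}: {note}")
            cfg = config.with_params(assignments)
            # survival curves are never varied here, so traces are reusable
            # unless the discount-free trace grid itself changed (it cannot)
            res = run_base_case(cfg, traces=traces)
            d = res.icer
            icers[end] = (d.delta_cost / d.delta_qaly
                          if d.delta_qaly != 0 else np.nan)
        rows.append({
            "parameter": pr.name,
            "base": base_value,
            "low": pr.low,
            "high": pr.high,
            "icer_low": icers["low"],
            "icer_high": icers["high"],
            "spread": abs(icers["high"] - icers["low"]),
            "note": "; ".join(notes),
        })
    out = pd.DataFrame(rows).sort_values("spread", ascending=False)
    return out.reset_index(drop=True)


# -- probabilistic sensitivity -----------------------------------------


@dataclass
class PSAResult:
    """Monte-Carlo incremental outcomes for one population."""

    draws: pd.DataFrame  # columns delta_cost, delta_qaly
    n: int
    seed: int
    label: str = ""
    fallback_uniform: list = field(default_factory=list)
    n_redraws: int = 0

    def acceptance_at(self, wtp: float) -> float:
        """Fraction of draws with positive incremental NMB at ``wtp``."""
        nmb = wtp * self.draws["delta_qaly"].to_numpy() \
            - self.draws["delta_cost"].to_numpy()
        return float(np.mean(nmb > 0))


def _draw_parameter(pr: ParamRange, base: float, n: int, rng,
                    fallback: list) -> np.ndarray:
    if pr.distribution == "fixed" or pr.low == pr.high:
        return np.full(n, base)
    if pr.distribution == "beta":
        ab = beta_from_mean_range(base, pr.low, pr.high)
        if ab is None:
            fallback.append(pr.name)
            log.warning("beta infeasible for %s; uniform fallback", pr.name)
            return rng.uniform(pr.low, pr.high, n)
        return rng.beta(*ab, n)
    if pr.distribution == "gamma":
        shape, scale = gamma_from_mean_range(base, pr.low, pr.high)
        return rng.gamma(shape, scale, n)
    if pr.distribution == "normal":
        sd = (pr.high - pr.low) / (2.0 * _Z95)
        return rng.normal(base, sd, n)
    if pr.distribution == "uniform":
        return rng.uniform(pr.low, pr.high, n)
    raise ValueError(f"unknown distribution {pr.distribution!r}")


def run_psa(config: StudyConfig, n: int = 10000, seed: int = 0) -> PSAResult:
    """``n`` seeded parameter draws, each evaluated through the model.

    Parameters are drawn in the fixed order of ``config.uncertainty``
    (costs, incidences, utilities, disutilities, weight, BSA, discount,
    proportions), so runs are bit-reproducible for a given seed.  Draws
    violating the utility ordering or non-positive weight/BSA are redrawn
    (counted on the result).  Survival parameters are not varied: the
    published inputs assign them no distribution.
    """
    if n < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(seed)
    fallback: list = []
    samples = {}
    for pr in config.uncertainty:
        base = get_path(config, pr.paths[0])
        samples[pr.name] = _draw_parameter(pr, base, n, rng, fallback)

    by_name = {pr.name: pr for pr in config.uncertainty}
    n_redraws = 0

    def redraw(name, mask):
        nonlocal n_redraws
        pr = by_name[name]
        base = get_path(config, pr.paths[0])
        while np.any(mask):
            n_redraws += int(np.sum(mask))
            samples[name][mask] = _draw_parameter(pr, base, int(np.sum(mask)),
                                                  rng, fallback)
            mask = _invalid_mask(name)

    def _invalid_mask(name):
        if name == "utility_pd":
            return samples["utility_pd"] > samples["utility_pfs"]
        if name in ("body_weight", "body_surface_area"):
            return samples[name] <= 0
        return np.zeros(n, dtype=bool)

    if "utility_pd" in samples and "utility_pfs" in samples:
        redraw("utility_pd", _invalid_mask("utility_pd"))
    for name in ("body_weight", "body_surface_area"):
        if name in samples:
            redraw(name, _invalid_mask(name))

    base = run_base_case(config)
    traces = (base.trace_intervention, base.trace_comparator)
    template = config.copy()
    template.uncertainty = []

    delta_cost = np.empty(n)
    delta_qaly = np.empty(n)
    for j in range(n):
        assignments = {}
        for pr in config.uncertainty:
            v = float(samples[pr.name][j])
            for p in pr.paths:
                assignments[p] = v
        cfg = template.with_params(assignments)
        res = run_base_case(cfg, traces=traces)
        delta_cost[j] = res.icer.delta_cost
        delta_qaly[j] = res.icer.delta_qaly

    draws = pd.DataFrame({"delta_cost": delta_cost, "delta_qaly": delta_qaly})
    return PSAResult(draws=draws, n=n, seed=seed, label=config.label,
                     fallback_uniform=fallback, n_redraws=n_redraws)


def ceac(psa: PSAResult, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    if wtp_grid is None:
        wtp_grid = np.arange(0, 100001, 1000)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    dq = psa.draws["delta_qaly"].to_numpy()
    dc = psa.draws["delta_cost"].to_numpy()
    probs = [float(np.mean(w * dq - dc > 0)) for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability": probs})


# -- price threshold ----------------------------------------------------


@dataclass
class ThresholdResult:
    multiplier: float
    price_per_cycle: float
    achieved_icer: float
    wtp: float


def threshold_price(config: StudyConfig, wtp: float | None = None,
                    target_param: str =
                    "intervention.first_line_drugs[serplulimab].cost_per_cycle",
                    tol: float = 1.0) -> ThresholdResult:
    """Price multiplier at which the base-case ICER meets the WTP.

    Bisects a scalar multiplier applied to the targeted per-cycle drug
    cost until |ICER - wtp| < ``tol`` ($/QALY).  The ICER is strictly
    monotone in the multiplier (incremental cost is linear in it and the
    incremental QALY does not depend on prices), so bisection is exact.
    """
    wtp = config.settings.wtp_per_qaly if wtp is None else wtp
    base_price = get_path(config, target_param)
    base = run_base_case(config)
    traces = (base.trace_intervention, base.trace_comparator)

    def icer_at(mult: float) -> float:
        res = run_base_case(
            config.with_params({target_param: base_price * mult}),
            traces=traces)
        if res.icer.delta_qaly <= 0:
            raise RuntimeError("incremental QALY not positive; threshold undefined")
        return res.icer.delta_cost / res.icer.delta_qaly

    lo, hi = 1.0, 1.0
    f_lo = f_hi = icer_at(1.0)
    if abs(f_lo - wtp) < tol:
        return ThresholdResult(1.0, base_price, f_lo, wtp)
    if f_lo < wtp:
        while f_hi < wtp:
            hi *= 2.0
            if hi > 1e6:
                raise RuntimeError("ICER never reaches WTP within bracket")
            f_hi = icer_at(hi)
    else:
        while f_lo > wtp:
            lo /= 2.0
            if lo < 1e-9:
                raise RuntimeError("ICER never falls to WTP within bracket")
            f_lo = icer_at(lo)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = icer_at(mid)
        if abs(f_mid - wtp) < tol:
            return ThresholdResult(mid, base_price * mid, f_mid, wtp)
        if f_mid < wtp:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("bisection failed to converge")  # pragma: no cover


# -- hazard-ratio subgroups ---------------------------------------------


@dataclass
class SubgroupSpec:
    """A trial subgroup characterized only by its OS and PFS hazard ratios."""

    name: str
    hr_os: float
    hr_pfs: float

    def __post_init__(self):
        if self.hr_os <= 0 or self.hr_pfs <= 0:
            raise ValueError("hazard ratios must be positive")


def subgroup_analysis(config: StudyConfig, subgroup: SubgroupSpec):
    """ICER for a subgroup defined by hazard ratios vs the comparator.

    The comparator keeps the baseline fitted curves; the intervention's
    curves are derived by proportional hazards,
    S_trt(t) = S_ctrl(t)**HR, per endpoint.  Everything else (costs,
    utilities, schedules) stays at baseline.
    """
    cfg = config.copy()
    cfg.survival.intervention.os = proportional_hazards(
        config.survival.comparator.os, subgroup.hr_os)
    cfg.survival.intervention.pfs = proportional_hazards(
        config.survival.comparator.pfs, subgroup.hr_pfs)
    cfg.label = f"{config.label}__subgroup_{subgroup.name}"
    return run_base_case(cfg)
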
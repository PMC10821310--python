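"""Parametric survival curves for extrapolating digitized Kaplan-Meier data.

Published oncology cost-effectiveness models rarely have individual patient
data to work with; instead the Kaplan-Meier figures are digitized into
(time, survival) point sets and a parametric family is fitted so survival
can be extrapolated beyond trial follow-up.  This module provides the five
families conventionally tried (exponential, Weibull, log-logistic,
log-normal, Gompertz), least-squares fitting to digitized points, AIC/BIC
model selection, and the per-cycle transition probabilities a state-
transition model consumes.

Parameterizations
-----------------
exponential   S(t) = exp(-lam*t),                    params = (lam,)
weibull       S(t) = exp(-lam*t**gam),               params = (lam, gam)
log-logistic  S(t) = 1 / (1 + (t/alpha)**beta),      params = (alpha, beta)
log-normal    S(t) = 1 - Phi((ln t - mu)/sigma),     params = (mu, sigma)
gompertz      h(t) = a*exp(b*t)  =>
              S(t) = exp(-a/b*(exp(b*t) - 1)),       params = (a, b)

Scale parameters (lam, alpha, a, sigma) must be strictly positive; the
Weibull/log-logistic shapes must be positive; the Gompertz rate ``b`` may
take either sign (b -> 0 recovers the exponential).  Times are in months
unless the caller deliberately rescales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

FAMILIES = ("exponential", "weibull", "log-logistic", "log-normal", "gompertz")

_N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "log-logistic": 2,
    "log-normal": 2,
    "gompertz": 2,
}


class SurvivalDomainError(ValueError):
    """Invalid argument to a survival function (negative time, bad params)."""


class FitError(RuntimeError):
    """A parametric fit could not be performed on the given points."""


@dataclass(frozen=True)
class ParametricSurvival:
    """A fitted or asserted parametric survival distribution.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    params : tuple of float
        Distribution parameters in the order documented in the module
        docstring (for Weibull: scale ``lam``, shape ``gam``).
    time_unit : str
        Unit of the time axis; ``"month"`` throughout this package.
    """

    family: str
    params: tuple
    time_unit: str = "month"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise SurvivalDomainError(f"unknown family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if len(self.params) != _N_PARAMS[self.family]:
            raise SurvivalDomainError(
                f"{self.family} needs {_N_PARAMS[self.family]} params, "
                f"got {len(self.params)}"
            )
        if self.family == "gompertz":
            if self.params[0] <= 0:
                raise SurvivalDomainError("gompertz baseline hazard a must be > 0")
        elif self.family == "log-normal":
            if self.params[1] <= 0:
                raise SurvivalDomainError("log-normal sigma must be > 0")
        else:
            if any(p <= 0 for p in self.params):
                raise SurvivalDomainError(
                    f"{self.family} parameters must be strictly positive: {self.params}"
                )

    # -- evaluation -----------------------------------------------------

    def survival(self, t):
        """S(t) for scalar or array ``t >= 0``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise SurvivalDomainError("time must be non-negative")
        if self.family == "exponential":
            (lam,) = self.params
            s = np.exp(-lam * t)
        elif self.family == "weibull":
            lam, gam = self.params
            s = np.exp(-lam * t**gam)
        elif self.family == "log-logistic":
            alpha, beta = self.params
            s = 1.0 / (1.0 + (t / alpha) ** beta)
        elif self.family == "log-normal":
            mu, sigma = self.params
            with np.errstate(divide="ignore"):
                s = np.where(t > 0, stats.norm.sf((np.log(np.maximum(t, 1e-300)) - mu) / sigma), 1.0)
        else:  # gompertz
            a, b = self.params
            if abs(b) < 1e-12:
                s = np.exp(-a * t)
            else:
                with np.errstate(over="ignore"):  # overflow -> S underflows to 0
                    s = np.exp(-a / b * np.expm1(b * t))
        return s if s.ndim else float(s)

    def transition_probability(self, t, u):
        """Per-cycle event probability 1 - S(t)/S(t-u) for the cycle ending at ``t``.

        ``u`` is the cycle length in the same unit as ``t``; requires
        ``t >= u > 0``.  This is the conditional probability of the event
        during (t-u, t] given event-free survival to t-u.
        """
        t = np.asarray(t, dtype=float)
        if u <= 0:
            raise SurvivalDomainError("cycle length u must be positive")
        if np.any(t < u):
            raise SurvivalDomainError("t must be >= u")
        s_prev = np.asarray(self.survival(t - u), dtype=float)
        s_now = np.asarray(self.survival(t), dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(s_prev > 0, 1.0 - s_now / s_prev, 1.0)
        p = np.clip(p, 0.0, 1.0)
        return p if p.ndim else float(p)

    def median(self):
        """Time at which S(t) = 1/2 (closed form for every family)."""
        ln2 = math.log(2.0)
        if self.family == "exponential":
            return ln2 / self.params[0]
        if self.family == "weibull":
            lam, gam = self.params
            return (ln2 / lam) ** (1.0 / gam)
        if self.family == "log-logistic":
            return self.params[0]
        if self.family == "log-normal":
            return math.exp(self.params[0])
        a, b = self.params
        if abs(b) < 1e-12:
            return ln2 / a
        arg = 1.0 + b * ln2 / a
        if arg <= 0:
            return math.inf  # defective Gompertz: plateau above 1/2
        return math.log(arg) / b


def survival_at(model: ParametricSurvival, t):
    """Functional alias for :meth:`ParametricSurvival.survival`."""
    return model.survival(t)


def transition_probability(model: ParametricSurvival, t, u):
    """Functional alias for :meth:`ParametricSurvival.transition_probability`."""
    return model.transition_probability(t, u)


def median_survival(model: ParametricSurvival) -> float:
    """Functional alias for :meth:`ParametricSurvival.median`."""
    return model.median()


def proportional_hazards(model: ParametricSurvival, hr: float) -> ParametricSurvival:
    """Apply a hazard ratio: S_new(t) = S(t)**hr.

    Closed under the families whose log-survival is linear in the scale
    parameter (exponential, Weibull, Gompertz); for the others a hazard
    ratio does not stay within the family and an error is raised.
    """
    if hr <= 0:
        raise SurvivalDomainError("hazard ratio must be positive")
    if model.family in ("exponential", "weibull"):
        return ParametricSurvival(model.family, (model.params[0] * hr, *model.params[1:]),
                                  model.time_unit)
    if model.family == "gompertz":
        a, b = model.params
        return ParametricSurvival("gompertz", (a * hr, b), model.time_unit)
    raise SurvivalDomainError(
        f"proportional hazards not closed for family {model.family!r}"
    )


# -- digitized Kaplan-Meier points -------------------------------------


@dataclass
class KMPoints:
    """Digitized (time, survival) points from a published Kaplan-Meier curve."""

    points: list  # list of (time, survival)
    label: str = ""

    def __post_init__(self):
        pts = [(float(t), float(s)) for t, s in self.points]
        times = [t for t, _ in pts]
        survs = [s for _, s in pts]
        if any(t < 0 for t in times):
            raise ValueError("times must be non-negative")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(s < 0 or s > 1 for s in survs):
            raise ValueError("survival values must lie in [0, 1]")
        if any(s2 > s1 + 1e-12 for s1, s2 in zip(survs, survs[1:])):
            raise ValueError("survival must be non-increasing")
        self.points = pts

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points])

    @property
    def survival(self) -> np.ndarray:
        return np.array([s for _, s in self.points])

    @classmethod
    def from_file(cls, path, label: str = "") -> "KMPoints":
        """Read two-column delimited text (time, survival).

        Header lines (non-numeric) and lines starting with ``#`` are skipped;
        comma or whitespace delimited.
        """
        pts = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.replace(",", " ").split()
                try:
                    t, s = float(fields[0]), float(fields[1])
                except (ValueError, IndexError):
                    continue  # header
                pts.append((t, s))
        return cls(pts, label=label or str(path))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self.label}\ntime\tsurvival\n")
            for t, s in self.points:
                fh.write(f"{t:.10g}\t{s:.10g}\n")


@dataclass
class FitResult:
    """Outcome of fitting one parametric family to digitized KM points."""

    model: ParametricSurvival
    aic: float
    bic: float
    sse: float
    n_points: int
    notes: str = ""


def _usable(points: KMPoints):
    """Drop S=0 and S=1 points (log transforms undefined there)."""
    t, s = points.times, points.survival
    keep = (s > 0.0) & (s < 1.0) & (t > 0.0)
    return t[keep], s[keep], int(np.sum(~keep))


def _information_criteria(sse: float, n: int, k_dist: int):
    # Gaussian residual likelihood; +1 free parameter for the residual variance
    sse = max(sse, 1e-300)
    k = k_dist + 1
    loglik_term = n * math.log(sse / n)
    return loglik_term + 2 * k, loglik_term + k * math.log(n)


def fit_parametric(points: KMPoints, family: str) -> FitResult:
    """Least-squares fit of one family to digitized KM points.

    Weibull (and exponential) use ordinary least squares on the
    complementary-log-log transform ``log(-log S) = log lam + gam*log t``,
    which is exactly linear so noise-free points are recovered to machine
    precision.  The remaining families use nonlinear least squares on the
    survival scale.  AIC/BIC come from the Gaussian residual likelihood on
    the survival scale with k = #distribution parameters + 1 (residual
    variance), so they are comparable across families.
    """
    if family not in FAMILIES:
        raise FitError(f"unknown family {family!r}")
    t, s, n_dropped = _usable(points)
    if len(t) < 3:
        raise FitError(
            f"need at least 3 points with survival strictly inside (0,1); "
            f"got {len(t)} usable of {len(points.points)}"
        )
    notes = f"dropped {n_dropped} boundary point(s)" if n_dropped else ""

    if family == "weibull":
        y = np.log(-np.log(s))
        x = np.log(t)
        A = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        lam, gam = math.exp(coef[0]), coef[1]
        if gam <= 0:
            raise FitError("weibull cloglog fit produced non-positive shape")
        model = ParametricSurvival("weibull", (lam, gam))
    elif family == "exponential":
        # -log S = lam * t: one-parameter regression through the origin
        y = -np.log(s)
        lam = float(np.dot(t, y) / np.dot(t, t))
        model = ParametricSurvival("exponential", (lam,))
    else:
        model = _fit_nls(t, s, family)

    resid = s - model.survival(t)
    sse = float(np.dot(resid, resid))
    aic, bic = _information_criteria(sse, len(t), _N_PARAMS[family])
    return FitResult(model=model, aic=aic, bic=bic, sse=sse, n_points=len(t),
                     notes=notes)


def _init_params(t, s, family):
    # moment-style starting values from the empirical median / cloglog slope
    y = np.log(-np.log(s))
    x = np.log(t)
    A = np.column_stack([np.ones_like(x), x])
    c0, c1 = np.linalg.lstsq(A, y, rcond=None)[0]
    lam_w, gam_w = math.exp(c0), max(c1, 0.1)
    med = float(np.interp(0.5, s[::-1], t[::-1])) if s.min() < 0.5 < s.max() else t.mean()
    med = max(med, 1e-6)
    if family == "log-logistic":
        return [med, max(gam_w, 0.2)]
    if family == "log-normal":
        return [math.log(med), max(1.0 / gam_w, 0.1)]
    # gompertz: a ~ initial hazard, b ~ 0 (near-exponential start)
    return [lam_w * gam_w * med ** (gam_w - 1) if gam_w != 1 else lam_w, 1e-3]


def _fit_nls(t, s, family):
    x0 = _init_params(t, s, family)

    def unpack(theta):
        if family == "log-logistic":
            return ParametricSurvival("log-logistic", (abs(theta[0]) + 1e-12,
                                                       abs(theta[1]) + 1e-12))
        if family == "log-normal":
            return ParametricSurvival("log-normal", (theta[0], abs(theta[1]) + 1e-12))
        return ParametricSurvival("gompertz", (abs(theta[0]) + 1e-12, theta[1]))

    def resid(theta):
        return unpack(theta).survival(t) - s

    sol = optimize.least_squares(resid, x0, method="lm", max_nfev=20000)
    if not sol.success:
        raise FitError(f"nonlinear fit failed for {family}: {sol.message}")
    return unpack(sol.x)


def fit_all_families(points: KMPoints,
                     families: Sequence[str] = FAMILIES) -> list:
    """Fit every requested family, skipping those that error out."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_parametric(points, fam))
        except FitError:
            continue
    if not fits:
        raise FitError("no family could be fitted")
    return fits


def select_model(fits: Iterable[FitResult]) -> FitResult:
    """Pick the fit with minimal AIC; ties by BIC, then family order."""
    fits = list(fits)
    if not fits:
        raise FitError("no fits to select from")
    return min(fits, key=lambda f: (f.aic, f.bic, FAMILIES.index(f.model.family)))


def fit_report(fits: Iterable[FitResult]):
    """Goodness-of-fit table (family, params, SSE, AIC, BIC) as a DataFrame."""
    import pandas as pd

    rows = []
    for f in fits:
        rows.append({
            "family": f.model.family,
            "params": "; ".join(f"{p:.6g}" for p in f.model.params),
            "n_points": f.n_points,
            "sse": f.sse,
            "aic": f.aic,
            "bic": f.bic,
        })
    return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
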
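"""Single-exponential kinetics of DNA cleavage and 2AP R-loop formation.

Two observation models are fitted by nonlinear least squares:

* cleavage (gel densitometry, cleaved fraction in [0, 1]):
  ``Y = Ymax * (1 - exp(-k*t))``, with ``0 <= Ymax <= 1``;
* 2AP fluorescence (arbitrary units):
  ``Y = Y0 + Ymax * (1 - exp(-k*t))``, with ``Y0`` fixed to the mean of a
  blank trace and ``Ymax >= 0``.

``k`` is the observed first-order rate constant ``k_obs`` in inverse time
units of the course.  A fit whose amplitude falls at or below the assay floor
(0.05 cleaved fraction; 100 AU of fluorescence) is flagged "nd" (not
determined) and reports no rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

ND_YMAX_CLEAVAGE = 0.05  # cleaved-fraction amplitude floor
ND_YMAX_2AP = 100.0  # fluorescence amplitude floor, AU

#: Gel sampling schedule of the cleavage assay, minutes
#: (0 s, 30 s, 1 min, 2.5 min, 5 min, 10 min, 30 min, 1 h, 2 h).
CLEAVAGE_TIMES_MIN = (0.0, 0.5, 1.0, 2.5, 5.0, 10.0, 30.0, 60.0, 120.0)

TimeUnit = Literal["minute", "second"]
Assay = Literal["cleavage_fraction", "fluorescence_AU"]


def nd_rule(model: Literal["cleavage", "two_ap"], ymax: float) -> bool:
    """Amplitude floor: a fit is "nd" when Ymax <= 0.05 (cleavage fraction)
    or Ymax <= 100 AU (2AP fluorescence); the boundary itself is nd."""
    floor = ND_YMAX_CLEAVAGE if model == "cleavage" else ND_YMAX_2AP
    return ymax <= floor


def fraction_cleaved(cleaved_density: float, uncleaved_density: float) -> float:
    """Cleaved fraction from band densities: cleaved / (cleaved + uncleaved)."""
    if cleaved_density < 0 or uncleaved_density < 0:
        raise ValueError("band densities must be non-negative")
    total = cleaved_density + uncleaved_density
    if total == 0:
        raise ValueError("empty lane: both band densities are zero")
    return cleaved_density / total


@dataclass
class TimeCourse:
    """Timestamped observations for one assay condition.

    ``observations`` is a long-format frame with columns
    ``replicate``, ``time``, ``value``.  Times are non-negative and strictly
    increasing within each replicate; cleavage-fraction values lie in [0, 1].
    """

    condition: str
    time_unit: TimeUnit
    observations: pd.DataFrame
    assay: Assay
    blank_mean: float | None = None  # 2AP only

    def __post_init__(self) -> None:
        required = {"replicate", "time", "value"}
        if not required <= set(self.observations.columns):
            raise ValueError(f"observations must have columns {sorted(required)}")
        if self.time_unit not in ("minute", "second"):
            raise ValueError(f"unknown time_unit {self.time_unit!r}")
        obs = self.observations
        if (obs["time"] < 0).any():
            raise ValueError("times must be non-negative")
        for rep, grp in obs.groupby("replicate"):
            t = grp["time"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"times not strictly increasing in replicate {rep!r}")
        if self.assay == "cleavage_fraction":
            v = obs["value"]
            if (v < 0).any() or (v > 1).any():
                raise ValueError("cleavage fractions must lie in [0, 1]")

    @property
    def replicates(self) -> list:
        return list(dict.fromkeys(self.observations["replicate"]))

    @property
    def n_distinct_times(self) -> int:
        return self.observations["time"].nunique()

    def replicate(self, replicate_id) -> "TimeCourse":
        sub = self.observations[self.observations["replicate"] == replicate_id]
        if sub.empty:
            raise KeyError(f"no replicate {replicate_id!r}")
        return replace(self, observations=sub.reset_index(drop=True))

    def converted(self, time_unit: TimeUnit) -> "TimeCourse":
        """Copy with times converted between minutes and seconds."""
        if time_unit == self.time_unit:
            return self
        factor = 60.0 if (self.time_unit, time_unit) == ("minute", "second") else 1 / 60.0
        obs = self.observations.assign(time=self.observations["time"] * factor)
        return replace(self, time_unit=time_unit, observations=obs)

    @classmethod
    def from_densities(
        cls,
        condition: str,
        records: Iterable[tuple[str, float, float, float]],
        time_unit: TimeUnit = "minute",
    ) -> "TimeCourse":
        """Build a cleavage course from (replicate, time, cleaved, uncleaved)."""
        rows = [
            (rep, t, fraction_cleaved(c, u)) for rep, t, c, u in records
        ]
        obs = pd.DataFrame(rows, columns=["replicate", "time", "value"])
        return cls(condition=condition, time_unit=time_unit, observations=obs,
                   assay="cleavage_fraction")


@dataclass(frozen=True)
class ExpFitResult:
    """One fitted exponential: parameters, nd flag and diagnostics.

    ``k_obs`` is ``None`` when the fit is nd (amplitude at or below the assay
    floor, or the optimiser failed); otherwise it is strictly positive.
    """

    model: Literal["cleavage", "two_ap"]
    k_obs: float | None
    ymax: float
    nd: bool
    rss: float
    n_points: int
    time_unit: TimeUnit
    y0: float | None = None  # two_ap only, fixed from blank
    condition: str = ""
    message: str = "converged"

    @property
    def nd_threshold(self) -> float:
        return ND_YMAX_CLEAVAGE if self.model == "cleavage" else ND_YMAX_2AP

    def k_display(self, sig_figs: int = 1) -> str:
        """k_obs rounded for reporting, or the literal string "nd"."""
        if self.nd or self.k_obs is None:
            return "nd"
        k = self.k_obs
        ndigits = -int(math.floor(math.log10(abs(k)))) + (sig_figs - 1)
        return f"{round(k, ndigits):g}"

    def as_dict(self) -> dict:
        return {
            "condition": self.condition,
            "model": self.model,
            "k_obs": "nd" if self.nd else self.k_obs,
            "ymax": self.ymax,
            "y0": self.y0,
            "nd": self.nd,
            "rss": None if math.isnan(self.rss) else self.rss,
            "n_points": self.n_points,
            "time_unit": self.time_unit,
            "message": self.message,
        }


def _predict(t: np.ndarray, k: float, ymax: float, y0: float = 0.0) -> np.ndarray:
    return y0 + ymax * (1.0 - np.exp(-k * t))


def _initial_k(t: np.ndarray, y: np.ndarray, ymax0: float, y0: float) -> float:
    # 1 / t*, with t* the first time the trace exceeds half the amplitude
    half = y0 + 0.5 * ymax0
    above = t[(y >= half) & (t > 0)]
    if above.size:
        return 1.0 / above.min()
    pos = t[t > 0]
    return 1.0 / np.median(pos) if pos.size else 1.0


def _fit_exponential(
    t: np.ndarray,
    y: np.ndarray,
    y0: float,
    ymax_upper: float,
) -> tuple[float, float, float, str]:
    """Bounded least squares for (k, ymax); multi-start on failure.

    Returns (k, ymax, rss, message).
    """
    ymax0 = float(np.clip(np.max(y) - y0, 1e-6, ymax_upper))
    k_starts = [_initial_k(t, y, ymax0, y0)]
    t_scale = max(float(np.max(t)), 1e-9)
    k_starts += list(np.geomspace(0.1 / t_scale, 100.0 / t_scale, 5))

    best = None
    for k0 in k_starts:
        try:
            popt, _ = optimize.curve_fit(
                lambda tt, k, ym: _predict(tt, k, ym, y0),
                t,
                y,
                p0=[float(np.clip(k0, 1e-9, None)), ymax0],
                bounds=([1e-12, 0.0], [np.inf, ymax_upper]),
                maxfev=10000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((y - _predict(t, popt[0], popt[1], y0)) ** 2))
        if best is None or rss < best[2]:
            best = (float(popt[0]), float(popt[1]), rss)
    if best is None:
        return math.nan, 0.0, math.nan, "optimizer failed to converge"
    return best[0], best[1], best[2], "converged"


def fit_cleavage(course: TimeCourse, pooled: bool = True) -> ExpFitResult:
    """Fit ``Y = Ymax*(1 - exp(-k*t))`` to a cleaved-fraction course.

    By default all replicate points are pooled into a single fit.  The fit is
    nd when the amplitude is at or below 0.05.
    """
    if course.assay != "cleavage_fraction":
        raise ValueError("fit_cleavage requires a cleavage_fraction course")
    if course.n_distinct_times < 3:
        raise ValueError("at least 3 distinct time points required")
    obs = course.observations
    t = obs["time"].to_numpy(dtype=float)
    y = obs["value"].to_numpy(dtype=float)
    k, ymax, rss, message = _fit_exponential(t, y, y0=0.0, ymax_upper=1.0)
    failed = message != "converged"
    nd = failed or nd_rule("cleavage", ymax)
    return ExpFitResult(
        model="cleavage",
        k_obs=None if nd else k,
        ymax=ymax,
        nd=nd,
        rss=rss,
        n_points=len(t),
        time_unit=course.time_unit,
        condition=course.condition,
        message=message,
    )


def fit_2ap(course: TimeCourse, replicate=None) -> ExpFitResult:
    """Fit ``Y = Y0 + Ymax*(1 - exp(-k*t))`` with Y0 fixed to the blank mean.

    ``replicate`` restricts the fit to a single replicate (the assay fits each
    replicate separately and averages the rates).  nd when Ymax <= 100 AU.
    """
    if course.blank_mean is None:
        raise ValueError("fit_2ap requires blank_mean (average of the blank trace)")
    if replicate is not None:
        course = course.replicate(replicate)
    if course.n_distinct_times < 3:
        raise ValueError("at least 3 distinct time points required")
    obs = course.observations
    t = obs["time"].to_numpy(dtype=float)
    y = obs["value"].to_numpy(dtype=float)
    k, ymax, rss, message = _fit_exponential(t, y, y0=course.blank_mean, ymax_upper=np.inf)
    failed = message != "converged"
    nd = failed or nd_rule("two_ap", ymax)
    return ExpFitResult(
        model="two_ap",
        k_obs=None if nd else k,
        ymax=ymax,
        nd=nd,
        rss=rss,
        n_points=len(t),
        time_unit=course.time_unit,
        y0=course.blank_mean,
        condition=course.condition,
        message=message,
    )


@dataclass(frozen=True)
class ReplicateAggregate:
    """Mean ± sample SD of k_obs over the non-nd replicate fits."""

    mean_k: float | None
    sd_k: float | None
    n: int  # replicates contributing (non-nd)
    n_total: int
    nd: bool  # all replicates nd
    any_nd: bool
    time_unit: TimeUnit | None = None

    def as_dict(self) -> dict:
        sd = self.sd_k
        return {
            "mean_k_obs": "nd" if self.nd else self.mean_k,
            "sd_k_obs": None if sd is None or math.isnan(sd) else sd,
            "n": self.n,
            "n_total": self.n_total,
            "any_nd": self.any_nd,
        }


def aggregate_replicates(fits: Sequence[ExpFitResult]) -> ReplicateAggregate:
    """Average k_obs across replicate fits (sample SD, n-1 denominator)."""
    if not fits:
        raise ValueError("no fits to aggregate")
    units = {f.time_unit for f in fits}
    if len(units) > 1:
        raise ValueError(f"mixed time units {sorted(units)}")
    ks = [f.k_obs for f in fits if not f.nd]
    if not ks:
        return ReplicateAggregate(None, None, 0, len(fits), nd=True, any_nd=True,
                                  time_unit=units.pop())
    arr = np.asarray(ks, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else math.nan
    return ReplicateAggregate(
        mean_k=float(arr.mean()),
        sd_k=sd,
        n=arr.size,
        n_total=len(fits),
        nd=False,
        any_nd=arr.size < len(fits),
        time_unit=units.pop(),
    )


def fold_change(
    numerator: ExpFitResult | ReplicateAggregate,
    denominator: ExpFitResult | ReplicateAggregate,
) -> float:
    """Ratio of rate constants, k(numerator) / k(denominator)."""

    def _k(x) -> tuple[float, TimeUnit | None]:
        if isinstance(x, ReplicateAggregate):
            if x.nd:
                raise ValueError("fold change undefined for nd")
            return x.mean_k, x.time_unit
        if x.nd or x.k_obs is None:
            raise ValueError("fold change undefined for nd")
        return x.k_obs, x.time_unit

    k_num, u_num = _k(numerator)
    k_den, u_den = _k(denominator)
    if u_num is not None and u_den is not None and u_num != u_den:
        raise ValueError(f"time-unit mismatch: {u_num} vs {u_den}")
    return k_num / k_den


class ExponentialKineticsModel:
    """Saturating-exponential model of an assay time course.

    statsmodels-style entry point: build from a :class:`TimeCourse` (the model
    family is inferred from the assay), call :meth:`fit`, and read parameters
    off the returned :class:`ExponentialFitResults`.

    Parameters
    ----------
    course
        Observations for one condition.
    model
        "cleavage" or "two_ap"; inferred from ``course.assay`` by default.
    """

    def __init__(self, course: TimeCourse, model: str | None = None):
        if model is None:
            model = "cleavage" if course.assay == "cleavage_fraction" else "two_ap"
        if model not in ("cleavage", "two_ap"):
            raise ValueError(f"unknown model {model!r}")
        self.course = course
        self.model = model

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        condition: str,
        assay: Assay = "cleavage_fraction",
        time_unit: TimeUnit = "minute",
        blank_mean: float | None = None,
    ) -> "ExponentialKineticsModel":
        course = TimeCourse(condition=condition, time_unit=time_unit,
                            observations=data[["replicate", "time", "value"]],
                            assay=assay, blank_mean=blank_mean)
        return cls(course)

    def fit(self, per_replicate: bool | None = None) -> "ExponentialFitResults":
        """Fit the model.

        ``per_replicate`` defaults to the assay convention: pooled points for
        cleavage, one fit per replicate (then averaged) for 2AP traces.
        """
        if per_replicate is None:
            per_replicate = self.model == "two_ap"
        fit_one = fit_cleavage if self.model == "cleavage" else fit_2ap
        if per_replicate:
            fits = [
                fit_one(self.course.replicate(rep) if self.model == "cleavage"
                        else self.course, **({} if self.model == "cleavage"
                                             else {"replicate": rep}))
                for rep in self.course.replicates
            ]
        else:
            fits = [fit_one(self.course)]
        return ExponentialFitResults(self, fits)


class ExponentialFitResults:
    """Fit results: per-replicate (or pooled) parameters and their aggregate."""

    def __init__(self, model: ExponentialKineticsModel, fits: list[ExpFitResult]):
        self.model = model
        self.fits = fits
        self.aggregate = aggregate_replicates(fits)

    @property
    def k_obs(self) -> float | None:
        return self.aggregate.mean_k

    @property
    def nd(self) -> bool:
        return self.aggregate.nd

    @property
    def ymax(self) -> float:
        return float(np.mean([f.ymax for f in self.fits]))

    def fold_change_vs(self, other: "ExponentialFitResults") -> float:
        return fold_change(self.aggregate, other.aggregate)

    def summary(self) -> str:
        course = self.model.course
        unit = {"minute": "min^-1", "second": "s^-1"}[course.time_unit]
        lines = [
            "Exponential kinetics fit",
            "=" * 40,
            f"condition:   {course.condition}",
            f"model:       {self.model.model}",
            f"n points:    {sum(f.n_points for f in self.fits)}"
            f" ({len(self.fits)} fit(s))",
        ]
        for f in self.fits:
            lines.append(
                f"  k_obs = {f.k_display()} {unit}   Ymax = {f.ymax:.4g}"
                f"   rss = {f.rss:.3g}" + ("   [nd]" if f.nd else "")
            )
        agg = self.aggregate
        if agg.nd:
            lines.append("k_obs: nd (amplitude at or below the assay floor)")
        elif len(self.fits) > 1:
            sd = "nan" if agg.sd_k is None or math.isnan(agg.sd_k) else f"{agg.sd_k:.3g}"
            lines.append(f"k_obs = {agg.mean_k:.3g} ± {sd} {unit} (n = {agg.n})")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "condition": self.model.course.condition,
            "fits": [f.as_dict() for f in self.fits],
            "aggregate": self.aggregate.as_dict(),
        }
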
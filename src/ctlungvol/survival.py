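"""Survival machinery for validating the prognostic scores.

Kaplan-Meier product-limit curves, the log-rank test, Cox proportional
hazards fits (Efron tie handling) and Harrell's concordance index, wrapped
in small result containers with the conventions used throughout the
package:

* median survival is the smallest observed time with S(t) <= 0.5, reported
  as ``None`` (never an infinite number) when the curve stays above 0.5;
* p-values are two-tailed with significance at 0.05;
* all stochastic helpers take explicit seeds.

Model fitting goes through lifelines; Harrell's C is computed in-package
because its pair counts (concordant / discordant / tied) are part of the
reported result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "SurvivalSample",
    "SurvivalCurve",
    "HazardFit",
    "Concordance",
    "km_curve",
    "logrank_test",
    "cox_fit",
    "harrell_c",
    "median_split_survival",
    "plot_km",
]


@dataclass(frozen=True)
class SurvivalSample:
    """One subject's follow-up: duration and event indicator (1 = death)."""

    time: float
    event: int
    unit: str = "years"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be non-negative")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def _to_arrays(samples) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(samples, pd.DataFrame):
        return samples["time"].to_numpy(float), samples["event"].to_numpy(int)
    times = np.asarray([s.time for s in samples], dtype=float)
    events = np.asarray([s.event for s in samples], dtype=int)
    return times, events


@dataclass
class SurvivalCurve:
    """A Kaplan-Meier estimate: S(t) after each distinct event time."""

    times: np.ndarray          # distinct event times, increasing
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # risk-set size just before each event time
    n_events: np.ndarray       # deaths at each event time
    median: float | None       # smallest time with S(t) <= 0.5, or None
    n: int = 0

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S at time t (S(0) = 1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.n_events,
                "survival": self.survival,
            }
        )


def km_curve(samples) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    times, events = _to_arrays(samples)
    if times.size == 0:
        raise ValueError("need at least one sample")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = np.sort(np.unique(times[events == 1]))
    if event_times.size:
        surv = np.asarray(
            [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times]
        )
        table = kmf.event_table
        at_risk = table.loc[event_times, "at_risk"].to_numpy(float)
        n_ev = table.loc[event_times, "observed"].to_numpy(float)
    else:
        surv = np.empty(0)
        at_risk = np.empty(0)
        n_ev = np.empty(0)
    below = np.flatnonzero(surv <= 0.5)
    median = float(event_times[below[0]]) if below.size else None
    return SurvivalCurve(
        times=event_times,
        survival=surv,
        at_risk=at_risk,
        n_events=n_ev,
        median=median,
        n=int(times.size),
    )


def logrank_test(samples, group_labels) -> tuple[float, float]:
    """Log-rank comparison of two or more groups.

    Returns ``(chi_square, p)`` with ``groups - 1`` degrees of freedom,
    using the hypergeometric variance form.
    """
    times, events = _to_arrays(samples)
    labels = np.asarray(group_labels)
    if labels.shape[0] != times.shape[0]:
        raise ValueError("group_labels must match samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    if (counts == 0).any():
        raise ValueError("every group must be non-empty")
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class HazardFit:
    """A fitted proportional-hazards coefficient for one covariate."""

    covariate: str
    coef: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    log_likelihood: float
    converged: bool
    n: int
    n_events: int

    def to_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "coef": self.coef,
            "hazard_ratio": self.hazard_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n": self.n,
            "n_events": self.n_events,
        }


def cox_fit(
    covariate_table: pd.DataFrame,
    samples,
    covariates: list[str] | None = None,
    multivariate: bool = False,
) -> list[HazardFit]:
    """Cox proportional-hazards regression with Efron tie handling.

    In univariate mode (default) each covariate is fitted in its own model;
    in multivariate mode a single joint model is fitted.  Wald 95%
    confidence intervals and two-tailed p-values are reported per
    coefficient; a model that fails to converge is returned flagged rather
    than silently.
    """
    times, events = _to_arrays(samples)
    covs = list(covariates) if covariates is not None else list(covariate_table.columns)
    for c in covs:
        if covariate_table[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant")
    n_events = int(events.sum())
    if multivariate and n_events < len(covs):
        raise ValueError(
            f"{n_events} events cannot support {len(covs)} joint covariates"
        )

    def one_model(cols: list[str]) -> list[HazardFit]:
        df = covariate_table[cols].copy()
        df["time"] = times
        df["event"] = events
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
            converged = True
            summary = cph.summary
            ll = float(cph.log_likelihood_)
        except ConvergenceError:
            return [
                HazardFit(c, np.nan, np.nan, np.nan, np.nan, np.nan,
                          np.nan, False, len(df), n_events)
                for c in cols
            ]
        return [
            HazardFit(
                covariate=c,
                coef=float(summary.loc[c, "coef"]),
                hazard_ratio=float(summary.loc[c, "exp(coef)"]),
                ci_low=float(summary.loc[c, "exp(coef) lower 95%"]),
                ci_high=float(summary.loc[c, "exp(coef) upper 95%"]),
                p=float(summary.loc[c, "p"]),
                log_likelihood=ll,
                converged=converged,
                n=len(df),
                n_events=n_events,
            )
            for c in cols
        ]

    if multivariate:
        return one_model(covs)
    fits: list[HazardFit] = []
    for c in covs:
        fits.extend(one_model([c]))
    return fits


@dataclass(frozen=True)
class Concordance:
    """Harrell's C with its pair bookkeeping."""

    c_index: float
    concordant: int
    discordant: int
    tied_risk: int
    usable_pairs: int


def harrell_c(risk_scores, samples) -> Concordance:
    """Harrell's concordance index for censored survival data.

    A pair is usable when the member with the earlier time had the event
    (ties in time between an event and a censoring count the event as
    earlier).  A usable pair is concordant when the earlier-dying member
    has the higher risk score; ties in risk credit 0.5.
    """
    risk = np.asarray(risk_scores, dtype=float)
    if not np.all(np.isfinite(risk)):
        raise ValueError("risk scores must be finite")
    times, events = _to_arrays(samples)
    n = times.size
    conc = disc = tied = 0
    for i in range(n):
        if events[i] != 1:
            continue
        # pairs where i is the (strictly or tied-)earlier event
        later = (times > times[i]) | ((times == times[i]) & (events == 0))
        dr = risk[i] - risk[later]
        conc += int((dr > 0).sum())
        disc += int((dr < 0).sum())
        tied += int((dr == 0).sum())
    usable = conc + disc + tied
    if usable == 0:
        raise ValueError("no usable pairs: C-index undefined")
    c = (conc + 0.5 * tied) / usable
    return Concordance(
        c_index=float(c), concordant=conc, discordant=disc,
        tied_risk=tied, usable_pairs=usable,
    )


@dataclass
class MedianSplitResult:
    cutoff: float
    labels: np.ndarray                 # "high" / "low" per subject
    curves: dict[str, SurvivalCurve] = field(default_factory=dict)
    chi_square: float = np.nan
    p: float = np.nan


def median_split_survival(values, samples) -> MedianSplitResult:
    """Split a cohort at the median of a marker and compare survival.

    Values at or above the cutoff form the "high" group (>= convention for
    two-group splits).  Returns the per-group KM curves and the log-rank
    comparison.
    """
    vals = np.asarray(values, dtype=float)
    times, events = _to_arrays(samples)
    if vals.shape[0] != times.shape[0]:
        raise ValueError("values must match samples")
    cutoff = float(np.median(vals[np.isfinite(vals)]))
    labels = np.where(vals >= cutoff, "high", "low")
    curves = {}
    for lab in ("high", "low"):
        sel = labels == lab
        if sel.any():
            curves[lab] = km_curve(
                pd.DataFrame({"time": times[sel], "event": events[sel]})
            )
    if len(curves) == 2:
        chi2, p = logrank_test(
            pd.DataFrame({"time": times, "event": events}), labels
        )
    else:
        chi2, p = np.nan, np.nan
    return MedianSplitResult(cutoff=cutoff, labels=labels, curves=curves,
                             chi_square=chi2, p=p)


def plot_km(curves: dict[str, SurvivalCurve], ax=None, max_time: float | None = None):
    """Step-plot one KM curve per labelled group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in curves.items():
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        if max_time is not None:
            t = np.append(t, max_time)
            s = np.append(s, s[-1])
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    return ax
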
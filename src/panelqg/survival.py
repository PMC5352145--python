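"""Survival phenotypes: product-limit curves, LT50 and per-line plasticity summaries.

LT50 follows the fixed convention "first event time at which S(t) <= 0.5",
without interpolation: on a 12-hour scoring grid interpolated medians would
be pseudo-precision.  Within-line spread (sigma_E) is the root mean squared
error of an intercept-only fit to uncensored death times, i.e. the ordinary
within-group standard deviation with an n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test

from .io_formats import EventTable


class EmptyInputError(ValueError):
    pass


SUMMARY_COLUMNS = ["line_id", "sex", "n", "lt50_h", "mean_h",
                   "sigma_e", "ln_sigma_e", "cv_e", "flags"]


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate with Greenwood variance."""

    times: np.ndarray        # distinct observation times, ascending
    n_risk: np.ndarray       # at risk just before each time
    n_death: np.ndarray      # deaths at each time
    n_censor: np.ndarray     # censorings at each time
    survival: np.ndarray     # S(t) just after each time
    greenwood_var: np.ndarray

    @property
    def n(self) -> int:
        return int(self.n_risk[0]) if len(self.n_risk) else 0


def kaplan_meier(durations, event_observed=None) -> SurvivalCurve:
    """Product-limit estimator for one group.

    ``durations`` may be an EventTable (its time_h/status columns are used),
    or an array with a parallel boolean/0-1 ``event_observed``.
    """
    if isinstance(durations, EventTable):
        df = durations.df
        times = df["time_h"].to_numpy(dtype=float)
        observed = (df["status"] == "dead").to_numpy()
    else:
        times = np.asarray(durations, dtype=float)
        observed = (np.ones_like(times, dtype=bool) if event_observed is None
                    else np.asarray(event_observed, dtype=bool))
    if len(times) == 0:
        raise EmptyInputError("no records in group")

    order = np.argsort(times, kind="stable")
    times, observed = times[order], observed[order]
    uniq = np.unique(times)
    n_risk = np.zeros(len(uniq))
    n_death = np.zeros(len(uniq))
    n_censor = np.zeros(len(uniq))
    at_risk = len(times)
    for i, t in enumerate(uniq):
        here = times == t
        n_risk[i] = at_risk
        n_death[i] = np.sum(here & observed)
        n_censor[i] = np.sum(here & ~observed)
        at_risk -= int(here.sum())

    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - n_death / n_risk
        survival = np.cumprod(factors)
        # Greenwood: Var[S] = S^2 * cumsum(d / (n (n - d)))
        terms = np.where(n_risk > n_death,
                         n_death / (n_risk * (n_risk - n_death)), 0.0)
        greenwood = survival ** 2 * np.cumsum(terms)
    return SurvivalCurve(uniq, n_risk, n_death, n_censor, survival, greenwood)


@dataclass
class Median:
    time_h: float
    defined: bool


def median_survival(curve: SurvivalCurve) -> Median:
    """Smallest event time with S(t) <= 0.5; undefined under heavy censoring."""
    if len(curve.times) == 0:
        raise EmptyInputError("empty curve")
    hit = np.nonzero(curve.survival <= 0.5 + 1e-12)[0]
    if len(hit) == 0:
        return Median(float("nan"), False)
    return Median(float(curve.times[hit[0]]), True)


def log_rank(events_a, events_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and two-sided P."""
    ta, oa = _durations(events_a)
    tb, ob = _durations(events_b)
    if len(ta) == 0 or len(tb) == 0:
        raise EmptyInputError("both groups must be non-empty")
    if oa.sum() + ob.sum() == 0:
        return float("nan"), float("nan")
    res = logrank_test(ta, tb, event_observed_A=oa, event_observed_B=ob)
    return float(res.test_statistic), float(res.p_value)


def _durations(events) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(events, EventTable):
        df = events.df
        return (df["time_h"].to_numpy(dtype=float),
                (df["status"] == "dead").to_numpy())
    arr = np.asarray(events, dtype=float)
    return arr, np.ones_like(arr, dtype=bool)


def _sd_intercept_only(values: np.ndarray) -> float:
    """Root-MSE of an intercept-only fit == SD with n-1 denominator."""
    resid = values - values.mean()
    return float(np.sqrt(np.sum(resid ** 2) / (len(values) - 1)))


def line_summaries(events: EventTable,
                   aggregation: str = "mean_of_replicates",
                   include_control: bool = False) -> pd.DataFrame:
    """Per line-by-sex phenotypes: LT50, mean, sigma_E, ln(sigma_E), CV_E.

    The line LT50 defaults to the arithmetic mean of replicate-tube LT50s;
    ``aggregation="pooled"`` takes the pooled-curve median instead.  Censored
    flies enter KM curves but are excluded from mean/sigma computations.
    """
    if aggregation not in ("mean_of_replicates", "pooled"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    df = events.df if include_control else events.pathogen_only().df
    rows = []
    for (lid, sex), grp in df.groupby(["line_id", "sex"], sort=True):
        flags = []
        dead = grp[grp["status"] == "dead"]["time_h"].to_numpy(dtype=float)
        n_cens = int((grp["status"] == "censored").sum())
        if n_cens:
            flags.append(f"censored_excluded={n_cens}")

        rep_lt50s = []
        for _, rep in grp.groupby("replicate_id"):
            med = median_survival(kaplan_meier(
                rep["time_h"].to_numpy(dtype=float),
                (rep["status"] == "dead").to_numpy()))
            if med.defined:
                rep_lt50s.append(med.time_h)
        if aggregation == "mean_of_replicates" and rep_lt50s:
            lt50 = float(np.mean(rep_lt50s))
        else:
            pooled = median_survival(kaplan_meier(
                grp["time_h"].to_numpy(dtype=float),
                (grp["status"] == "dead").to_numpy()))
            lt50 = pooled.time_h
            if not pooled.defined:
                flags.append("lt50_undefined")

        mean_h = float(dead.mean()) if len(dead) else float("nan")
        if len(dead) >= 2:
            sigma = _sd_intercept_only(dead)
            if sigma > 0:
                ln_sigma = float(np.log(sigma))
            else:
                ln_sigma = float("nan")
                flags.append("ln_sigma_undefined(sigma=0)")
            cv = sigma / mean_h if mean_h else float("nan")
        else:
            sigma = ln_sigma = cv = float("nan")
            flags.append("sigma_undefined(<2 deaths)")

        rows.append({"line_id": lid, "sex": sex, "n": len(grp),
                     "lt50_h": lt50, "mean_h": mean_h, "sigma_e": sigma,
                     "ln_sigma_e": ln_sigma, "cv_e": cv,
                     "flags": ",".join(flags),
                     "replicate_lt50s": rep_lt50s})
    return pd.DataFrame(rows)


def replicate_ln_sigma(events: EventTable,
                       include_control: bool = False) -> pd.DataFrame:
    """sigma_E estimated separately for each line, sex and replicate tube.

    Each tube contributes one ln(sigma_E) observation to the variance-level
    heritability analysis.
    """
    df = events.df if include_control else events.pathogen_only().df
    rows = []
    for (lid, sex, rep), grp in df.groupby(["line_id", "sex", "replicate_id"]):
        dead = grp[grp["status"] == "dead"]["time_h"].to_numpy(dtype=float)
        if len(dead) < 2:
            continue
        sigma = _sd_intercept_only(dead)
        rows.append({"line_id": lid, "sex": sex, "replicate_id": rep,
                     "n_dead": len(dead), "sigma_e": sigma,
                     "ln_sigma_e": float(np.log(sigma)) if sigma > 0
                     else float("nan")})
    return pd.DataFrame(rows)


def write_line_summaries(summaries: pd.DataFrame, path) -> None:
    summaries[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False,
                                      float_format="%.6g", lineterminator="\n")


def read_line_summaries(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"line_id": str},
                       keep_default_na=True)
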
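"""Expression-stratified survival analysis from first principles.

The workflow mirrors the standard cohort analysis for a single gene:
log2-transform and z-normalize the expression values within the cohort,
split subjects into high/low strata at the mean, estimate each stratum's
Kaplan-Meier survival curve, and compare strata with the log-rank test.
The product-limit estimator and the log-rank statistic are implemented
here directly (they are the point of the module); external survival
packages appear only as cross-checks in the test suite.

Conventions (recorded, configurable where noted):
- z-normalization uses the population SD (divisor n).
- log2 pseudocount is 1 for raw-scale inputs.
- mean-split ties (value == mean) go to the "low" stratum.
- at a tied event/censoring time the censored subject is still at risk
  (censoring processed after the event).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateCohortError(ValueError):
    """Raised when a cohort has zero expression variance."""


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit curve over distinct event times."""

    event_times: np.ndarray     # sorted distinct times with >= 1 event
    survival: np.ndarray        # S(t) just after each event time
    at_risk: np.ndarray         # risk-set size just before each event time
    n_events: np.ndarray        # events at each event time

    def __post_init__(self):
        s = np.asarray(self.survival, dtype=float)
        if s.size and (s[0] > 1 + 1e-12 or (np.diff(s) > 1e-12).any()
                       or (s < -1e-12).any()):
            raise ValueError("survival must start <= 1 and be non-increasing in [0, 1]")

    def survival_at(self, t: float) -> float:
        """S(t): probability of surviving beyond time t."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    @property
    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5 (inf if never reached)."""
        below = np.flatnonzero(self.survival <= 0.5)
        return float(self.event_times[below[0]]) if below.size else float("inf")


def normalize_expression(raw_values, pseudocount: float = 1.0,
                         ddof: int = 0) -> np.ndarray:
    """log2(x + pseudocount), then center to mean 0 and scale to SD 1."""
    x = np.asarray(raw_values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    v = np.log2(x + pseudocount)
    sd = v.std(ddof=ddof)
    if sd == 0:
        raise DegenerateCohortError("zero variance after log transform")
    return (v - v.mean()) / sd


def stratify_by_mean(values) -> np.ndarray:
    """Label each subject 'high' (value > mean) or 'low' (value <= mean)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    labels = np.where(v > mean, "high", "low")
    if (labels == "low").all():
        warnings.warn("all values <= mean; every subject assigned to 'low'",
                      stacklevel=2)
    return labels


def _check_times_events(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if (t <= 0).any():
        raise ValueError("times must be > 0")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0 (censored) or 1 (event)")
    return t, e.astype(int)


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Steps down at each distinct event time t_i by the factor
    (n_i - d_i) / n_i where n_i subjects are at risk and d_i fail at t_i;
    censored-only times shrink later risk sets without producing steps.
    """
    t, e = _check_times_events(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]

    event_times, surv, at_risk, n_events = [], [], [], []
    s = 1.0
    n = len(t)
    distinct = np.unique(t)
    # risk set just before time u: subjects with time >= u
    for u in distinct:
        here = t == u
        d = int(e[here].sum())
        n_risk = int((t >= u).sum())
        if d > 0:
            s *= (n_risk - d) / n_risk
            event_times.append(float(u))
            surv.append(s)
            at_risk.append(n_risk)
            n_events.append(d)
    return KMCurve(event_times=np.array(event_times),
                   survival=np.array(surv),
                   at_risk=np.array(at_risk, dtype=int),
                   n_events=np.array(n_events, dtype=int))


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-sample log-rank test.

    At each distinct event time, the observed events in group 1 are
    compared with their hypergeometric expectation given the pooled risk
    set; chi_square = (sum O - sum E)^2 / sum Var with the hypergeometric
    variance, and the p-value is the 1-df chi-square upper tail.
    Returns (chi_square, p_value).
    """
    t, e = _check_times_events(times, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise ValueError("groups must have the same length as times")
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 non-empty strata, got {len(labels)}")
    if e.sum() == 0:
        raise ValueError("log-rank undefined with zero events")
    in1 = g == labels[0]

    O = E = V = 0.0
    for u in np.unique(t[e == 1]):
        at_risk = t >= u
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        here = (t == u) & (e == 1)
        d = int(here.sum())
        d1 = int((here & in1).sum())
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1.0
    chi2 = (O - E) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def analyze_cohort(cohort: pd.DataFrame, pseudocount: float = 1.0,
                   ddof: int = 0) -> dict:
    """Full single-gene pipeline: normalize, stratify, KM per stratum,
    log-rank between strata.

    ``cohort`` needs columns expression, time, event. Returns a dict with
    the stratified cohort, one KMCurve per stratum, and the test result.
    """
    required = {"expression", "time", "event"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort missing columns: {sorted(missing)}")
    z = normalize_expression(cohort["expression"].to_numpy(), pseudocount,
                             ddof)
    strata = stratify_by_mean(z)
    out = cohort.copy()
    out["expression_z"] = z
    out["stratum"] = strata
    curves = {}
    for label in ("high", "low"):
        sel = strata == label
        if sel.any():
            curves[label] = km_estimate(out.loc[sel, "time"],
                                        out.loc[sel, "event"])
    chi2, p = logrank_test(out["time"], out["event"], strata)
    return {"cohort": out, "curves": curves, "chi_square": chi2,
            "p_value": p}


def km_table(curve: KMCurve) -> pd.DataFrame:
    return pd.DataFrame({
        "time": curve.event_times,
        "survival": curve.survival,
        "at_risk": curve.at_risk,
        "n_events": curve.n_events,
    })


def save_km_plot(curves: dict[str, KMCurve], path: str, *,
                 title: str | None = None) -> None:
    """Stepped survival curves per stratum (vector format)."""
    import matplotlib
    matplotlib.use("Agg")
    matplotlib.rcParams["svg.hashsalt"] = "spherotrack"  # deterministic ids
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in sorted(curves.items()):
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.savefig(path, metadata={"Date": None}
                if path.endswith(".svg") else None)
    plt.close(fig)
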
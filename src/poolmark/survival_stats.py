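"""Kaplan-Meier, two-group log-rank, and binary-covariate Cox regression.

These run on a *pooled* two-group cohort: high/low labels assigned within
each cohort, then concatenated across cohorts with no further adjustment.
The Cox model uses a single binary covariate (group, high vs low) with the
Efron correction for tied event times, maximized by a one-dimensional
Newton iteration driven to machine precision.  The group is coded
+1/2 / -1/2 internally, which makes the swapped-label partial likelihood
the exact mirror image of the original — so swapping high and low returns
exactly the reciprocal hazard ratio, and rescaling all times (which the
partial likelihood sees only through ordering and ties) leaves the
estimate bit-identical.

Times are in months and never rescaled internally.  The headline p-value
of a query is the log-rank p; the Cox Wald p accompanies it in the
detailed result.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ClinicalTable, ENDPOINTS
from .errors import DataError
from .grouping import EXCLUDED, HIGH, LOW, GroupAssignment

logger = logging.getLogger(__name__)

Z_95 = float(stats.norm.ppf(0.975))


@dataclass
class PooledCohort:
    """(time, event, group, dataset) records pooled across cohorts for one endpoint."""

    endpoint: str
    records: pd.DataFrame  # columns: time, event, group, dataset_id

    def __post_init__(self) -> None:
        need = {"time", "event", "group", "dataset_id"}
        if not need.issubset(self.records.columns):
            raise DataError(f"pooled cohort needs columns {sorted(need)}")
        t = self.records["time"]
        if len(t) and not (np.isfinite(t).all() and (t > 0).all()):
            raise DataError("survival times must be finite and positive")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def n_events(self) -> int:
        return int(self.records["event"].sum())

    @property
    def per_dataset_n(self) -> dict[str, int]:
        return self.records["dataset_id"].value_counts().to_dict()

    def group_sizes(self) -> dict[str, int]:
        return self.records["group"].value_counts().to_dict()


@dataclass
class KMCurve:
    """Product-limit curves per group: time grid, survival, at-risk, censoring."""

    curves: dict[str, pd.DataFrame]  # group -> (time, n_at_risk, n_events, n_censored, survival)

    def survival_at(self, group: str, t: float) -> float:
        df = self.curves[group]
        s = 1.0
        for time, surv in zip(df["time"], df["survival"]):
            if time <= t:
                s = surv
            else:
                break
        return s


@dataclass
class TestResult:
    """Pooled two-group comparison: log-rank test + Cox hazard ratio (high vs low)."""

    hr: float
    hr_ci_low: float
    hr_ci_high: float
    beta: float
    se: float
    cox_p: float
    logrank_chi2: float
    logrank_p: float
    n: int
    events: int
    separation: bool = False
    converged: bool = True
    n_iter: int = 0


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def _km_one_group(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    grid = np.unique(time)
    n = len(time)
    rows = []
    surv = 1.0
    for t in grid:
        at = time == t
        n_at_risk = int((time >= t).sum())
        d = int(event[at].sum())
        c = int((~event[at].astype(bool)).sum())
        if d:
            surv *= 1.0 - d / n_at_risk
        rows.append((float(t), n_at_risk, d, c, surv))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "n_censored", "survival"])


def km_estimate(cohort: PooledCohort) -> KMCurve:
    """Kaplan-Meier product-limit estimate per group.

    Subjects censored at an event time are counted at risk at that time.
    """
    curves = {}
    for group in (HIGH, LOW):
        sub = cohort.records[cohort.records["group"] == group]
        if len(sub) == 0:
            raise DataError(f"empty group {group!r}")
        curves[group] = _km_one_group(
            sub["time"].to_numpy(dtype=float), sub["event"].to_numpy(dtype=float)
        )
    return KMCurve(curves)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def logrank_test(cohort: PooledCohort) -> tuple[float, float]:
    """Standard two-group log-rank test.

    At each distinct event time the observed events in the high group are
    compared with the hypergeometric expectation; chi2 = (sum O-E)^2 / sum V
    on 1 df.
    """
    df = cohort.records
    for group in (HIGH, LOW):
        if (df["group"] == group).sum() == 0:
            raise DataError(f"empty group {group!r}")
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=float)
    is_high = (df["group"] == HIGH).to_numpy()
    if event.sum() == 0:
        raise DataError("no events")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_tot = int(at_risk.sum())
        n_high = int((at_risk & is_high).sum())
        dying = (time == t) & (event == 1)
        d = int(dying.sum())
        o1 = int((dying & is_high).sum())
        e1 = d * n_high / n_tot
        o_minus_e += o1 - e1
        if n_tot > 1:
            var += d * (n_high / n_tot) * (1 - n_high / n_tot) * (n_tot - d) / (n_tot - 1)
    if var == 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e * o_minus_e / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


# ---------------------------------------------------------------------------
# Cox (one binary covariate, Efron ties)
# ---------------------------------------------------------------------------

def _efron_llgh(
    beta: float, time: np.ndarray, event: np.ndarray, x: np.ndarray
) -> tuple[float, float, float]:
    """Log partial likelihood, gradient and Hessian for one stratum.

    Subjects must be pre-sorted by ascending time.  x is the covariate
    (+1/2 high, -1/2 low).
    """
    ex = np.exp(beta * x)
    s0 = np.cumsum(ex[::-1])[::-1]          # suffix sums over the risk set
    s1 = np.cumsum((x * ex)[::-1])[::-1]
    s2 = np.cumsum((x * x * ex)[::-1])[::-1]
    ll = grad = hess = 0.0
    i, n = 0, len(time)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        dying = event[i:j] == 1
        d = int(dying.sum())
        if d:
            xs = x[i:j][dying]
            exs = ex[i:j][dying]
            s0d = float(exs.sum())
            s1d = float((xs * exs).sum())
            s2d = float((xs * xs * exs).sum())
            ll += beta * float(xs.sum())
            grad += float(xs.sum())
            for l in range(d):
                f = l / d
                phi = s0[i] - f * s0d
                a = s1[i] - f * s1d
                b = s2[i] - f * s2d
                ll -= math.log(phi)
                grad -= a / phi
                hess -= b / phi - (a / phi) ** 2
        i = j
    return ll, grad, hess


def _separation_result(
    events_high: int, events_low: int, lr: tuple[float, float], n: int, events: int
) -> TestResult:
    hr = math.inf if events_low == 0 else 0.0
    beta = math.inf if events_low == 0 else -math.inf
    return TestResult(
        hr=hr, hr_ci_low=0.0, hr_ci_high=math.inf, beta=beta, se=math.inf,
        cox_p=float("nan"), logrank_chi2=lr[0], logrank_p=lr[1],
        n=n, events=events, separation=True, converged=False,
    )


def cox_hr(
    cohort: PooledCohort,
    stratify_by_dataset: bool = False,
    max_iter: int = 50,
    tol: float = 1e-12,
) -> TestResult:
    """Cox proportional-hazards hazard ratio of the high vs low group.

    Maximum partial likelihood with the Efron tie correction; Wald 95% CI
    and Wald p.  With ``stratify_by_dataset`` each cohort keeps its own
    baseline hazard.  Monotone likelihood (all events in one group) is
    returned as a flagged result with an infinite-bound CI rather than an
    exception.
    """
    df = cohort.records
    lr = logrank_test(cohort)  # validates groups and event presence
    n, events = cohort.n, cohort.n_events
    events_high = int(df.loc[df["group"] == HIGH, "event"].sum())
    events_low = events - events_high
    if events_high == 0 or events_low == 0:
        return _separation_result(events_high, events_low, lr, n, events)

    strata: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    groups = [df] if not stratify_by_dataset else [g for _, g in df.groupby("dataset_id", sort=True)]
    for g in groups:
        t = g["time"].to_numpy(dtype=float)
        order = np.argsort(t, kind="stable")
        strata.append(
            (
                t[order],
                g["event"].to_numpy(dtype=float)[order],
                np.where((g["group"] == HIGH).to_numpy()[order], 0.5, -0.5),
            )
        )

    beta = 0.0
    converged = False
    it = 0
    hess = -1.0
    for it in range(1, max_iter + 1):
        grad = 0.0
        hess = 0.0
        for t, e, x in strata:
            _, g1, h1 = _efron_llgh(beta, t, e, x)
            grad += g1
            hess += h1
        if hess >= 0:  # no information (e.g. all events in single-subject risk sets)
            return _separation_result(events_high, events_low, lr, n, events)
        step = -grad / hess
        if step > 2.0:
            step = 2.0
        elif step < -2.0:
            step = -2.0
        beta += step
        if abs(beta) > 15.0:
            return _separation_result(events_high, events_low, lr, n, events)
        if abs(step) < tol:
            converged = True
            break
    if not converged:
        raise DataError(
            f"Cox fit failed to converge after {max_iter} iterations (beta={beta:.6g})"
        )
    se = math.sqrt(-1.0 / hess)
    hr = math.exp(beta)
    return TestResult(
        hr=hr,
        hr_ci_low=math.exp(beta - Z_95 * se),
        hr_ci_high=math.exp(beta + Z_95 * se),
        beta=beta,
        se=se,
        cox_p=float(2.0 * stats.norm.sf(abs(beta) / se)),
        logrank_chi2=lr[0],
        logrank_p=lr[1],
        n=n,
        events=events,
        separation=False,
        converged=True,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def build_pooled_cohort(
    assignments: Sequence[GroupAssignment],
    clinical: Mapping[str, ClinicalTable],
    endpoint: str,
) -> PooledCohort:
    """Concatenate per-cohort group labels with the endpoint's (time, event).

    Only samples labelled high/low with an observed endpoint contribute;
    cohorts lacking the endpoint entirely contribute nothing (logged).
    Zero or negative times cannot enter a hazard model and are dropped
    with a warning.
    """
    endpoint = endpoint.lower()
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    frames = []
    for a in assignments:
        ct = clinical.get(a.dataset_id)
        if ct is None:
            raise DataError(f"no clinical table for dataset {a.dataset_id!r}")
        avail = ct.endpoint_available(endpoint)
        if not avail.any():
            logger.warning(
                "dataset %r has no %s data; contributes nothing", a.dataset_id, endpoint.upper()
            )
            continue
        labels = a.labels
        usable = labels.isin([HIGH, LOW]) & avail.reindex(labels.index, fill_value=False)
        t = ct.data[f"{endpoint}_time"].reindex(labels.index)
        nonpos = usable & (t <= 0)
        if nonpos.any():
            logger.warning(
                "dataset %r: %d sample(s) with non-positive %s time dropped",
                a.dataset_id, int(nonpos.sum()), endpoint.upper(),
            )
            usable &= t > 0
        sub = pd.DataFrame(
            {
                "time": t[usable].to_numpy(dtype=float),
                "event": ct.data[f"{endpoint}_event"].reindex(labels.index)[usable].to_numpy(dtype=float),
                "group": labels[usable].to_numpy(),
                "dataset_id": a.dataset_id,
            }
        )
        frames.append(sub)
    records = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["time", "event", "group", "dataset_id"])
    )
    return PooledCohort(endpoint=endpoint, records=records)


def analyze_pooled(
    assignments: Sequence[GroupAssignment],
    clinical: Mapping[str, ClinicalTable],
    endpoint: str,
    stratify_by_dataset: bool = False,
) -> tuple[PooledCohort, KMCurve, TestResult]:
    """Full pooled two-group analysis: KM curves, log-rank test, Cox HR."""
    cohort = build_pooled_cohort(assignments, clinical, endpoint)
    sizes = cohort.group_sizes()
    if sizes.get(HIGH, 0) == 0 or sizes.get(LOW, 0) == 0:
        raise DataError("single-group cohort after exclusions")
    km = km_estimate(cohort)
    test = cox_hr(cohort, stratify_by_dataset=stratify_by_dataset)
    return cohort, km, test


# ---------------------------------------------------------------------------
# utilities / export
# ---------------------------------------------------------------------------

def adjust_pvalues(pvalues: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment for multi-gene sweeps (off by default in
    single-marker analyses)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method=method)[1]


def km_to_tsv(km: KMCurve, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("group\ttime\tsurvival\tn_at_risk\tn_events\tn_censored\n")
        for group, df in km.curves.items():
            for _, row in df.iterrows():
                fh.write(
                    f"{group}\t{row['time']!r}\t{row['survival']!r}\t"
                    f"{int(row['n_at_risk'])}\t{int(row['n_events'])}\t{int(row['n_censored'])}\n"
                )


def plot_km(
    km: KMCurve,
    test: Optional[TestResult] = None,
    path: Optional[str | Path] = None,
    title: Optional[str] = None,
):
    """Step plot of the two survival curves, annotated with n / HR / log-rank p."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    colors = {HIGH: "#c0392b", LOW: "#2980b9"}
    for group, df in km.curves.items():
        t = np.concatenate([[0.0], df["time"].to_numpy()])
        s = np.concatenate([[1.0], df["survival"].to_numpy()])
        ax.step(t, s, where="post", label=group, color=colors.get(group))
        cens = df[df["n_censored"] > 0]
        ax.plot(cens["time"], cens["survival"], "|", color=colors.get(group), ms=8)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if test is not None:
        ax.text(
            0.02, 0.06,
            f"n = {test.n}\nHR = {test.hr:.3g} ({test.hr_ci_low:.3g}-{test.hr_ci_high:.3g})\n"
            f"log-rank p = {test.logrank_p:.3g}",
            transform=ax.transAxes, fontsize=9, va="bottom",
        )
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
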
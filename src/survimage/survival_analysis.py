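"""Risk-group validation of predicted scores with survival statistics.

Test samples are split at the Youden-optimal threshold into predicted
high-risk (score strictly above the threshold) and low-risk groups, and the
separation is quantified three ways on the FULL follow-up times and event
flags (not the binarized horizon labels):

* Kaplan-Meier product-limit curves per group,
  S(t) = prod_{t_i <= t} (1 - d_i / n_i);
* the two-group log-rank test (observed-minus-expected event counts with
  hypergeometric variance at each distinct event time, chi-square with 1 df);
* a univariate Cox proportional-hazards fit on the binary predicted-dead
  indicator (Breslow tie handling), reporting HR = exp(beta), a 95% Wald CI
  and p-value.  Non-convergence (e.g. complete separation) is flagged on
  the result rather than raised or hidden.

Estimation is delegated to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _lifelines_logrank

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "CoxResult",
    "assign_risk_groups",
    "km_estimate",
    "logrank_test",
    "cox_univariate_hr",
    "plot_km_groups",
]


@dataclass
class SurvivalRecord:
    sample_id: str
    time: float  # months
    event: int  # 1 = death observed
    group: str  # "high" or "low"

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if self.group not in ("high", "low"):
            raise ValueError("group must be 'high' or 'low'")


def assign_risk_groups(scores: Sequence[float], threshold: float) -> np.ndarray:
    """'high' where score is strictly larger than the threshold, else 'low'."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    s = np.asarray(scores, dtype=float)
    return np.where(s > threshold, "high", "low")


@dataclass
class KMCurve:
    """Product-limit estimate stepping only at observed event times."""

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk_counts: np.ndarray

    def __post_init__(self):
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.survival_probs = np.asarray(self.survival_probs, dtype=float)
        self.at_risk_counts = np.asarray(self.at_risk_counts, dtype=int)
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly ascending")
        if np.any(np.diff(self.survival_probs) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if len(self.survival_probs) and (
            self.survival_probs.max() > 1 or self.survival_probs.min() < 0
        ):
            raise ValueError("survival probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival_probs,
                "at_risk": self.at_risk_counts,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier estimate; censored records leave the risk set after their time."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    event_times = event_rows.index.to_numpy(dtype=float)
    survival = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = event_rows["at_risk"].to_numpy(dtype=int)
    return KMCurve(event_times, survival, at_risk)


def logrank_test(
    high: Sequence[SurvivalRecord], low: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test -> (chi-square statistic, p-value), 1 df."""
    if not len(high) or not len(low):
        raise ValueError("both risk groups must be non-empty")
    t1 = np.array([r.time for r in high])
    e1 = np.array([r.event for r in high])
    t2 = np.array([r.time for r in low])
    e2 = np.array([r.event for r in low])
    if e1.sum() + e2.sum() == 0:
        raise ValueError("need at least one event overall")
    res = _lifelines_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool
    message: str = ""


def cox_univariate_hr(
    times: Sequence[float],
    events: Sequence[int],
    indicator: Sequence[int],
) -> CoxResult:
    """Univariate proportional-hazards fit on a binary indicator.

    HR = exp(beta) maximizing the partial likelihood with Breslow tie
    handling; Wald 95% CI and p-value.  Monotone likelihood / complete
    separation yields a flagged (``converged=False``) result.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    x = np.asarray(indicator, dtype=int)
    levels = np.unique(x)
    if len(levels) != 2:
        raise ValueError("indicator must take exactly two values")
    for lvl in levels:
        if e[x == lvl].sum() < 1:
            raise ValueError(f"indicator level {lvl} has no events")
    df = pd.DataFrame({"time": t, "event": e, "indicator": x})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(df, duration_col="time", event_col="event")
        convergence_msgs = [
            str(w.message)
            for w in caught
            if any(
                key in str(w.message).lower()
                for key in ("converg", "separation", "collinear", "ill-conditioned")
            )
        ]
        summary = cph.summary.loc["indicator"]
        with np.errstate(over="ignore"):  # CI bounds may overflow when flagged
            hr, lo, hi = np.exp(
                [summary["coef"], summary["coef lower 95%"], summary["coef upper 95%"]]
            )
        return CoxResult(
            hr=float(hr),
            ci_low=float(lo),
            ci_high=float(hi),
            p_value=float(summary["p"]),
            converged=not convergence_msgs,
            message="; ".join(convergence_msgs),
        )
    except ConvergenceError as exc:
        return CoxResult(
            hr=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            p_value=float("nan"),
            converged=False,
            message=str(exc),
        )


def plot_km_groups(
    high: Sequence[SurvivalRecord],
    low: Sequence[SurvivalRecord],
    path: str | Path,
) -> None:
    """Paired KM curves of the two risk groups as a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for records, label, color in ((high, "high risk", "C3"), (low, "low risk", "C0")):
        kmf = KaplanMeierFitter()
        kmf.fit(
            [r.time for r in records],
            event_observed=[r.event for r in records],
            label=label,
        )
        kmf.plot_survival_function(ax=ax, color=color)
    ax.set_xlabel("overall survival (months)")
    ax.set_ylabel("survival probability")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
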
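"""Kaplan-Meier estimation and log-rank comparison for disease-specific survival.

The event is death of disease (DSS endpoint); all other exits are treated
as censoring. Ties between events and censorings at the same time follow
the standard convention that events are processed first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


@dataclass
class SurvivalCurve:
    """Product-limit estimate at observed event times."""

    group: str
    event_times: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        """S(t): survival just after time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.event_times, "n_risk": self.n_risk,
                             "n_event": self.n_events,
                             "survival": self.survival})


def km_curve(records: pd.DataFrame, group: str = "all") -> SurvivalCurve:
    """Kaplan-Meier curve from records with followup_months / dss_event.

    Censored times reduce the risk set without introducing steps.
    """
    if len(records) == 0:
        raise ValueError("need >= 1 record")
    t = records["followup_months"].to_numpy(dtype=float)
    if (t < 0).any():
        raise ValueError("negative follow-up time")
    e = records["dss_event"].to_numpy(dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    is_event = table["observed"] > 0
    event_times = table.index.to_numpy(dtype=float)[is_event]
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    return SurvivalCurve(
        group=group,
        event_times=event_times,
        n_risk=table.loc[is_event, "at_risk"].to_numpy(dtype=int),
        n_events=table.loc[is_event, "observed"].to_numpy(dtype=int),
        survival=surv,
    )


def logrank(records: pd.DataFrame, labels: pd.Series) -> tuple[float, float]:
    """Standard k-group log-rank test: (chi2 with k−1 df, two-sided p)."""
    labels = pd.Series(labels)
    if "sample_id" in records and set(records["sample_id"]) <= set(labels.index):
        labels = labels.reindex(records["sample_id"])
    elif len(labels) == len(records):
        labels = pd.Series(labels.to_numpy(), index=records.index)
    else:
        raise ValueError("labels align neither by sample_id nor by position")
    groups = pd.unique(labels.dropna())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g in groups:
        if (labels == g).sum() == 0:
            raise ValueError(f"group {g!r} has no records")
    if records["dss_event"].sum() == 0:
        raise ValueError("need >= 1 event in total")
    res = multivariate_logrank_test(
        records["followup_months"].to_numpy(dtype=float),
        labels.to_numpy(),
        records["dss_event"].to_numpy(dtype=bool))
    return float(res.test_statistic), float(res.p_value)


def define_survival_groups(complexity: pd.DataFrame, mode: str,
                           custom: pd.Series | None = None) -> pd.Series:
    """Group labels for survival stratification.

    ``nfga_binary`` splits 0 vs >= 1 focal amplicon; ``cin_median`` splits
    at the median CIN score with the median sample going to the lower
    group; ``custom_labels`` passes ``custom`` through.
    """
    if mode == "nfga_binary":
        return pd.Series(np.where(complexity["nFGA"] == 0, "nFGA=0", "nFGA>=1"),
                         index=complexity.index)
    if mode == "cin_median":
        v = complexity["cin_score"]
        med = float(v.median())
        return pd.Series(np.where(v <= med, "CIN-low", "CIN-high"),
                         index=complexity.index)
    if mode == "custom_labels":
        if custom is None:
            raise ValueError("custom_labels mode needs the custom series")
        return custom.reindex(complexity.index)
    raise ValueError(f"unknown mode {mode!r}")
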
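"""Outcome association for compositional shift.

Two analyses link the diagnosis-to-relapse Aitchison distance to patient
outcome:

* a univariate comparison splitting patients into high/low groups at the
  mean distance, compared by Kaplan-Meier curves and the log-rank test;
* Cox proportional-hazards regression of overall survival (or time to
  relapse) on the continuous distance with patient sex as a covariate,
  reporting the hazard ratio per unit distance with Wald p-value and 95% CI.

Ties in the Cox partial likelihood use the Efron approximation (the
lifelines default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "SurvivalRecord",
    "records_to_frame",
    "mean_split_logrank",
    "cox_fit",
]


@dataclass
class SurvivalRecord:
    """One patient's outcome data plus the compositional-shift covariate."""

    patient_id: str
    os_time: float  # months
    event: int  # 1 = death observed
    sex: int  # 0/1 encoding, recorded in output
    distance: float  # Aitchison distance, continuous covariate
    time_to_relapse: Optional[float] = None

    def __post_init__(self) -> None:
        if self.os_time <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event flag must be 0 or 1")


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "os_time": [r.os_time for r in records],
            "event": [r.event for r in records],
            "sex": [r.sex for r in records],
            "distance": [r.distance for r in records],
            "time_to_relapse": [r.time_to_relapse for r in records],
        }
    ).set_index("patient_id")


def mean_split_logrank(
    records: Sequence[SurvivalRecord] | pd.DataFrame,
    *,
    split: str = "mean",
) -> dict:
    """High/low split at the mean (or median) distance, log-rank compared.

    Returns the group labels, the log-rank test statistic and p-value, and
    Kaplan-Meier survival-curve points per group for plotting.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    cutoff = df["distance"].mean() if split == "mean" else df["distance"].median()
    high = df["distance"] > cutoff
    if high.all() or (~high).all():
        raise ValueError(
            f"degenerate split: all distances on one side of the {split} ({cutoff:.4g})"
        )
    result = logrank_test(
        df.loc[high, "os_time"],
        df.loc[~high, "os_time"],
        event_observed_A=df.loc[high, "event"],
        event_observed_B=df.loc[~high, "event"],
    )
    curves = {}
    for name, mask in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter()
        km.fit(df.loc[mask, "os_time"], df.loc[mask, "event"], label=name)
        curves[name] = km.survival_function_.reset_index().rename(
            columns={"timeline": "time", name: "survival"}
        )
    return {
        "cutoff": float(cutoff),
        "groups": high.map({True: "high", False: "low"}),
        "statistic": float(result.test_statistic),
        "p_value": float(result.p_value),
        "km_curves": curves,
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
    }


def cox_fit(
    records: Sequence[SurvivalRecord] | pd.DataFrame,
    covariates: Sequence[str] = ("sex",),
    outcome: str = "os",
) -> dict:
    """Cox PH fit of the hazard on continuous distance plus covariates.

    ``outcome`` is ``"os"`` (overall survival) or ``"relapse"`` (time to
    relapse; patients without one are treated as censored at os_time).
    Returns the hazard ratio per unit distance, Wald p, and 95% CI.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if outcome == "os":
        work = df[["os_time", "event", "distance", *covariates]].rename(
            columns={"os_time": "time"}
        )
    elif outcome == "relapse":
        relapsed = df["time_to_relapse"].notna()
        work = pd.DataFrame(
            {
                "time": df["time_to_relapse"].where(relapsed, df["os_time"]),
                "event": relapsed.astype(int),
                "distance": df["distance"],
            }
        )
        for c in covariates:
            work[c] = df[c]
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    for col in ("distance", *covariates):
        if work[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} is constant; Cox model unidentifiable")
    cph = CoxPHFitter()
    cph.fit(work, duration_col="time", event_col="event")
    summary = cph.summary.loc["distance"]
    return {
        "hazard_ratio": float(summary["exp(coef)"]),
        "coef": float(summary["coef"]),
        "p_value": float(summary["p"]),
        "ci_lower": float(summary["exp(coef) lower 95%"]),
        "ci_upper": float(summary["exp(coef) upper 95%"]),
        "n": int(work.shape[0]),
        "n_events": int(work["event"].sum()),
        "covariates": list(covariates),
        "summary": cph.summary,
    }
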
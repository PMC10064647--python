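"""Score-based cohort stratification, Kaplan–Meier curves and log-rank tests.

Patients are split on their signature score into low / mid / high groups
(tertiles with the remainder assigned to the outer groups, so a 277-patient
cohort yields 93/91/93) or into halves at the median; survival between the
low and high groups is compared with the standard two-group log-rank test.
Estimation is delegated to lifelines.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = ["stratify", "km_estimate", "logrank", "score_correlation_panel"]


def stratify(scores: pd.Series, clinical: pd.DataFrame,
             scheme: str = "tertiles") -> pd.DataFrame:
    """Assign each patient a low/mid/high group by signature score.

    ``tertiles``: sort by (score, patient id); the lowest ceil(n/3) patients
    are ``low``, the highest ceil(n/3) are ``high``, the remainder ``mid``
    (remainder patients go to the outer groups, matching equal-size low/high
    arms).  ``median``: lower half ``low``, upper half ``high``, no mid.
    Ties are broken by patient id for determinism; all-equal scores warn.
    """
    unmatched = scores.index.symmetric_difference(clinical.index)
    if len(unmatched):
        raise ValueError(f"patients not shared between scores and clinical table: "
                         f"{sorted(unmatched)[:10]}")
    if scheme not in {"tertiles", "median"}:
        raise ValueError(f"unknown stratification scheme {scheme!r}")
    n = len(scores)
    if scores.nunique() <= 1:
        warnings.warn("all scores equal: group assignment falls back to patient-id order",
                      stacklevel=2)
    order = scores.to_frame("score").sort_values(["score"], kind="stable")
    order = order.loc[sorted(order.index, key=lambda p: (order.at[p, "score"], p))]
    group = np.empty(n, dtype=object)
    if scheme == "tertiles":
        k = int(np.ceil(n / 3))
        group[:] = "mid"
        group[:k] = "low"
        group[n - k:] = "high"
    else:
        half = n // 2
        group[:half] = "low"
        group[half:] = "high"
    out = clinical.loc[order.index].copy()
    out.insert(0, "score", order["score"])
    out["group"] = group
    return out.loc[scores.index]  # original patient order


def km_estimate(time: pd.Series | np.ndarray, event: pd.Series | np.ndarray) -> pd.DataFrame:
    """Product-limit (Kaplan–Meier) survival curve as a step table.

    Censored subjects leave the risk set without a step.  Returns a
    DataFrame with columns ``time`` and ``survival`` starting at (0, 1).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if time.size == 0:
        raise ValueError("need at least one subject")
    if (time < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p-value).

    Observed-vs-expected events summed over the distinct event times with the
    hypergeometric variance, one degree of freedom.  With no events in either
    group the test is undefined and (0, 1) is returned with a warning.
    """
    time_a = np.asarray(time_a, dtype=float)
    time_b = np.asarray(time_b, dtype=float)
    event_a = np.asarray(event_a).astype(bool)
    event_b = np.asarray(event_b).astype(bool)
    if time_a.size == 0 or time_b.size == 0:
        raise ValueError("both groups must be nonempty")
    if not event_a.any() and not event_b.any():
        warnings.warn("no events in either group: log-rank undefined, returning p=1",
                      stacklevel=2)
        return 0.0, 1.0
    res = logrank_test(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)


def score_correlation_panel(score: pd.Series, others: Mapping[str, pd.Series],
                            method: str = "spearman") -> pd.DataFrame:
    """Correlate the signature score with companion scores patient-by-patient.

    Returns one row per companion (name, n, r, p) using Spearman (default) or
    Pearson correlation over the shared patients; fewer than 3 shared
    patients is an error.
    """
    if method not in {"spearman", "pearson"}:
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    for name, other in others.items():
        shared = score.index.intersection(other.index)
        if len(shared) < 3:
            raise ValueError(f"only {len(shared)} shared patients with {name!r} (need ≥3)")
        r, p = corr(score.loc[shared].to_numpy(), other.loc[shared].to_numpy())
        rows.append({"name": name, "n": len(shared), "r": float(r), "p": float(p)})
    return pd.DataFrame(rows, columns=["name", "n", "r", "p"])
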
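"""Survival endpoints, maximally selected rank cutpoints, Cox workflow.

Endpoints follow registry conventions: overall survival (OS) runs from
diagnosis to death (censored at last follow-up); recurrence-free survival
(RFS) from surgery to the earliest of recurrence or death (censored at last
follow-up), with patients at stage IV at diagnosis ineligible; survival
after recurrence (SAR) from recurrence to death. Times are in years
(365.25 days).

The maximally selected rank statistic dichotomises a continuous marker at
the cutpoint maximising the standardised two-group log-rank statistic over
all admissible splits (each side keeping at least a minimum fraction of the
cohort). The statistic is computed from log-rank (Savage) scores
``a_i = delta_i - Lambda(t_i)`` (Nelson-Aalen cumulative hazard at the
subject's time) with the conditional permutation mean and variance, making
it invariant under monotone transformations of the marker.

The Cox workflow applies the two-stage contract: univariable screening of
each feature at p < 0.05, then multivariable refit of the survivors with the
clinical covariates; hazard ratios with confidence intervals are reported
for both stages. Model fitting is delegated to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "derive_endpoints",
    "CutpointResult",
    "maxstat_cutpoint",
    "logrank_scores",
    "cox_workflow",
]

DAYS_PER_YEAR = 365.25
DEFAULT_MIN_GROUP_FRACTION = 0.1
DEFAULT_COX_COVARIATES = ("site", "pretreated", "stage", "age_group", "grade")


def _years(later, earlier) -> float:
    return (later - earlier).days / DAYS_PER_YEAR


def derive_endpoints(clinical: pd.DataFrame) -> pd.DataFrame:
    """Derive OS, RFS and SAR rows for every patient.

    Parameters
    ----------
    clinical
        One row per patient with columns sample_id, stage (I..IV),
        date_diagnosis, date_surgery, date_recurrence, date_death,
        date_last_followup (dates parseable by pandas; recurrence/death
        empty when the event did not occur).

    Returns
    -------
    DataFrame with columns sample_id, endpoint, time (years), event,
    eligible, reason. Every patient receives one row per endpoint; the
    derivation is idempotent and total.
    """
    df = clinical.copy()
    for col in (
        "date_diagnosis",
        "date_surgery",
        "date_recurrence",
        "date_death",
        "date_last_followup",
    ):
        df[col] = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
    rows = []
    for r in df.itertuples(index=False):
        pid = r.sample_id
        if pd.isna(r.date_diagnosis):
            raise ValidationError(f"{pid}: missing diagnosis date")
        end_fu = r.date_death if pd.notna(r.date_death) else r.date_last_followup
        if pd.isna(end_fu):
            raise ValidationError(f"{pid}: no death or last follow-up date")
        if end_fu < r.date_diagnosis:
            raise ValidationError(f"{pid}: follow-up ends before diagnosis")
        if (
            pd.notna(r.date_recurrence)
            and pd.notna(r.date_surgery)
            and r.date_recurrence < r.date_surgery
        ):
            raise ValidationError(f"{pid}: recurrence precedes surgery")

        died = pd.notna(r.date_death)
        rows.append(
            {
                "sample_id": pid,
                "endpoint": "OS",
                "time": _years(end_fu, r.date_diagnosis),
                "event": died,
                "eligible": True,
                "reason": "",
            }
        )

        # RFS: surgery -> earliest(recurrence, death), censor at follow-up.
        if str(r.stage) == "IV":
            rfs = {
                "time": np.nan,
                "event": False,
                "eligible": False,
                "reason": "stage IV at diagnosis",
            }
        elif pd.isna(r.date_surgery):
            rfs = {
                "time": np.nan,
                "event": False,
                "eligible": False,
                "reason": "no surgery date",
            }
        else:
            events = [
                d
                for d in (r.date_recurrence, r.date_death)
                if pd.notna(d)
            ]
            if events:
                first = min(events)
                rfs = {
                    "time": _years(first, r.date_surgery),
                    "event": True,
                    "eligible": True,
                    "reason": "",
                }
            else:
                rfs = {
                    "time": _years(r.date_last_followup, r.date_surgery),
                    "event": False,
                    "eligible": True,
                    "reason": "",
                }
        rows.append({"sample_id": pid, "endpoint": "RFS", **rfs})

        if pd.notna(r.date_recurrence):
            sar = {
                "time": _years(end_fu, r.date_recurrence),
                "event": died,
                "eligible": True,
                "reason": "",
            }
        else:
            sar = {
                "time": np.nan,
                "event": False,
                "eligible": False,
                "reason": "no recurrence",
            }
        rows.append({"sample_id": pid, "endpoint": "SAR", **sar})
    out = pd.DataFrame(rows)
    if (out.loc[out["eligible"], "time"] < 0).any():
        raise ValidationError("negative survival time derived")
    return out


def logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Log-rank (Savage) scores ``a_i = delta_i - Lambda(t_i)``.

    Lambda is the Nelson-Aalen cumulative hazard evaluated at each
    subject's observed time, with ties handled through event counts.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    order = np.argsort(time, kind="stable")
    n = len(time)
    at_risk = n
    cumhaz = 0.0
    scores = np.empty(n, dtype=float)
    i = 0
    t_sorted = time[order]
    e_sorted = event[order]
    while i < n:
        j = i
        while j < n and t_sorted[j] == t_sorted[i]:
            j += 1
        d = int(e_sorted[i:j].sum())
        if d > 0:
            cumhaz += d / at_risk
        for k in range(i, j):
            scores[order[k]] = float(e_sorted[k]) - cumhaz
        at_risk -= j - i
        i = j
    return scores


@dataclass(frozen=True)
class CutpointResult:
    variable: str
    cutpoint: float
    statistic: float  # max |standardised log-rank| over admissible splits
    n_low: int
    n_high: int


def maxstat_cutpoint(
    values,
    time,
    event,
    min_group_fraction: float = DEFAULT_MIN_GROUP_FRACTION,
    variable: str = "marker",
) -> CutpointResult:
    """Maximally selected log-rank cutpoint for a continuous marker.

    Candidate cutpoints are midpoints between consecutive distinct marker
    values whose induced groups each keep at least ``min_group_fraction``
    of the cohort. At each candidate, the standardised statistic is
    ``(S - E) / sqrt(V)`` where S sums the log-rank scores of the low
    group and E, V are the conditional permutation mean and variance. The
    cutpoint maximising |Z| is returned (smallest cutpoint on ties).
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if not (len(x) == len(t) == len(e)):
        raise ValidationError("values, time and event must be equal length")
    if np.isnan(x).any() or np.isnan(t).any():
        raise ValidationError("NaN in marker or time")
    n_events = int(e.sum())
    if n_events == 0:
        raise ValidationError("no events; log-rank statistic undefined")
    if np.unique(x).size < 2:
        raise ValidationError("marker is constant; no admissible cutpoint")
    if n_events < 20:
        warnings.warn(
            f"only {n_events} events; selected cutpoint will be unstable",
            stacklevel=2,
        )

    a = logrank_scores(t, e)
    n = len(x)
    abar = a.mean()
    ss = float(((a - abar) ** 2).sum())
    if ss == 0:
        raise ValidationError("degenerate survival data (all scores equal)")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    cs = np.cumsum(a[order])
    # Split after position k (0-based): low group = first k+1 subjects.
    distinct_end = np.nonzero(xs[:-1] < xs[1:])[0]  # last index of each run
    best = None
    min_m = min_group_fraction * n - 1e-9  # tolerate exact-boundary fractions
    for k in distinct_end:
        m = k + 1
        if m < min_m or (n - m) < min_m:
            continue
        S = cs[k]
        E = m * abar
        V = m * (n - m) * ss / (n * (n - 1))
        z = abs(S - E) / np.sqrt(V)
        cut = (xs[k] + xs[k + 1]) / 2.0
        if best is None or z > best[0] + 1e-12:
            best = (z, cut, m)
    if best is None:
        raise ValidationError(
            "no admissible cutpoint under the minimum group fraction"
        )
    z, cut, m = best
    return CutpointResult(
        variable=variable,
        cutpoint=float(cut),
        statistic=float(z),
        n_low=int(m),
        n_high=int(n - m),
    )


def _fit_cox(frame: pd.DataFrame) -> CoxPHFitter | None:
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="time", event_col="event")
    except Exception:
        return None
    return cph


def cox_workflow(
    endpoints: pd.DataFrame,
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    screen_p: float = 0.05,
    min_carriers: int = 5,
    covariate_names=DEFAULT_COX_COVARIATES,
) -> pd.DataFrame:
    """Univariable screen then multivariable Cox refit, per endpoint.

    Parameters
    ----------
    endpoints
        Output of :func:`derive_endpoints` (eligible rows are used).
    features
        Patients x features, binary or continuous, indexed by sample_id.
    covariates
        Patients x clinical covariates, indexed by sample_id; categorical
        columns are dummy-coded. Only columns named in ``covariate_names``
        and present are used.

    Returns
    -------
    DataFrame with one row per endpoint x feature x stage
    (``univariable`` / ``multivariable``): hazard_ratio, ci_low, ci_high,
    p_value, n, n_events. Binary features with fewer than ``min_carriers``
    carriers are skipped with a warning, as are rank-deficient fits.
    """
    cov = covariates[[c for c in covariate_names if c in covariates.columns]]
    cov_design = pd.get_dummies(cov, drop_first=True, dtype=float)
    out = []
    for endpoint, ep in endpoints.groupby("endpoint", sort=True):
        ep = ep[ep["eligible"]].set_index("sample_id")
        if ep.empty:
            continue
        base = ep[["time", "event"]].astype(float)
        for feat in features.columns:
            f = features[feat].reindex(base.index)
            data = pd.concat([base, f.rename("feature")], axis=1).dropna()
            uniq = data["feature"].nunique()
            if uniq <= 1:
                warnings.warn(f"{feat}: constant over {endpoint} cohort; skipped")
                continue
            if uniq == 2:
                carriers = int((data["feature"] == data["feature"].max()).sum())
                if carriers < min_carriers:
                    warnings.warn(
                        f"{feat}: only {carriers} carriers; skipped", stacklevel=2
                    )
                    continue
            uni = _fit_cox(data)
            if uni is None:
                warnings.warn(f"{feat}: univariable Cox fit failed; skipped")
                continue
            s = uni.summary.loc["feature"]
            out.append(
                {
                    "endpoint": endpoint,
                    "feature": feat,
                    "stage": "univariable",
                    "hazard_ratio": float(s["exp(coef)"]),
                    "ci_low": float(s["exp(coef) lower 95%"]),
                    "ci_high": float(s["exp(coef) upper 95%"]),
                    "p_value": float(s["p"]),
                    "n": int(len(data)),
                    "n_events": int(data["event"].sum()),
                }
            )
            if s["p"] >= screen_p:
                continue
            multi_frame = pd.concat(
                [data, cov_design.reindex(data.index)], axis=1
            ).dropna()
            X = multi_frame.drop(columns=["time", "event"])
            keep = [c for c in X.columns if X[c].nunique() > 1]
            X = X[keep]
            if "feature" not in X.columns:
                continue
            if np.linalg.matrix_rank(X.to_numpy(float)) < X.shape[1]:
                warnings.warn(
                    f"{feat}: covariate design rank deficient; dropping "
                    "collinear columns",
                    stacklevel=2,
                )
                q, r = np.linalg.qr(X.to_numpy(float))
                indep = np.abs(np.diag(r)) > 1e-10
                X = X.loc[:, X.columns[: len(indep)][indep]]
                if "feature" not in X.columns:
                    continue
            multi = _fit_cox(
                pd.concat([multi_frame[["time", "event"]], X], axis=1)
            )
            if multi is None:
                warnings.warn(f"{feat}: multivariable Cox fit failed; skipped")
                continue
            s2 = multi.summary.loc["feature"]
            out.append(
                {
                    "endpoint": endpoint,
                    "feature": feat,
                    "stage": "multivariable",
                    "hazard_ratio": float(s2["exp(coef)"]),
                    "ci_low": float(s2["exp(coef) lower 95%"]),
                    "ci_high": float(s2["exp(coef) upper 95%"]),
                    "p_value": float(s2["p"]),
                    "n": int(len(multi_frame)),
                    "n_events": int(multi_frame["event"].sum()),
                }
            )
    return pd.DataFrame(
        out,
        columns=[
            "endpoint",
            "feature",
            "stage",
            "hazard_ratio",
            "ci_low",
            "ci_high",
            "p_value",
            "n",
            "n_events",
        ],
    )
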
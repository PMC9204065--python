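"""Response-time inconsistency (RTI) as residualized intraindividual SD.

Raw latencies confound trial-to-trial fluctuation with systematic
structure: between-person speed differences, developmental trends across
years, and practice gains across trials within a session.  RTI therefore
uses the *residualized* intraindividual standard deviation (ISD): within
each person x task x year x session cell, latencies are residualized on
the cell mean (absorbing person- and occasion-level speed) and on trial-
level trend terms pooled across cells, and the ISD is the n-1 sample SD
of those residuals.  ISDs are finally put on a T metric (mean 50, SD 10)
relative to a fixed baseline reference distribution per task, so that
change across sessions and years is preserved.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL = ["person_id", "task", "year", "session"]


@dataclass(frozen=True)
class ResidualSpec:
    """Which systematic terms to remove from raw latencies.

    ``regressors`` are residualized by pooled least squares after
    absorbing the per-cell means; the trial index (within-session
    practice) is the named confound and must be present.  Regressors that
    are constant within cells (session, year, baseline age) are already
    absorbed by the cell means and are dropped as collinear with a
    warning.
    """

    regressors: tuple[str, ...] = ("trial",)

    def __post_init__(self) -> None:
        if "trial" not in self.regressors:
            raise ValueError("trial index must be among the regressors")


class TrialResidualizer:
    """Remove per-cell means and pooled trial-level trends, per task.

    fit/transform operate on a screened trial table; ``transform`` returns
    the table with a ``resid`` column carrying only trial-level
    fluctuation.
    """

    def __init__(self, spec: ResidualSpec | None = None):
        self.spec = spec or ResidualSpec()

    def get_params(self, deep: bool = True) -> dict:
        return {"spec": self.spec}

    def set_params(self, **params) -> "TrialResidualizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, trials: pd.DataFrame, y=None) -> "TrialResidualizer":
        self.coef_ = {}
        self.dropped_ = {}
        for task, sub in trials.groupby("task", observed=True):
            demeaned = self._demean(sub)
            X, kept, dropped = self._design(demeaned)
            self.dropped_[task] = dropped
            if dropped:
                warnings.warn(
                    f"{task}: regressors {dropped} constant within cells "
                    "(absorbed by cell means), dropped as collinear")
            if X.shape[1]:
                y_ = demeaned["rt_dm"].to_numpy()
                beta, *_ = np.linalg.lstsq(X, y_, rcond=None)
            else:
                beta = np.zeros(0)
            self.coef_[task] = (kept, beta)
        return self

    def transform(self, trials: pd.DataFrame) -> pd.DataFrame:
        out = []
        for task, sub in trials.groupby("task", observed=True):
            kept, beta = self.coef_[task]
            demeaned = self._demean(sub)
            X, _, _ = self._design(demeaned, kept)
            fitted = X @ beta if X.shape[1] else 0.0
            demeaned["resid"] = demeaned["rt_dm"] - fitted
            out.append(demeaned.drop(columns=["rt_dm"]))
        return pd.concat(out, ignore_index=True)

    def fit_transform(self, trials: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(trials).transform(trials)

    def _demean(self, sub: pd.DataFrame) -> pd.DataFrame:
        sub = sub.copy()
        g = sub.groupby(CELL)
        sub["rt_dm"] = sub["rt_ms"] - g["rt_ms"].transform("mean")
        for reg in self.spec.regressors:
            if reg in sub:
                sub[f"_{reg}_dm"] = sub[reg] - g[reg].transform("mean")
        return sub

    def _design(self, demeaned: pd.DataFrame,
                kept: tuple[str, ...] | None = None):
        cols, dropped = [], []
        cand = kept if kept is not None else self.spec.regressors
        for reg in cand:
            col = f"_{reg}_dm"
            if col not in demeaned:
                dropped.append(reg)
                continue
            v = demeaned[col].to_numpy(float)
            if kept is None and np.allclose(v, 0.0):
                dropped.append(reg)  # constant within every cell
                continue
            cols.append((reg, v))
        X = (np.column_stack([v for _, v in cols])
             if cols else np.empty((len(demeaned), 0)))
        return X, tuple(r for r, _ in cols), dropped


def residualize_trials(trials: pd.DataFrame,
                       spec: ResidualSpec | None = None) -> pd.DataFrame:
    return TrialResidualizer(spec).fit_transform(trials)


def compute_isd(residuals: pd.DataFrame, min_trials: int = 2) -> pd.DataFrame:
    """Sample SD (n-1) of residuals per person x task x year x session.

    Cells with fewer than ``min_trials`` residuals cannot support an SD
    and are omitted (the downstream mixed model treats them as missing
    occasions under MAR).
    """
    g = residuals.groupby(CELL)["resid"]
    isd = g.agg(isd_raw=lambda x: x.std(ddof=1), n_trials="count").reset_index()
    n_bad = int((isd["n_trials"] < min_trials).sum())
    if n_bad:
        warnings.warn(f"{n_bad} cells with <{min_trials} usable trials "
                      "dropped (RTI undefined)")
    return isd.loc[isd["n_trials"] >= min_trials].reset_index(drop=True)


@dataclass
class TStandardizer:
    """Affine map of ISDs to the T metric (mean 50, SD 10) per task.

    The reference distribution is, by default, the pooled Year-1 /
    Session-1 ISDs across persons within each task; one standardizer is
    estimated there and applied to every occasion, so occasion-to-occasion
    change survives the transform.
    """

    target_mean: float = 50.0
    target_sd: float = 10.0
    reference_year: int = 1
    reference_session: int = 1
    per_occasion: bool = False   # literal per-occasion reading (destroys change)
    reference_: dict = field(default_factory=dict, repr=False)

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("target_mean", "target_sd", "reference_year",
                 "reference_session", "per_occasion")}

    def set_params(self, **params) -> "TStandardizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, isd: pd.DataFrame, y=None) -> "TStandardizer":
        self.reference_ = {}
        for task, sub in isd.groupby("task", observed=True):
            ref = sub[(sub["year"] == self.reference_year)
                      & (sub["session"] == self.reference_session)]
            if len(ref) < 2:
                raise ValueError(f"reference cell for {task} is degenerate")
            m = float(ref["isd_raw"].mean())
            s = float(ref["isd_raw"].std(ddof=1))
            if s <= 0:
                raise ValueError(f"reference SD for {task} is zero")
            self.reference_[task] = {"mean": m, "sd": s}
        return self

    def transform(self, isd: pd.DataFrame) -> pd.DataFrame:
        isd = isd.copy()
        if self.per_occasion:
            g = isd.groupby(["task", "year", "session"])["isd_raw"]
            isd["t_score"] = (self.target_mean + self.target_sd
                              * (isd["isd_raw"] - g.transform("mean"))
                              / g.transform(lambda x: x.std(ddof=1)))
            return isd
        parts = []
        for task, sub in isd.groupby("task", observed=True):
            ref = self.reference_[task]
            sub = sub.copy()
            sub["t_score"] = (self.target_mean + self.target_sd
                              * (sub["isd_raw"] - ref["mean"]) / ref["sd"])
            parts.append(sub)
        return pd.concat(parts, ignore_index=True)

    def fit_transform(self, isd: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(isd).transform(isd)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"params": self.get_params(),
                       "reference": self.reference_}, fh, indent=2)


def t_standardize(isd: pd.DataFrame,
                  standardizer: TStandardizer | None = None) -> pd.DataFrame:
    std = standardizer or TStandardizer()
    if not std.reference_ and not std.per_occasion:
        std.fit(isd)
    return std.transform(isd)


def compute_rti(clean_trials: pd.DataFrame,
                spec: ResidualSpec | None = None,
                standardizer: TStandardizer | None = None) -> pd.DataFrame:
    """Screened trials -> RTI table (person, task, year, session,
    isd_raw, t_score)."""
    resid = residualize_trials(clean_trials, spec)
    isd = compute_isd(resid)
    return t_standardize(isd, standardizer)
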
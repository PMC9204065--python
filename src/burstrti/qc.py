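"""Trial-level screening of response-time data.

Screening follows the conservative convention for intraindividual-
variability work: drop missing and incorrect responses, enforce a fixed
150 ms anticipation floor, and trim any trial at or beyond the person's
own mean + 3 SD for that task and measurement occasion.  The one-back
(BRT) task's structurally unanalyzable first trial is removed before any
accounting.  Cell statistics are computed once, before any bound-based
removal (a single non-iterative pass), so repeated screening removes
nothing further.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import BRT

KEY_COLS = ["person_id", "task", "year", "session"]


@dataclass(frozen=True)
class QCRules:
    """Screening thresholds.

    ``scope`` names the grouping within which each person's mean/SD are
    computed for the upper bound; the default is per task and measurement
    occasion (person x task x year x session).
    """

    lower_bound_ms: float = 150.0
    upper_sd_multiplier: float = 3.0
    scope: tuple[str, ...] = ("person_id", "task", "year", "session")
    brt_omit_first: bool = True

    def __post_init__(self) -> None:
        if self.lower_bound_ms <= 0 or self.upper_sd_multiplier <= 0:
            raise ValueError("QC bounds must be positive")


@dataclass
class ExclusionReport:
    """Per-task exclusion accounting against the possible-trial denominator."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add_task(self, task: str, possible: int, missing: int,
                 incorrect: int, outlier: int) -> None:
        usable = possible - missing - incorrect - outlier
        self.counts[task] = {
            "possible": int(possible), "missing": int(missing),
            "incorrect": int(incorrect), "outlier": int(outlier),
            "usable": int(usable),
        }

    def percentages(self, task: str) -> dict[str, float]:
        c = self.counts[task]
        if c["possible"] == 0:
            raise ZeroDivisionError(f"no possible trials for task {task}")
        return {k: 100.0 * c[k] / c["possible"]
                for k in ("missing", "incorrect", "outlier", "usable")}

    def summary(self) -> str:
        lines = []
        for task in sorted(self.counts):
            p = self.percentages(task)
            lines.append(
                f"{task}: {self.counts[task]['possible']} possible trials; "
                f"{p['missing']:.2f}% missing, {p['incorrect']:.2f}% "
                f"incorrect, {p['outlier']:.2f}% outliers trimmed, "
                f"{p['usable']:.2f}% usable")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "percentages": {t: self.percentages(t) for t in self.counts},
            "warnings": list(self.warnings),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def omit_first_brt_trial(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop the structurally unanalyzable first trial of each BRT session."""
    if trials.empty:
        return trials.copy()
    drop = (trials["task"] == BRT) & (trials["trial"] == 1)
    return trials.loc[~drop].copy()


class TrialScreener:
    """Transformer applying the full screening pass.

    ``fit`` computes per-cell intraindividual means/SDs from non-missing,
    correct trials; ``transform`` removes missing, incorrect and
    out-of-bounds trials and records the accounting in ``report_``.
    Exclusions are attributed in the order missing -> incorrect -> bounds.
    """

    def __init__(self, rules: QCRules | None = None):
        self.rules = rules or QCRules()

    def get_params(self, deep: bool = True) -> dict:
        return {"rules": self.rules}

    def set_params(self, **params) -> "TrialScreener":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, trials: pd.DataFrame, y=None) -> "TrialScreener":
        rules = self.rules
        t = omit_first_brt_trial(trials) if rules.brt_omit_first else trials
        ok = (t["missing"] == 0) & (t["correct"] == 1) & t["rt_ms"].notna()
        scope = list(rules.scope)
        stats = (t.loc[ok].groupby(scope)["rt_ms"]
                 .agg(cell_mean="mean", cell_sd=lambda x: x.std(ddof=1),
                      cell_n="count").reset_index())
        self.cell_stats_ = stats
        self.small_cells_ = stats.loc[stats["cell_n"] < 2, scope]
        return self

    def transform(self, trials: pd.DataFrame) -> pd.DataFrame:
        clean, self.report_ = self._screen(trials)
        return clean

    def fit_transform(self, trials: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(trials).transform(trials)

    def _screen(self, trials: pd.DataFrame):
        rules = self.rules
        report = ExclusionReport()
        t = omit_first_brt_trial(trials) if rules.brt_omit_first else trials.copy()
        scope = list(rules.scope)
        t = t.merge(self.cell_stats_, on=scope, how="left")

        missing = (t["missing"] == 1) | t["rt_ms"].isna()
        incorrect = ~missing & (t["correct"] == 0)
        candidate = ~missing & ~incorrect

        sd_ok = t["cell_sd"].notna() & (t["cell_n"] >= 2)
        n_small = int((candidate & ~sd_ok).sum())
        if n_small:
            msg = (f"{n_small} trials in cells with <2 usable trials: "
                   "upper bound undefined, trials retained")
            warnings.warn(msg)
            report.warnings.append(msg)

        low = candidate & (t["rt_ms"] < rules.lower_bound_ms)
        # "exceeds the personal mean by three or more SD" -> >= is excluded
        high = (candidate & sd_ok
                & (t["rt_ms"] - t["cell_mean"]
                   >= rules.upper_sd_multiplier * t["cell_sd"]))
        outlier = low | high

        for task, grp in t.groupby("task", observed=True):
            mask = t["task"] == task
            report.add_task(task, possible=int(mask.sum()),
                            missing=int((missing & mask).sum()),
                            incorrect=int((incorrect & mask).sum()),
                            outlier=int((outlier & mask).sum()))
        clean = t.loc[candidate & ~outlier].drop(
            columns=["cell_mean", "cell_sd", "cell_n"])
        return clean.reset_index(drop=True), report


def screen_trials(trials: pd.DataFrame, rules: QCRules | None = None
                  ) -> tuple[pd.DataFrame, ExclusionReport]:
    """One-call screening: returns (clean trials, exclusion report)."""
    screener = TrialScreener(rules)
    clean = screener.fit_transform(trials)
    return clean, screener.report_


def exclusion_summary(report: ExclusionReport) -> str:
    """Human-readable exclusion percentages (2-decimal formatting)."""
    return report.summary()
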
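"""Cognitive-status classification: HC vs CIND-S vs CIND-M.

A person-year is scored on five cognitive domains (perceptual speed,
verbal fluency, vocabulary, episodic memory, inductive reasoning); each
score is z-standardized against an age-band x education-band normative
cell.  A deficit is a domain falling 1.5 SD or more below the norm; no
deficits -> healthy control (HC), exactly one -> single-domain impairment
(CIND-S), two or more -> multi-domain impairment (CIND-M).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import DOMAINS, age_band, edu_band

LABELS = ("HC", "CIND-S", "CIND-M")


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class StatusRules:
    """Deficit threshold and label boundaries.

    The boundary is inclusive: z exactly at the threshold counts as a
    deficit.
    """

    z_threshold: float = -1.5
    cind_m_min_deficits: int = 2
    use_age_at_year: bool = True   # norm age band at classification year

    def __post_init__(self) -> None:
        if self.z_threshold >= 0:
            raise ValueError("deficit threshold must be negative")

    def label(self, deficit_count: int) -> str:
        if deficit_count == 0:
            return "HC"
        if deficit_count < self.cind_m_min_deficits:
            return "CIND-S"
        return "CIND-M"


def zscore_domains(scores: pd.DataFrame, norms: pd.DataFrame,
                   covariates: pd.DataFrame,
                   rules: StatusRules | None = None) -> pd.DataFrame:
    """z = (score - norm mean) / norm SD per person x year x domain."""
    rules = rules or StatusRules()
    cov = covariates.set_index("person_id")
    df = scores.copy()
    base_age = cov["age_baseline"].reindex(df["person_id"]).to_numpy()
    if np.isnan(base_age).any():
        bad = df.loc[np.isnan(base_age), "person_id"].unique()
        raise ClassificationError(f"persons without covariates: {list(bad)}")
    age = base_age + (df["year"] - 1) if rules.use_age_at_year else base_age
    df["age_band"] = [age_band(a) for a in np.asarray(age, float)]
    edu = cov["education"].reindex(df["person_id"]).to_numpy()
    df["edu_band"] = [edu_band(e) for e in edu]

    merged = df.merge(norms, on=["age_band", "edu_band", "domain"],
                      how="left")
    if merged["mean"].isna().any():
        bad = merged.loc[merged["mean"].isna(),
                         ["person_id", "age_band", "edu_band", "domain"]]
        raise ClassificationError(
            "unmatched norm cells for: "
            + ", ".join(map(str, bad.itertuples(index=False, name=None))))
    merged["z"] = (merged["score"] - merged["mean"]) / merged["sd"]
    return merged[["person_id", "year", "domain", "score", "z"]]


def classify_status(z_table: pd.DataFrame,
                    rules: StatusRules | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label each person-year; person-years missing any domain are
    returned separately as unclassifiable."""
    rules = rules or StatusRules()
    labels, skipped = [], []
    for (pid, year), sub in z_table.groupby(["person_id", "year"]):
        have = set(sub["domain"])
        if set(DOMAINS) - have or sub["z"].isna().any():
            skipped.append({"person_id": pid, "year": year,
                            "reason": "missing domain score"})
            continue
        deficits = sub.loc[sub["z"] <= rules.z_threshold, "domain"]
        labels.append({
            "person_id": pid, "year": year,
            "label": rules.label(len(deficits)),
            "deficit_count": int(len(deficits)),
            "deficit_domains": ",".join(sorted(deficits)),
        })
    return pd.DataFrame(labels), pd.DataFrame(skipped)


class CognitiveStatusClassifier:
    """Transformer: domain scores -> status labels.

    ``fit`` stores the normative table and covariates; ``transform``
    z-scores and labels each person-year.  Unclassifiable person-years
    (missing domains) are recorded in ``skipped_``.
    """

    def __init__(self, rules: StatusRules | None = None):
        self.rules = rules or StatusRules()

    def get_params(self, deep: bool = True) -> dict:
        return {"rules": self.rules}

    def set_params(self, **params) -> "CognitiveStatusClassifier":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, norms: pd.DataFrame, covariates: pd.DataFrame
            ) -> "CognitiveStatusClassifier":
        need = {"age_band", "edu_band", "domain", "mean", "sd"}
        if need - set(norms.columns):
            raise ClassificationError(f"norm table lacks {need - set(norms.columns)}")
        if (norms["sd"] <= 0).any():
            raise ClassificationError("norm SDs must be positive")
        self.norms_ = norms.copy()
        self.covariates_ = covariates.copy()
        return self

    def transform(self, scores: pd.DataFrame) -> pd.DataFrame:
        z = zscore_domains(scores, self.norms_, self.covariates_, self.rules)
        labels, self.skipped_ = classify_status(z, self.rules)
        return labels
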
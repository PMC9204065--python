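"""Person-specific short-term (retest) and long-term (developmental) slopes.

Each person's slopes combine the population fixed effect with their
empirical-Bayes deviation:

    short_term (per week) = g100 + u10k
    long_term  (per year) = g010 + u01k

Covariate (age/sex) contributions are deliberately excluded: the slopes
are later entered in regressions alongside age and sex, and folding the
covariates in would double-count them.  A configurable scale factor is
applied to the weekly slope (weekly change is numerically tiny, so
rescaling aids the interpretability of odds ratios downstream).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .mlm import ThreeLevelModel


def extract_person_slopes(model: ThreeLevelModel,
                          eb: dict[str, pd.DataFrame] | None = None,
                          scale_factor: float = 1.0) -> pd.DataFrame:
    """PersonSlopes table: person_id, short_term, long_term,
    scale_factor_applied."""
    if eb is None:
        eb = model.random_effects()
    fe = dict(zip(model.gamma_["term"], model.gamma_["estimate"]))
    g100 = fe.get("week", 0.0)
    g010 = fe.get("year", 0.0)
    person = eb["person"]
    all_ids = pd.Index(model.prep_.person_ids, name="person_id")
    person = person.set_index("person_id").reindex(all_ids)
    absent = person["u10"].isna()
    if absent.any():
        warnings.warn(f"{int(absent.sum())} persons absent from EB "
                      "estimates; slopes set to the fixed effects")
        person = person.fillna(0.0)
    out = pd.DataFrame({
        "person_id": all_ids,
        "short_term": (g100 + person["u10"].to_numpy()) * scale_factor,
        "long_term": g010 + person["u01"].to_numpy(),
        "scale_factor_applied": scale_factor,
        "flagged_no_eb": absent.to_numpy().astype(int),
    })
    return out


def slope_correlation(slopes: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation (r, two-tailed p) of short- vs long-term slopes."""
    s = slopes.dropna(subset=["short_term", "long_term"])
    if len(s) < 3:
        raise ValueError("need at least 3 persons with both slopes")
    if s["short_term"].std() == 0 or s["long_term"].std() == 0:
        raise ValueError("zero variance in a slope column")
    r, p = stats.pearsonr(s["short_term"], s["long_term"])
    return float(r), float(p)
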
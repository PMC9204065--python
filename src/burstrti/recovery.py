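"""Parameter-recovery simulation studies.

Each study repeatedly (i) draws a synthetic burst dataset from a known
generating process, (ii) runs the corresponding estimator, and (iii)
summarizes the estimates against the generating value.  These are the
package's calibration experiments: because the real study data cannot be
shared, recovery of the generating quantities under the published design
(304 persons, 4 annual waves of 5/4/4/4 biweekly sessions) is the
operative evidence that the estimators do what they claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import BurstDesign
from .mlm import fit_conditional, fit_unconditional
from .outcomes import MultinomialLogit
from .simulate import GeneratingParams, simulate_rti
from .slopes import slope_correlation


@dataclass
class StudyResult:
    estimates: np.ndarray
    true_value: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.estimates))

    @property
    def mc_se(self) -> float:
        return float(np.std(self.estimates, ddof=1)
                     / np.sqrt(len(self.estimates)))


def _child_seeds(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def unconditional_share_study(var_person: float, var_year: float,
                              var_week: float, n_reps: int = 20,
                              seed: int = 0,
                              design: BurstDesign | None = None
                              ) -> StudyResult:
    """Between-person share (%) of total RTI variance recovered by the
    unconditional three-level fit."""
    design = design or BurstDesign()
    params = GeneratingParams.unconditional(var_person, var_year, var_week)
    true_share = 100.0 * var_person / (var_person + var_year + var_week)
    shares = []
    for rng in _child_seeds(seed, n_reps):
        rti = simulate_rti(design, params, rng)
        decomp, _ = fit_unconditional(rti)
        shares.append(decomp.shares["between_person"])
    return StudyResult(np.array(shares), true_share)


def fixed_effect_recovery_study(params: GeneratingParams, term: str,
                                true_value: float, n_reps: int = 20,
                                seed: int = 0,
                                design: BurstDesign | None = None,
                                collect_ci: bool = False):
    """Recovery of one fixed effect from conditional three-level fits.

    Returns a :class:`StudyResult`; with ``collect_ci`` also returns the
    fraction of 95% Wald intervals covering the generating value.
    """
    design = design or BurstDesign()
    ests, covered = [], []
    for rng in _child_seeds(seed, n_reps):
        rti = simulate_rti(design, params, rng)
        model = fit_conditional(rti)
        row = model.gamma_.set_index("term").loc[term]
        ests.append(float(row["estimate"]))
        covered.append(row["ci_low"] <= true_value <= row["ci_high"])
    res = StudyResult(np.array(ests), true_value)
    if collect_ci:
        return res, float(np.mean(covered))
    return res


def simulate_status_outcome(n: int, or_cind_s: float, or_cind_m: float,
                            rng: np.random.Generator,
                            base_odds: tuple[float, float] = (88 / 136,
                                                              80 / 136)):
    """Three-category status from a multinomial-logit process on one
    standardized slope predictor; age/sex covariates included at null."""
    x = rng.normal(0.0, 1.0, n)
    age = rng.normal(0.0, 5.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    eta = np.column_stack([np.log(base_odds[0]) + np.log(or_cind_s) * x,
                           np.log(base_odds[1]) + np.log(or_cind_m) * x])
    e = np.exp(eta)
    denom = 1.0 + e.sum(axis=1, keepdims=True)
    P = np.column_stack([1.0 / denom[:, 0], e[:, 0] / denom[:, 0],
                         e[:, 1] / denom[:, 0]])
    labels = np.array(["HC", "CIND-S", "CIND-M"])
    y = labels[(rng.random(n)[:, None] > P.cumsum(axis=1)).sum(axis=1)]
    return np.column_stack([x, age, sex]), y


def or_recovery_study(true_or: float = 3.82, n: int = 5000,
                      n_reps: int = 20, seed: int = 0,
                      category: str = "CIND-M",
                      or_cind_s: float = 2.26) -> StudyResult:
    """Per-unit odds-ratio recovery for the multinomial engine.

    Estimates are summarized on the log scale (the scale on which the
    estimator is asymptotically normal) and reported as exp(mean log-OR).
    """
    log_ors = []
    for rng in _child_seeds(seed, n_reps):
        X, y = simulate_status_outcome(n, or_cind_s, true_or, rng)
        model = MultinomialLogit().fit(X, y)
        i = model.categories_.index(category) - 1
        log_ors.append(model.coef_[i, 1])
    res = StudyResult(np.exp(np.array(log_ors)), true_or)
    return res


def slope_correlation_study(rho: float = 0.87, n: int = 10_000,
                            seed: int = 0) -> tuple[float, float]:
    """Pearson r between simulated bivariate-normal slope pairs."""
    import pandas as pd
    rng = np.random.default_rng(seed)
    xy = rng.multivariate_normal([0.0, 0.0],
                                 [[1.0, rho], [rho, 1.0]], size=n)
    slopes = pd.DataFrame({"person_id": np.arange(n),
                           "short_term": xy[:, 0], "long_term": xy[:, 1]})
    return slope_correlation(slopes)
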
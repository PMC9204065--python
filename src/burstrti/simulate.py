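"""Synthetic measurement-burst data with known ground truth.

Emulates a four-year biweekly burst study of older adults (n = 304,
aged 64-92) in which response-time inconsistency (RTI) follows a
three-level process: biweekly sessions (level 1) nested in annual waves
(level 2) nested in persons (level 3).  Every construct the downstream
analysis estimates — fixed retest/developmental slopes, random-effect
covariances, trial screening rates, attrition, cognitive-status group
structure — has an explicit generating counterpart here, so recovery can
be tested against truth.

The latent occasion-level RTI (in T-score units) drives the trial-level
latency dispersion through a configurable linear link; trial latencies
are drawn lognormal (moment-matched) by default, with missing, incorrect
and outlier trials injected at configured rates and flagged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .design import BRT, CRT, BurstDesign

GROUPS = ("HC", "CIND-S", "CIND-M")
DOMAINS = ("speed", "fluency", "vocabulary", "memory", "reasoning")

AGE_CENTER = 74.0


class ParameterError(ValueError):
    """Raised for invalid generating parameters (e.g. non-PSD covariance)."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_psd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T):
        raise ParameterError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh(mat)
    if eig.min() < -1e-10:
        raise ParameterError(f"{name} is not positive semi-definite")
    return mat


def _cov_from_sd_corr(sds, corr) -> np.ndarray:
    sds = np.asarray(sds, float)
    corr = np.asarray(corr, float)
    return corr * np.outer(sds, sds)


@dataclass
class TrialNoiseModel:
    """Linear link from latent occasion RTI (T units) to trial dispersion (ms).

    trial SD (ms) = base_sd_ms + sd_per_t_unit * latent RTI, floored at
    min_sd_ms.  Trial latencies are drawn from ``distribution`` with that
    mean/SD (lognormal draws are moment-matched so the ms-scale mean and
    SD are exact).  A small negative per-trial trend emulates within-
    session trial-level practice, the confound the residualization step
    is designed to remove.
    """

    base_sd_ms: float = 30.0
    sd_per_t_unit: float = 4.0
    min_sd_ms: float = 5.0
    mean_rt_ms: float = 900.0
    person_mean_sd_ms: float = 100.0
    trial_trend_ms: float = -0.3
    distribution: str = "lognormal"  # or "normal"

    def trial_sd(self, latent_t: np.ndarray) -> np.ndarray:
        sd = self.base_sd_ms + self.sd_per_t_unit * np.asarray(latent_t, float)
        return np.maximum(sd, self.min_sd_ms)


@dataclass
class GeneratingParams:
    """Ground-truth parameters of the three-level RTI process for one task.

    Fixed effects are in T-score units; codings match the analysis model
    (week 0-based within year, year 0-based at baseline, age centered at
    74, sex 0 = male / 1 = female).
    """

    # fixed effects (intercept, week, year, age, sex, age x year, sex x year)
    gamma000: float = 7.44
    gamma100: float = -0.02
    gamma010: float = 0.15
    gamma001: float = 0.21
    gamma002: float = -0.24
    gamma011: float = 0.0
    gamma012: float = 0.0
    # random-effect (co)variances
    level3_cov: np.ndarray = field(default_factory=lambda: _cov_from_sd_corr(
        np.sqrt([30.0, 0.40, 0.04]),
        [[1.0, 0.30, 0.20], [0.30, 1.0, 0.39], [0.20, 0.39, 1.0]]))
    level2_vars: tuple[float, float] = (2.5, 0.02)
    level1_var: float = 12.0
    # latent -> trial link and data-quality injection
    trial_noise_model: TrialNoiseModel = field(default_factory=TrialNoiseModel)
    rate_missing: float = 0.0013
    rate_incorrect: float = 0.0143
    rate_outlier: float = 0.0178
    # sample structure
    attrition_hazard: tuple[float, ...] = (0.110, 0.035, 0.045)
    followup_attrition: float = 0.26
    group_mix: tuple[float, float, float] = (136 / 304, 88 / 304, 80 / 304)
    group_rti_shift: tuple[float, float, float] = (0.0, 1.0, 2.5)
    group_year_slope_shift: tuple[float, float, float] = (0.0, 0.10, 0.25)
    # covariate sampling
    age_mean: float = 74.02
    age_sd: float = 5.95
    age_range: tuple[float, float] = (64.0, 92.0)
    prop_female: float = 208 / 304
    edu_mean: float = 15.15
    edu_sd: float = 3.14
    edu_range: tuple[float, float] = (7.0, 24.0)
    # five-domain cognitive scores
    deficit_shift_sd: float = -2.0
    domain_noise_sd: float = 0.5
    mmse_group_means: tuple[float, float, float] = (29.0, 28.7, 28.3)
    mmse_group_sds: tuple[float, float, float] = (1.0, 1.1, 1.5)
    mmse_range: tuple[float, float] = (24.0, 30.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.level3_cov = _check_psd(self.level3_cov, "level3_cov")
        for r in (self.rate_missing, self.rate_incorrect, self.rate_outlier,
                  self.followup_attrition, *self.attrition_hazard):
            if not 0.0 <= r <= 1.0:
                raise ParameterError(f"rate {r} outside [0, 1]")
        if not np.isclose(sum(self.group_mix), 1.0):
            raise ParameterError("group_mix must sum to 1")
        if min(self.level2_vars) < 0 or self.level1_var < 0:
            raise ParameterError("variances must be non-negative")

    @classmethod
    def crt_like(cls, **over) -> "GeneratingParams":
        """Defaults mirror the CRT fixed-effect estimates."""
        return cls(**over)

    @classmethod
    def brt_like(cls, **over) -> "GeneratingParams":
        """One-back task: practice gain across weeks, flat across years,
        stronger age gradient and short/long slope coupling."""
        kw = dict(
            gamma000=7.23, gamma100=-0.06, gamma010=-0.09,
            gamma001=0.34, gamma002=0.25,
            level3_cov=_cov_from_sd_corr(
                np.sqrt([33.0, 0.50, 0.05]),
                [[1.0, 0.30, 0.25], [0.30, 1.0, 0.87], [0.25, 0.87, 1.0]]),
            level2_vars=(3.0, 0.02), level1_var=8.0,
            rate_missing=0.0020, rate_incorrect=0.1046, rate_outlier=0.0242,
            trial_noise_model=TrialNoiseModel(mean_rt_ms=1100.0),
        )
        kw.update(over)
        return cls(**kw)

    @classmethod
    def unconditional(cls, var_person: float, var_year: float,
                      var_week: float, grand_mean: float = 50.0,
                      **over) -> "GeneratingParams":
        """Intercept-only process with the given variance at each level."""
        kw = dict(
            gamma000=grand_mean, gamma100=0.0, gamma010=0.0,
            gamma001=0.0, gamma002=0.0,
            level3_cov=np.diag([var_person, 0.0, 0.0]),
            level2_vars=(var_year, 0.0), level1_var=var_week,
            group_rti_shift=(0.0, 0.0, 0.0),
            group_year_slope_shift=(0.0, 0.0, 0.0),
        )
        kw.update(over)
        return cls(**kw)


@dataclass
class PersonCovariates:
    person_id: int
    age_baseline: float
    sex: int
    education: float
    true_group: str


def sample_covariates(design: BurstDesign, params: GeneratingParams,
                      rng) -> pd.DataFrame:
    """Draw person-level covariates, group labels, MMSE and retention.

    Group counts are the expected counts under ``group_mix`` (largest-
    remainder rounding), then shuffled across persons.  Attrition is MAR:
    dropout is independent of all latent quantities, monotone (once a
    person misses a wave they do not return), with a separate hazard for
    the post-burst follow-up.
    """
    rng = _as_rng(rng)
    n = design.n_persons
    lo, hi = params.age_range
    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), lo, hi)
    sex = (rng.random(n) < params.prop_female).astype(int)
    edu = np.clip(rng.normal(params.edu_mean, params.edu_sd, n),
                  *params.edu_range).round(0)

    counts = np.floor(np.asarray(params.group_mix) * n).astype(int)
    rem = np.asarray(params.group_mix) * n - counts
    for _ in range(n - counts.sum()):
        i = int(np.argmax(rem))
        counts[i] += 1
        rem[i] = -1
    groups = np.repeat(GROUPS, counts)
    rng.shuffle(groups)

    gi = np.array([GROUPS.index(g) for g in groups])
    mmse = np.clip(
        rng.normal(np.asarray(params.mmse_group_means)[gi],
                   np.asarray(params.mmse_group_sds)[gi]),
        *params.mmse_range).round(0)

    # monotone dropout between burst waves, extra hazard before follow-up
    last_year = np.full(n, design.n_years)
    for y, hz in enumerate(params.attrition_hazard[:design.n_years - 1],
                           start=1):
        drops = (rng.random(n) < hz) & (last_year == design.n_years)
        last_year[drops & (last_year > y)] = y
    completed = last_year == design.n_years
    present_y8 = completed & (rng.random(n) >= params.followup_attrition)

    return pd.DataFrame({
        "person_id": np.arange(1, n + 1),
        "age_baseline": age,
        "sex": sex,
        "education": edu,
        "true_group": groups,
        "mmse_baseline": mmse,
        "last_burst_year": last_year,
        "present_year8": present_y8.astype(int),
    })


def _occasion_grid(design: BurstDesign, covariates: pd.DataFrame,
                   apply_attrition: bool = True) -> pd.DataFrame:
    """Long person x year x session grid restricted to retained waves."""
    rows = [(y, s) for y, s in design.session_grid()]
    grid = pd.DataFrame(rows, columns=["year", "session"])
    occ = covariates.merge(grid, how="cross")
    if apply_attrition and "last_burst_year" in covariates:
        occ = occ[occ["year"] <= occ["last_burst_year"]]
    occ = occ.copy()
    occ["week"] = occ["session"] - 1          # 0-based within each year
    occ["year0"] = occ["year"] - 1            # 0-based at baseline
    occ["age_c"] = occ["age_baseline"] - AGE_CENTER
    return occ.reset_index(drop=True)


def simulate_rti(design: BurstDesign, params: GeneratingParams, rng,
                 covariates: pd.DataFrame | None = None,
                 group_effects: bool = False,
                 apply_attrition: bool = False) -> pd.DataFrame:
    """Draw latent occasion-level RTI directly from the three-level model.

    Returns one row per person x year x session with the latent ``t_score``.
    With ``group_effects`` the HC / CIND-S / CIND-M shifts are added on top
    of the covariate structure (used for full-pipeline simulations); without
    them the draw is exactly the analysis model, which is what parameter-
    recovery studies need.
    """
    rng = _as_rng(rng)
    if covariates is None:
        covariates = sample_covariates(design, params, rng)
    occ = _occasion_grid(design, covariates, apply_attrition)

    n = len(covariates)
    u3 = rng.multivariate_normal(np.zeros(3), params.level3_cov, size=n,
                                 method="svd")
    u3 = pd.DataFrame(u3, columns=["u00", "u01", "u10"])
    u3["person_id"] = covariates["person_id"].to_numpy()

    ny = design.n_years
    mu0 = rng.normal(0.0, np.sqrt(params.level2_vars[0]), size=(n, ny))
    mu1 = rng.normal(0.0, np.sqrt(params.level2_vars[1]), size=(n, ny))
    l2 = pd.DataFrame({
        "person_id": np.repeat(covariates["person_id"].to_numpy(), ny),
        "year": np.tile(np.arange(1, ny + 1), n),
        "mu0": mu0.ravel(), "mu1": mu1.ravel(),
    })

    occ = occ.merge(u3, on="person_id").merge(l2, on=["person_id", "year"])
    p = params
    mean = (p.gamma000 + p.gamma100 * occ["week"] + p.gamma010 * occ["year0"]
            + p.gamma001 * occ["age_c"] + p.gamma002 * occ["sex"]
            + p.gamma011 * occ["age_c"] * occ["year0"]
            + p.gamma012 * occ["sex"] * occ["year0"])
    if group_effects:
        gi = occ["true_group"].map({g: i for i, g in enumerate(GROUPS)})
        mean = (mean + np.asarray(p.group_rti_shift)[gi]
                + np.asarray(p.group_year_slope_shift)[gi] * occ["year0"])
    latent = (mean + occ["u00"] + occ["u01"] * occ["year0"]
              + occ["u10"] * occ["week"] + occ["mu0"] + occ["mu1"] * occ["week"]
              + rng.normal(0.0, np.sqrt(p.level1_var), len(occ)))
    occ["t_score"] = latent
    cols = ["person_id", "year", "session", "week", "year0", "age_c", "sex",
            "true_group", "t_score", "u00", "u01", "u10", "mu0", "mu1"]
    return occ[[c for c in cols if c in occ]].copy()


def generate_trials(design: BurstDesign,
                    params: GeneratingParams | Mapping[str, GeneratingParams],
                    rng, covariates: pd.DataFrame | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate trial-level latency tables for both tasks.

    Returns ``(trials, covariates, latent)`` where ``latent`` carries the
    ground-truth occasion-level RTI and trial SD per person x session x
    task.  Trial latencies are drawn around a person-specific mean speed
    with SD given by the latent-to-trial link; missing, incorrect and
    outlier trials are then injected at the configured per-task rates and
    flagged (``missing``, ``correct``, ``injected_outlier``).  BRT sessions
    carry an extra leading trial (trial 1) on which no response is
    possible.
    """
    rng = _as_rng(rng)
    if isinstance(params, GeneratingParams):
        task_params = {t: params for t in design.tasks}
    else:
        task_params = dict(params)
    base = task_params[design.tasks[0]]
    if covariates is None:
        covariates = sample_covariates(design, base, rng)

    trial_frames, latent_frames = [], []
    n = design.n_persons
    for task in design.tasks:
        p = task_params[task]
        occ = simulate_rti(design, p, rng, covariates, group_effects=True,
                           apply_attrition=True)
        nm = p.trial_noise_model
        person_speed = rng.normal(0.0, nm.person_mean_sd_ms, n)
        speed = pd.Series(person_speed,
                          index=covariates["person_id"]).reindex(
                              occ["person_id"]).to_numpy()
        occ = occ.assign(task=task,
                         mean_ms=nm.mean_rt_ms + speed,
                         sd_ms=nm.trial_sd(occ["t_score"].to_numpy()))

        n_tr = design.administered_trials(task)
        ncell = len(occ)
        idx = np.repeat(np.arange(ncell), n_tr)
        trial_no = np.tile(np.arange(1, n_tr + 1), ncell)
        m = occ["mean_ms"].to_numpy()[idx] + nm.trial_trend_ms * (
            trial_no - (n_tr + 1) / 2.0)
        s = occ["sd_ms"].to_numpy()[idx]
        if nm.distribution == "lognormal":
            sig2 = np.log1p((s / m) ** 2)
            mu = np.log(m) - sig2 / 2.0
            rt = rng.lognormal(mu, np.sqrt(sig2))
        elif nm.distribution == "normal":
            rt = rng.normal(m, s)
        else:
            raise ParameterError(f"unknown distribution {nm.distribution!r}")

        miss = rng.random(len(rt)) < p.rate_missing
        incorrect = rng.random(len(rt)) < p.rate_incorrect
        outl = rng.random(len(rt)) < p.rate_outlier
        # injected outliers: mostly implausibly slow, some anticipations
        slow = rng.random(len(rt)) >= 0.2
        rt_out = np.where(slow,
                          m + rng.uniform(5.0, 10.0, len(rt)) * s,
                          rng.uniform(40.0, 140.0, len(rt)))
        rt = np.where(outl & ~miss, rt_out, rt)
        rt = np.where(miss, np.nan, rt)

        tdf = pd.DataFrame({
            "person_id": occ["person_id"].to_numpy()[idx],
            "task": task,
            "year": occ["year"].to_numpy()[idx],
            "session": occ["session"].to_numpy()[idx],
            "trial": trial_no,
            "rt_ms": rt,
            "correct": (~incorrect).astype(int),
            "missing": miss.astype(int),
            "injected_outlier": (outl & ~miss).astype(int),
        })
        if task == BRT:
            first = tdf["trial"] == 1   # structurally unanalyzable
            tdf.loc[first, ["rt_ms"]] = np.nan
            tdf.loc[first, "missing"] = 1
            tdf.loc[first, "correct"] = 0
            tdf.loc[first, "injected_outlier"] = 0
        trial_frames.append(tdf)
        latent_frames.append(occ[["person_id", "task", "year", "session",
                                  "t_score", "mean_ms", "sd_ms"]])

    trials = pd.concat(trial_frames, ignore_index=True)
    latent = pd.concat(latent_frames, ignore_index=True)
    return trials, covariates, latent


# ---------------------------------------------------------------------------
# five-domain cognitive scores and normative table


def make_norm_table() -> pd.DataFrame:
    """Synthetic normative table: age band x education band x domain.

    A deterministic stand-in for external norms (the real normative sample
    is not public): older band scores 4 points lower, higher education 3
    points higher, on a mean-50 / SD-10 scale per domain.
    """
    rows = []
    for ab, a_off in (("65-74", 0.0), ("75+", -4.0)):
        for eb, e_off in (("0-12", 0.0), ("13+", 3.0)):
            for d_i, dom in enumerate(DOMAINS):
                rows.append({
                    "age_band": ab, "edu_band": eb, "domain": dom,
                    "mean": 50.0 + a_off + e_off + 1.5 * d_i,
                    "sd": 10.0,
                })
    return pd.DataFrame(rows)


def age_band(age: float) -> str:
    return "75+" if age >= 75 else "65-74"


def edu_band(years: float) -> str:
    return "13+" if years >= 13 else "0-12"


def generate_domain_scores(design: BurstDesign, params: GeneratingParams,
                           covariates: pd.DataFrame, rng,
                           norms: pd.DataFrame | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per person x assessment year x domain scores plus the norm table.

    HC persons score at their norm-cell mean; CIND-S persons carry one and
    CIND-M two persistent deficit domains shifted by ``deficit_shift_sd``
    norm SDs; all scores get ``domain_noise_sd`` SDs of noise.  Assessment
    years are the burst years plus any later follow-up years; scores are
    generated only for retained person-years.
    """
    rng = _as_rng(rng)
    if norms is None:
        norms = make_norm_table()
    if len(norms) < len(DOMAINS) * 4:
        raise ParameterError("norm table is missing cells")
    years = sorted(set(range(1, design.n_years + 1))
                   | set(design.followup_years))
    n_def = {"HC": 0, "CIND-S": 1, "CIND-M": 2}

    deficit_domains = {}
    for pid, grp in zip(covariates["person_id"], covariates["true_group"]):
        k = n_def[grp]
        deficit_domains[pid] = set(
            rng.choice(len(DOMAINS), size=k, replace=False)) if k else set()

    norm_idx = norms.set_index(["age_band", "edu_band", "domain"])
    rows = []
    for _, person in covariates.iterrows():
        pid = person["person_id"]
        for year in years:
            if year > design.n_years:
                if not person.get("present_year8", 1):
                    continue
            elif year > person.get("last_burst_year", design.n_years):
                continue
            ab = age_band(person["age_baseline"] + (year - 1))
            eb = edu_band(person["education"])
            for d_i, dom in enumerate(DOMAINS):
                try:
                    cell = norm_idx.loc[(ab, eb, dom)]
                except KeyError as exc:
                    raise ParameterError(
                        f"missing norm cell ({ab}, {eb}, {dom})") from exc
                shift = (params.deficit_shift_sd
                         if d_i in deficit_domains[pid] else 0.0)
                score = (cell["mean"] + shift * cell["sd"]
                         + rng.normal(0.0, params.domain_noise_sd * cell["sd"]))
                rows.append({"person_id": pid, "year": year, "domain": dom,
                             "score": score})
    return pd.DataFrame(rows), norms


def generate_dataset(design: BurstDesign | None = None,
                     params: Mapping[str, GeneratingParams] | None = None,
                     seed: int | None = 0) -> dict[str, pd.DataFrame]:
    """Full synthetic study: trials, covariates, latent truth, domain
    scores and norms, with named substreams so each component is
    reproducible in isolation."""
    design = design or BurstDesign()
    if params is None:
        params = {CRT: GeneratingParams.crt_like(),
                  BRT: GeneratingParams.brt_like()}
    ss = np.random.SeedSequence(seed)
    s_cov, s_trials, s_dom = ss.spawn(3)
    base = params[design.tasks[0]]
    covariates = sample_covariates(design, base,
                                   np.random.default_rng(s_cov))
    trials, _, latent = generate_trials(design, params,
                                        np.random.default_rng(s_trials),
                                        covariates)
    scores, norms = generate_domain_scores(design, base, covariates,
                                           np.random.default_rng(s_dom))
    return {"trials": trials, "covariates": covariates, "latent": latent,
            "domain_scores": scores, "norms": norms}
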
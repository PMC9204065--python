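"""Three-level linear mixed model for measurement-burst RTI.

Sessions (level 1, indexed by week within a year) are nested in annual
waves (level 2, indexed by year) nested in persons (level 3).  The
conditional model for a person k, year j, week i is

    RTI_ijk = g000 + g100*week + g010*year + g001*age_c + g002*sex
              [+ g011*age_c*year + g012*sex*year]
              + u00k + u01k*year + u10k*week        (person level)
              + m0jk + m1jk*week                    (person-year level)
              + e_ijk

with (u00k, u01k, u10k) ~ N(0, G3) unstructured, (m0jk, m1jk) diagonal,
e iid N(0, s2).  g100 is the short-term (retest/practice) slope and g010
the long-term (developmental) slope; separating them is the point of the
burst design.

Estimation is full-information maximum likelihood over whatever cells a
person contributes (missing occasions simply absent, MAR).  Fixed
effects are profiled out by GLS, and the variance parameters are
optimized by quasi-Newton on a log-Cholesky scale, so every iterate is a
valid covariance.  Empirical-Bayes (BLUP) random effects are the exact
Gaussian conditional means at the ML estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular

FIXED_TERMS = ("intercept", "week", "year", "age", "sex",
               "age:year", "sex:year")


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class MLMSpec:
    """Model layout and codings.

    week is 0-based at the first session of each year (within-burst
    coding); year is 0-based at baseline; age is centered at 74 and sex
    coded 0 = male / 1 = female upstream.
    """

    outcome: str = "t_score"
    fixed: tuple[str, ...] = ("intercept", "week", "year", "age", "sex")
    random_level3: str = "unstructured"   # unstructured | diagonal | intercept
    random_level2: str = "diagonal"       # diagonal (intercept+week) | intercept
    week_col: str = "week"
    year_col: str = "year0"
    age_col: str = "age_c"
    sex_col: str = "sex"
    person_col: str = "person_id"

    def __post_init__(self) -> None:
        for t in self.fixed:
            if t not in FIXED_TERMS:
                raise ValueError(f"unknown fixed term {t!r}")
        if self.random_level3 not in ("unstructured", "diagonal", "intercept"):
            raise ValueError("bad random_level3")
        if self.random_level2 not in ("diagonal", "intercept"):
            raise ValueError("bad random_level2")

    @classmethod
    def unconditional(cls, outcome: str = "t_score") -> "MLMSpec":
        """Random intercepts only at every level, grand-mean fixed effect."""
        return cls(outcome=outcome, fixed=("intercept",),
                   random_level3="intercept", random_level2="intercept")


@dataclass
class VarianceComponents:
    level3_cov: np.ndarray        # 3x3 for (intercept, year slope, week slope)
    level2_vars: np.ndarray       # (var m0, var m1)
    resid_var: float

    def as_dict(self) -> dict:
        return {"level3_cov": self.level3_cov.tolist(),
                "level2_vars": self.level2_vars.tolist(),
                "resid_var": float(self.resid_var)}


@dataclass
class VarianceDecomposition:
    """Unconditional split of total RTI variance across the three levels."""
    var_between_person: float
    var_within_person_year: float
    var_within_person_week: float

    @property
    def total(self) -> float:
        return (self.var_between_person + self.var_within_person_year
                + self.var_within_person_week)

    @property
    def shares(self) -> dict[str, float]:
        t = self.total
        return {"between_person": 100.0 * self.var_between_person / t,
                "within_person_year": 100.0 * self.var_within_person_year / t,
                "within_person_week": 100.0 * self.var_within_person_week / t}

    def as_dict(self) -> dict:
        return {"components": {
                    "between_person": self.var_between_person,
                    "within_person_year": self.var_within_person_year,
                    "within_person_week": self.var_within_person_week},
                "shares_pct": self.shares}


@dataclass
class MLMFit:
    """Fitted model summary: fixed effects, variance components, fit info."""
    gamma: pd.DataFrame
    varcomp: VarianceComponents
    loglik: float
    converged: bool
    structure_level3: str
    n_obs: int
    n_persons: int
    n_person_years: int
    spec: MLMSpec

    def fixed_effect(self, term: str) -> float:
        return float(self.gamma.set_index("term").loc[term, "estimate"])

    def fixed_se(self, term: str) -> float:
        return float(self.gamma.set_index("term").loc[term, "se"])

    def as_dict(self) -> dict:
        return {"fixed_effects": self.gamma.to_dict(orient="records"),
                "variance_components": self.varcomp.as_dict(),
                "loglik": self.loglik, "converged": self.converged,
                "structure_level3": self.structure_level3,
                "n_obs": self.n_obs, "n_persons": self.n_persons,
                "n_person_years": self.n_person_years}

    def summary(self) -> str:
        lines = [f"Three-level mixed model: {self.n_obs} occasions, "
                 f"{self.n_person_years} person-years, "
                 f"{self.n_persons} persons",
                 f"log-likelihood {self.loglik:.3f}  "
                 f"(converged={self.converged}, "
                 f"level-3 structure={self.structure_level3})",
                 f"{'term':<10}{'beta':>8}  {'95% CI':>16}  {'p':>8}"]
        for _, r in self.gamma.iterrows():
            lines.append(f"{r['term']:<10}{r['estimate']:>8.3f}  "
                         f"[{r['ci_low']:>6.3f}, {r['ci_high']:>6.3f}]  "
                         f"{r['p']:>8.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# internal data layout: persons grouped by identical (year, week) pattern


class _PreparedData:
    def __init__(self, data: pd.DataFrame, spec: MLMSpec):
        need = [spec.person_col, spec.outcome, spec.week_col, spec.year_col]
        if any(t in spec.fixed for t in ("age", "sex", "age:year", "sex:year")):
            need += [spec.age_col, spec.sex_col]
        missing = [c for c in need if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks required columns {missing}")
        df = data[list(dict.fromkeys(need))].dropna(subset=[spec.outcome])
        df = df.sort_values([spec.person_col, spec.year_col, spec.week_col])

        self.spec = spec
        self.groups = []      # per pattern: dict of arrays
        self.n_obs = 0
        self.person_ids = []
        self.n_person_years = 0

        pat_map: dict[tuple, list] = {}
        for pid, sub in df.groupby(spec.person_col, sort=True):
            yr = sub[spec.year_col].to_numpy(float)
            wk = sub[spec.week_col].to_numpy(float)
            key = tuple(zip(yr, wk))
            rec = {
                "pid": pid,
                "y": sub[spec.outcome].to_numpy(float),
                "age": float(sub[spec.age_col].iloc[0])
                        if spec.age_col in sub else 0.0,
                "sex": float(sub[spec.sex_col].iloc[0])
                        if spec.sex_col in sub else 0.0,
            }
            pat_map.setdefault(key, []).append(rec)
            self.n_obs += len(yr)
            self.person_ids.append(pid)
            self.n_person_years += len(np.unique(yr))
        self.n_persons = len(self.person_ids)

        for key, recs in pat_map.items():
            yr = np.array([k[0] for k in key])
            wk = np.array([k[1] for k in key])
            m = len(yr)
            age = np.array([r["age"] for r in recs])
            sex = np.array([r["sex"] for r in recs])
            Y = np.stack([r["y"] for r in recs])          # (N, m)
            ones = np.ones(m)
            term_vecs = {"intercept": (ones, None), "week": (wk, None),
                         "year": (yr, None), "age": (ones, age),
                         "sex": (ones, sex), "age:year": (yr, age),
                         "sex:year": (yr, sex)}
            p = len(spec.fixed)
            X = np.empty((len(recs), m, p))
            for j, t in enumerate(spec.fixed):
                tv, sc = term_vecs[t]
                X[:, :, j] = tv[None, :] if sc is None else sc[:, None] * tv
            # level-2 blocks: slices of rows per distinct year
            blocks = []
            for yv in np.unique(yr):
                sel = np.flatnonzero(yr == yv)
                blocks.append(sel)
            self.groups.append({
                "yr": yr, "wk": wk, "m": m, "Y": Y, "X": X,
                "pids": [r["pid"] for r in recs], "age": age, "sex": sex,
                "year_blocks": blocks,
            })
        self.p = len(spec.fixed)


def _pattern_cov(g: dict, vc: VarianceComponents) -> np.ndarray:
    """Marginal covariance of one person's cells for a design pattern."""
    yr, wk, m = g["yr"], g["wk"], g["m"]
    Z3 = np.column_stack([np.ones(m), yr, wk])
    V = Z3 @ vc.level3_cov @ Z3.T
    t0, t1 = vc.level2_vars
    for sel in g["year_blocks"]:
        Z2 = np.column_stack([np.ones(len(sel)), wk[sel]])
        G2 = np.diag([t0, t1])
        V[np.ix_(sel, sel)] += Z2 @ G2 @ Z2.T
    V[np.diag_indices(m)] += vc.resid_var
    return V


def _safe_cho(V: np.ndarray):
    try:
        return cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        warnings.warn("singular marginal covariance: ridge-stabilized")
        return cho_factor(V + 1e-8 * np.trace(V) / len(V) * np.eye(len(V)),
                          lower=True)


def _profiled_nll(vc: VarianceComponents, prep: _PreparedData):
    """Negative profiled log-likelihood; also returns GLS pieces.

    Fixed effects are profiled by least squares on Cholesky-whitened
    blocks rather than by the normal equations, so the GLS solution stays
    accurate even when V is nearly singular (degenerate, noise-free data).
    """
    p = prep.p
    logdet = 0.0
    wx_parts, wy_parts = [], []
    for g in prep.groups:
        V = _pattern_cov(g, vc)
        cf = _safe_cho(V)
        L = np.tril(cf[0])
        m, n_g = g["m"], g["Y"].shape[0]
        logdet += n_g * 2.0 * np.log(np.diag(L)).sum()
        WX = solve_triangular(L, g["X"].transpose(1, 0, 2).reshape(m, -1),
                              lower=True, check_finite=False)
        wx_parts.append(WX.reshape(m, n_g, p).transpose(1, 0, 2)
                        .reshape(n_g * m, p))
        Wy = solve_triangular(L, g["Y"].T, lower=True, check_finite=False)
        wy_parts.append(Wy.T.ravel())
    A = np.concatenate(wx_parts)
    b = np.concatenate(wy_parts)
    gamma, *_ = np.linalg.lstsq(A, b, rcond=None)
    rss = float(((b - A @ gamma) ** 2).sum())
    XtAX = A.T @ A
    ll = -0.5 * (prep.n_obs * np.log(2.0 * np.pi) + logdet + rss)
    return -ll, gamma, XtAX


# parameter vector <-> VarianceComponents

def _n_theta(l3: str, l2: str) -> int:
    return {"unstructured": 6, "diagonal": 3, "intercept": 1}[l3] + \
           {"diagonal": 2, "intercept": 1}[l2] + 1


def _theta_to_vc(theta: np.ndarray, l3: str, l2: str) -> VarianceComponents:
    i = 0
    L = np.zeros((3, 3))
    if l3 == "unstructured":
        L[0, 0] = np.exp(theta[0]); L[1, 0] = theta[1]
        L[1, 1] = np.exp(theta[2]); L[2, 0] = theta[3]
        L[2, 1] = theta[4]; L[2, 2] = np.exp(theta[5])
        i = 6
        G3 = L @ L.T
    elif l3 == "diagonal":
        G3 = np.diag(np.exp(theta[:3]))
        i = 3
    else:
        G3 = np.diag([np.exp(theta[0]), 0.0, 0.0])
        i = 1
    if l2 == "diagonal":
        l2v = np.exp(theta[i:i + 2]); i += 2
    else:
        l2v = np.array([np.exp(theta[i]), 0.0]); i += 1
    return VarianceComponents(G3, l2v, float(np.exp(theta[i])))


def _start_theta(prep: _PreparedData, l3: str, l2: str) -> np.ndarray:
    y = np.concatenate([g["Y"].ravel() for g in prep.groups])
    s2 = max(float(np.var(y)), 1e-3)
    lv0, lvs, lt, le = (np.log(0.5 * s2), np.log(0.01 * s2 + 1e-4),
                        np.log(0.1 * s2), np.log(0.4 * s2))
    if l3 == "unstructured":
        head = [0.5 * lv0, 0.0, 0.5 * lvs, 0.0, 0.0, 0.5 * lvs]
    elif l3 == "diagonal":
        head = [lv0, lvs, lvs]
    else:
        head = [lv0]
    mid = [lt, lvs] if l2 == "diagonal" else [lt]
    return np.array(head + mid + [le])


class ThreeLevelModel:
    """Maximum-likelihood estimator for the three-level burst model.

    sklearn-style: construct with an :class:`MLMSpec`, call ``fit`` on a
    long-format DataFrame (one row per person x year x week), then read
    ``gamma_``, ``varcomp_``, ``loglik_``, ``converged_`` or call
    ``random_effects()`` for the empirical-Bayes person / person-year
    estimates.  On non-convergence the level-3 structure falls back
    unstructured -> diagonal -> intercept-only (recorded in ``result_``).
    """

    def __init__(self, spec: MLMSpec | None = None, maxiter: int = 500):
        self.spec = spec or MLMSpec()
        self.maxiter = maxiter

    def get_params(self, deep: bool = True) -> dict:
        return {"spec": self.spec, "maxiter": self.maxiter}

    def set_params(self, **params) -> "ThreeLevelModel":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- fitting ------------------------------------------------------------

    def fit(self, data: pd.DataFrame, y=None) -> "ThreeLevelModel":
        spec = self.spec
        prep = _PreparedData(data, spec)
        if prep.n_persons < 2:
            raise ValueError("need at least two persons")
        # degenerate designs (e.g. a single wave makes `year` constant):
        # drop constant non-intercept fixed terms so the information
        # matrix stays invertible
        stacked = np.concatenate(
            [g["X"].reshape(-1, prep.p) for g in prep.groups])
        dead = [t for j, t in enumerate(spec.fixed)
                if t != "intercept" and np.ptp(stacked[:, j]) == 0.0]
        if dead:
            warnings.warn(f"fixed terms {dead} are constant in this design; "
                          "dropped")
            spec = replace(spec, fixed=tuple(t for t in spec.fixed
                                             if t not in dead))
            self.spec = spec
            prep = _PreparedData(data, spec)

        ladder = {"unstructured": ["unstructured", "diagonal", "intercept"],
                  "diagonal": ["diagonal", "intercept"],
                  "intercept": ["intercept"]}[spec.random_level3]
        last_err = None
        for l3 in ladder:
            try:
                res, vc, gamma, XtAX = self._optimize(prep, l3,
                                                      spec.random_level2)
            except Exception as exc:   # noqa: BLE001 - fall down the ladder
                last_err = exc
                continue
            if res["converged"]:
                break
        else:
            if last_err is not None:
                raise ConvergenceError(
                    f"no structure converged: {last_err}") from last_err
            warnings.warn("optimizer did not meet tolerance; "
                          "using best point found")

        self.prep_ = prep
        self.varcomp_ = vc
        self.loglik_ = res["loglik"]
        self.converged_ = res["converged"]
        cov = np.linalg.inv(XtAX)
        se = np.sqrt(np.diag(cov))
        z = gamma / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        ci = 1.959963984540054 * se
        self.gamma_ = pd.DataFrame({
            "term": list(spec.fixed), "estimate": gamma, "se": se,
            "ci_low": gamma - ci, "ci_high": gamma + ci, "z": z, "p": pvals,
        })
        self.fixed_cov_ = cov
        self.result_ = MLMFit(
            gamma=self.gamma_, varcomp=vc, loglik=self.loglik_,
            converged=self.converged_, structure_level3=l3,
            n_obs=prep.n_obs, n_persons=prep.n_persons,
            n_person_years=prep.n_person_years, spec=spec)
        return self

    def _optimize(self, prep: _PreparedData, l3: str, l2: str):
        theta0 = _start_theta(prep, l3, l2)

        def nll(theta):
            theta = np.clip(theta, -16.0, 16.0)
            vc = _theta_to_vc(theta, l3, l2)
            val, _, _ = _profiled_nll(vc, prep)
            return val if np.isfinite(val) else 1e12

        bounds = [(-16.0, 16.0)] * len(theta0)
        res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": self.maxiter,
                                         "ftol": 1e-11, "gtol": 1e-6})
        converged = bool(res.success)
        best_x, best_f = res.x, res.fun
        if not converged:
            # quasi-Newton stalled on the numerical gradient: polish
            # derivative-free and accept if the optimum barely moves
            pol = optimize.minimize(nll, best_x, method="Nelder-Mead",
                                    options={"maxiter": 400 * len(theta0),
                                             "xatol": 1e-8, "fatol": 1e-9})
            if pol.fun <= best_f:
                improvement = best_f - pol.fun
                best_x, best_f = pol.x, pol.fun
                converged = bool(pol.success) and improvement < 1e-2
        vc = _theta_to_vc(np.clip(best_x, -16.0, 16.0), l3, l2)
        val, gamma, XtAX = _profiled_nll(vc, prep)
        return ({"loglik": -val, "converged": converged, "opt": res},
                vc, gamma, XtAX)

    # -- empirical Bayes ----------------------------------------------------

    def random_effects(self) -> dict[str, pd.DataFrame]:
        """BLUPs: conditional means of the random effects given the data.

        Returns ``{"person": ..., "person_year": ...}``; the person-year
        frame also carries the derived latent coefficients beta0 (year-
        specific intercept) and beta1 (year-specific week slope).
        """
        vc, spec, prep = self.varcomp_, self.spec, self.prep_
        gamma = self.gamma_["estimate"].to_numpy()
        fe = dict(zip(self.gamma_["term"], gamma))
        rows3, rows2 = [], []
        for g in prep.groups:
            V = _pattern_cov(g, vc)
            c = _safe_cho(V)
            A = cho_solve(c, np.eye(g["m"]))
            yr, wk = g["yr"], g["wk"]
            Z3 = np.column_stack([np.ones(g["m"]), yr, wk])
            W3 = vc.level3_cov @ Z3.T @ A          # (3, m)
            t0, t1 = vc.level2_vars
            G2 = np.diag([t0, t1])
            for n, pid in enumerate(g["pids"]):
                r = g["Y"][n] - g["X"][n] @ gamma
                Ar = A @ r
                u = W3 @ r
                rows3.append({"person_id": pid, "u00": u[0], "u01": u[1],
                              "u10": u[2]})
                age, sex = g["age"][n], g["sex"][n]
                for sel in g["year_blocks"]:
                    yv = yr[sel[0]]
                    Z2 = np.column_stack([np.ones(len(sel)), wk[sel]])
                    mu = G2 @ (Z2.T @ Ar[sel])
                    beta1 = fe.get("week", 0.0) + u[2] + mu[1]
                    beta0 = (fe.get("intercept", 0.0)
                             + fe.get("age", 0.0) * age
                             + fe.get("sex", 0.0) * sex + u[0]
                             + (fe.get("year", 0.0)
                                + fe.get("age:year", 0.0) * age
                                + fe.get("sex:year", 0.0) * sex + u[1]) * yv
                             + mu[0])
                    rows2.append({"person_id": pid, "year0": yv,
                                  "mu0": mu[0], "mu1": mu[1],
                                  "beta0": beta0, "beta1": beta1})
        return {"person": pd.DataFrame(rows3),
                "person_year": pd.DataFrame(rows2)}


# ---------------------------------------------------------------------------
# module-level functional surface


def marginal_loglik(data: pd.DataFrame, spec: MLMSpec, fixef: np.ndarray,
                    varcomp: VarianceComponents) -> float:
    """Exact Gaussian marginal log-likelihood at given parameter values,
    computed per person block (missing cells simply absent)."""
    prep = _PreparedData(data, spec)
    fixef = np.asarray(fixef, float)
    ll = 0.0
    for g in prep.groups:
        V = _pattern_cov(g, varcomp)
        c = _safe_cho(V)
        logdet = 2.0 * np.log(np.diag(c[0])).sum()
        R = g["Y"] - np.einsum("nmp,p->nm", g["X"], fixef)
        for n in range(R.shape[0]):
            r = R[n]
            ll += -0.5 * (g["m"] * np.log(2 * np.pi) + logdet
                          + r @ cho_solve(c, r))
    return float(ll)


def prepare_rti_data(rti: pd.DataFrame, covariates: pd.DataFrame | None = None,
                     task: str | None = None,
                     age_center: float = 74.0) -> pd.DataFrame:
    """Merge an RTI table with person covariates and add model codings."""
    df = rti.copy()
    if task is not None:
        df = df[df["task"] == task].copy()
    if covariates is not None:
        keep = [c for c in ("person_id", "age_baseline", "sex") if
                c in covariates.columns]
        df = df.merge(covariates[keep], on="person_id", how="left")
    if "week" not in df:
        df["week"] = df["session"] - 1
    if "year0" not in df:
        df["year0"] = df["year"] - 1
    if "age_c" not in df and "age_baseline" in df:
        df["age_c"] = df["age_baseline"] - age_center
    return df


def fit_unconditional(rti: pd.DataFrame, outcome: str = "t_score"
                      ) -> tuple[VarianceDecomposition, MLMFit]:
    """Random-intercepts-only decomposition of total variability."""
    spec = MLMSpec.unconditional(outcome)
    model = ThreeLevelModel(spec).fit(rti)
    vc = model.varcomp_
    decomp = VarianceDecomposition(
        var_between_person=float(vc.level3_cov[0, 0]),
        var_within_person_year=float(vc.level2_vars[0]),
        var_within_person_week=float(vc.resid_var))
    return decomp, model.result_


def fit_conditional(rti: pd.DataFrame, covariates: pd.DataFrame | None = None,
                    spec: MLMSpec | None = None, task: str | None = None
                    ) -> ThreeLevelModel:
    """Fit the conditional three-level model; returns the fitted estimator."""
    data = prepare_rti_data(rti, covariates, task) \
        if (covariates is not None or task is not None or
            "year0" not in rti.columns) else rti
    return ThreeLevelModel(spec or MLMSpec()).fit(data)


def extract_random_effects(model: ThreeLevelModel) -> dict[str, pd.DataFrame]:
    return model.random_effects()
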
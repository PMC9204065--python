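"""Multinomial logistic prediction of cognitive status from change slopes.

Each model regresses Year-4 or Year-8 status (HC as the referent
category) on a single slope predictor plus baseline age (centered at 74)
and sex, one predictor per model to avoid collinearity between the
short- and long-term slopes.  Estimation is Newton-Raphson maximum
likelihood; odds ratios carry Wald 95% confidence intervals.  A
baseline-MMSE comparison model swaps the slope for the person's baseline
MMSE score and reports a likelihood-ratio test of its contribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

LABELS = ("HC", "CIND-S", "CIND-M")


class SeparationError(RuntimeError):
    """Perfect or quasi-separation: coefficients diverge."""


class DegenerateDesignError(ValueError):
    pass


class MultinomialLogit:
    """Newton-Raphson multinomial logistic regression with a fixed referent.

    sklearn-style: ``fit(X, y)`` with X an (n, p) array (no intercept
    column; one is added) and y string labels.  ``categories_`` lists the
    referent first; ``coef_`` has shape (K-1, p+1).
    """

    def __init__(self, referent: str = "HC", tol: float = 1e-10,
                 max_iter: int = 100, max_coef: float = 30.0):
        self.referent = referent
        self.tol = tol
        self.max_iter = max_iter
        self.max_coef = max_coef

    def get_params(self, deep: bool = True) -> dict:
        return {"referent": self.referent, "tol": self.tol,
                "max_iter": self.max_iter, "max_coef": self.max_coef}

    def set_params(self, **params) -> "MultinomialLogit":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "MultinomialLogit":
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        if not np.isfinite(X).all():
            raise DegenerateDesignError("non-finite predictor values")
        if X.shape[0] == 0:
            raise DegenerateDesignError("empty design")
        for j in range(X.shape[1]):
            if np.ptp(X[:, j]) == 0.0:
                raise DegenerateDesignError(
                    f"predictor column {j} has zero variance")
        y = np.asarray(y)
        cats = [c for c in LABELS if c in set(y)]
        cats += sorted(set(y) - set(cats))
        if self.referent not in cats:
            raise DegenerateDesignError(
                f"referent {self.referent!r} absent from outcome")
        if len(cats) < 3:
            warnings.warn("an outcome category is empty: "
                          "reduced to a binary logit")
        if len(cats) < 2:
            raise DegenerateDesignError("outcome has a single category")
        cats = [self.referent] + [c for c in cats if c != self.referent]
        self.categories_ = tuple(cats)
        K = len(cats)
        n, p = X.shape
        # center predictors for Newton stability; intercept unshifted below
        x_mean = X.mean(axis=0)
        x_scale = np.maximum(X.std(axis=0), 1e-12)
        Xd = np.column_stack([np.ones(n), X - x_mean])
        q = p + 1
        Yind = np.stack([(y == c).astype(float) for c in cats[1:]], axis=1)

        beta = np.zeros((K - 1, q))
        for it in range(self.max_iter):
            eta = Xd @ beta.T                     # (n, K-1)
            eta = np.clip(eta, -500, 500)
            expeta = np.exp(eta)
            denom = 1.0 + expeta.sum(axis=1, keepdims=True)
            P = expeta / denom                    # (n, K-1)
            grad = np.concatenate([
                Xd.T @ (Yind[:, c] - P[:, c]) for c in range(K - 1)])
            H = np.zeros(((K - 1) * q, (K - 1) * q))
            for c in range(K - 1):
                for d in range(K - 1):
                    w = P[:, c] * ((1.0 if c == d else 0.0) - P[:, d])
                    H[c * q:(c + 1) * q, d * q:(d + 1) * q] = \
                        -(Xd * w[:, None]).T @ Xd
            try:
                step = np.linalg.solve(H, -grad)
            except np.linalg.LinAlgError as exc:
                raise SeparationError(
                    "singular Hessian (separation or collinearity)") from exc
            beta = beta + step.reshape(K - 1, q)
            # divergence check on standardized slopes (intercept exempt)
            if (np.abs(beta[:, 1:]) * x_scale).max() > self.max_coef:
                raise SeparationError(
                    f"coefficients diverging (standardized |beta| > "
                    f"{self.max_coef}): likely perfect separation")
            if np.abs(step).max() < self.tol:
                break
        else:
            warnings.warn("Newton-Raphson hit max_iter without tolerance")

        # undo the centering: b0_orig = b0 - sum_j b_j * mean_j
        T = np.eye(q)
        T[0, 1:] = -x_mean
        eta = np.clip(Xd @ beta.T, -500, 500)
        denom = 1.0 + np.exp(eta).sum(axis=1)
        ll = float(np.sum(eta * Yind) - np.log(denom).sum())
        self.coef_ = beta @ T.T
        self.hessian_ = H
        TK = np.kron(np.eye(K - 1), T)
        cov = TK @ np.linalg.inv(-H) @ TK.T
        self.coef_cov_ = cov
        self.coef_se_ = np.sqrt(np.diag(cov)).reshape(K - 1, q)
        self.loglik_ = ll
        self.n_ = n
        self.n_per_category_ = {c: int((y == c).sum()) for c in cats}
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        Xd = np.column_stack([np.ones(len(X)), X])
        eta = np.clip(Xd @ self.coef_.T, -500, 500)
        expeta = np.exp(eta)
        denom = 1.0 + expeta.sum(axis=1, keepdims=True)
        return np.column_stack([1.0 / denom, expeta / denom])

    def predict(self, X) -> np.ndarray:
        P = self.predict_proba(X)
        return np.asarray(self.categories_)[P.argmax(axis=1)]


@dataclass
class MultinomResult:
    """Wald summary per non-referent category for one fitted model."""
    predictor: str
    table: pd.DataFrame          # category, term, coef, se, or_, ci, p
    loglik: float
    n_per_category: dict[str, int]
    outcome_year: int | None = None
    lr_stat: float | None = None
    lr_p: float | None = None
    model: MultinomialLogit | None = field(default=None, repr=False)

    def odds_ratio(self, category: str, term: str | None = None) -> float:
        t = self.table
        term = term or self.predictor
        row = t[(t["category"] == category) & (t["term"] == term)]
        return float(row["or"].iloc[0])

    def ci(self, category: str, term: str | None = None) -> tuple[float, float]:
        t = self.table
        term = term or self.predictor
        row = t[(t["category"] == category) & (t["term"] == term)]
        return float(row["ci_low"].iloc[0]), float(row["ci_high"].iloc[0])


def _summarize(model: MultinomialLogit, terms: list[str],
               predictor: str, outcome_year=None) -> MultinomResult:
    rows = []
    zcrit = 1.959963984540054
    for c_i, cat in enumerate(model.categories_[1:]):
        for t_i, term in enumerate(["intercept"] + terms):
            b = model.coef_[c_i, t_i]
            se = model.coef_se_[c_i, t_i]
            rows.append({
                "category": cat, "term": term, "coef": b, "se": se,
                "or": np.exp(b),
                "ci_low": np.exp(b - zcrit * se),
                "ci_high": np.exp(b + zcrit * se),
                "p": 2.0 * stats.norm.sf(abs(b / se)),
            })
    return MultinomResult(predictor=predictor, table=pd.DataFrame(rows),
                          loglik=model.loglik_,
                          n_per_category=model.n_per_category_,
                          outcome_year=outcome_year, model=model)


def fit_multinomial(status: pd.DataFrame, predictors: pd.DataFrame,
                    predictor: str, outcome_year: int | None = None,
                    covariate_terms: tuple[str, ...] = ("age_c", "sex"),
                    referent: str = "HC") -> MultinomResult:
    """Fit one status model: label ~ predictor + age + sex.

    ``status`` needs person_id, label (and year if ``outcome_year``
    given); ``predictors`` needs person_id, the predictor column and the
    covariate columns.  Persons missing the outcome or any predictor are
    dropped listwise.
    """
    st = status
    if outcome_year is not None:
        st = st[st["year"] == outcome_year]
    cols = [predictor, *covariate_terms]
    df = st.merge(predictors[["person_id", *cols]], on="person_id")
    df = df.dropna(subset=["label", *cols])
    model = MultinomialLogit(referent=referent).fit(
        df[cols].to_numpy(float), df["label"].to_numpy())
    res = _summarize(model, cols, predictor, outcome_year)
    return res


def compare_baseline_predictor(status: pd.DataFrame,
                               predictors: pd.DataFrame,
                               mmse_col: str = "mmse_baseline",
                               outcome_year: int | None = None,
                               covariate_terms: tuple[str, ...] = ("age_c",
                                                                   "sex"),
                               referent: str = "HC") -> MultinomResult:
    """Baseline-MMSE model plus a likelihood-ratio test of MMSE's
    contribution over the covariates-only model."""
    st = status
    if outcome_year is not None:
        st = st[st["year"] == outcome_year]
    cols = [mmse_col, *covariate_terms]
    df = st.merge(predictors[["person_id", *cols]], on="person_id")
    df = df.dropna(subset=["label", *cols])
    y = df["label"].to_numpy()
    full = MultinomialLogit(referent=referent).fit(df[cols].to_numpy(float), y)
    reduced = MultinomialLogit(referent=referent).fit(
        df[list(covariate_terms)].to_numpy(float), y)
    lr = 2.0 * (full.loglik_ - reduced.loglik_)
    dof = len(full.categories_) - 1
    p = float(stats.chi2.sf(max(lr, 0.0), dof))
    res = _summarize(full, cols, mmse_col, outcome_year)
    res.lr_stat = float(lr)
    res.lr_p = p
    return res


def or_percent_increase(or_value: float) -> float:
    """Express an odds ratio as a percent change in odds: (OR - 1) x 100."""
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    return (or_value - 1.0) * 100.0
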
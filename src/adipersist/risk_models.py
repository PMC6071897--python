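"""Logistic odds-ratio models for address-change outcomes.

Binary-outcome logistic regression over categorical patient factors with
declared reference levels, fit by iteratively reweighted least squares
(Newton scoring).  Odds ratios are ``exp(beta)`` with Wald 95% intervals
``exp(beta +/- 1.96 SE)``.  Convergence: change in log-likelihood below 1e-8,
at most 100 iterations; the log-likelihood is monotone non-decreasing across
iterations (a step-halving safeguard enforces this).  Quasi-complete
separation is detected and reported as an error naming the offending term
rather than returning divergent estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

try:  # pragma: no cover
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    from .adi import BaseEstimator  # type: ignore[attr-defined]

Z95 = 1.959963984540054  # standard-normal 97.5% quantile

#: Reference level per factor (the baseline each OR is relative to).
DEFAULT_REFERENCES: dict[str, str] = {
    "adi_quintile": "1",
    "sex": "male",
    "race": "white",
    "ethnicity": "non_hispanic",
    "marital_status": "married",
    "age_band": "<18",
    "residence": "urban",
}

FULL_ADJUSTMENT = ("age_band", "sex", "race", "ethnicity", "marital_status", "residence")


class SeparationError(RuntimeError):
    """Raised when a model term perfectly separates the outcome."""


@dataclass
class LogisticFit:
    """A fitted logistic model on the log-odds scale.

    ``params``/``bse`` are indexed by term name ("intercept" or
    "factor[level]"); ``or_table()`` exposes odds ratios with Wald CIs.
    """

    params: pd.Series
    bse: pd.Series
    loglike: float
    loglike_path: list[float]
    n: int
    converged: bool
    references: dict[str, str] = field(default_factory=dict)

    def or_table(self) -> pd.DataFrame:
        """Odds ratio, 95% CI, and n for every non-intercept term."""
        rows = []
        for term in self.params.index:
            if term == "intercept":
                continue
            factor, _, level = term.partition("[")
            beta = self.params[term]
            se = self.bse[term]
            # a near-empty level can carry a huge SE; its CI is legitimately
            # unbounded above, so let exp overflow to inf silently
            err = np.errstate(over="ignore")
            with err:
                rows.append(
                {
                    "term": factor,
                    "level": level.rstrip("]"),
                    "odds_ratio": float(np.exp(beta)),
                    "ci_low": float(np.exp(beta - Z95 * se)),
                    "ci_high": float(np.exp(beta + Z95 * se)),
                    "n": self.n,
                }
            )
        return pd.DataFrame(rows)


def build_design(
    data: pd.DataFrame,
    factors,
    references: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Dummy-encode categorical *factors* with declared reference levels.

    Returns a design matrix with an ``intercept`` column and one
    ``factor[level]`` indicator per non-reference level, reference levels
    taken from *references* (falling back to :data:`DEFAULT_REFERENCES`, then
    to the lexicographically first observed level).
    """
    refs = {**DEFAULT_REFERENCES, **(references or {})}
    cols = {"intercept": np.ones(len(data))}
    for f in factors:
        levels = sorted(data[f].astype(str).unique())
        ref = refs.get(f, levels[0])
        if str(ref) not in levels:
            ref = levels[0]
        for lev in levels:
            if lev == str(ref):
                continue
            cols[f"{f}[{lev}]"] = (data[f].astype(str) == lev).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=data.index)


def _loglike(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood: y*eta - log(1+exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_design(
    y: np.ndarray,
    X: pd.DataFrame,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
    references: dict[str, str] | None = None,
) -> LogisticFit:
    """IRLS maximum-likelihood fit of P(y=1) = expit(X beta).

    Step-halving keeps the log-likelihood non-decreasing each iteration.
    Raises :class:`SeparationError` naming the worst term when estimates
    diverge (quasi-complete separation) and ``ValueError`` on a single-class
    outcome.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; logistic model is undefined")
    Xm = X.to_numpy(dtype=float)
    n, p = Xm.shape
    beta = np.zeros(p)
    ll = _loglike(y, Xm @ beta)
    path = [ll]
    converged = False
    for _ in range(max_iter):
        eta = Xm @ beta
        mu = expit(eta)
        W = mu * (1 - mu)
        grad = Xm.T @ (y - mu)
        H = (Xm * W[:, None]).T @ Xm
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halve until the likelihood does not decrease
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new = _loglike(y, Xm @ cand)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta = beta + t * step
        path.append(ll_new)
        if np.max(np.abs(beta)) > 30.0:
            worst = X.columns[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"complete or quasi-complete separation detected on term {worst!r}"
            )
        if abs(ll_new - ll) < tol:
            converged = True
            ll = ll_new
            break
        ll = ll_new
    mu = expit(Xm @ beta)
    W = mu * (1 - mu)
    H = (Xm * W[:, None]).T @ Xm
    cov = np.linalg.pinv(H)
    bse = np.sqrt(np.diag(cov))
    return LogisticFit(
        params=pd.Series(beta, index=X.columns),
        bse=pd.Series(bse, index=X.columns),
        loglike=ll,
        loglike_path=path,
        n=n,
        converged=converged,
        references=dict(references or {}),
    )


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    factors,
    references: dict[str, str] | None = None,
    **kw,
) -> LogisticFit:
    """Fit a logistic model of binary column *outcome* on categorical *factors*."""
    X = build_design(data, factors, references)
    return fit_logistic_design(
        data[outcome].to_numpy(dtype=float), X, references=references, **kw
    )


def unadjusted_or_from_counts(a: int, b: int, c: int, d: int):
    """Odds ratio and Wald 95% CI from a 2x2 table.

    Layout: exposed (a events, b non-events) vs reference (c events, d
    non-events); OR = ad/bc.  Zero cells are an error — apply a continuity
    correction explicitly if that is what you want.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0) or np.any(cells != np.floor(cells)):
        raise ValueError("cell counts must be non-negative integers")
    if np.any(cells == 0):
        raise ValueError(
            "zero cell in 2x2 table; consider an explicit continuity correction"
        )
    orr = (a * d) / (b * c)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return float(orr), (float(orr * np.exp(-Z95 * se)), float(orr * np.exp(Z95 * se)))


def adjusted_or_report(
    cohort: pd.DataFrame,
    outcome: str = "changed_address",
    adjustment: tuple[str, ...] | str = "full",
    references: dict[str, str] | None = None,
    stratify_age: bool = False,
) -> pd.DataFrame:
    """Multivariate ORs for ADI quintile (vs quintile 1) with adjustment.

    ``adjustment="full"`` adjusts for age band, sex, race, ethnicity, marital
    status and residence; ``"none"`` fits quintile alone.  With
    ``stratify_age=True`` separate adult (>=18) and pediatric (<18) models are
    fit (age band dropped within strata where degenerate) and a ``stratum``
    column distinguishes them.
    """
    if adjustment == "full":
        adjust = [f for f in FULL_ADJUSTMENT if f in cohort.columns]
    elif adjustment in ("none", ()):  # quintile-only model
        adjust = []
    else:
        adjust = [f for f in adjustment if f in cohort.columns]
    cohort = cohort.copy()
    cohort["adi_quintile"] = cohort["adi_quintile"].astype(str)

    def _fit(df: pd.DataFrame, label: str) -> pd.DataFrame:
        facs = ["adi_quintile"] + [
            f for f in adjust if df[f].astype(str).nunique() > 1
        ]
        fit = fit_logistic(df, outcome, facs, references)
        tab = fit.or_table()
        tab = tab[tab["term"] == "adi_quintile"].copy()
        tab.insert(0, "stratum", label)
        tab["n"] = len(df)
        return tab

    if not stratify_age:
        return _fit(cohort, "all")
    adult = cohort[cohort["age_band"] != "<18"]
    child = cohort[cohort["age_band"] == "<18"]
    return pd.concat(
        [_fit(adult, "adult"), _fit(child, "pediatric")], ignore_index=True
    )


class OddsRatioModel(BaseEstimator):
    """scikit-learn-style categorical logistic odds-ratio model.

    Parameters
    ----------
    factors : sequence of categorical column names.
    references : optional mapping factor -> reference level.

    Fitted attributes: ``fit_`` (the :class:`LogisticFit`), ``or_table_``,
    ``coef_``, ``converged_``.
    """

    def __init__(self, factors=("adi_quintile",), references=None):
        self.factors = factors
        self.references = references

    def fit(self, X: pd.DataFrame, y):
        design = build_design(X, self.factors, self.references)
        self.fit_ = fit_logistic_design(
            np.asarray(y, dtype=float), design, references=self.references
        )
        self.design_columns_ = list(design.columns)
        self.coef_ = self.fit_.params.to_numpy()
        self.or_table_ = self.fit_.or_table()
        self.converged_ = self.fit_.converged
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        design = build_design(X, self.factors, self.references)
        design = design.reindex(columns=self.design_columns_, fill_value=0.0)
        p1 = expit(design.to_numpy(dtype=float) @ self.coef_)
        return np.column_stack([1 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
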
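"""Area deprivation index (ADI) construction for census block groups.

The ADI is a weighted composite of 17 block-group socioeconomic indicators
(education, income, employment, housing quality).  Each indicator carries a
direction flag so that, after standardization, a larger value always means
more deprivation; the index is a weighted sum of the direction-aligned
z-scores, rescaled to ``base_score + scale * sum_j w_j z_j``.  Scores are
grouped into quintiles of the block-group score distribution (quintile 1 =
least deprived fifth), and each block group is classified urban or rural by
where the majority of its population lives.

`ADIScorer` packages the steps as a scikit-learn transformer so it can sit in
a pipeline; the module functions are the underlying primitives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

try:  # pragma: no cover - sklearn is optional at runtime
    from sklearn.base import BaseEstimator, TransformerMixin
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        def get_params(self, deep=True):
            return {k: v for k, v in self.__dict__.items() if not k.endswith("_")}

        def set_params(self, **params):
            for k, v in params.items():
                setattr(self, k, v)
            return self

    class TransformerMixin:  # type: ignore[no-redef]
        def fit_transform(self, X, y=None, **kw):
            return self.fit(X, y, **kw).transform(X)

logger = logging.getLogger(__name__)

#: The 17 census indicators of the Singh-style deprivation index, with a
#: direction flag: +1 if larger raw values mean more deprivation.
DEFAULT_INDICATORS: dict[str, int] = {
    "pct_less_than_9th_grade": +1,
    "pct_no_high_school_diploma": +1,
    "median_family_income": -1,
    "income_disparity": +1,
    "pct_below_poverty": +1,
    "pct_below_150pct_poverty": +1,
    "pct_single_parent_households": +1,
    "median_home_value": -1,
    "median_gross_rent": -1,
    "median_monthly_mortgage": -1,
    "pct_owner_occupied": -1,
    "pct_unemployed": +1,
    "pct_white_collar": -1,
    "pct_no_vehicle": +1,
    "pct_no_telephone": +1,
    "pct_no_plumbing": +1,
    "pct_crowded_housing": +1,
}

ID_COL = "block_group_id"
STRUCTURAL_COLS = (ID_COL, "population", "urban_population", "rural_population")


@dataclass
class AdiWeights:
    """Per-indicator weights plus the affine score transform.

    ``score = base_score + scale * sum_j w_j z_j`` where ``z_j`` are the
    direction-aligned standardized indicators.
    """

    weights: dict[str, float]
    base_score: float = 100.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        vals = np.asarray(list(self.weights.values()), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("ADI weights must be finite")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @classmethod
    def preset(cls, name: str, indicators=None) -> "AdiWeights":
        """Named weight presets.  ``"equal"``: 1/17 on every indicator."""
        names = list(indicators or DEFAULT_INDICATORS)
        if name == "equal":
            w = 1.0 / len(names)
            return cls(weights={n: w for n in names})
        raise KeyError(f"unknown weight preset {name!r}")

    def aligned(self, indicator_names) -> np.ndarray:
        missing = [n for n in indicator_names if n not in self.weights]
        if missing:
            raise KeyError(
                "weights missing for indicators: " + ", ".join(sorted(missing))
            )
        return np.array([self.weights[n] for n in indicator_names], dtype=float)


def _indicator_columns(table: pd.DataFrame, indicators=None) -> list[str]:
    if indicators is not None:
        cols = list(indicators)
    else:
        cols = [c for c in table.columns if c not in STRUCTURAL_COLS]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError("indicator columns absent from table: " + ", ".join(missing))
    return cols


def standardize_indicators(
    table: pd.DataFrame,
    directions: dict[str, int] | None = None,
    *,
    indicators=None,
) -> pd.DataFrame:
    """Z-score each indicator column (sample SD, ddof=1) and align directions.

    After this step a larger standardized value always means more deprivation.
    Constant columns (zero variance) map to all-zero.  Raises on fewer than two
    block groups or on any missing indicator value (naming the block group and
    indicator).
    """
    directions = dict(DEFAULT_INDICATORS if directions is None else directions)
    cols = _indicator_columns(table, indicators)
    if len(table) < 2:
        raise ValueError("insufficient block groups: need >= 2 rows to standardize")
    for c in cols:
        if table[c].isna().any():
            bg = table.loc[table[c].isna(), ID_COL].iloc[0] if ID_COL in table else "?"
            raise ValueError(f"missing indicator value: block group {bg!r}, indicator {c!r}")
    out = table.copy()
    for c in cols:
        x = table[c].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        z = np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd
        out[c] = directions.get(c, +1) * z
    return out


def compute_adi(
    standardized: pd.DataFrame,
    weights: AdiWeights,
    *,
    indicators=None,
) -> pd.Series:
    """Weighted-sum ADI score per block group from standardized indicators."""
    cols = _indicator_columns(standardized, indicators)
    w = weights.aligned(cols)
    z = standardized[cols].to_numpy(dtype=float)
    score = weights.base_score + weights.scale * z @ w
    return pd.Series(score, index=standardized.index, name="adi_score")


def _cut_points(scores: np.ndarray, population: np.ndarray | None) -> np.ndarray:
    """Inverted-CDF 20/40/60/80th percentiles, optionally population-weighted."""
    if population is None:
        return np.percentile(scores, [20, 40, 60, 80], method="inverted_cdf")
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    cw = np.cumsum(population[order].astype(float))
    frac = cw / cw[-1]
    cuts = []
    for k in (0.2, 0.4, 0.6, 0.8):
        idx = int(np.searchsorted(frac, k, side="left"))
        cuts.append(s[min(idx, len(s) - 1)])
    return np.asarray(cuts)


def assign_quintiles(
    scores,
    basis: str = "block_group",
    population=None,
) -> pd.Series:
    """Assign ADI quintiles 1..5 (1 = least deprived) from scores.

    Cut points are the 20/40/60/80th percentiles of the chosen basis
    distribution (``block_group``: unweighted over block groups;
    ``population_weighted``: weighted by block-group population).  A score
    exactly at a cut point falls in the lower quintile.
    """
    s = pd.Series(scores)
    x = s.to_numpy(dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 block groups to form quintiles")
    if basis == "block_group":
        pop = None
    elif basis == "population_weighted":
        if population is None:
            raise ValueError("population_weighted basis requires population counts")
        pop = np.asarray(population, dtype=float)
    else:
        raise ValueError(f"unknown quintile basis {basis!r}")
    if np.unique(x).size == 1:
        warnings.warn("all ADI scores identical; assigning every block group to quintile 1")
        return pd.Series(np.ones(len(x), dtype=int), index=s.index, name="adi_quintile")
    cuts = _cut_points(x, pop)
    q = 1 + (x[:, None] > cuts[None, :]).sum(axis=1)
    return pd.Series(q.astype(int), index=s.index, name="adi_quintile")


def classify_urban_rural(urban_population, rural_population) -> pd.Series:
    """Majority rule: urban iff urban_population >= rural_population.

    Exact ties classify as urban (documented tie-break).  Errors on zero total
    population.
    """
    u = pd.Series(urban_population).to_numpy(dtype=float)
    r = pd.Series(rural_population).to_numpy(dtype=float)
    if np.any(u + r <= 0):
        raise ValueError("block group with zero population cannot be classified")
    return pd.Series(u >= r, name="urban_flag")


class ADIScorer(BaseEstimator, TransformerMixin):
    """Score block groups with an area deprivation index and assign quintiles.

    Parameters
    ----------
    weights : str or AdiWeights, default "equal"
        Named preset or explicit :class:`AdiWeights`.
    basis : {"block_group", "population_weighted"}
        Distribution over which quintile cut points are taken.
    directions : dict, optional
        Indicator -> direction flag; defaults to :data:`DEFAULT_INDICATORS`.

    Fitted attributes
    -----------------
    indicator_names_ : list of indicator columns used
    mean_, sd_ : per-indicator standardization parameters
    cut_points_ : the four quintile cut points on the score scale
    """

    def __init__(self, weights="equal", basis="block_group", directions=None):
        self.weights = weights
        self.basis = basis
        self.directions = directions

    def _resolve_weights(self, names) -> AdiWeights:
        if isinstance(self.weights, AdiWeights):
            return self.weights
        return AdiWeights.preset(self.weights, indicators=names)

    def fit(self, X: pd.DataFrame, y=None):
        names = _indicator_columns(X)
        z = standardize_indicators(X, self.directions, indicators=names)
        w = self._resolve_weights(names)
        self.indicator_names_ = names
        self.mean_ = X[names].mean().to_numpy()
        sd = X[names].std(ddof=1).to_numpy()
        self.sd_ = np.where(sd == 0, 1.0, sd)
        self.weights_ = w
        scores = compute_adi(z, w, indicators=names)
        pop = X["population"].to_numpy() if "population" in X else None
        self.cut_points_ = (
            None
            if np.unique(scores.to_numpy()).size == 1
            else _cut_points(
                scores.to_numpy(dtype=float),
                pop if self.basis == "population_weighted" else None,
            )
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        names = self.indicator_names_
        directions = dict(DEFAULT_INDICATORS if self.directions is None else self.directions)
        z = (X[names].to_numpy(dtype=float) - self.mean_) / self.sd_
        z = z * np.array([directions.get(n, +1) for n in names], dtype=float)
        w = self.weights_.aligned(names)
        score = self.weights_.base_score + self.weights_.scale * z @ w
        if self.cut_points_ is None:
            warnings.warn("degenerate score distribution; all block groups in quintile 1")
            q = np.ones(len(X), dtype=int)
        else:
            q = 1 + (score[:, None] > self.cut_points_[None, :]).sum(axis=1)
        out = pd.DataFrame({ID_COL: X[ID_COL].to_numpy(), "adi_score": score, "adi_quintile": q})
        if {"urban_population", "rural_population"}.issubset(X.columns):
            out["urban_flag"] = classify_urban_rural(
                X["urban_population"], X["rural_population"]
            ).to_numpy()
        return out


def score_block_groups(
    table: pd.DataFrame,
    weights: AdiWeights | str = "equal",
    basis: str = "block_group",
) -> pd.DataFrame:
    """One-shot convenience: fit an :class:`ADIScorer` on *table* and score it."""
    return ADIScorer(weights=weights, basis=basis).fit(table).transform(table)
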
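"""Neighborhood-deprivation persistence statistics.

Movers are patients whose address of record changed between the baseline and
endpoint measurement dates.  Persistence is the tendency of movers to land in
a destination block group of similar deprivation.  Per origin quintile q the
report carries:

* ``A_q`` — 1-year probability of an address-of-record change,
* ``B_q`` — P(destination outside quintile q | change),
* ``D_q`` — P(destination outside the same-or-neighboring set | change),
* composites ``A_q*B_q`` and ``A_q*D_q``, and
* population-weighted headline probabilities across quintiles.

The same-or-neighboring set is +/-1 quintile for origins 2-4; the edge
quintiles count two inward steps instead (origin 1 -> {1,2,3}, origin 5 ->
{3,4,5}), so every origin's "outside" set has exactly two quintiles.

Report tables round half-up to 2 d.p. and headline scalars to the nearest
percent, matching the arithmetic convention of published study tables;
full-precision values are retained alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

QUINTILES = (1, 2, 3, 4, 5)
CATEGORY_FACTORS = (
    "sex",
    "race",
    "ethnicity",
    "marital_status",
    "age_band",
    "adi_quintile",
    "residence",
)


def round_half_up(x, decimals: int = 2):
    """Decimal round-half-up (0.085 -> 0.09), elementwise on arrays."""
    q = Decimal(1).scaleb(-decimals)

    def _one(v):
        if not np.isfinite(v):
            return v
        return float(Decimal(repr(float(v))).quantize(q, rounding=ROUND_HALF_UP))

    arr = np.asarray(x, dtype=float)
    out = np.vectorize(_one)(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def pro_rata_rate(observed_rate: float, window_months: float) -> float:
    """Linearly annualize a rate observed over *window_months* (x 12/w)."""
    if window_months <= 0:
        raise ValueError("window_months must be positive")
    if not 0 <= observed_rate <= 1:
        raise ValueError("observed_rate must be in [0, 1]")
    return observed_rate * 12.0 / window_months


def neighboring_set(q: int) -> frozenset[int]:
    """Same-or-neighboring quintile set for origin *q* (always 3 quintiles)."""
    if q not in QUINTILES:
        raise ValueError(f"quintile must be in 1..5, got {q!r}")
    if q == 1:
        return frozenset({1, 2, 3})
    if q == 5:
        return frozenset({3, 4, 5})
    return frozenset({q - 1, q, q + 1})


def change_rates_by_category(cohort: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Per-level count, cohort share, and observed change probability.

    *cohort* must carry the factor column and a boolean ``changed_address``.
    """
    if factor not in CATEGORY_FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {CATEGORY_FACTORS}")
    if factor not in cohort.columns:
        raise ValueError(f"cohort table lacks column {factor!r}")
    g = cohort.groupby(factor, observed=True)["changed_address"]
    out = g.agg(count="size", movers="sum").reset_index().rename(columns={factor: "level"})
    out.insert(0, "factor", factor)
    out["share"] = out["count"] / out["count"].sum()
    out["observed_change_probability"] = out["movers"] / out["count"]
    return out


def transition_matrix(
    origin_quintile, destination_quintile
) -> tuple[pd.DataFrame, pd.Series]:
    """Empirical mover origin->destination quintile matrix.

    Returns (matrix, counts): *matrix* is 5x5 row-stochastic over quintiles
    1..5; rows with no movers are NaN (undefined) and excluded from
    downstream weighted summaries.  *counts* holds movers per origin.
    """
    o = pd.Series(origin_quintile).astype(int)
    d = pd.Series(destination_quintile).astype(int)
    if len(o) != len(d):
        raise ValueError("origin/destination length mismatch")
    for s in (o, d):
        bad = ~s.isin(QUINTILES)
        if bad.any():
            raise ValueError(f"quintile outside 1..5: {sorted(s[bad].unique())}")
    counts = pd.crosstab(o, d).reindex(index=QUINTILES, columns=QUINTILES, fill_value=0)
    row_tot = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = counts.div(row_tot.replace(0, np.nan), axis=0)
    mat.index.name = "origin_quintile"
    mat.columns.name = "destination_quintile"
    return mat, row_tot.rename("movers")


def persistence_summary(matrix: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-quintile B (leave-quintile) and D (leave-neighborhood-set) given a move."""
    B = pd.Series(index=list(QUINTILES), dtype=float, name="B")
    D = pd.Series(index=list(QUINTILES), dtype=float, name="D")
    for q in QUINTILES:
        row = matrix.loc[q]
        if row.isna().all():
            B[q] = np.nan
            D[q] = np.nan
            continue
        B[q] = 1.0 - row[q]
        D[q] = 1.0 - sum(row[j] for j in neighboring_set(q))
    return B, D


def composite_probabilities(A, B, D) -> tuple[np.ndarray, np.ndarray]:
    """AB_q = A_q*B_q and AD_q = A_q*D_q at full precision."""
    A, B, D = (np.asarray(v, dtype=float) for v in (A, B, D))
    for name, v in (("A", A), ("B", B), ("D", D)):
        if np.nanmin(v) < 0 or np.nanmax(v) > 1:
            raise ValueError(f"{name} values must lie in [0, 1]")
    return A * B, A * D


def population_weighted_probability(shares, values) -> float:
    """Share-weighted mean probability across quintiles.

    Undefined (NaN) entries are dropped and the remaining shares renormalized,
    with a logged warning.  Errors if shares do not sum to 1 (+/-1e-6).
    """
    s = np.asarray(shares, dtype=float)
    v = np.asarray(values, dtype=float)
    if abs(s.sum() - 1.0) > 1e-6:
        raise ValueError(f"quintile shares must sum to 1, got {s.sum():.6f}")
    ok = np.isfinite(v)
    if not ok.all():
        logger.warning(
            "dropping %d undefined quintile value(s) from weighted summary", (~ok).sum()
        )
        s, v = s[ok], v[ok]
        s = s / s.sum()
    return float(np.dot(s, v))


@dataclass
class PersistenceReport:
    """The per-quintile persistence table plus headline weighted scalars.

    Vectors are indexed by origin quintile 1..5.  ``weighted_outside_same``
    and ``weighted_outside_neighboring`` weight the 2-d.p.-rounded composite
    rows by the quintile shares (the published convention); the ``*_exact``
    fields use unrounded composites.
    """

    A: np.ndarray
    B: np.ndarray
    D: np.ndarray
    shares: np.ndarray
    mover_counts: np.ndarray | None = None
    AB: np.ndarray = field(init=False)
    AD: np.ndarray = field(init=False)
    weighted_outside_same: float = field(init=False)
    weighted_outside_neighboring: float = field(init=False)
    weighted_outside_same_exact: float = field(init=False)
    weighted_outside_neighboring_exact: float = field(init=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.shares = np.asarray(self.shares, dtype=float)
        self.AB, self.AD = composite_probabilities(self.A, self.B, self.D)
        self.weighted_outside_same = population_weighted_probability(
            self.shares, round_half_up(self.AB, 2)
        )
        self.weighted_outside_neighboring = population_weighted_probability(
            self.shares, round_half_up(self.AD, 2)
        )
        self.weighted_outside_same_exact = population_weighted_probability(self.shares, self.AB)
        self.weighted_outside_neighboring_exact = population_weighted_probability(
            self.shares, self.AD
        )

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        """Persistence table, rows A/B/AxB/D/AxD by quintile columns."""
        rows = {"A": self.A, "B": self.B, "AxB": self.AB, "D": self.D, "AxD": self.AD}
        df = pd.DataFrame(rows, index=list(QUINTILES)).T
        df.columns = [f"q{q}" for q in QUINTILES]
        df.index.name = "measure"
        return df.map(lambda v: round_half_up(v, 2)) if rounded else df


def compare_composites(A, B, D, printed_AB, printed_AD) -> pd.DataFrame:
    """Check printed composite cells against round-half-up products.

    Returns a long table (measure, quintile, computed, printed, match) used to
    flag cells where a published table disagrees with the rounded product of
    its own inputs.
    """
    AB, AD = composite_probabilities(A, B, D)
    recs = []
    for name, comp, printed in (("AxB", AB, printed_AB), ("AxD", AD, printed_AD)):
        comp_r = round_half_up(comp, 2)
        for i, q in enumerate(QUINTILES):
            recs.append(
                {
                    "measure": name,
                    "quintile": q,
                    "computed": comp_r[i],
                    "printed": float(np.asarray(printed, dtype=float)[i]),
                    "match": bool(np.isclose(comp_r[i], np.asarray(printed, dtype=float)[i])),
                }
            )
    return pd.DataFrame(recs)


class PersistenceAnalyzer:
    """Compute the full persistence report from an analysis cohort.

    The cohort table needs ``changed_address``, ``adi_quintile`` (baseline),
    and for movers ``endpoint_quintile``.  ``A`` defaults to the pro-rata
    annualized per-quintile observed change rates; pass ``A=...`` to supply
    the 1-year probabilities directly (e.g. from an external table).
    """

    def __init__(self, window_months: float = 14.0, A=None):
        self.window_months = window_months
        self.A = A

    def fit(self, cohort: pd.DataFrame):
        rates = change_rates_by_category(cohort, "adi_quintile").set_index("level")
        rates = rates.reindex(list(QUINTILES))
        shares = rates["share"].to_numpy(dtype=float)
        observed = rates["observed_change_probability"].to_numpy(dtype=float)
        movers = cohort[cohort["changed_address"].astype(bool)]
        movers = movers.dropna(subset=["endpoint_quintile"])
        mat, counts = transition_matrix(
            movers["adi_quintile"], movers["endpoint_quintile"]
        )
        B, D = persistence_summary(mat)
        if self.A is not None:
            A = np.asarray(self.A, dtype=float)
        else:
            A = np.array([pro_rata_rate(r, self.window_months) for r in observed])
        self.rates_ = rates.reset_index()
        self.transition_matrix_ = mat
        self.mover_counts_ = counts
        self.report_ = PersistenceReport(
            A=A, B=B.to_numpy(), D=D.to_numpy(), shares=shares,
            mover_counts=counts.to_numpy(),
        )
        return self
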
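"""Published cohort reference values.

Summary statistics from a ~490,000-patient integrated-delivery-system cohort
study of address-of-record change and neighborhood-deprivation persistence
(Utah, 2014-2016 measurement windows).  These printed values serve two roles:

* defaults for the synthetic cohort generator (:mod:`adipersist.synthetic`),
  so that simulated data reproduce the study's marginal structure, and
* inputs to worked examples and consistency checks (the cohort demographics
  table and the per-quintile persistence table are the only quantitative
  record of the source cohort; the underlying patient data are not public).

All probabilities are on the [0, 1] scale as printed (2-3 decimal places).
"""

from __future__ import annotations

import numpy as np

#: Total cohort size after eligibility and exclusions.
COHORT_N = 490_228

#: Observed probability of an address-of-record change over the 14-month window.
OVERALL_CHANGE_RATE = 0.272

#: Length of the observation window between the two address measurement dates.
WINDOW_MONTHS = 14

#: 1-year pro-rata annualization of the overall change rate, as published.
ANNUALIZED_CHANGE_RATE = 0.233

# ---------------------------------------------------------------------------
# Cohort demographics table: per-factor level counts, share of cohort, and
# observed probability of an address-of-record change.
# ---------------------------------------------------------------------------

DEMOGRAPHICS_TABLE: dict[str, dict[str, tuple[int, float, float]]] = {
    # level: (count, pct_total, observed_change_probability)
    "sex": {
        "male": (212_088, 43.3, 0.259),
        "female": (278_130, 56.7, 0.282),
    },
    "race": {
        "white": (453_836, 92.5, 0.267),
        "black": (5_402, 1.1, 0.394),
        "asian": (7_112, 1.5, 0.260),
        "american_indian": (2_770, 0.6, 0.328),
        "hawaiian": (6_337, 1.3, 0.353),
        "other": (13_444, 2.7, 0.316),
        "unknown": (1_327, 0.3, 0.427),
    },
    "ethnicity": {
        "hispanic": (47_085, 9.6, 0.334),
        "non_hispanic": (443_143, 90.4, 0.265),
    },
    "marital_status": {
        "married": (237_439, 48.4, 0.231),
        "single": (196_935, 40.2, 0.310),
        "other": (55_854, 11.4, 0.313),
    },
    "age_band": {
        "<18": (117_531, 24.0, 0.287),
        "18-30": (67_256, 13.7, 0.417),
        "30-50": (120_724, 24.6, 0.310),
        "50-70": (116_218, 23.7, 0.200),
        "70+": (68_499, 14.0, 0.160),
    },
    "adi_quintile": {
        "1": (130_394, 26.6, 0.229),
        "2": (132_016, 26.9, 0.241),
        "3": (91_520, 18.7, 0.282),
        "4": (72_687, 14.8, 0.309),
        "5": (63_611, 13.0, 0.366),
    },
    "residence": {
        "urban": (474_456, 96.8, 0.273),
        "rural": (15_772, 3.2, 0.251),
    },
}

#: Patient counts per ADI quintile (1 = least deprived ... 5 = most deprived).
QUINTILE_COUNTS = np.array([130_394, 132_016, 91_520, 72_687, 63_611])

#: Share of the cohort in each ADI quintile.
QUINTILE_SHARES = np.array([0.266, 0.269, 0.187, 0.148, 0.130])

#: Observed 14-month change-of-address probability per ADI quintile.
QUINTILE_CHANGE_RATES = np.array([0.229, 0.241, 0.282, 0.309, 0.366])

# ---------------------------------------------------------------------------
# Per-quintile persistence table.
#   A  : 1-year probability of an address-of-record change
#   B  : P(destination outside same quintile | change)
#   D  : P(destination outside same-or-neighboring quintile | change)
#   A*B, A*D as printed (products of rounded inputs, rounded to 2 d.p.;
#   the quintile-2 A*B cell is printed as 0.09, inconsistent with
#   round(0.15 * 0.56) = 0.08 -- see persistence.compare_composites).
# ---------------------------------------------------------------------------

PERSISTENCE_A = np.array([0.15, 0.15, 0.17, 0.18, 0.22])
PERSISTENCE_B = np.array([0.45, 0.56, 0.63, 0.66, 0.57])
PERSISTENCE_D = np.array([0.14, 0.22, 0.27, 0.27, 0.20])
PERSISTENCE_AB_PRINTED = np.array([0.07, 0.09, 0.11, 0.12, 0.13])
PERSISTENCE_AD_PRINTED = np.array([0.02, 0.03, 0.05, 0.05, 0.04])

#: Share of movers relocating within their origin ADI quintile.
MOVER_SAME_QUINTILE_SHARE = 0.42

#: Share of movers relocating within the same-or-neighboring quintile set.
MOVER_SAME_OR_NEIGHBORING_SHARE = 0.78

#: Headline population-weighted probabilities (nearest percent, as published):
#: chance a random cohort patient changes address outside their quintile
#: (resp. outside the same-or-neighboring set) within one year.
WEIGHTED_OUTSIDE_SAME = 0.10
WEIGHTED_OUTSIDE_NEIGHBORING = 0.04

#: Adjusted odds ratio, quintile 5 vs quintile 1, change of address of record
#: (adjusted for age, sex, race, ethnicity, marital status, residence).
ADJUSTED_OR_Q5 = 1.75
#: Same contrast within the pediatric (<18) stratum.
PEDIATRIC_OR_Q5 = 2.13


def demographic_marginals(factor: str) -> dict[str, float]:
    """Return level -> cohort share for *factor*, normalized to sum to 1."""
    levels = DEMOGRAPHICS_TABLE[factor]
    total = sum(v[1] for v in levels.values())
    return {k: v[1] / total for k, v in levels.items()}


def change_rate_table(factor: str):
    """Return (levels, counts, shares, probabilities) arrays for *factor*."""
    levels = list(DEMOGRAPHICS_TABLE[factor])
    counts = np.array([DEMOGRAPHICS_TABLE[factor][k][0] for k in levels])
    probs = np.array([DEMOGRAPHICS_TABLE[factor][k][2] for k in levels])
    return levels, counts, counts / counts.sum(), probs
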
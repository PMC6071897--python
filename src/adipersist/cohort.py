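"""Cohort eligibility, exclusions, and address-of-record change detection.

The study design: patients are "active" if they have at least one clinical
encounter in the enrollment-to-baseline window and a second encounter in the
baseline-to-endpoint window; the address of record captured at those
encounters is then compared between the two measurement dates.  Exclusions
remove decedents, Post-Office-Box baseline addresses, and baseline addresses
that could not be geocoded to a census block group.

Addresses of record are free-text registration strings; equality is judged
after a conservative normalization (case, whitespace, light punctuation).
When raw strings are unavailable the geocoded block-group IDs stand in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

#: Fixed exclusion precedence; a patient is logged under the first matching reason.
EXCLUSION_REASONS = ("died", "po_box", "missing_geocode")

AGE_BAND_EDGES = (18, 30, 50, 70)
AGE_BAND_LABELS = ("<18", "18-30", "30-50", "50-70", "70+")

_PO_BOX_RE = re.compile(r"(?:^|\s)(?:P\s?O|POST OFFICE)\s?BOX\s+\d")
_PUNCT_RE = re.compile(r"[.,#]")
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class StudyWindows:
    """The three measurement dates delimiting the two encounter windows.

    ``[enrollment_start, baseline_date]`` is the baseline window (closed);
    ``(baseline_date, endpoint_date]`` is the follow-up window (half-open), so
    an encounter exactly on the baseline date counts only toward baseline.
    """

    enrollment_start: date = date(2014, 1, 1)
    baseline_date: date = date(2015, 8, 31)
    endpoint_date: date = date(2016, 10, 31)

    def __post_init__(self) -> None:
        if not (self.enrollment_start < self.baseline_date < self.endpoint_date):
            raise ValueError("require enrollment_start < baseline_date < endpoint_date")

    @property
    def window_months(self) -> float:
        """Length of the baseline-to-endpoint window in (30.44-day) months."""
        days = (self.endpoint_date - self.baseline_date).days
        return days / 30.44


def age_band(age_years) -> pd.Series:
    """Half-open age bands: <18, [18,30), [30,50), [50,70), 70+."""
    a = pd.Series(age_years)
    if (a < 0).any():
        raise ValueError("negative age")
    bins = [-np.inf, *AGE_BAND_EDGES, np.inf]
    return pd.cut(a, bins=bins, labels=AGE_BAND_LABELS, right=False).astype(str)


def normalize_address(raw: str) -> str:
    """Canonicalize an address string: uppercase, collapse whitespace, strip .,#."""
    if raw is None or not str(raw).strip():
        raise ValueError("missing address")
    s = _PUNCT_RE.sub("", str(raw).upper())
    return _WS_RE.sub(" ", s).strip()


def is_po_box(raw: str) -> bool:
    """True iff the (normalized) address is a Post Office Box."""
    return bool(_PO_BOX_RE.search(normalize_address(raw)))


def detect_address_change(
    baseline_address=None,
    endpoint_address=None,
    baseline_block_group=None,
    endpoint_block_group=None,
) -> bool:
    """True iff the endpoint address of record differs from the baseline one.

    Raw strings are compared after :func:`normalize_address`; when both raw
    strings are absent the geocoded block-group IDs are compared instead.
    Raises if neither representation is available.
    """

    def present(x):
        return x is not None and not (isinstance(x, float) and np.isnan(x)) and str(x).strip() != ""

    if present(baseline_address) and present(endpoint_address):
        return normalize_address(baseline_address) != normalize_address(endpoint_address)
    if present(baseline_block_group) and present(endpoint_block_group):
        return str(baseline_block_group) != str(endpoint_block_group)
    raise ValueError("no comparable address representation on both observations")


def _encounter_lists(patients: pd.DataFrame, encounters: pd.DataFrame | None):
    """Yield per-patient encounter date arrays from either table layout."""
    if encounters is not None:
        enc = encounters.copy()
        enc["encounter_date"] = pd.to_datetime(enc["encounter_date"])
        return enc.groupby("patient_id")["encounter_date"]
    if "encounter_dates" not in patients.columns:
        raise KeyError("need an encounters table or an 'encounter_dates' column")
    long = (
        patients[["patient_id", "encounter_dates"]]
        .assign(encounter_date=lambda d: d["encounter_dates"].str.split(";"))
        .explode("encounter_date")
    )
    long["encounter_date"] = pd.to_datetime(long["encounter_date"].str.strip())
    return long.groupby("patient_id")["encounter_date"]


def select_active_patients(
    patients: pd.DataFrame,
    windows: StudyWindows,
    encounters: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Retain patients with >=1 encounter in each study window.

    The baseline window is the closed interval [enrollment_start,
    baseline_date]; the follow-up window is (baseline_date, endpoint_date].
    """
    if patients["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in patient table")
    start = pd.Timestamp(windows.enrollment_start)
    base = pd.Timestamp(windows.baseline_date)
    end = pd.Timestamp(windows.endpoint_date)
    groups = _encounter_lists(patients, encounters)
    in_first = groups.apply(lambda d: bool(((d >= start) & (d <= base)).any()))
    in_second = groups.apply(lambda d: bool(((d > base) & (d <= end)).any()))
    active = in_first & in_second
    keep = active[active].index
    return patients[patients["patient_id"].isin(keep)].reset_index(drop=True)


def apply_exclusions(patients: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the study exclusions; return (eligible patients, exclusion log).

    Reasons, in precedence order (a patient counts once, under the first that
    applies): ``died`` (deceased during the study period), ``po_box``
    (baseline address of record is a PO Box), ``missing_geocode`` (baseline
    observation lacks a block-group ID).
    """
    df = patients
    died = df.get("deceased_flag", pd.Series(False, index=df.index)).fillna(False).astype(bool)

    def _pobox(row) -> bool:
        addr = row.get("baseline_address")
        if addr is None or (isinstance(addr, float) and np.isnan(addr)) or not str(addr).strip():
            return False
        return is_po_box(addr)

    pobox = df.apply(_pobox, axis=1) if len(df) else pd.Series(dtype=bool)
    bg = df.get("baseline_block_group", pd.Series(np.nan, index=df.index))
    nogeo = bg.isna() | (bg.astype(str).str.strip() == "")

    reason = pd.Series("", index=df.index, dtype=object)
    reason[nogeo] = "missing_geocode"
    reason[pobox] = "po_box"
    reason[died] = "died"

    excluded = reason != ""
    log = (
        reason[excluded]
        .value_counts()
        .reindex(EXCLUSION_REASONS, fill_value=0)
        .rename_axis("reason")
        .reset_index(name="count")
    )
    return df[~excluded].reset_index(drop=True), log


def flag_address_changes(patients: pd.DataFrame) -> pd.Series:
    """Vectorized change detection over a patient table.

    Uses ``baseline_address``/``endpoint_address`` when both are present,
    else the block-group-ID fallback, per :func:`detect_address_change`.
    """
    return patients.apply(
        lambda r: detect_address_change(
            r.get("baseline_address"),
            r.get("endpoint_address"),
            r.get("baseline_block_group"),
            r.get("endpoint_block_group"),
        ),
        axis=1,
    ).rename("changed_address")


class CohortSelector:
    """Fit-style wrapper composing eligibility, exclusions, and change flags.

    After :meth:`fit`, ``cohort_`` holds the analysis cohort with an
    ``age_band`` and ``changed_address`` column, and ``exclusion_log_`` the
    per-reason exclusion counts.
    """

    def __init__(self, windows: StudyWindows | None = None):
        self.windows = windows or StudyWindows()

    def fit(self, patients: pd.DataFrame, encounters: pd.DataFrame | None = None):
        active = select_active_patients(patients, self.windows, encounters)
        eligible, log = apply_exclusions(active)
        cohort = eligible.copy()
        if "age_years" in cohort.columns:
            cohort["age_band"] = age_band(cohort["age_years"]).to_numpy()
        cohort["changed_address"] = flag_address_changes(cohort).to_numpy() if len(cohort) else []
        self.n_input_ = len(patients)
        self.n_active_ = len(active)
        self.cohort_ = cohort
        self.exclusion_log_ = log
        return self
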
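"""Synthetic block groups, patients, mobility, and encounter streams.

The generator emulates the data structure of an integrated-delivery-system
cohort study of address-of-record change:

* block groups carry 17 correlated socioeconomic indicators driven by a
  latent deprivation factor, so the ADI pipeline has real structure to find;
* patients are allocated to ADI quintiles with the study's unequal shares and
  carry independently drawn demographics with the study's marginals;
* at most one true residential move per patient occurs in the observation
  window, with a quintile-dependent move probability and a destination
  kernel concentrated on the same and neighboring quintiles;
* encounters are drawn per study window, and the *observed* address of record
  at each measurement date is the true address at the last encounter on or
  before that date — reproducing the registration-system lag that makes
  late moves unobservable (false negatives, never false positives).

All stages are pure functions of (config, seed); a single root seed is
split into independent per-stage streams.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from . import reference
from .adi import DEFAULT_INDICATORS, score_block_groups
from .cohort import StudyWindows, age_band
from .persistence import QUINTILES, neighboring_set

_STAGES = ("block_groups", "patients", "mobility", "encounters")


def _marginals(factor: str) -> dict[str, float]:
    return reference.demographic_marginals(factor)


@dataclass
class SimConfig:
    """All generator parameters; defaults reproduce the study's marginals.

    ``move_probability_by_quintile`` is over the full observation window
    (``window_months``).  The destination kernel per origin quintile places
    ``destination_same_quintile`` mass on the origin, splits
    ``destination_neighboring_mass`` evenly over the (always two) neighbors in
    the same-or-neighboring set, and the remainder evenly over the two
    outside quintiles.

    ``quintile_log_odds`` switches the mobility model to an explicit
    log-odds-linear parametrization — logit(p) = logit(base_move_probability)
    + quintile_log_odds[q-1] + demographic offsets — used for odds-ratio
    parameter-recovery experiments; ``pediatric_quintile_log_odds`` overrides
    the quintile effects for patients under 18.
    """

    n_block_groups: int = 400
    n_patients: int = 20_000
    seed: int = 0
    quintile_shares: tuple = tuple(map(float, reference.QUINTILE_SHARES))
    move_probability_by_quintile: tuple = tuple(map(float, reference.QUINTILE_CHANGE_RATES))
    destination_same_quintile: tuple = tuple(map(float, 1.0 - reference.PERSISTENCE_B))
    destination_neighboring_mass: tuple = tuple(
        map(float, reference.PERSISTENCE_B - reference.PERSISTENCE_D)
    )
    demographic_effects: dict = field(default_factory=dict)
    quintile_log_odds: tuple | None = None
    pediatric_quintile_log_odds: tuple | None = None
    base_move_probability: float = 0.15
    indicator_loading: float = 1.0
    indicator_noise_sd: float = 0.3
    rural_block_group_share: float = 0.032
    encounters_per_window_mean: float = 2.0
    final_encounter_at_endpoint: bool = True
    followup_dropout_rate: float = 0.0
    deceased_rate: float = 0.0
    po_box_rate: float = 0.0
    missing_geocode_rate: float = 0.0
    multi_move: bool = False
    window_months: float = 14.0
    windows: StudyWindows = field(default_factory=StudyWindows)

    def __post_init__(self) -> None:
        shares = np.asarray(self.quintile_shares, dtype=float)
        if len(shares) != 5 or abs(shares.sum() - 1.0) > 1e-6:
            raise ValueError("quintile_shares: need 5 fractions summing to 1")
        for name in (
            "move_probability_by_quintile",
            "destination_same_quintile",
            "destination_neighboring_mass",
        ):
            v = np.asarray(getattr(self, name), dtype=float)
            if len(v) != 5 or v.min() < 0 or v.max() > 1:
                raise ValueError(f"{name}: need 5 probabilities in [0, 1]")
        same = np.asarray(self.destination_same_quintile, dtype=float)
        neigh = np.asarray(self.destination_neighboring_mass, dtype=float)
        if np.any(same + neigh > 1 + 1e-9):
            raise ValueError(
                "destination_same_quintile + destination_neighboring_mass must be <= 1"
            )
        if self.n_block_groups < 25:
            raise ValueError("n_block_groups: need at least 25")

    def streams(self, seed: int | None = None) -> dict[str, np.random.Generator]:
        """Independent per-stage random generators derived from one root seed."""
        root = np.random.SeedSequence(self.seed if seed is None else seed)
        return dict(zip(_STAGES, map(np.random.default_rng, root.spawn(len(_STAGES)))))

    def to_dict(self) -> dict:
        d = asdict(self)
        w = d.pop("windows")
        d["windows"] = {k: v.isoformat() for k, v in w.items()}
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def simulate_block_groups(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Indicator table for ``n_block_groups`` synthetic census block groups.

    A latent deprivation factor z ~ N(0,1) drives every indicator through
    ``indicator_loading`` (sign-flipped for protective indicators) plus
    independent N(0, indicator_noise_sd) noise; populations are lognormal
    around a realistic block-group size, split urban/rural by a majority draw.
    """
    n = config.n_block_groups
    z = rng.standard_normal(n)
    df = pd.DataFrame({"block_group_id": [f"BG{i:05d}" for i in range(n)]})
    pop = np.maximum(50, rng.lognormal(mean=np.log(1500), sigma=0.4, size=n)).astype(int)
    rural = rng.random(n) < config.rural_block_group_share
    # rural-majority block groups get a 60-95% rural population share
    rural_frac = np.where(rural, rng.uniform(0.6, 0.95, n), rng.uniform(0.0, 0.4, n))
    df["population"] = pop
    df["rural_population"] = np.round(pop * rural_frac).astype(int)
    df["urban_population"] = pop - df["rural_population"]
    for name, direction in DEFAULT_INDICATORS.items():
        noise = rng.standard_normal(n) * config.indicator_noise_sd
        df[name] = direction * (config.indicator_loading * z + noise)
    df.attrs["latent_deprivation"] = z
    return df


def _allocate_quintiles(rng, n, shares) -> np.ndarray:
    return rng.choice(np.arange(1, 6), size=n, p=np.asarray(shares, dtype=float))


def simulate_patients(
    config: SimConfig, block_groups: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Patients with demographics and a home block group.

    *block_groups* must already carry ``adi_quintile`` (score the indicator
    table first).  Patients are allocated across quintiles by
    ``quintile_shares`` and uniformly over block groups within quintile;
    demographics are independent draws from the study's marginal mixes.
    """
    if "adi_quintile" not in block_groups.columns:
        raise ValueError("block groups must be scored and quintiled before patients")
    by_q = {
        q: block_groups.loc[block_groups["adi_quintile"] == q, "block_group_id"].to_numpy()
        for q in QUINTILES
    }
    empty = [q for q, v in by_q.items() if len(v) == 0]
    if empty:
        raise ValueError(f"no block groups available in quintile(s) {empty}")
    n = config.n_patients
    quintile = _allocate_quintiles(rng, n, config.quintile_shares)
    bg = np.array([by_q[q][rng.integers(len(by_q[q]))] for q in quintile])

    def draw(factor):
        m = _marginals(factor)
        return rng.choice(list(m), size=n, p=np.asarray(list(m.values())))

    band = draw("age_band")
    low = {"<18": 0, "18-30": 18, "30-50": 30, "50-70": 50, "70+": 70}
    high = {"<18": 18, "18-30": 30, "30-50": 50, "50-70": 70, "70+": 90}
    age = np.array([rng.integers(low[b], high[b]) for b in band])
    house = rng.integers(100, 9900, size=n)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "sex": draw("sex"),
            "race": draw("race"),
            "ethnicity": draw("ethnicity"),
            "marital_status": draw("marital_status"),
            "age_years": age,
            "deceased_flag": rng.random(n) < config.deceased_rate,
            "home_block_group": bg,
            "home_quintile": quintile,
            "home_address": [f"{h} {b} ST" for h, b in zip(house, bg)],
        }
    )
    return df


def _move_probability(config: SimConfig, patients: pd.DataFrame) -> np.ndarray:
    """Per-patient true move probability over the observation window."""
    q = patients["home_quintile"].to_numpy()
    if config.quintile_log_odds is not None:
        base = np.log(config.base_move_probability / (1 - config.base_move_probability))
        qeff = np.asarray(config.quintile_log_odds, dtype=float)[q - 1]
        if config.pediatric_quintile_log_odds is not None:
            ped = np.asarray(config.pediatric_quintile_log_odds, dtype=float)[q - 1]
            child = (patients["age_years"] < 18).to_numpy()
            qeff = np.where(child, ped, qeff)
        eta = base + qeff
    else:
        p = np.asarray(config.move_probability_by_quintile, dtype=float)[q - 1]
        with np.errstate(divide="ignore"):  # p = 0 or 1 -> eta = -/+inf, expit is exact
            eta = np.log(p / (1 - p))
    for factor, offsets in config.demographic_effects.items():
        lev = patients[factor].astype(str)
        eta = eta + lev.map(lambda v: float(offsets.get(v, 0.0))).to_numpy()
    return expit(eta)


def _destination_kernel(config: SimConfig) -> np.ndarray:
    """5x5 row-stochastic destination-quintile kernel from the config masses."""
    K = np.zeros((5, 5))
    for q in QUINTILES:
        same = config.destination_same_quintile[q - 1]
        neigh = config.destination_neighboring_mass[q - 1]
        outside = 1.0 - same - neigh
        nb = sorted(neighboring_set(q) - {q})
        out = sorted(set(QUINTILES) - neighboring_set(q))
        K[q - 1, q - 1] = same
        for j in nb:
            K[q - 1, j - 1] = neigh / len(nb)
        for j in out:
            K[q - 1, j - 1] = outside / len(out)
    return K


def simulate_mobility(
    config: SimConfig,
    patients: pd.DataFrame,
    block_groups: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """True move history: at most one move per patient in the window.

    Returns one row per patient: ``moved`` flag, ``move_date`` (uniform in the
    baseline-to-endpoint window), destination quintile / block group / address.
    Movers draw a destination quintile from the same/neighboring/outside
    kernel, then a uniform block group within that quintile.
    """
    n = len(patients)
    p_move = _move_probability(config, patients)
    moved = rng.random(n) < p_move
    K = _destination_kernel(config)
    by_q = {
        q: block_groups.loc[block_groups["adi_quintile"] == q, "block_group_id"].to_numpy()
        for q in QUINTILES
    }
    base = pd.Timestamp(config.windows.baseline_date)
    span = (pd.Timestamp(config.windows.endpoint_date) - base).days
    origin = patients["home_quintile"].to_numpy()
    dest_q = np.zeros(n, dtype=int)
    dest_bg = np.array([""] * n, dtype=object)
    dest_addr = np.array([""] * n, dtype=object)
    move_day = np.full(n, -1)
    idx = np.flatnonzero(moved)
    for i in idx:
        q = int(rng.choice(np.arange(1, 6), p=K[origin[i] - 1]))
        cand = by_q[q]
        bg = cand[rng.integers(len(cand))]
        old = patients["home_address"].iat[i]
        addr = old
        while addr == old:
            addr = f"{rng.integers(100, 9900)} {bg} ST"
        dest_q[i] = q
        dest_bg[i] = bg
        dest_addr[i] = addr
        move_day[i] = rng.integers(1, span + 1)
    out = patients[["patient_id", "home_quintile", "home_block_group"]].copy()
    out["moved"] = moved
    out["move_date"] = pd.NaT
    out.loc[moved, "move_date"] = base + pd.to_timedelta(move_day[moved], unit="D")
    out["destination_quintile"] = np.where(moved, dest_q, np.nan)
    out["destination_block_group"] = np.where(moved, dest_bg, None)
    out["destination_address"] = np.where(moved, dest_addr, None)
    return out


def simulate_encounters(
    config: SimConfig,
    patients: pd.DataFrame,
    history: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Encounter dates plus observed baseline/endpoint address observations.

    Every patient draws ``1 + Poisson(mean - 1)`` encounters uniformly in each
    study window (guaranteeing eligibility by construction), except a
    ``followup_dropout_rate`` fraction who lose their follow-up encounters.
    The observed address at each measurement date is the true address at the
    patient's last encounter on or before that date, so a move after the last
    follow-up encounter is invisible (a false negative).  By default
    (``final_encounter_at_endpoint``) each retained patient's last follow-up
    encounter falls on the endpoint measurement date, emulating a study whose
    endpoint addresses are revalidated at measurement time; switch it off to
    expose the registration lag.
    """
    w = config.windows
    start, base, end = (
        pd.Timestamp(w.enrollment_start),
        pd.Timestamp(w.baseline_date),
        pd.Timestamp(w.endpoint_date),
    )
    n = len(patients)
    lam = max(config.encounters_per_window_mean - 1.0, 0.0)
    n1 = 1 + rng.poisson(lam, size=n)
    n2 = 1 + rng.poisson(lam, size=n)
    dropout = rng.random(n) < config.followup_dropout_rate
    n2[dropout] = 0
    d1 = (base - start).days
    d2 = (end - base).days
    rows = []
    last_enc2 = np.full(n, -1)
    for i in range(n):
        pid = patients["patient_id"].iat[i]
        days1 = rng.integers(0, d1 + 1, size=n1[i])
        days2 = rng.integers(1, d2 + 1, size=n2[i]) if n2[i] else np.array([], dtype=int)
        if n2[i]:
            if config.final_encounter_at_endpoint:
                days2[-1] = d2
            last_enc2[i] = days2.max()
        for d in days1:
            rows.append((pid, (start + timedelta(int(d))).date().isoformat()))
        for d in days2:
            rows.append((pid, (base + timedelta(int(d))).date().isoformat()))
    encounters = pd.DataFrame(rows, columns=["patient_id", "encounter_date"])

    moved = history["moved"].to_numpy()
    move_day = np.where(
        moved, (pd.to_datetime(history["move_date"]) - base).dt.days.to_numpy(), np.inf
    )
    observed_moved = moved & (last_enc2 >= move_day)
    missing_geo = rng.random(n) < config.missing_geocode_rate
    po_box = rng.random(n) < config.po_box_rate

    obs = patients[["patient_id"]].copy()
    obs["baseline_address"] = patients["home_address"].to_numpy()
    obs["baseline_block_group"] = patients["home_block_group"].to_numpy()
    obs["baseline_date"] = base.date().isoformat()
    obs["endpoint_address"] = np.where(
        observed_moved, history["destination_address"].to_numpy(), obs["baseline_address"]
    )
    obs["endpoint_block_group"] = np.where(
        observed_moved, history["destination_block_group"].to_numpy(), obs["baseline_block_group"]
    )
    obs["endpoint_date"] = end.date().isoformat()
    obs.loc[po_box, "baseline_address"] = [
        f"PO BOX {rng.integers(1, 9999)}" for _ in range(int(po_box.sum()))
    ]
    obs.loc[missing_geo, "baseline_block_group"] = np.nan
    return encounters, obs


@dataclass
class SimulatedStudy:
    """Bundle of all generated tables for one simulation run."""

    config: SimConfig
    block_groups: pd.DataFrame  # raw indicator table
    scored_block_groups: pd.DataFrame  # ADI scores, quintiles, urban flags
    patients: pd.DataFrame  # demographics + observed address columns
    encounters: pd.DataFrame  # long-format (patient_id, encounter_date)
    true_history: pd.DataFrame  # oracle: true moves and destinations


def simulate_study(config: SimConfig, seed: int | None = None) -> SimulatedStudy:
    """Run all generator stages and assemble the patient-facing tables."""
    streams = config.streams(seed)
    bg = simulate_block_groups(config, streams["block_groups"])
    scored = score_block_groups(bg)
    bg_q = bg.merge(scored[["block_group_id", "adi_quintile"]], on="block_group_id")
    patients = simulate_patients(config, bg_q, streams["patients"])
    history = simulate_mobility(config, patients, bg_q, streams["mobility"])
    encounters, obs = simulate_encounters(config, patients, history, streams["encounters"])
    full = patients.merge(obs, on="patient_id")
    urban = scored.set_index("block_group_id")["urban_flag"]
    full["residence"] = np.where(
        full["home_block_group"].map(urban).fillna(True), "urban", "rural"
    )
    full["age_band"] = age_band(full["age_years"]).to_numpy()
    return SimulatedStudy(
        config=config,
        block_groups=bg,
        scored_block_groups=scored,
        patients=full,
        encounters=encounters,
        true_history=history,
    )


def analysis_cohort(study: SimulatedStudy) -> pd.DataFrame:
    """Attach baseline/endpoint quintiles and the observed change flag.

    This is the generator-side shortcut used by tests and experiments; the
    full pipeline derives the same table through the cohort module.
    """
    q = study.scored_block_groups.set_index("block_group_id")["adi_quintile"]
    df = study.patients.copy()
    df["adi_quintile"] = df["baseline_block_group"].map(q)
    df["endpoint_quintile"] = df["endpoint_block_group"].map(q)
    df["changed_address"] = (
        df["baseline_address"].str.upper().str.strip()
        != df["endpoint_address"].str.upper().str.strip()
    )
    return df


def emit_fixture(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write every table (and the config) as CSV/YAML that the readers accept.

    Patient encounter dates are also embedded in the patient table as a
    semicolon-delimited column so both reader layouts round-trip.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enc_join = (
        study.encounters.sort_values(["patient_id", "encounter_date"])
        .groupby("patient_id")["encounter_date"]
        .agg(";".join)
        .rename("encounter_dates")
    )
    patients = study.patients.merge(enc_join, on="patient_id", how="left")
    paths = {}
    tables = {
        "block_groups.csv": study.block_groups,
        "patients.csv": patients,
        "encounters.csv": study.encounters,
        "true_history.csv": study.true_history,
    }
    for name, df in tables.items():
        p = out / name
        df.to_csv(p, index=False)
        paths[name] = p
    cfg = out / "sim_config.yaml"
    cfg.write_text(yaml.safe_dump(study.config.to_dict(), sort_keys=True))
    paths["sim_config.yaml"] = cfg
    manifest = out / "manifest.json"
    manifest.write_text(
        json.dumps(
            {
                "config_hash": study.config.config_hash(),
                "seed": study.config.seed,
                "n_patients": len(study.patients),
                "n_block_groups": len(study.block_groups),
            },
            indent=2,
        )
        + "\n"
    )
    paths["manifest.json"] = manifest
    return paths
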
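"""End-to-end pipeline: ADI scoring -> cohort -> persistence -> odds ratios.

`run_pipeline` drives the whole analysis from a :class:`RunConfig` and writes
the report bundle: a demographics/change-rate table, the persistence table,
an odds-ratio report, the exclusion log, and a JSON run manifest.  Reruns on
identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .adi import ADIScorer, AdiWeights
from .cohort import CohortSelector, StudyWindows
from .persistence import (
    CATEGORY_FACTORS,
    PersistenceAnalyzer,
    QUINTILES,
    change_rates_by_category,
    compare_composites,
    round_half_up,
)
from .risk_models import adjusted_or_report

logger = logging.getLogger(__name__)

TABLE2_ROW_LABELS = {
    "A": "One-year probability of change in address of record-estimate (A)",
    "B": "Probability of change outside same ADI quintile, given a change in address of record (B)",
    "AxB": "Probability of a change in address of record outside same ADI quintile (AxB)",
    "D": "Probability of change outside same or neighboring ADI quintile, given a change in address of record (D)",
    "AxD": "Probability of change in address of record outside same or neighboring quintile (AxD)",
}
TABLE2_FOOTNOTE = (
    "A neighboring quintile is +/-1 quintile for origins in the middle three "
    "quintiles, or +2 / -2 for origins in the first / fifth quintile, respectively."
)


@dataclass
class RunConfig:
    """Everything a full pipeline run needs."""

    indicators_path: str
    patients_path: str
    out_dir: str
    encounters_path: str | None = None
    weights: str = "equal"  # preset name or path to a weights file
    basis: str = "block_group"
    windows: StudyWindows = field(default_factory=StudyWindows)
    a_row: tuple | None = None  # supplied 1-year A probabilities, else pro-rata
    adjustment: str = "full"
    seed: int = 0

    def resolve_weights(self):
        if isinstance(self.weights, AdiWeights):
            return self.weights
        if self.weights == "equal":
            return "equal"
        return io.read_weights(self.weights)


def render_table2(report, mover_counts=None) -> pd.DataFrame:
    """Format a persistence report as the five-row published-style table.

    Undefined cells render as an em dash.  Returns a DataFrame of strings
    whose CSV form re-parses to the same 2-d.p. numbers.
    """
    frame = report.to_frame(rounded=True)

    def fmt(v):
        return "-" if not np.isfinite(v) else f"{v:.2f}"

    out = frame.map(fmt)
    out.index = [TABLE2_ROW_LABELS[m] for m in frame.index]
    out.index.name = "Deprivation persistence measure"
    return out


def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute adi -> cohort -> persistence -> risk_models; write reports.

    Returns a dict with the in-memory results and output paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for label, p in (("indicators", config.indicators_path), ("patients", config.patients_path)):
        if not Path(p).exists():
            raise FileNotFoundError(f"{label} file not found: {p}")

    logger.info("stage adi: scoring block groups from %s", config.indicators_path)
    indicators = io.read_indicator_table(config.indicators_path)
    scorer = ADIScorer(weights=config.resolve_weights(), basis=config.basis)
    scored = scorer.fit(indicators).transform(indicators)
    io.write_csv(scored, out / "block_groups_scored.csv")

    logger.info("stage cohort: %s", config.patients_path)
    patients = io.read_patient_table(config.patients_path)
    encounters = io.read_encounters(config.encounters_path) if config.encounters_path else None
    selector = CohortSelector(config.windows).fit(patients, encounters)
    cohort = selector.cohort_
    logger.info(
        "cohort: %d input, %d active, %d eligible",
        selector.n_input_, selector.n_active_, len(cohort),
    )
    io.write_csv(selector.exclusion_log_, out / "exclusion_log.csv")

    qmap = scored.set_index("block_group_id")["adi_quintile"]
    urban = scored.set_index("block_group_id")["urban_flag"]
    cohort = cohort.copy()
    cohort["adi_quintile"] = cohort["baseline_block_group"].map(qmap)
    cohort["endpoint_quintile"] = cohort["endpoint_block_group"].map(qmap)
    if "residence" not in cohort.columns:
        cohort["residence"] = np.where(
            cohort["baseline_block_group"].map(urban).fillna(True), "urban", "rural"
        )

    logger.info("stage persistence: %d patients, %d movers",
                len(cohort), int(cohort["changed_address"].sum()))
    table1 = pd.concat(
        [change_rates_by_category(cohort, f) for f in CATEGORY_FACTORS if f in cohort],
        ignore_index=True,
    )
    io.write_csv(table1, out / "table1_change_rates.csv")

    analyzer = PersistenceAnalyzer(
        window_months=config.windows.window_months, A=config.a_row
    ).fit(cohort)
    report = analyzer.report_
    table2 = render_table2(report)
    table2.reset_index().to_csv(out / "table2_persistence.csv", index=False)
    io.write_csv(
        analyzer.transition_matrix_.reset_index(), out / "transition_matrix.csv"
    )

    # Does recomputing the composites from the table's own 2-d.p. rows give
    # back the reported cells?  (Published tables can fail this when their
    # composites were formed from unrounded inputs upstream.)
    flags = compare_composites(
        round_half_up(report.A, 2), round_half_up(report.B, 2), round_half_up(report.D, 2),
        round_half_up(report.AB, 2), round_half_up(report.AD, 2),
    )

    logger.info("stage risk_models: adjusted odds ratios (%s)", config.adjustment)
    or_table = adjusted_or_report(cohort, adjustment=config.adjustment)
    io.write_csv(or_table, out / "odds_ratios.csv")

    manifest = {
        "seed": config.seed,
        "n_input_patients": int(selector.n_input_),
        "n_active": int(selector.n_active_),
        "n_cohort": int(len(cohort)),
        "n_movers": int(cohort["changed_address"].sum()),
        "exclusions": {
            r["reason"]: int(r["count"]) for _, r in selector.exclusion_log_.iterrows()
        },
        "weighted_outside_same": round_half_up(report.weighted_outside_same, 4),
        "weighted_outside_neighboring": round_half_up(report.weighted_outside_neighboring, 4),
        "composite_cells_flagged": int((~flags["match"]).sum()),
        "input_hashes": {
            "indicators": _file_hash(config.indicators_path),
            "patients": _file_hash(config.patients_path),
        },
        "table2_footnote": TABLE2_FOOTNOTE,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "scored_block_groups": scored,
        "cohort": cohort,
        "table1": table1,
        "report": report,
        "table2": table2,
        "transition_matrix": analyzer.transition_matrix_,
        "or_table": or_table,
        "exclusion_log": selector.exclusion_log_,
        "manifest": manifest,
        "out_dir": out,
    }
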
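"""CSV readers and writers for the pipeline's tables.

All interchange is plain CSV with a header row.  Patient encounter dates are
accepted either embedded in the patient table (an ``encounter_dates`` column,
semicolon-delimited ISO dates) or as a separate long-format encounters table
(``patient_id, encounter_date``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .adi import AdiWeights


def read_indicator_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"block_group_id", "population", "urban_population", "rural_population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"indicator table {path}: missing columns {sorted(missing)}")
    bad = df["urban_population"] + df["rural_population"] != df["population"]
    if bad.any():
        raise ValueError(
            f"indicator table {path}: urban+rural != population for "
            f"{df.loc[bad, 'block_group_id'].tolist()[:5]}"
        )
    return df


def read_patient_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise ValueError(f"patient table {path}: missing patient_id column")
    return df


def read_encounters(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    if not {"patient_id", "encounter_date"}.issubset(df.columns):
        raise ValueError(f"encounters table {path}: need patient_id, encounter_date")
    return df


def read_weights(path) -> AdiWeights:
    """Load ADI weights from YAML ({weights: {...}, base_score, scale}) or CSV."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text())
        return AdiWeights(
            weights={str(k): float(v) for k, v in raw["weights"].items()},
            base_score=float(raw.get("base_score", 100.0)),
            scale=float(raw.get("scale", 1.0)),
        )
    df = pd.read_csv(path)
    return AdiWeights(weights=dict(zip(df["indicator"].astype(str), df["weight"].astype(float))))


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
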
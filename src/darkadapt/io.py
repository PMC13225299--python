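"""CSV/JSON input-output with schema validation and the run configuration.

All tables are plain UTF-8 CSV with '.' decimals and required headers; no
domain-standard binary format exists for adaptometry exports.  Rows that
violate record invariants are rejected individually with line numbers and
collected into a report rather than aborting the whole load.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .exceptions import ConfigurationError, SchemaError
from .fitting import DB_MAX, PRESENTATION_COLUMNS
from .model import RIT_CRITERION, SESSION_CAP_MIN
from .normative import NormativeModel

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_presentations",
    "write_presentations",
    "read_outcomes",
    "write_outcomes",
    "save_models",
    "load_models",
]

THRESHOLD_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "eccentricity_deg",
    "color",
    "t_min",
    "threshold_log",
]

OUTCOME_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "eccentricity_deg",
    "CT",
    "FT",
    "RIT",
    "rit_censored",
    "rod_function_present",
    "fit_quality",
]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    The RIT criterion must lie inside the instrument's dynamic range
    implied by the calibration constant, otherwise censoring would be
    decided by the device floor rather than the rod plateau.
    """

    out_dir: str = "runs/out"
    presentations_path: str | None = None
    criterion: float = RIT_CRITERION
    t_max: float = SESSION_CAP_MIN
    cal_const: float = 2.0
    fit_mode: str = "map_penalized"
    seed: int = 17
    n_boot: int = 500
    markers: tuple = ("RIT", "FT", "CT")
    exclude_censored_normative: bool = False
    make_plots: bool = True
    # synthetic-cohort settings used when no presentations file is given
    cohort_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        floor = self.cal_const - DB_MAX / 10.0
        if not (floor < self.criterion < 0.0):
            raise ConfigurationError(
                f"criterion {self.criterion} must be negative and above the "
                f"device floor {floor}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_presentations(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Load and validate a presentations CSV.

    Returns ``(records, report)`` where ``report`` lists rejected rows
    with 1-based data line numbers and the violated invariant.  An empty
    file yields an empty table with a warning.
    """
    df = pd.read_csv(path)
    if len(df) == 0:
        logger.warning("%s: empty presentations file", path)
        return df.reindex(columns=PRESENTATION_COLUMNS), []
    _require_columns(df, PRESENTATION_COLUMNS, path)
    report: list[str] = []
    ok = pd.Series(True, index=df.index)

    def reject(mask, reason):
        nonlocal ok
        for i in df.index[mask & ok]:
            report.append(f"line {i + 1}: {reason}")
        ok &= ~mask

    lv = pd.to_numeric(df["level_db"], errors="coerce")
    tm = pd.to_numeric(df["t_min"], errors="coerce")
    reject(lv.isna() | (lv < 0) | (lv > DB_MAX), f"level_db outside [0, {DB_MAX}]")
    reject(tm.isna() | (tm < 0), "t_min must be >= 0")
    reject(~df["eccentricity_deg"].isin([2, 4, 6, 2.0, 4.0, 6.0]), "eccentricity_deg not in {2, 4, 6}")
    reject(~df["color"].isin(["cyan505", "red627"]), "unknown stimulus color")
    reject(~df["seen"].isin([0, 1, True, False]), "seen must be 0/1")
    for line in report:
        logger.warning("%s: rejected %s", path, line)
    out = df[ok].copy()
    out["seen"] = out["seen"].astype(int)
    return out.reset_index(drop=True), report


def write_presentations(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, columns=PRESENTATION_COLUMNS)


def read_outcomes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, OUTCOME_COLUMNS, path)
    df["rit_censored"] = df["rit_censored"].astype(bool)
    df["rod_function_present"] = df["rod_function_present"].astype(bool)
    return df


def write_outcomes(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in OUTCOME_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in OUTCOME_COLUMNS
    ]
    df.to_csv(path, index=False, columns=cols)


def save_models(models: dict, path: str | Path) -> None:
    """Write a dict of outcome -> NormativeModel to JSON."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    payload = {name: m.to_dict() for name, m in models.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_models(path: str | Path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    return {name: NormativeModel.from_dict(d) for name, d in payload.items()}
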
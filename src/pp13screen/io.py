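"""Reading, validating and writing the pipeline's delimited text tables.

All tables are UTF-8 CSV with a mandatory header row and "." decimal
separator. Validation collects every row-level problem (unknown blood-group
label, orphan sample, nonpositive concentration, ...) and reports them
together rather than stopping at the first.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .config import BLOOD_GROUPS, OUTCOMES
from .simulate import SAMPLE_COLUMNS, SUBJECT_COLUMNS


class CohortValidationError(ValueError):
    """Raised with the full list of row-level validation problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "cohort validation failed:\n" + "\n".join(f"  - {p}" for p in problems)
        )


def read_cohort(
    subjects_path: str | Path, samples_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and cross-validate the subject and sample tables.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    subjects = pd.read_csv(subjects_path)
    samples = pd.read_csv(samples_path)
    problems: list[str] = []

    missing = [c for c in SUBJECT_COLUMNS if c not in subjects.columns]
    if missing:
        raise CohortValidationError([f"subjects table is missing columns {missing}"])
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise CohortValidationError([f"samples table is missing columns {missing}"])

    if subjects["subject_id"].duplicated().any():
        dup = subjects.loc[subjects["subject_id"].duplicated(), "subject_id"].tolist()
        problems.append(f"duplicate subject ids {dup}")
    for i, row in enumerate(subjects.itertuples(index=False), start=1):
        if row.blood_group not in BLOOD_GROUPS:
            problems.append(f"subjects row {i}: unknown blood group {row.blood_group!r}")
        if row.outcome not in OUTCOMES:
            problems.append(f"subjects row {i}: unknown outcome {row.outcome!r}")
        if str(row.rh) not in ("+", "-"):
            problems.append(f"subjects row {i}: unknown Rh value {row.rh!r}")

    known = set(subjects["subject_id"])
    for i, row in enumerate(samples.itertuples(index=False), start=1):
        if row.subject_id not in known:
            problems.append(f"samples row {i}: orphan sample for subject {row.subject_id!r}")
        if not (row.concentration_pg_ml > 0):
            problems.append(
                f"samples row {i}: nonpositive concentration {row.concentration_pg_ml!r}"
            )
        if not (6 <= int(row.ga_week) <= 28):
            problems.append(f"samples row {i}: gestational week {row.ga_week} out of range")

    if problems:
        raise CohortValidationError(problems)
    subjects = subjects.copy()
    subjects["smoking"] = subjects["smoking"].astype(bool)
    return subjects, samples


def write_cohort(
    subjects: pd.DataFrame, samples: pd.DataFrame, out_dir: str | Path
) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sub_path = out / "subjects.csv"
    samp_path = out / "samples.csv"
    subjects.to_csv(sub_path, index=False)
    samples.to_csv(samp_path, index=False)
    return sub_path, samp_path


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written once per output directory."""

    seed: int | None
    config: dict = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)
    record_counts: dict[str, int] = field(default_factory=dict)
    stages: list[str] = field(default_factory=list)
    tool_version: str = ""
    created: str = ""

    def add_stage(self, name: str, **counts: int) -> None:
        self.stages.append(name)
        for key, value in counts.items():
            self.record_counts[f"{name}.{key}"] = int(value)

    def write(self, out_dir: str | Path) -> Path:
        from . import __version__

        self.tool_version = __version__
        self.created = datetime.now(timezone.utc).isoformat()
        path = Path(out_dir) / "manifest.json"
        payload = {
            "seed": self.seed,
            "tool_version": self.tool_version,
            "created": self.created,
            "python": platform.python_version(),
            "config": self.config,
            "input_checksums": self.input_checksums,
            "stages": self.stages,
            "record_counts": self.record_counts,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return path
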
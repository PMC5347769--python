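"""Reading, writing and validating the delimited-text table formats.

All tables are plain CSV with fixed headers; empty fields encode
non-applicable values (e.g. no construct on a gating-control well).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputValidationError
from .simulate import (ANNOTATION_COLUMNS, CELL_COLUMNS, CONTROL_ROLES,
                       GATING_ROLES, ROLE_TREATMENT)

VALID_ROLES = (ROLE_TREATMENT,) + CONTROL_ROLES + GATING_ROLES


@dataclass
class TableProblem:
    row: int | None      # 0-based data row, None for table-level problems
    column: str | None
    message: str


@dataclass
class TableValidation:
    path: str
    passed: bool
    problems: list[TableProblem] = field(default_factory=list)

    @property
    def first_problem(self) -> TableProblem | None:
        return self.problems[0] if self.problems else None


def _check_columns(df: pd.DataFrame, expected: tuple[str, ...],
                   problems: list[TableProblem]) -> bool:
    missing = [c for c in expected if c not in df.columns]
    for col in missing:
        problems.append(TableProblem(None, col, "missing required column"))
    return not missing


def validate_cell_table(df: pd.DataFrame,
                        path: str = "<memory>") -> TableValidation:
    problems: list[TableProblem] = []
    if _check_columns(df, CELL_COLUMNS, problems):
        for col in ("intensity_k5", "intensity_k8"):
            vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
            bad = np.flatnonzero(~np.isfinite(vals) | (vals < 0))
            if len(bad):
                problems.append(TableProblem(
                    int(bad[0]), col,
                    "intensity must be a finite number >= 0"))
        areas = pd.to_numeric(df["cell_area"], errors="coerce").to_numpy()
        bad = np.flatnonzero(~np.isfinite(areas) | (areas <= 0))
        if len(bad):
            problems.append(TableProblem(
                int(bad[0]), "cell_area", "cell area must be > 0"))
        if df["well_id"].isna().any():
            problems.append(TableProblem(
                int(df["well_id"].isna().to_numpy().argmax()), "well_id",
                "well_id must not be empty"))
    return TableValidation(path=path, passed=not problems, problems=problems)


def validate_annotation_table(df: pd.DataFrame,
                              path: str = "<memory>") -> TableValidation:
    problems: list[TableProblem] = []
    if _check_columns(df, ANNOTATION_COLUMNS, problems):
        role = df["role"].astype(str)
        bad = np.flatnonzero(~role.isin(VALID_ROLES).to_numpy())
        if len(bad):
            problems.append(TableProblem(
                int(bad[0]), "role",
                f"role must be one of {VALID_ROLES}"))
        treat = role == ROLE_TREATMENT
        for col in ("construct_id", "gene_id"):
            bad = np.flatnonzero((treat & df[col].isna()).to_numpy())
            if len(bad):
                problems.append(TableProblem(
                    int(bad[0]), col,
                    f"treatment wells must carry a {col}"))
        gating = role.isin(GATING_ROLES)
        for col in ("construct_id", "gene_id"):
            bad = np.flatnonzero((gating & df[col].notna()).to_numpy())
            if len(bad):
                problems.append(TableProblem(
                    int(bad[0]), col,
                    f"gating wells must not carry a {col}"))
        rep = pd.to_numeric(df["replicate_index"], errors="coerce")
        bad = np.flatnonzero((rep.isna() | (rep < 1)).to_numpy())
        if len(bad):
            problems.append(TableProblem(
                int(bad[0]), "replicate_index",
                "replicate_index must be an integer >= 1"))
        if df["well_id"].duplicated().any():
            problems.append(TableProblem(
                int(df["well_id"].duplicated().to_numpy().argmax()),
                "well_id", "duplicate well_id"))
    return TableValidation(path=path, passed=not problems, problems=problems)


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    report = validate_cell_table(df, path=str(path))
    if not report.passed:
        first = report.first_problem
        raise InputValidationError(
            f"{path}: invalid cell table — row {first.row}, column "
            f"{first.column}: {first.message}")
    df["well_id"] = df["well_id"].astype("category")
    df["pyknotic"] = df["pyknotic"].astype(bool)
    return df


def write_cell_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(CELL_COLUMNS))


def read_annotation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    report = validate_annotation_table(df, path=str(path))
    if not report.passed:
        first = report.first_problem
        raise InputValidationError(
            f"{path}: invalid annotation table — row {first.row}, column "
            f"{first.column}: {first.message}")
    return df


def write_annotation_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(ANNOTATION_COLUMNS))


def read_qpcr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"sample_id", "condition", "gene", "ct"} - set(df.columns)
    if missing:
        raise InputValidationError(
            f"{path}: qPCR table missing columns {sorted(missing)}")
    return df


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"gene_id", "log2fc"} - set(df.columns)
    if missing:
        raise InputValidationError(
            f"{path}: DE table missing columns {sorted(missing)}")
    return df
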
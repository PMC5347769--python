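"""Keratin gating: threshold calibration, cell classification, well summaries.

Positivity thresholds are anchored on gating-control cell lines rather
than on the screened cells themselves: the K5 channel threshold is the
mean + z·SD (sample SD, z = 2.5 by default) of the K5 intensity of
MCF7-like cells (a luminal line that is K5-negative), and the K8
threshold likewise comes from MCF10A-like cells (a basal line that is
K8-negative). Calibration pools gating wells across the entire plate
set by default. A cell is positive in a channel iff its intensity
strictly exceeds that channel's threshold; cells flagged pyknotic are
excluded before any population accounting.

Wells are summarized into counts and percentages of the four
populations (K5⁺K8⁺, K5⁺K8⁻, K5⁻K8⁺, K5⁻K8⁻) over analyzable
(non-pyknotic) cells; wells with fewer than ``min_cells`` (default 200)
analyzable cells fail QC, since low counts usually indicate
cytotoxicity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (CalibrationError, DegenerateInputError,
                     InputValidationError)
from .simulate import POPULATIONS

CELL_CLASSES = POPULATIONS + ("excluded_pyknotic",)
_CLASS_CODE = {name: i for i, name in enumerate(CELL_CLASSES)}

DEFAULT_Z_MULTIPLIER = 2.5
DEFAULT_MIN_CELLS = 200
DEFAULT_AREA_CUTOFF_UM2 = 830.0


@dataclass(frozen=True)
class GateThresholds:
    """Calibrated channel thresholds (linear fluorescence units)."""

    k5_threshold: float
    k8_threshold: float
    z_multiplier: float
    n_mcf7_cells: int
    n_mcf10a_cells: int

    def to_dict(self) -> dict:
        return {
            "k5_threshold": self.k5_threshold,
            "k8_threshold": self.k8_threshold,
            "z_multiplier": self.z_multiplier,
            "n_mcf7_cells": self.n_mcf7_cells,
            "n_mcf10a_cells": self.n_mcf10a_cells,
        }


@dataclass(frozen=True)
class SizeClassConfig:
    """Cell-size dichotomy; a cell exactly on the cutoff counts as small."""

    area_cutoff: float = DEFAULT_AREA_CUTOFF_UM2

    def validate(self) -> None:
        if self.area_cutoff <= 0:
            raise InputValidationError("area_cutoff must be > 0")


@dataclass(frozen=True)
class WellSummary:
    """Population accounting for one well."""

    well_id: str
    n_analyzable: int
    n_pyknotic_excluded: int
    count_dp: int
    count_k5_only: int
    count_k8_only: int
    count_dn: int
    pct_dp: float
    pct_k5_only: float
    pct_k8_only: float
    pct_dn: float
    qc_pass: bool


def _calibration_values(cells: pd.DataFrame, channel: str,
                        line_name: str) -> np.ndarray:
    values = cells.loc[~cells["pyknotic"].astype(bool), channel].to_numpy(
        dtype=float)
    if len(values) < 2:
        raise CalibrationError(
            f"need at least 2 non-pyknotic {line_name} cells to calibrate, "
            f"got {len(values)}")
    if not np.all(np.isfinite(values)):
        raise InputValidationError(
            f"non-finite {channel} intensity in {line_name} gating cells")
    return values


def calibrate_thresholds(
    mcf7_cells: pd.DataFrame,
    mcf10a_cells: pd.DataFrame,
    z_multiplier: float = DEFAULT_Z_MULTIPLIER,
) -> GateThresholds:
    """Mean + z·SD thresholds from the two gating-control cell sets.

    SD is the sample standard deviation (ddof=1); zero variance is
    allowed, in which case the threshold equals the mean.
    """
    if z_multiplier <= 0:
        raise CalibrationError("z_multiplier must be > 0")
    k5 = _calibration_values(mcf7_cells, "intensity_k5", "MCF7")
    k8 = _calibration_values(mcf10a_cells, "intensity_k8", "MCF10A")
    return GateThresholds(
        k5_threshold=float(k5.mean() + z_multiplier * k5.std(ddof=1)),
        k8_threshold=float(k8.mean() + z_multiplier * k8.std(ddof=1)),
        z_multiplier=float(z_multiplier),
        n_mcf7_cells=len(k5),
        n_mcf10a_cells=len(k8),
    )


def calibrate_from_tables(
    cells: pd.DataFrame,
    annotations: pd.DataFrame,
    z_multiplier: float = DEFAULT_Z_MULTIPLIER,
) -> GateThresholds:
    """Calibrate from full tables, pooling gating wells across all plates."""
    roles = annotations.set_index("well_id")["role"]
    well_role = cells["well_id"].map(roles)
    return calibrate_thresholds(
        cells[well_role == "gating_mcf7"],
        cells[well_role == "gating_mcf10a"],
        z_multiplier=z_multiplier,
    )


def calibrate_per_plate(
    cells: pd.DataFrame,
    annotations: pd.DataFrame,
    z_multiplier: float = DEFAULT_Z_MULTIPLIER,
) -> dict[str, GateThresholds]:
    """Non-default per-plate calibration (``threshold_scope = "plate"``)."""
    ann = annotations.set_index("well_id")
    well_plate = cells["well_id"].map(ann["plate_id"])
    out = {}
    for plate, sub in cells.groupby(well_plate, observed=True):
        out[str(plate)] = calibrate_from_tables(
            sub, annotations, z_multiplier=z_multiplier)
    return out


def _validate_intensities(cells: pd.DataFrame) -> None:
    for col in ("intensity_k5", "intensity_k8"):
        vals = cells[col].to_numpy(dtype=float)
        if len(vals) and (not np.all(np.isfinite(vals)) or vals.min() < 0):
            raise InputValidationError(
                f"{col} must be finite and >= 0")


def classify_cells(cells: pd.DataFrame,
                   thresholds: GateThresholds) -> pd.Categorical:
    """Assign each cell to one of the four populations or pyknotic exclusion.

    Positivity is strict: an intensity exactly equal to the threshold is
    called negative in that channel.
    """
    _validate_intensities(cells)
    k5_pos = cells["intensity_k5"].to_numpy(dtype=float) > thresholds.k5_threshold
    k8_pos = cells["intensity_k8"].to_numpy(dtype=float) > thresholds.k8_threshold
    # DP=0, K5_only=1, K8_only=2, DN=3 per CELL_CLASSES ordering
    codes = np.where(k5_pos, np.where(k8_pos, 0, 1), np.where(k8_pos, 2, 3))
    codes = np.where(cells["pyknotic"].to_numpy(dtype=bool), 4, codes)
    return pd.Categorical.from_codes(codes.astype(np.int8),
                                     categories=list(CELL_CLASSES))


def classify_cell(cell: Mapping, thresholds: GateThresholds) -> str:
    """Classify one cell record; see :func:`classify_cells`."""
    frame = pd.DataFrame([{
        "intensity_k5": cell["intensity_k5"],
        "intensity_k8": cell["intensity_k8"],
        "pyknotic": bool(cell.get("pyknotic", False)),
    }])
    return str(classify_cells(frame, thresholds)[0])


def _summaries_frame(well_ids: list[str], counts: np.ndarray,
                     min_cells: int) -> pd.DataFrame:
    """Build the well-summary table from a (n_wells, 5) class-count array."""
    analyzable = counts[:, :4].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(analyzable[:, None] > 0,
                       100.0 * counts[:, :4] / analyzable[:, None], 0.0)
    return pd.DataFrame({
        "well_id": well_ids,
        "n_analyzable": analyzable.astype(int),
        "n_pyknotic_excluded": counts[:, 4].astype(int),
        "count_dp": counts[:, 0].astype(int),
        "count_k5_only": counts[:, 1].astype(int),
        "count_k8_only": counts[:, 2].astype(int),
        "count_dn": counts[:, 3].astype(int),
        "pct_dp": pct[:, 0],
        "pct_k5_only": pct[:, 1],
        "pct_k8_only": pct[:, 2],
        "pct_dn": pct[:, 3],
        "qc_pass": analyzable >= min_cells,
    })


def summarize_wells(
    cells: pd.DataFrame,
    thresholds: GateThresholds,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> pd.DataFrame:
    """Per-well population counts/percentages and QC for a whole cell table.

    Percentages are over analyzable (non-pyknotic) cells; a well passes
    QC iff it has at least ``min_cells`` analyzable cells. Wells with no
    analyzable cells report all-zero percentages and fail QC.
    """
    classes = classify_cells(cells, thresholds)
    well = cells["well_id"]
    if not isinstance(well.dtype, pd.CategoricalDtype):
        well = well.astype("category")
    wcodes = well.cat.codes.to_numpy()
    well_ids = list(well.cat.categories)
    n_wells = len(well_ids)
    flat = wcodes.astype(np.int64) * 5 + classes.codes
    counts = np.bincount(flat, minlength=n_wells * 5).reshape(n_wells, 5)
    return _summaries_frame(well_ids, counts, min_cells)


def summarize_well(
    cells: pd.DataFrame,
    thresholds: GateThresholds,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> WellSummary:
    """Summarize the cells of a single well; all rows must share one well_id."""
    unique_wells = pd.unique(cells["well_id"].astype(str))
    if len(unique_wells) != 1:
        raise InputValidationError(
            f"summarize_well expects one well, got {len(unique_wells)} "
            f"well_ids: {sorted(map(str, unique_wells))[:5]}")
    codes = classify_cells(cells, thresholds).codes
    counts = np.bincount(codes, minlength=5)[None, :]
    row = _summaries_frame([str(unique_wells[0])], counts, min_cells).iloc[0]
    return WellSummary(
        well_id=row["well_id"],
        n_analyzable=int(row["n_analyzable"]),
        n_pyknotic_excluded=int(row["n_pyknotic_excluded"]),
        count_dp=int(row["count_dp"]),
        count_k5_only=int(row["count_k5_only"]),
        count_k8_only=int(row["count_k8_only"]),
        count_dn=int(row["count_dn"]),
        pct_dp=float(row["pct_dp"]),
        pct_k5_only=float(row["pct_k5_only"]),
        pct_k8_only=float(row["pct_k8_only"]),
        pct_dn=float(row["pct_dn"]),
        qc_pass=bool(row["qc_pass"]),
    )


def classify_cell_size(
    cells: pd.DataFrame | Iterable[float],
    config: SizeClassConfig | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Dichotomize cells into small/big at the area cutoff (default 830 μm²).

    Accepts a cell table (grouped by ``well_id`` when present) or a bare
    sequence of areas. Returns per-cell labels plus a summary of
    small/big fractions per group; a group with no cells is flagged
    undefined rather than reporting fractions.
    """
    config = config or SizeClassConfig()
    config.validate()
    if isinstance(cells, pd.DataFrame):
        areas = cells["cell_area"].to_numpy(dtype=float)
        groups = (cells["well_id"].astype(str).to_numpy()
                  if "well_id" in cells.columns
                  else np.repeat("all", len(areas)))
        index = cells.index
    else:
        areas = np.asarray(list(cells), dtype=float)
        groups = np.repeat("all", len(areas))
        index = pd.RangeIndex(len(areas))
    if len(areas) and (not np.all(np.isfinite(areas)) or areas.min() <= 0):
        raise InputValidationError("cell areas must be finite and > 0")

    small = areas <= config.area_cutoff
    labels = pd.Series(np.where(small, "small", "big"), index=index,
                       name="size_class")

    rows = []
    for group in (pd.unique(groups) if len(groups) else ["all"]):
        mask = groups == group
        n = int(mask.sum())
        n_small = int(small[mask].sum())
        rows.append({
            "group": group,
            "n_cells": n,
            "n_small": n_small,
            "n_big": n - n_small,
            "fraction_small": n_small / n if n else float("nan"),
            "fraction_big": (n - n_small) / n if n else float("nan"),
            "defined": n > 0,
        })
    return labels, pd.DataFrame(rows)


@dataclass(frozen=True)
class IntensityComparison:
    statistic: float
    df: float
    p_value: float


def compare_group_intensity(
    group_a: Iterable[float],
    group_b: Iterable[float],
    equal_var: bool = False,
) -> IntensityComparison:
    """Two-sided two-sample t-test between two intensity groups.

    Welch's unequal-variance variant by default; set ``equal_var=True``
    for the pooled-variance test. Each group needs at least two values,
    and two constant, equal groups are rejected as degenerate (the
    statistic is undefined there).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError(
            "each group needs at least 2 values for a t-test")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InputValidationError("intensities must be finite")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            raise DegenerateInputError(
                "both groups are constant and equal; the t statistic is "
                "undefined")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return IntensityComparison(statistic=float(res.statistic),
                               df=float(res.df),
                               p_value=float(res.pvalue))
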
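"""Construct scoring, z-score hit calling, gene calls and screen frequencies.

Each shRNA construct is scored as the mean of its QC-passing replicate
wells (matching the "average of triplicate wells" readout of arrayed
screens). The null distribution comes from the vector-control
constructs only — empty vector, non-specific and GFP controls; the
MCF7/MCF10A gating wells exist to calibrate intensity thresholds and
never enter the null pool. A construct is a hit in a direction
(toward K5⁻K8⁺ or toward K5⁺K8⁻) when its replicate-averaged
single-positive percentage lies at least ``z_cutoff`` (default 2.5)
control SDs above the control mean; a gene is a hit when at least two
distinct constructs hit in the same direction, which guards against
single-shRNA off-target effects.

The screen-level arithmetic mirrors the published accounting: the
background hit frequency p is the fraction of scored control constructs
called hits, the chance that one gene scores twice by chance is p², and
the gene-hit frequency is the number of ≥2-construct gene hits over the
number of genes targeted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError, InputValidationError
from .simulate import CONTROL_ROLES, GATING_ROLES, ROLE_TREATMENT

DEFAULT_Z_CUTOFF = 2.5
DEFAULT_MIN_CONSTRUCTS = 2

METRICS = ("pct_k8_only", "pct_k5_only")
DIRECTION_OF_METRIC = {"pct_k8_only": "toward_K8_only",
                       "pct_k5_only": "toward_K5_only"}

STATUS_SCORED = "scored"
STATUS_NOT_SCORED = "not_scored"


def score_constructs(well_summaries: pd.DataFrame,
                     annotations: pd.DataFrame) -> pd.DataFrame:
    """Average well summaries into one score row per construct.

    Metrics (percent K5⁻K8⁺, percent K5⁺K8⁻, mean analyzable cells,
    mean absolute K5⁻K8⁺ count) are averaged over QC-passing wells
    only. A construct whose wells all fail QC is emitted with status
    ``not_scored`` and NaN metrics rather than silently dropped.
    Gating wells carry no construct and are excluded here.
    """
    merged = annotations.merge(well_summaries, on="well_id", how="left",
                               validate="one_to_one")
    merged = merged[merged["construct_id"].notna()].copy()
    if merged["n_analyzable"].isna().any():
        missing = merged.loc[merged["n_analyzable"].isna(), "well_id"]
        raise InputValidationError(
            f"annotated wells missing from well summaries: "
            f"{sorted(missing)[:5]}")

    genes_per_construct = (
        merged[merged["gene_id"].notna()]
        .groupby("construct_id", sort=False)["gene_id"].nunique())
    conflicted = genes_per_construct[genes_per_construct > 1]
    if len(conflicted):
        raise InputValidationError(
            "constructs annotated with conflicting genes: "
            f"{sorted(conflicted.index)[:5]}")

    rows = []
    for construct, grp in merged.groupby("construct_id", sort=False):
        passing = grp[grp["qc_pass"].astype(bool)]
        n_used = len(passing)
        gene = grp["gene_id"].dropna().iloc[0] if grp["gene_id"].notna().any() else None
        row = {
            "construct_id": construct,
            "gene_id": gene,
            "role": grp["role"].iloc[0],
            "n_wells_total": len(grp),
            "n_wells_used": n_used,
            "status": STATUS_SCORED if n_used else STATUS_NOT_SCORED,
        }
        for col, out in (("pct_k8_only", "pct_k8_only"),
                         ("pct_k5_only", "pct_k5_only"),
                         ("n_analyzable", "mean_analyzable_cells"),
                         ("count_k8_only", "mean_count_k8_only")):
            row[out] = float(passing[col].mean()) if n_used else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ControlStats:
    """Null-pool statistics per metric over scored vector-control constructs."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_constructs: int

    def to_dict(self) -> dict:
        return {"mean": dict(self.mean), "sd": dict(self.sd),
                "n_constructs": self.n_constructs}


def control_statistics(construct_scores: pd.DataFrame) -> ControlStats:
    """Mean and sample SD of each metric over eligible control constructs.

    Eligible means: vector-control role (empty/non-specific/GFP — never
    the gating cell lines) and at least one QC-passing well.
    """
    ctrl = construct_scores[
        construct_scores["role"].isin(CONTROL_ROLES)
        & (construct_scores["status"] == STATUS_SCORED)]
    if len(ctrl) < 2:
        raise CalibrationError(
            f"need at least 2 scored vector-control constructs, got "
            f"{len(ctrl)}")
    metrics = METRICS + ("mean_count_k8_only",)
    mean = {m: float(ctrl[m].mean()) for m in metrics}
    sd = {m: float(ctrl[m].std(ddof=1)) for m in metrics}
    return ControlStats(mean=mean, sd=sd, n_constructs=len(ctrl))


def _z_scores(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    if sd > 0:
        return (values - mean) / sd
    # zero control variance: any excess over the mean is infinitely many
    # SDs away; report a signed infinity sentinel
    out = np.where(values > mean, np.inf, np.where(values < mean, -np.inf, 0.0))
    return out


def call_hits(
    construct_scores: pd.DataFrame,
    control_stats: ControlStats,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
    direction: str = "both",
) -> pd.DataFrame:
    """Per-construct z-scores and hit flags against the control null.

    A construct hits in a direction iff its z-score is ≥ ``z_cutoff``
    (inclusive at the cutoff). ``direction`` restricts calling to one
    metric (``"k8_only"`` / ``"k5_only"``) or both. Unscored constructs
    propagate their status with NaN z-scores and no hit.
    """
    if direction not in ("both", "k8_only", "k5_only"):
        raise InputValidationError(
            f"direction must be both|k8_only|k5_only, got {direction!r}")
    active = {m for m in METRICS
              if direction == "both" or m == f"pct_{direction}"}

    out = construct_scores[
        ["construct_id", "gene_id", "role", "status"]].copy()
    scored = (construct_scores["status"] == STATUS_SCORED).to_numpy()
    any_hit = np.zeros(len(out), dtype=bool)
    best_z = np.full(len(out), -np.inf)
    direction_label = np.full(len(out), None, dtype=object)
    for metric in METRICS:
        vals = construct_scores[metric].to_numpy(dtype=float)
        z = np.full(len(out), np.nan)
        z[scored] = _z_scores(vals[scored], control_stats.mean[metric],
                              control_stats.sd[metric])
        hit = np.zeros(len(out), dtype=bool)
        if metric in active:
            hit[scored] = z[scored] >= z_cutoff
        short = metric.removeprefix("pct_")
        out[f"z_{short}"] = z
        out[f"hit_{short}"] = hit
        newly_best = hit & (~any_hit | (z > best_z))
        direction_label[newly_best] = DIRECTION_OF_METRIC[metric]
        best_z = np.where(hit & (z > best_z), z, best_z)
        any_hit |= hit
    out["is_hit"] = any_hit
    out["direction"] = direction_label
    return out


def call_genes(
    hit_calls: pd.DataFrame,
    min_constructs: int = DEFAULT_MIN_CONSTRUCTS,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Gene-level replication rule over treatment constructs.

    A gene is a hit iff at least ``min_constructs`` distinct constructs
    are hits in the same direction. Genes none of whose constructs
    could be scored are flagged ``not_scored`` and are not hits.
    ``annotations`` may be supplied to include genes absent from
    ``hit_calls`` entirely.
    """
    treat = hit_calls[hit_calls["role"] == ROLE_TREATMENT]
    rows = []
    for gene, grp in treat.groupby("gene_id", sort=True):
        n_scored = int((grp["status"] == STATUS_SCORED).sum())
        n_hit_k8 = int(grp["hit_k8_only"].sum())
        n_hit_k5 = int(grp["hit_k5_only"].sum())
        is_hit = max(n_hit_k8, n_hit_k5) >= min_constructs
        if is_hit:
            gene_direction = ("toward_K8_only" if n_hit_k8 >= n_hit_k5
                              else "toward_K5_only")
        else:
            gene_direction = None
        rows.append({
            "gene_id": gene,
            "n_constructs": len(grp),
            "n_constructs_scored": n_scored,
            "n_hit_toward_k8_only": n_hit_k8,
            "n_hit_toward_k5_only": n_hit_k5,
            "is_gene_hit": bool(is_hit),
            "direction": gene_direction,
            "status": STATUS_SCORED if n_scored else STATUS_NOT_SCORED,
        })
    seen = {r["gene_id"] for r in rows}
    if annotations is not None:
        for gene in annotations["gene_id"].dropna().unique():
            if gene not in seen:
                rows.append({
                    "gene_id": gene, "n_constructs": 0,
                    "n_constructs_scored": 0, "n_hit_toward_k8_only": 0,
                    "n_hit_toward_k5_only": 0, "is_gene_hit": False,
                    "direction": None, "status": STATUS_NOT_SCORED,
                })
    return (pd.DataFrame(rows)
            .sort_values("gene_id")
            .reset_index(drop=True))


def chance_double_hit(background_hit_frequency: float) -> float:
    """Probability of two chance hits on one gene: exactly p·p."""
    if not 0.0 <= background_hit_frequency <= 1.0:
        raise InputValidationError(
            "background hit frequency must lie in [0, 1]")
    return background_hit_frequency * background_hit_frequency


@dataclass(frozen=True)
class ScreenFrequencies:
    """Screen-level hit-rate arithmetic, with the counts behind it."""

    background_hit_frequency: float
    chance_double_hit_probability: float
    gene_hit_frequency: float
    n_control_constructs_scored: int
    n_control_construct_hits: int
    n_gene_hits: int
    n_genes_targeted: int

    def to_dict(self) -> dict:
        return {
            "background_hit_frequency": self.background_hit_frequency,
            "chance_double_hit_probability":
                self.chance_double_hit_probability,
            "gene_hit_frequency": self.gene_hit_frequency,
            "n_control_constructs_scored": self.n_control_constructs_scored,
            "n_control_construct_hits": self.n_control_construct_hits,
            "n_gene_hits": self.n_gene_hits,
            "n_genes_targeted": self.n_genes_targeted,
        }


def screen_frequencies(
    hit_calls: pd.DataFrame,
    gene_calls: pd.DataFrame,
    n_genes_targeted: int,
) -> ScreenFrequencies:
    """Background hit frequency p, chance double-hit p², gene-hit frequency.

    p is denominated by scored control constructs; the gene-hit
    frequency by the number of genes targeted in the screen.
    """
    if n_genes_targeted <= 0:
        raise InputValidationError("n_genes_targeted must be > 0")
    ctrl = hit_calls[hit_calls["role"].isin(CONTROL_ROLES)
                     & (hit_calls["status"] == STATUS_SCORED)]
    if len(ctrl) == 0:
        raise CalibrationError("no scored control constructs")
    p = float(ctrl["is_hit"].mean())
    n_gene_hits = int(gene_calls["is_gene_hit"].sum())
    return ScreenFrequencies(
        background_hit_frequency=p,
        chance_double_hit_probability=chance_double_hit(p),
        gene_hit_frequency=n_gene_hits / n_genes_targeted,
        n_control_constructs_scored=len(ctrl),
        n_control_construct_hits=int(ctrl["is_hit"].sum()),
        n_gene_hits=n_gene_hits,
        n_genes_targeted=int(n_genes_targeted),
    )


def absolute_count_check(
    construct_scores: pd.DataFrame,
    control_stats: ControlStats,
) -> pd.DataFrame:
    """Annotation: did the absolute K5⁻K8⁺ cell count rise above control?

    A true percentage increase could reflect selective loss of
    double-positive cells; a higher absolute count supports genuine
    induced differentiation. This is reported as an annotation, never
    as a hit criterion.
    """
    ctrl_mean = control_stats.mean["mean_count_k8_only"]
    delta = construct_scores["mean_count_k8_only"] - ctrl_mean
    return pd.DataFrame({
        "construct_id": construct_scores["construct_id"],
        "delta_count_k8_only_vs_control": delta,
        "count_increased": (delta > 0).fillna(False).astype(bool),
    })
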
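"""End-to-end orchestration: simulate → gate → score → call → report.

``run_pipeline`` executes the whole screen analysis as one reproducible
run: it either generates a synthetic screen or loads user-supplied cell
and annotation tables, calibrates gating thresholds from the
MCF7/MCF10A gating wells, summarizes every well, scores constructs
against the vector-control null, applies the ≥2-construct gene rule,
and computes the screen-level hit frequencies. All stage artifacts can
be written to an output directory as delimited tables plus JSON
reports; identical config and seed produce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, gating, hits, io
from .errors import ConfigurationError, InputValidationError
from .simulate import (CONTROL_ROLES, GATING_ROLES, ROLE_TREATMENT,
                       EffectModel, IntensityModel, ScreenDesign,
                       generate_screen)


@dataclass(frozen=True)
class GatingConfig:
    z_multiplier: float = gating.DEFAULT_Z_MULTIPLIER
    min_cells: int = gating.DEFAULT_MIN_CELLS
    area_cutoff_um2: float = gating.DEFAULT_AREA_CUTOFF_UM2
    threshold_scope: str = "screen"   # "screen" (default) or "plate"

    def validate(self) -> None:
        if self.threshold_scope not in ("screen", "plate"):
            raise ConfigurationError(
                "gating.threshold_scope must be 'screen' or 'plate', got "
                f"{self.threshold_scope!r}")
        if self.min_cells < 0:
            raise ConfigurationError("gating.min_cells must be >= 0")
        if self.z_multiplier <= 0:
            raise ConfigurationError("gating.z_multiplier must be > 0")
        if self.area_cutoff_um2 <= 0:
            raise ConfigurationError("gating.area_cutoff_um2 must be > 0")


@dataclass(frozen=True)
class HitsConfig:
    z_cutoff: float = hits.DEFAULT_Z_CUTOFF
    min_constructs_per_gene: int = hits.DEFAULT_MIN_CONSTRUCTS
    direction: str = "both"           # both | k8_only | k5_only

    def validate(self) -> None:
        if self.direction not in ("both", "k8_only", "k5_only"):
            raise ConfigurationError(
                "hits.direction must be both|k8_only|k5_only, got "
                f"{self.direction!r}")
        if self.min_constructs_per_gene < 1:
            raise ConfigurationError(
                "hits.min_constructs_per_gene must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; defaults are the published screen constants."""

    seed: int = 0
    mode: str = "synthetic"           # "synthetic" or "user-data"
    design: ScreenDesign = field(default_factory=ScreenDesign)
    effects: EffectModel = field(default_factory=EffectModel)
    intensity: IntensityModel = field(default_factory=IntensityModel)
    gating: GatingConfig = field(default_factory=GatingConfig)
    hits: HitsConfig = field(default_factory=HitsConfig)
    cell_table: str | None = None     # user-data mode inputs
    annotation_table: str | None = None
    write_cell_table: bool = False    # synthetic cell tables are large

    def validate(self) -> None:
        if self.mode not in ("synthetic", "user-data"):
            raise ConfigurationError(
                f"mode must be 'synthetic' or 'user-data', got {self.mode!r}")
        if self.mode == "user-data" and not (self.cell_table
                                             and self.annotation_table):
            raise ConfigurationError(
                "user-data mode needs cell_table and annotation_table paths")
        self.gating.validate()
        self.hits.validate()

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        """Build a config from a nested mapping (the YAML layout).

        Recognized blocks: ``simulate`` (design/effects/intensity keys),
        ``gating``, ``hits``, plus top-level ``seed``, ``mode``, paths.
        """
        raw = dict(raw or {})
        sim = dict(raw.pop("simulate", {}) or {})

        def build(cls_, block):
            names = {f.name for f in dataclasses.fields(cls_)}
            kwargs = {k: v for k, v in block.items() if k in names}
            unknown = set(block) - names
            if unknown:
                raise ConfigurationError(
                    f"unknown {cls_.__name__} keys: {sorted(unknown)}")
            return cls_(**kwargs)

        design_keys = {f.name for f in dataclasses.fields(ScreenDesign)}
        effect_keys = {f.name for f in dataclasses.fields(EffectModel)}
        intensity_keys = {f.name for f in dataclasses.fields(IntensityModel)}
        design = build(ScreenDesign,
                       {k: v for k, v in sim.items() if k in design_keys})
        effect_kwargs = {k: v for k, v in sim.items() if k in effect_keys}
        for key in ("differentiator_gene_ids", "cytotoxic_construct_ids"):
            if key in effect_kwargs:
                effect_kwargs[key] = frozenset(effect_kwargs[key])
        effects = EffectModel(**effect_kwargs)
        intensity = build(IntensityModel,
                          {k: v for k, v in sim.items() if k in intensity_keys})
        leftover = set(sim) - design_keys - effect_keys - intensity_keys
        if leftover:
            raise ConfigurationError(
                f"unknown simulate keys: {sorted(leftover)}")
        if "constructs_per_gene" in design_keys and isinstance(
                design.constructs_per_gene, list):
            design = dataclasses.replace(
                design, constructs_per_gene=tuple(design.constructs_per_gene))
        return cls(
            seed=int(raw.pop("seed", 0)),
            mode=raw.pop("mode", "synthetic"),
            design=design,
            effects=effects,
            intensity=intensity,
            gating=build(GatingConfig, dict(raw.pop("gating", {}) or {})),
            hits=build(HitsConfig, dict(raw.pop("hits", {}) or {})),
            cell_table=raw.pop("cell_table", None),
            annotation_table=raw.pop("annotation_table", None),
            write_cell_table=bool(raw.pop("write_cell_table", False)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("differentiator_gene_ids", "cytotoxic_construct_ids"):
            out["effects"][key] = sorted(out["effects"][key])
        out["design"]["constructs_per_gene"] = list(
            out["design"]["constructs_per_gene"])
        return out


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run."""

    config: dict
    versions: dict
    n_cells: int
    wells_by_role: dict[str, int]
    n_wells_qc_pass: int
    n_wells_qc_fail: int
    thresholds: dict
    control_stats: dict
    frequencies: dict
    gene_hits: list[str]
    warnings: list[str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)


REPORT_REQUIRED_KEYS = ("config", "versions", "n_cells", "wells_by_role",
                        "n_wells_qc_pass", "n_wells_qc_fail", "thresholds",
                        "control_stats", "frequencies", "gene_hits",
                        "warnings")


def validate_report(report: dict) -> list[str]:
    """Schema check for a run-report dict; returns a list of problems."""
    problems = [f"missing key: {k}" for k in REPORT_REQUIRED_KEYS
                if k not in report]
    if not problems:
        total = sum(report["wells_by_role"].values())
        accounted = report["n_wells_qc_pass"] + report["n_wells_qc_fail"]
        if total != accounted:
            problems.append(
                f"well accounting mismatch: {total} wells by role vs "
                f"{accounted} by QC status")
    return problems


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    # per-stage substreams derived from the one run seed; kept below 2**31
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2 ** 31)) for s in state]


@dataclass
class PipelineResult:
    """Report plus all in-memory stage artifacts of one run."""

    report: RunReport
    thresholds: gating.GateThresholds | dict
    well_summaries: pd.DataFrame
    construct_scores: pd.DataFrame
    hit_calls: pd.DataFrame
    gene_calls: pd.DataFrame
    frequencies: hits.ScreenFrequencies
    annotations: pd.DataFrame
    truth: object | None = None       # GroundTruth in synthetic mode


def run_pipeline(config: RunConfig,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full screen analysis described by ``config``."""
    config.validate()
    seeds = _stage_seeds(config.seed)
    warnings: list[str] = []
    truth = None

    if config.mode == "synthetic":
        cells, annotations, truth = generate_screen(
            config.design, config.effects, config.intensity, seed=seeds[0])
        n_genes_targeted = config.design.n_genes
    else:
        cells = io.read_cell_table(config.cell_table)
        annotations = io.read_annotation_table(config.annotation_table)
        n_genes_targeted = int(annotations["gene_id"].dropna().nunique())

    # --- gating ---------------------------------------------------------
    if config.gating.threshold_scope == "screen":
        thresholds = gating.calibrate_from_tables(
            cells, annotations, z_multiplier=config.gating.z_multiplier)
        summaries = gating.summarize_wells(
            cells, thresholds, min_cells=config.gating.min_cells)
        thresholds_payload = thresholds.to_dict()
    else:
        per_plate = gating.calibrate_per_plate(
            cells, annotations, z_multiplier=config.gating.z_multiplier)
        ann = annotations.set_index("well_id")
        well_plate = cells["well_id"].map(ann["plate_id"])
        parts = [
            gating.summarize_wells(sub, per_plate[str(plate)],
                                   min_cells=config.gating.min_cells)
            for plate, sub in cells.groupby(well_plate, observed=True)]
        summaries = pd.concat(parts, ignore_index=True)
        thresholds = per_plate
        thresholds_payload = {p: t.to_dict() for p, t in per_plate.items()}

    # summarize_wells enumerates only wells that contain cells; empty wells
    # still need summary rows (zero counts, QC fail) for full accounting
    missing_wells = set(annotations["well_id"]) - set(summaries["well_id"])
    if missing_wells:
        empty = pd.DataFrame({"well_id": sorted(missing_wells)})
        for col in summaries.columns:
            if col == "well_id":
                continue
            empty[col] = False if col == "qc_pass" else 0
        summaries = pd.concat([summaries, empty], ignore_index=True)

    # --- scoring and calling --------------------------------------------
    scores = hits.score_constructs(summaries, annotations)
    control_stats = hits.control_statistics(scores)
    hit_calls = hits.call_hits(scores, control_stats,
                               z_cutoff=config.hits.z_cutoff,
                               direction=config.hits.direction)
    gene_calls = hits.call_genes(
        hit_calls, min_constructs=config.hits.min_constructs_per_gene,
        annotations=annotations)
    frequencies = hits.screen_frequencies(hit_calls, gene_calls,
                                          n_genes_targeted)
    count_check = hits.absolute_count_check(scores, control_stats)

    n_not_scored = int((scores["status"] == hits.STATUS_NOT_SCORED).sum())
    if n_not_scored:
        warnings.append(
            f"{n_not_scored} constructs had no QC-passing wells "
            "(not_scored)")
    n_qc_fail = int((~summaries["qc_pass"].astype(bool)).sum())
    if n_qc_fail:
        warnings.append(f"{n_qc_fail} wells failed the "
                        f"{config.gating.min_cells}-cell QC minimum")

    report = RunReport(
        config=config.to_dict(),
        versions={"bilineage": __version__,
                  "numpy": np.__version__, "pandas": pd.__version__},
        n_cells=int(len(cells)),
        wells_by_role=annotations["role"].value_counts().to_dict(),
        n_wells_qc_pass=int(summaries["qc_pass"].astype(bool).sum()),
        n_wells_qc_fail=n_qc_fail,
        thresholds=thresholds_payload,
        control_stats=control_stats.to_dict(),
        frequencies=frequencies.to_dict(),
        gene_hits=sorted(gene_calls.loc[gene_calls["is_gene_hit"],
                                        "gene_id"].astype(str)),
        warnings=warnings,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summaries.to_csv(outdir / "well_summary.csv", index=False)
        scores.to_csv(outdir / "construct_scores.csv", index=False)
        hit_calls.to_csv(outdir / "hit_calls.csv", index=False)
        gene_calls.to_csv(outdir / "gene_calls.csv", index=False)
        count_check.to_csv(outdir / "absolute_count_check.csv", index=False)
        with open(outdir / "gate_thresholds.json", "w") as fh:
            json.dump(thresholds_payload, fh, indent=2)
        with open(outdir / "screen_frequencies.json", "w") as fh:
            json.dump(frequencies.to_dict(), fh, indent=2)
        if config.mode == "synthetic":
            io.write_annotation_table(annotations,
                                      outdir / "annotations.csv")
            truth.to_json(outdir / "ground_truth.json")
            if config.write_cell_table:
                io.write_cell_table(cells, outdir / "cell_table.csv")
        report.write(outdir / "run_report.json")   # report written last

    return PipelineResult(
        report=report, thresholds=thresholds, well_summaries=summaries,
        construct_scores=scores, hit_calls=hit_calls, gene_calls=gene_calls,
        frequencies=frequencies, annotations=annotations, truth=truth)


def validate_tables(paths: dict[str, str]) -> dict[str, io.TableValidation]:
    """Validate files against their schemas; never mutates inputs.

    ``paths`` maps a table kind (``"cells"`` or ``"annotations"``) to a
    file path. Unreadable files raise an I/O error naming the path.
    """
    validators = {"cells": io.validate_cell_table,
                  "annotations": io.validate_annotation_table}
    out = {}
    for kind, path in paths.items():
        if kind not in validators:
            raise InputValidationError(
                f"unknown table kind {kind!r}; expected one of "
                f"{sorted(validators)}")
        try:
            df = pd.read_csv(path)
        except OSError as exc:
            raise OSError(f"cannot read {kind} table at {path}: {exc}") from exc
        out[kind] = validators[kind](df, path=str(path))
    return out
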
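"""Synthetic bi-lineage differentiation screens with planted ground truth.

The generator emulates an arrayed lentiviral shRNA screen read out by
two-channel keratin immunofluorescence: ~hundreds of genes, several
independent constructs per gene, replicate wells, per-plate vector
controls, and dedicated gating-control wells seeded with luminal
(MCF7-like, K5⁻K8⁺) and basal (MCF10A-like, K5⁺K8⁻) cell lines.

Each well yields a table of per-cell measurements (two linear
fluorescence intensities, a cell area in μm², a pyknotic flag).
"Differentiator" genes planted in the ground truth shift a fraction of
cells from the double-positive (K5⁺K8⁺) population to the luminal
single-positive (K5⁻K8⁺) population; cytotoxic constructs yield wells
with too few cells to pass quality control.

Companion generators produce qPCR Ct tables with known expression
ratios (for efficiency-corrected relative quantification) and paired
differential-expression tables with planted shared/unique regulated
genes (for cutoff filtering and overlap counting).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError

# Population order used everywhere a four-vector of fractions appears.
POPULATIONS = ("DP", "K5_only", "K8_only", "DN")

ROLE_TREATMENT = "treatment"
CONTROL_ROLES = ("control_empty", "control_nonspecific", "control_gfp")
GATING_ROLES = ("gating_mcf7", "gating_mcf10a")

CELL_COLUMNS = ("cell_id", "well_id", "intensity_k5", "intensity_k8",
                "cell_area", "pyknotic")
ANNOTATION_COLUMNS = ("well_id", "plate_id", "role", "construct_id",
                      "gene_id", "replicate_index")


def gene_ids(n_genes: int) -> list[str]:
    """Deterministic gene identifiers used by the generator (``g0001``…)."""
    return [f"g{i:04d}" for i in range(1, n_genes + 1)]


def construct_ids(gene: str, n_constructs: int) -> list[str]:
    """Deterministic construct identifiers for one gene (``g0001-sh1``…)."""
    return [f"{gene}-sh{j}" for j in range(1, n_constructs + 1)]


@dataclass(frozen=True)
class ScreenDesign:
    """Plate and replication layout of the screen.

    Defaults follow the published screen: 420 targeted genes with 4–10
    constructs each, triplicate wells, 1200 seeded cells per well, and
    56 vector-control wells on every 384-well plate, plus gating-control
    wells for both calibration cell lines on every plate.
    """

    n_genes: int = 420
    constructs_per_gene: tuple[int, int] = (4, 10)
    replicates_per_construct: int = 3
    cells_per_well_mean: int = 1200
    controls_per_plate: int = 56
    wells_per_plate: int = 384
    n_gating_control_wells_per_line: int = 4

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "replicates_per_construct": self.replicates_per_construct,
            "cells_per_well_mean": self.cells_per_well_mean,
            "controls_per_plate": self.controls_per_plate,
            "wells_per_plate": self.wells_per_plate,
            "n_gating_control_wells_per_line":
                self.n_gating_control_wells_per_line,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigurationError(
                    f"design invariant violated: {name} must be a positive "
                    f"integer, got {value!r}")
        low, high = self.constructs_per_gene
        if low < 1 or high < low:
            raise ConfigurationError(
                "design invariant violated: constructs_per_gene must satisfy "
                f"1 <= low <= high, got {self.constructs_per_gene!r}")
        if self.wells_per_plate < self.controls_per_plate:
            raise ConfigurationError(
                "design invariant violated: wells_per_plate "
                f"({self.wells_per_plate}) < controls_per_plate "
                f"({self.controls_per_plate})")
        if self.treatment_wells_per_plate < self.replicates_per_construct:
            raise ConfigurationError(
                "design invariant violated: no room for treatment wells after "
                f"controls and gating wells ({self.treatment_wells_per_plate} "
                "free slots per plate)")

    @property
    def treatment_wells_per_plate(self) -> int:
        return (self.wells_per_plate - self.controls_per_plate
                - 2 * self.n_gating_control_wells_per_line)


@dataclass(frozen=True)
class EffectModel:
    """Planted biology: population composition and its perturbations.

    Baseline composition reflects a bi-potential line in which most
    cells co-express both keratins; the K5⁻K8⁺ (luminal single
    positive) fraction is 4% at baseline and rises to 24% in wells of
    an effect-carrying construct, matching the strongest published hit.
    Penetrance is the probability that a given construct of a
    differentiator gene actually carries the effect — distinct shRNAs
    of one gene differ in knockdown strength.
    """

    baseline_k5neg_k8pos_fraction: float = 0.04
    effect_k5neg_k8pos_fraction: float = 0.24
    differentiator_gene_ids: frozenset[str] = frozenset()
    per_construct_effect_penetrance: float = 0.8
    cytotoxic_construct_ids: frozenset[str] = frozenset()
    cytotoxic_cell_count_mean: int = 120
    well_to_well_cv: float = 0.10
    # Remaining baseline composition; the K5+K8+ fraction is the residual.
    baseline_k5pos_k8neg_fraction: float = 0.06
    baseline_double_negative_fraction: float = 0.10

    def validate(self) -> None:
        proportions = {
            "baseline_k5neg_k8pos_fraction": self.baseline_k5neg_k8pos_fraction,
            "effect_k5neg_k8pos_fraction": self.effect_k5neg_k8pos_fraction,
            "per_construct_effect_penetrance":
                self.per_construct_effect_penetrance,
            "baseline_k5pos_k8neg_fraction": self.baseline_k5pos_k8neg_fraction,
            "baseline_double_negative_fraction":
                self.baseline_double_negative_fraction,
        }
        for name, value in proportions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(
                    f"effect invariant violated: {name} must lie in [0, 1], "
                    f"got {value!r}")
        if self.effect_k5neg_k8pos_fraction < self.baseline_k5neg_k8pos_fraction:
            raise ConfigurationError(
                "effect invariant violated: effect_k5neg_k8pos_fraction < "
                "baseline_k5neg_k8pos_fraction")
        if self.well_to_well_cv < 0:
            raise ConfigurationError(
                "effect invariant violated: well_to_well_cv must be >= 0")
        if self.cytotoxic_cell_count_mean <= 0:
            raise ConfigurationError(
                "effect invariant violated: cytotoxic_cell_count_mean must "
                "be positive")
        if sum(self.baseline_fractions()) > 1.0 + 1e-12:
            raise ConfigurationError(
                "effect invariant violated: baseline fractions exceed 1")
        if (self.effect_k5neg_k8pos_fraction
                - self.baseline_k5neg_k8pos_fraction) > self.baseline_dp_fraction:
            raise ConfigurationError(
                "effect invariant violated: effect shift exceeds the "
                "available K5+K8+ pool")

    @property
    def baseline_dp_fraction(self) -> float:
        return 1.0 - (self.baseline_k5neg_k8pos_fraction
                      + self.baseline_k5pos_k8neg_fraction
                      + self.baseline_double_negative_fraction)

    def baseline_fractions(self) -> tuple[float, float, float, float]:
        """(DP, K5_only, K8_only, DN) at baseline."""
        return (self.baseline_dp_fraction,
                self.baseline_k5pos_k8neg_fraction,
                self.baseline_k5neg_k8pos_fraction,
                self.baseline_double_negative_fraction)

    def effect_fractions(self) -> tuple[float, float, float, float]:
        """(DP, K5_only, K8_only, DN) in effect-carrying wells.

        The K5⁻K8⁺ gain is drawn from the double-positive pool: induced
        differentiation converts bi-lineage cells, it does not create
        cells from the other compartments.
        """
        shift = (self.effect_k5neg_k8pos_fraction
                 - self.baseline_k5neg_k8pos_fraction)
        return (self.baseline_dp_fraction - shift,
                self.baseline_k5pos_k8neg_fraction,
                self.effect_k5neg_k8pos_fraction,
                self.baseline_double_negative_fraction)


@dataclass(frozen=True)
class IntensityModel:
    """Distributional stand-in for the immunofluorescence readout.

    Intensities are log-normal per population and channel (fluorescence
    intensities are canonically right-skewed); a population positive in
    a channel draws from the high log-mean, a negative one from the low
    log-mean. Cell areas are a two-component log-normal mixture
    straddling the 830 μm² small/big boundary; effect-carrying wells
    contain a larger big-cell fraction, mimicking the enlarged, flatter
    morphology of differentiated cells.
    """

    k5_log_mean_positive: float = math.log(1000.0)
    k5_log_mean_negative: float = math.log(100.0)
    k5_log_sd: float = 0.35
    k8_log_mean_positive: float = math.log(1000.0)
    k8_log_mean_negative: float = math.log(100.0)
    k8_log_sd: float = 0.35
    pyknotic_fraction: float = 0.05
    area_log_mean_small: float = math.log(600.0)
    area_log_mean_big: float = math.log(1200.0)
    area_log_sd: float = 0.30
    big_cell_fraction_baseline: float = 0.25
    big_cell_fraction_effect: float = 0.55

    def validate(self) -> None:
        for name in ("k5_log_sd", "k8_log_sd", "area_log_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(
                    f"intensity invariant violated: {name} must be > 0")
        if self.k5_log_mean_positive <= self.k5_log_mean_negative:
            raise ConfigurationError(
                "intensity invariant violated: K5 positive log-mean must "
                "exceed the negative log-mean")
        if self.k8_log_mean_positive <= self.k8_log_mean_negative:
            raise ConfigurationError(
                "intensity invariant violated: K8 positive log-mean must "
                "exceed the negative log-mean")
        if not 0.0 <= self.pyknotic_fraction < 1.0:
            raise ConfigurationError(
                "intensity invariant violated: pyknotic_fraction must lie "
                "in [0, 1)")
        for name in ("big_cell_fraction_baseline", "big_cell_fraction_effect"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(
                    f"intensity invariant violated: {name} must lie in [0, 1]")

    def population_log_means(self) -> np.ndarray:
        """(4, 2) array of (K5, K8) log-means in POPULATIONS order."""
        hi5, lo5 = self.k5_log_mean_positive, self.k5_log_mean_negative
        hi8, lo8 = self.k8_log_mean_positive, self.k8_log_mean_negative
        return np.array([
            [hi5, hi8],   # DP
            [hi5, lo8],   # K5_only
            [lo5, hi8],   # K8_only
            [lo5, lo8],   # DN
        ])


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for recovery checks downstream."""

    differentiator_gene_ids: frozenset[str]
    effect_construct_ids: frozenset[str]
    cytotoxic_construct_ids: frozenset[str]
    true_fractions: pd.DataFrame  # well_id + frac_{dp,k5_only,k8_only,dn}

    def to_json(self, path) -> None:
        payload = {
            "differentiator_genes": sorted(self.differentiator_gene_ids),
            "effect_constructs": sorted(self.effect_construct_ids),
            "cytotoxic_constructs": sorted(self.cytotoxic_construct_ids),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _well_count_rng_sigma(cv: float) -> float:
    # multiplicative log-normal well factor with unit mean and the given CV
    return math.sqrt(math.log1p(cv * cv))


def generate_screen(
    design: ScreenDesign | None = None,
    effects: EffectModel | None = None,
    intensity: IntensityModel | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one full screen.

    Returns ``(cells, annotations, truth)``: a per-cell measurement
    table, the well annotation table linking wells to plates, roles,
    constructs and genes, and the planted ground truth. Identical
    arguments (including ``seed``) produce identical tables.
    """
    design = design or ScreenDesign()
    effects = effects or EffectModel()
    intensity = intensity or IntensityModel()
    design.validate()
    effects.validate()
    intensity.validate()
    if seed < 0 or int(seed) != seed:
        raise ConfigurationError("seed must be a non-negative integer")

    rng = np.random.default_rng(seed)

    genes = gene_ids(design.n_genes)
    unknown_genes = effects.differentiator_gene_ids - set(genes)
    if unknown_genes:
        raise ConfigurationError(
            "differentiator_gene_ids not in the design: "
            f"{sorted(unknown_genes)}")

    low, high = design.constructs_per_gene
    n_constructs_per_gene = rng.integers(low, high + 1, size=design.n_genes)

    constructs: list[str] = []
    construct_gene: list[str] = []
    for gene, k in zip(genes, n_constructs_per_gene):
        constructs.extend(construct_ids(gene, int(k)))
        construct_gene.extend([gene] * int(k))

    unknown_constructs = effects.cytotoxic_construct_ids - set(constructs)
    if unknown_constructs:
        raise ConfigurationError(
            "cytotoxic_construct_ids not in the design: "
            f"{sorted(unknown_constructs)}")

    # Per-construct effect status (penetrance draw; one per construct so
    # different shRNAs of one gene can differ in strength).
    is_diff_gene = np.array(
        [g in effects.differentiator_gene_ids for g in construct_gene])
    penetrant = rng.random(len(constructs)) < effects.per_construct_effect_penetrance
    effect_active = is_diff_gene & penetrant
    is_toxic = np.array(
        [c in effects.cytotoxic_construct_ids for c in constructs])

    # ---- well layout -----------------------------------------------------
    r = design.replicates_per_construct
    slots = design.treatment_wells_per_plate
    n_treat_wells = len(constructs) * r
    n_plates = -(-n_treat_wells // slots)

    well_rows: list[tuple] = []   # (plate_idx, role, construct, gene, rep)
    for ci, construct in enumerate(constructs):
        for rep in range(1, r + 1):
            slot = ci * r + (rep - 1)
            well_rows.append(
                (slot // slots, ROLE_TREATMENT, construct,
                 construct_gene[ci], rep))

    n_ctrl_chunks = -(-design.controls_per_plate // r)
    for p in range(n_plates):
        remaining = design.controls_per_plate
        for c in range(n_ctrl_chunks):
            size = min(r, remaining)
            remaining -= size
            role = CONTROL_ROLES[c % len(CONTROL_ROLES)]
            ctrl_id = f"ctrl-P{p + 1:02d}-{c + 1:02d}"
            for rep in range(1, size + 1):
                well_rows.append((p, role, ctrl_id, None, rep))
        for line_role in GATING_ROLES:
            for rep in range(1, design.n_gating_control_wells_per_line + 1):
                well_rows.append((p, line_role, None, None, rep))

    # stable ordering: by plate, treatments first, then controls, then gating
    role_order = {ROLE_TREATMENT: 0}
    role_order.update({role: 1 for role in CONTROL_ROLES})
    role_order.update({role: 2 for role in GATING_ROLES})
    well_rows.sort(key=lambda t: (t[0], role_order[t[1]]))

    plate_ids = [f"P{p + 1:02d}" for p in range(n_plates)]
    well_ids: list[str] = []
    counter_per_plate = [0] * n_plates
    for row in well_rows:
        p = row[0]
        counter_per_plate[p] += 1
        well_ids.append(f"{plate_ids[p]}-W{counter_per_plate[p]:03d}")

    annotations = pd.DataFrame({
        "well_id": well_ids,
        "plate_id": [plate_ids[row[0]] for row in well_rows],
        "role": [row[1] for row in well_rows],
        "construct_id": [row[2] for row in well_rows],
        "gene_id": [row[3] for row in well_rows],
        "replicate_index": [row[4] for row in well_rows],
    })

    # ---- per-well composition and cell counts ---------------------------
    n_wells = len(annotations)
    construct_index = {c: i for i, c in enumerate(constructs)}
    well_construct = annotations["construct_id"].to_numpy()
    well_role = annotations["role"].to_numpy()

    well_effect = np.zeros(n_wells, dtype=bool)
    well_toxic = np.zeros(n_wells, dtype=bool)
    treat_mask = well_role == ROLE_TREATMENT
    treat_cidx = np.array(
        [construct_index[c] for c in well_construct[treat_mask]])
    well_effect[treat_mask] = effect_active[treat_cidx]
    well_toxic[treat_mask] = is_toxic[treat_cidx]

    probs = np.tile(np.array(effects.baseline_fractions()), (n_wells, 1))
    probs[well_effect] = effects.effect_fractions()
    probs[well_role == "gating_mcf7"] = (0.0, 0.0, 1.0, 0.0)
    probs[well_role == "gating_mcf10a"] = (0.0, 1.0, 0.0, 0.0)

    mean_counts = np.where(well_toxic, effects.cytotoxic_cell_count_mean,
                           design.cells_per_well_mean).astype(float)
    sigma = _well_count_rng_sigma(effects.well_to_well_cv)
    well_factor = rng.lognormal(-0.5 * sigma * sigma, sigma, size=n_wells)
    counts = rng.poisson(mean_counts * well_factor)

    class_counts = rng.multinomial(counts, probs)   # (n_wells, 4)

    # ---- per-cell draws --------------------------------------------------
    n_cells = int(counts.sum())
    cell_well = np.repeat(np.arange(n_wells), counts)
    cell_class = np.repeat(
        np.tile(np.arange(4), n_wells), class_counts.ravel())

    log_means = intensity.population_log_means()
    k5 = rng.lognormal(log_means[cell_class, 0], intensity.k5_log_sd)
    k8 = rng.lognormal(log_means[cell_class, 1], intensity.k8_log_sd)
    pyknotic = rng.random(n_cells) < intensity.pyknotic_fraction

    big_frac = np.where(well_effect, intensity.big_cell_fraction_effect,
                        intensity.big_cell_fraction_baseline)
    big = rng.random(n_cells) < big_frac[cell_well]
    area = rng.lognormal(
        np.where(big, intensity.area_log_mean_big,
                 intensity.area_log_mean_small),
        intensity.area_log_sd)

    cells = pd.DataFrame({
        "cell_id": np.arange(n_cells, dtype=np.int64),
        "well_id": pd.Categorical.from_codes(cell_well, categories=well_ids),
        "intensity_k5": k5,
        "intensity_k8": k8,
        "cell_area": area,
        "pyknotic": pyknotic,
    })

    true_fractions = pd.DataFrame(
        probs, columns=[f"frac_{p.lower()}" for p in POPULATIONS])
    true_fractions.insert(0, "well_id", well_ids)

    truth = GroundTruth(
        differentiator_gene_ids=frozenset(effects.differentiator_gene_ids),
        effect_construct_ids=frozenset(
            np.array(constructs)[effect_active].tolist()),
        cytotoxic_construct_ids=frozenset(effects.cytotoxic_construct_ids),
        true_fractions=true_fractions,
    )
    return cells, annotations, truth


# ---------------------------------------------------------------------------
# qPCR fixture generator
# ---------------------------------------------------------------------------

_DEFAULT_REFERENCE_CT = 20.0
_DEFAULT_TARGET_CT = 24.0


def generate_qpcr_table(
    true_ratios: Mapping[str, float],
    n_samples: int = 3,
    efficiencies: Mapping[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    reference_gene: str = "HPRT1",
) -> pd.DataFrame:
    """Simulate a Ct table whose efficiency-corrected ratios are known.

    ``true_ratios`` maps each target gene to its knockdown/control
    expression ratio. Knockdown target Cts are shifted by
    ``-log_E(ratio)`` cycles relative to the control condition while the
    reference gene is left unchanged, so with ``noise_sd = 0`` the
    relative-quantification step recovers the planted ratios exactly.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    if n_samples < 1:
        raise ConfigurationError("n_samples must be >= 1")
    efficiencies = dict(efficiencies or {})
    all_genes = list(true_ratios) + [reference_gene]
    for gene in all_genes:
        e = efficiencies.setdefault(gene, 2.0)
        if not 1.0 < e <= 2.0:
            raise ConfigurationError(
                f"amplification efficiency for {gene} must lie in (1, 2], "
                f"got {e!r}")
    for gene, ratio in true_ratios.items():
        if ratio <= 0:
            raise ConfigurationError(
                f"true ratio for {gene} must be positive, got {ratio!r}")

    rng = np.random.default_rng(seed)
    rows = []
    for condition in ("control", "knockdown"):
        for s in range(1, n_samples + 1):
            sample_id = f"{condition}_{s}"
            for gene in all_genes:
                base = (_DEFAULT_REFERENCE_CT if gene == reference_gene
                        else _DEFAULT_TARGET_CT)
                ct = base
                if condition == "knockdown" and gene != reference_gene:
                    ct -= math.log(true_ratios[gene], efficiencies[gene])
                if noise_sd > 0:
                    ct += rng.normal(0.0, noise_sd)
                rows.append((sample_id, condition, gene, ct))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene", "ct"])


# ---------------------------------------------------------------------------
# DE-table fixture generator
# ---------------------------------------------------------------------------

def generate_de_tables(
    n_genes: int = 2000,
    n_shared_up: int = 50,
    n_shared_down: int = 30,
    n_unique_each: int = 20,
    n_boundary: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, set[str]]]:
    """Two paired differential-expression tables with planted overlap.

    Planted regulated genes lie strictly beyond the |log2FC| > 0.5,
    adjusted p < 0.05 cutoffs; unplanted genes lie strictly inside.
    ``n_unique_each`` regulated genes per direction are unique to each
    signature. ``n_boundary`` genes sit exactly on the fold-change
    boundary (|log2FC| = 0.5) with a tiny adjusted p; the strict cutoff
    must exclude them, and the truth sets list them as unregulated.
    """
    for name, v in {"n_genes": n_genes, "n_shared_up": n_shared_up,
                    "n_shared_down": n_shared_down,
                    "n_unique_each": n_unique_each,
                    "n_boundary": n_boundary}.items():
        if v < 0 or int(v) != v:
            raise ConfigurationError(f"{name} must be a non-negative integer")
    planted = n_shared_up + n_shared_down + 4 * n_unique_each + n_boundary
    if planted > n_genes:
        raise ConfigurationError(
            f"planted gene counts ({planted}) exceed n_genes ({n_genes})")

    rng = np.random.default_rng(seed)
    genes = np.array([f"de_g{i:05d}" for i in range(1, n_genes + 1)])
    order = rng.permutation(n_genes)

    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = genes[order[cursor:cursor + k]]
        cursor += k
        return out

    shared_up = take(n_shared_up)
    shared_down = take(n_shared_down)
    unique_up_a = take(n_unique_each)
    unique_down_a = take(n_unique_each)
    unique_up_b = take(n_unique_each)
    unique_down_b = take(n_unique_each)
    boundary = take(n_boundary)

    def null_lfc(size):
        return rng.uniform(-0.45, 0.45, size)

    def null_p(size):
        return rng.uniform(0.06, 0.99, size)

    def hit_lfc(size, sign):
        return sign * rng.uniform(1.0, 3.0, size)

    def hit_p(size):
        return rng.uniform(1e-8, 1e-3, size)

    tables = []
    for up, down in ((set(shared_up) | set(unique_up_a),
                      set(shared_down) | set(unique_down_a)),
                     (set(shared_up) | set(unique_up_b),
                      set(shared_down) | set(unique_down_b))):
        lfc = null_lfc(n_genes)
        adj_p = null_p(n_genes)
        up_mask = np.isin(genes, list(up))
        down_mask = np.isin(genes, list(down))
        bnd_mask = np.isin(genes, list(boundary))
        lfc[up_mask] = hit_lfc(up_mask.sum(), +1.0)
        lfc[down_mask] = hit_lfc(down_mask.sum(), -1.0)
        adj_p[up_mask | down_mask] = hit_p((up_mask | down_mask).sum())
        # boundary genes: significant p but fold change exactly on the cutoff
        lfc[bnd_mask] = 0.5 * np.where(rng.random(bnd_mask.sum()) < 0.5,
                                       1.0, -1.0)
        adj_p[bnd_mask] = 1e-6
        tables.append(pd.DataFrame({
            "gene_id": genes,
            "log2fc": lfc,
            "p": adj_p,
            "adj_p": adj_p,
        }))

    truth = {
        "shared_up": set(shared_up),
        "shared_down": set(shared_down),
        "unique_up_a": set(unique_up_a),
        "unique_down_a": set(unique_down_a),
        "unique_up_b": set(unique_up_b),
        "unique_down_b": set(unique_down_b),
        "boundary": set(boundary),
    }
    return tables[0], tables[1], truth
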
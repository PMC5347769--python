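"""Downstream quantification: relative qPCR expression, DE filtering, overlap.

Relative expression follows the efficiency-corrected ratio method
(Pfaffl):

    ratio = E_target^ΔCt_target / E_reference^ΔCt_reference,
    ΔCt = Ct(control) − Ct(sample),

with the reference gene (HPRT1 by default) normalizing for input
amounts and per-primer amplification efficiencies E in (1, 2] (2 means
perfect doubling each cycle and is the default when no standard-curve
efficiency is available).

Differential-expression tables are filtered at strict cutoffs
(log2 fold change > 0.5 for up, < −0.5 for down, adjusted p < 0.05);
if only raw p values are supplied they are adjusted by the
Benjamini–Hochberg step-up procedure first. Two filtered signatures
are compared by exact set intersection per direction (Venn counting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InputValidationError

DEFAULT_REFERENCE_GENE = "HPRT1"
DEFAULT_LFC_CUTOFF = 0.5
DEFAULT_ALPHA = 0.05


def _check_efficiency(value: float, name: str) -> float:
    if not 1.0 < value <= 2.0:
        raise ConfigurationError(
            f"{name} must lie in (1, 2], got {value!r}")
    return float(value)


def _check_ct(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise InputValidationError(
            f"{name} must be finite and > 0, got {value!r}")
    return value


def pfaffl_ratio(
    ct_target_control: float,
    ct_target_sample: float,
    ct_reference_control: float,
    ct_reference_sample: float,
    efficiency_target: float = 2.0,
    efficiency_reference: float = 2.0,
) -> float:
    """Efficiency-corrected expression ratio of sample relative to control.

    A sample identical to its control (both ΔCt zero) has ratio exactly
    1, matching the convention of setting control expression to 1.
    """
    e_t = _check_efficiency(efficiency_target, "efficiency_target")
    e_r = _check_efficiency(efficiency_reference, "efficiency_reference")
    d_target = (_check_ct(ct_target_control, "ct_target_control")
                - _check_ct(ct_target_sample, "ct_target_sample"))
    d_reference = (_check_ct(ct_reference_control, "ct_reference_control")
                   - _check_ct(ct_reference_sample, "ct_reference_sample"))
    return e_t ** d_target / e_r ** d_reference


@dataclass(frozen=True)
class PfafflResult:
    """Replicate-summarized relative expression for one target gene."""

    target_gene: str
    reference_gene: str
    ratio: float
    sem: float            # delta-method propagation of Ct-mean SEMs
    n_control: int
    n_knockdown: int


def pfaffl_from_table(
    table: pd.DataFrame,
    target_gene: str,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    efficiencies: Mapping[str, float] | None = None,
) -> PfafflResult:
    """Relative expression from a long Ct table.

    The table needs columns ``sample_id, condition, gene, ct`` with
    conditions ``control`` and ``knockdown``. Replicates are summarized
    by mean Ct before the ratio; the SEM of the ratio is propagated
    from the Ct-mean standard errors by the delta method on the log
    scale (NaN when any condition has a single replicate).
    """
    required = {"sample_id", "condition", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise InputValidationError(
            f"qPCR table missing columns: {sorted(missing)}")
    efficiencies = dict(efficiencies or {})
    e_t = _check_efficiency(efficiencies.get(target_gene, 2.0),
                            f"efficiency for {target_gene}")
    e_r = _check_efficiency(efficiencies.get(reference_gene, 2.0),
                            f"efficiency for {reference_gene}")

    stats: dict[tuple[str, str], tuple[float, float, int]] = {}
    for condition in ("control", "knockdown"):
        for gene in (target_gene, reference_gene):
            cts = table.loc[(table["condition"] == condition)
                            & (table["gene"] == gene), "ct"]
            if cts.empty:
                raise InputValidationError(
                    f"no Ct values for gene {gene!r} in condition "
                    f"{condition!r}")
            vals = np.array([_check_ct(v, "ct") for v in cts])
            sem = (vals.std(ddof=1) / math.sqrt(len(vals))
                   if len(vals) > 1 else float("nan"))
            stats[(condition, gene)] = (float(vals.mean()), sem, len(vals))

    ratio = pfaffl_ratio(
        stats[("control", target_gene)][0],
        stats[("knockdown", target_gene)][0],
        stats[("control", reference_gene)][0],
        stats[("knockdown", reference_gene)][0],
        efficiency_target=e_t, efficiency_reference=e_r)

    var_log = (math.log(e_t) ** 2
               * (stats[("control", target_gene)][1] ** 2
                  + stats[("knockdown", target_gene)][1] ** 2)
               + math.log(e_r) ** 2
               * (stats[("control", reference_gene)][1] ** 2
                  + stats[("knockdown", reference_gene)][1] ** 2))
    return PfafflResult(
        target_gene=target_gene,
        reference_gene=reference_gene,
        ratio=ratio,
        sem=ratio * math.sqrt(var_log),
        n_control=min(stats[("control", g)][2]
                      for g in (target_gene, reference_gene)),
        n_knockdown=min(stats[("knockdown", g)][2]
                        for g in (target_gene, reference_gene)),
    )


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise InputValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_filter(
    de_table: pd.DataFrame,
    lfc_cutoff: float = DEFAULT_LFC_CUTOFF,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[set[str], set[str]]:
    """Strict-cutoff up/down gene sets from a DE table.

    up: log2FC > ``lfc_cutoff`` and adjusted p < ``alpha``;
    down: log2FC < −``lfc_cutoff`` and adjusted p < ``alpha``.
    Both inequalities are strict, so a gene exactly at the fold-change
    cutoff is excluded. Supplied ``adj_p`` values take precedence; when
    absent they are computed from ``p`` by Benjamini–Hochberg.
    """
    if "gene_id" not in de_table.columns:
        raise InputValidationError("DE table must have a gene_id column")
    if "log2fc" not in de_table.columns:
        raise InputValidationError("DE table must have a log2fc column")
    lfc = de_table["log2fc"].to_numpy(dtype=float)
    if np.isnan(lfc).any():
        raise InputValidationError("log2fc contains missing values")
    if "adj_p" in de_table.columns and de_table["adj_p"].notna().all():
        adj = de_table["adj_p"].to_numpy(dtype=float)
        if len(adj) and (adj.min() < 0 or adj.max() > 1):
            raise InputValidationError("adj_p values must lie in [0, 1]")
    elif "p" in de_table.columns:
        adj = bh_adjust(de_table["p"].to_numpy(dtype=float))
    else:
        raise InputValidationError(
            "DE table needs an adj_p or p column")
    genes = de_table["gene_id"].astype(str).to_numpy()
    significant = adj < alpha
    up = set(genes[(lfc > lfc_cutoff) & significant])
    down = set(genes[(lfc < -lfc_cutoff) & significant])
    return up, down


@dataclass(frozen=True)
class OverlapCounts:
    """Per-direction signature sizes and exact overlap counts."""

    up_a: int
    down_a: int
    up_b: int
    down_b: int
    shared_up: int
    shared_down: int
    shared_up_genes: frozenset[str] = frozenset()
    shared_down_genes: frozenset[str] = frozenset()

    def to_dict(self) -> dict:
        return {
            "up_a": self.up_a, "down_a": self.down_a,
            "up_b": self.up_b, "down_b": self.down_b,
            "shared_up": self.shared_up, "shared_down": self.shared_down,
            "shared_up_genes": sorted(self.shared_up_genes),
            "shared_down_genes": sorted(self.shared_down_genes),
        }


def venn_overlap(
    up_a: Iterable[str], down_a: Iterable[str],
    up_b: Iterable[str], down_b: Iterable[str],
) -> OverlapCounts:
    """Exact per-direction intersection counts between two signatures."""
    up_a, down_a = set(up_a), set(down_a)
    up_b, down_b = set(up_b), set(down_b)
    shared_up = up_a & up_b
    shared_down = down_a & down_b
    return OverlapCounts(
        up_a=len(up_a), down_a=len(down_a),
        up_b=len(up_b), down_b=len(down_b),
        shared_up=len(shared_up), shared_down=len(shared_down),
        shared_up_genes=frozenset(shared_up),
        shared_down_genes=frozenset(shared_down),
    )
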
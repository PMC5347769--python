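"""Brute-force re-implementation of the screen analysis for oracle tests.

Pure-python loops and the ``statistics`` module only — deliberately
independent of the vectorized implementation under test. Works from the
raw cell and annotation tables.
"""

import math
import statistics
from collections import defaultdict


def _rows(df):
    return df.to_dict("records")


def oracle_thresholds(cells, annotations, z=2.5):
    role_of = {r["well_id"]: r["role"] for r in _rows(annotations)}
    k5, k8 = [], []
    for row in _rows(cells):
        if row["pyknotic"]:
            continue
        role = role_of[str(row["well_id"])]
        if role == "gating_mcf7":
            k5.append(row["intensity_k5"])
        elif role == "gating_mcf10a":
            k8.append(row["intensity_k8"])
    return (statistics.mean(k5) + z * statistics.stdev(k5),
            statistics.mean(k8) + z * statistics.stdev(k8))


def oracle_classify(row, k5_threshold, k8_threshold):
    if row["pyknotic"]:
        return "excluded_pyknotic"
    k5 = row["intensity_k5"] > k5_threshold
    k8 = row["intensity_k8"] > k8_threshold
    if k5 and k8:
        return "DP"
    if k5:
        return "K5_only"
    if k8:
        return "K8_only"
    return "DN"


def oracle_well_summaries(cells, k5_threshold, k8_threshold, min_cells=200):
    per_well = defaultdict(lambda: {"DP": 0, "K5_only": 0, "K8_only": 0,
                                    "DN": 0, "excluded_pyknotic": 0})
    for row in _rows(cells):
        cls = oracle_classify(row, k5_threshold, k8_threshold)
        per_well[str(row["well_id"])][cls] += 1
    out = {}
    for well, counts in per_well.items():
        n = sum(counts[c] for c in ("DP", "K5_only", "K8_only", "DN"))
        out[well] = {
            "n_analyzable": n,
            "n_pyknotic_excluded": counts["excluded_pyknotic"],
            "counts": {c: counts[c] for c in ("DP", "K5_only",
                                              "K8_only", "DN")},
            "pct": {c: (100.0 * counts[c] / n if n else 0.0)
                    for c in ("DP", "K5_only", "K8_only", "DN")},
            "qc_pass": n >= min_cells,
        }
    return out


def oracle_pipeline(cells, annotations, z=2.5, min_cells=200,
                    z_cutoff=2.5, min_constructs=2):
    """Thresholds -> summaries -> construct scores -> hits -> gene calls."""
    k5_t, k8_t = oracle_thresholds(cells, annotations, z=z)
    summaries = oracle_well_summaries(cells, k5_t, k8_t, min_cells=min_cells)

    wells_of = defaultdict(list)
    meta = {}
    for row in _rows(annotations):
        cid = row["construct_id"]
        if cid is None or (isinstance(cid, float) and math.isnan(cid)):
            continue
        wells_of[cid].append(row["well_id"])
        meta[cid] = (row["gene_id"], row["role"])

    scores = {}
    for cid, wells in wells_of.items():
        used = [summaries[w] for w in wells
                if w in summaries and summaries[w]["qc_pass"]]
        if used:
            scores[cid] = {
                "pct_k8_only": statistics.mean(
                    s["pct"]["K8_only"] for s in used),
                "pct_k5_only": statistics.mean(
                    s["pct"]["K5_only"] for s in used),
                "n_wells_used": len(used),
            }
        else:
            scores[cid] = None

    control_roles = ("control_empty", "control_nonspecific", "control_gfp")
    ctrl_vals = {m: [scores[c][m] for c in scores
                     if meta[c][1] in control_roles and scores[c]]
                 for m in ("pct_k8_only", "pct_k5_only")}
    stats = {m: (statistics.mean(v), statistics.stdev(v))
             for m, v in ctrl_vals.items()}

    hit_calls = {}
    for cid, score in scores.items():
        if score is None:
            hit_calls[cid] = {"status": "not_scored",
                              "hit_k8_only": False, "hit_k5_only": False}
            continue
        call = {"status": "scored"}
        for m in ("pct_k8_only", "pct_k5_only"):
            mean, sd = stats[m]
            if sd > 0:
                z_val = (score[m] - mean) / sd
            else:
                z_val = (math.inf if score[m] > mean
                         else (-math.inf if score[m] < mean else 0.0))
            call[f"z_{m.removeprefix('pct_')}"] = z_val
            call[f"hit_{m.removeprefix('pct_')}"] = z_val >= z_cutoff
        hit_calls[cid] = call

    per_gene = defaultdict(lambda: {"k8": 0, "k5": 0})
    for cid, call in hit_calls.items():
        gene, role = meta[cid]
        if role != "treatment":
            continue
        per_gene[gene]["k8"] += call["hit_k8_only"]
        per_gene[gene]["k5"] += call["hit_k5_only"]
    gene_hits = {g for g, c in per_gene.items()
                 if max(c["k8"], c["k5"]) >= min_constructs}

    n_ctrl = len(ctrl_vals["pct_k8_only"])
    n_ctrl_hits = sum(
        1 for cid, call in hit_calls.items()
        if meta[cid][1] in control_roles and call["status"] == "scored"
        and (call["hit_k8_only"] or call["hit_k5_only"]))
    return {
        "thresholds": (k5_t, k8_t),
        "summaries": summaries,
        "scores": scores,
        "control_stats": stats,
        "hit_calls": hit_calls,
        "gene_hits": gene_hits,
        "background_hit_frequency": n_ctrl_hits / n_ctrl,
    }


def oracle_bh(p_values):
    """Exhaustive step-up: adj(i) = min over j>=i (rank) of p(j)*m/j, cap 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [None] * m
    for rank_index, i in enumerate(order):
        candidates = []
        for later_rank in range(rank_index, m):
            j = order[later_rank]
            candidates.append(p_values[j] * m / (later_rank + 1))
        adjusted[i] = min(1.0, min(candidates))
    return adjusted
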
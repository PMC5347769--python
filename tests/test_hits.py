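"""Construct scoring, control null, hit/gene calling, screen frequencies."""

import numpy as np
import pandas as pd
import pytest

import bilineage as bl
from bilineage.errors import CalibrationError, InputValidationError
from bilineage.hits import STATUS_NOT_SCORED, STATUS_SCORED

from _oracle import oracle_pipeline


def _summary_row(well_id, pct_k8=4.0, pct_k5=6.0, n=1000, qc=True,
                 count_k8=None):
    count_k8 = int(round(pct_k8 / 100 * n)) if count_k8 is None else count_k8
    return {
        "well_id": well_id, "n_analyzable": n, "n_pyknotic_excluded": 0,
        "count_dp": 0, "count_k5_only": 0, "count_k8_only": count_k8,
        "count_dn": 0, "pct_dp": 0.0, "pct_k5_only": pct_k5,
        "pct_k8_only": pct_k8, "pct_dn": 0.0, "qc_pass": qc,
    }


def _annotation_row(well_id, role="treatment", construct="c1", gene="g1",
                    rep=1):
    return {"well_id": well_id, "plate_id": "P01", "role": role,
            "construct_id": construct, "gene_id": gene,
            "replicate_index": rep}


class TestScoreConstructs:
    def test_triplicate_mean(self):
        summaries = pd.DataFrame([
            _summary_row("w1", pct_k8=10.0),
            _summary_row("w2", pct_k8=12.0),
            _summary_row("w3", pct_k8=14.0),
        ])
        ann = pd.DataFrame([_annotation_row(f"w{i}", rep=i)
                            for i in (1, 2, 3)])
        scores = bl.score_constructs(summaries, ann)
        assert len(scores) == 1
        assert scores.loc[0, "pct_k8_only"] == pytest.approx(12.0)
        assert scores.loc[0, "n_wells_used"] == 3
        assert scores.loc[0, "status"] == STATUS_SCORED

    def test_qc_failed_replicate_dropped_from_mean(self):
        summaries = pd.DataFrame([
            _summary_row("w1", pct_k8=99.0, n=50, qc=False),
            _summary_row("w2", pct_k8=10.0),
            _summary_row("w3", pct_k8=14.0),
        ])
        ann = pd.DataFrame([_annotation_row(f"w{i}", rep=i)
                            for i in (1, 2, 3)])
        scores = bl.score_constructs(summaries, ann)
        assert scores.loc[0, "pct_k8_only"] == pytest.approx(12.0)
        assert scores.loc[0, "n_wells_used"] == 2

    def test_all_wells_failed_emits_not_scored(self):
        summaries = pd.DataFrame([
            _summary_row(f"w{i}", n=150, qc=False) for i in (1, 2, 3)])
        ann = pd.DataFrame([_annotation_row(f"w{i}", rep=i)
                            for i in (1, 2, 3)])
        scores = bl.score_constructs(summaries, ann)
        assert scores.loc[0, "status"] == STATUS_NOT_SCORED
        assert scores.loc[0, "n_wells_used"] == 0
        assert np.isnan(scores.loc[0, "pct_k8_only"])

    def test_conflicting_gene_annotation_rejected(self):
        summaries = pd.DataFrame([_summary_row("w1"), _summary_row("w2")])
        ann = pd.DataFrame([
            _annotation_row("w1", gene="g1"),
            _annotation_row("w2", gene="g2", rep=2),
        ])
        with pytest.raises(InputValidationError, match="conflicting"):
            bl.score_constructs(summaries, ann)


def _control_scores(values, metric="pct_k8_only"):
    rows = []
    for i, v in enumerate(values):
        rows.append({
            "construct_id": f"ctrl-{i}", "gene_id": None,
            "role": "control_empty", "n_wells_total": 3, "n_wells_used": 3,
            "status": STATUS_SCORED, "pct_k8_only": 4.0, "pct_k5_only": 6.0,
            "mean_analyzable_cells": 1000.0, "mean_count_k8_only": 40.0,
        })
        rows[-1][metric] = v
    return pd.DataFrame(rows)


class TestControlStatistics:
    def test_constant_controls(self):
        cs = bl.control_statistics(_control_scores([4.0, 4.0, 4.0]))
        assert cs.mean["pct_k8_only"] == 4.0
        assert cs.sd["pct_k8_only"] == 0.0
        assert cs.n_constructs == 3

    def test_hand_computed_sample_sd(self):
        cs = bl.control_statistics(_control_scores([2.0, 4.0, 6.0]))
        assert cs.mean["pct_k8_only"] == pytest.approx(4.0)
        assert cs.sd["pct_k8_only"] == pytest.approx(2.0)

    def test_gating_rows_never_enter_null_pool(self):
        scores = _control_scores([2.0, 4.0, 6.0])
        gating_row = scores.iloc[0].copy()
        gating_row["construct_id"] = "mcf7-like"
        gating_row["role"] = "gating_mcf7"
        gating_row["pct_k8_only"] = 99.0
        scores = pd.concat([scores, gating_row.to_frame().T],
                           ignore_index=True)
        cs = bl.control_statistics(scores)
        assert cs.n_constructs == 3
        assert cs.mean["pct_k8_only"] == pytest.approx(4.0)

    def test_too_few_controls_raises(self):
        with pytest.raises(CalibrationError, match="at least 2"):
            bl.control_statistics(_control_scores([4.0]))


class TestCallHits:
    def _scores_with(self, pct_k8):
        df = _control_scores([2.0, 4.0, 6.0])
        row = df.iloc[0].copy()
        row["construct_id"] = "g1-sh1"
        row["gene_id"] = "g1"
        row["role"] = "treatment"
        row["pct_k8_only"] = pct_k8
        return pd.concat([df, row.to_frame().T], ignore_index=True)

    def test_hand_arithmetic_z3_is_hit(self):
        scores = self._scores_with(10.0)    # (10-4)/2 = 3
        calls = bl.call_hits(scores, bl.control_statistics(scores))
        row = calls.set_index("construct_id").loc["g1-sh1"]
        assert row["z_k8_only"] == pytest.approx(3.0)
        assert row["is_hit"] and row["hit_k8_only"]
        assert row["direction"] == "toward_K8_only"

    def test_metric_at_control_mean_not_hit(self):
        scores = self._scores_with(4.0)
        calls = bl.call_hits(scores, bl.control_statistics(scores))
        row = calls.set_index("construct_id").loc["g1-sh1"]
        assert row["z_k8_only"] == pytest.approx(0.0)
        assert not row["is_hit"]

    def test_z_cutoff_inclusive(self):
        scores = self._scores_with(9.0)     # z exactly 2.5
        calls = bl.call_hits(scores, bl.control_statistics(scores))
        assert calls.set_index("construct_id").loc["g1-sh1", "is_hit"]

    def test_published_effect_size_is_hit(self):
        """Control 4% vs construct 24% (SD 2) is far beyond z = 2.5."""
        scores = self._scores_with(24.0)
        calls = bl.call_hits(scores, bl.control_statistics(scores))
        row = calls.set_index("construct_id").loc["g1-sh1"]
        assert row["is_hit"]
        assert row["z_k8_only"] == pytest.approx(10.0)

    def test_zero_control_sd_sentinel(self):
        df = _control_scores([4.0, 4.0, 4.0])
        row = df.iloc[0].copy()
        row["construct_id"] = "g1-sh1"
        row["role"] = "treatment"
        row["pct_k8_only"] = 4.5
        scores = pd.concat([df, row.to_frame().T], ignore_index=True)
        calls = bl.call_hits(scores, bl.control_statistics(scores))
        got = calls.set_index("construct_id")
        assert np.isinf(got.loc["g1-sh1", "z_k8_only"])
        assert got.loc["g1-sh1", "is_hit"]
        assert got.loc["ctrl-0", "z_k8_only"] == 0.0

    def test_not_scored_propagates(self):
        df = _control_scores([2.0, 4.0, 6.0])
        row = df.iloc[0].copy()
        row["construct_id"] = "g1-sh1"
        row["role"] = "treatment"
        row["status"] = STATUS_NOT_SCORED
        for m in ("pct_k8_only", "pct_k5_only"):
            row[m] = np.nan
        scores = pd.concat([df, row.to_frame().T], ignore_index=True)
        calls = bl.call_hits(scores, bl.control_statistics(scores))
        got = calls.set_index("construct_id").loc["g1-sh1"]
        assert got["status"] == STATUS_NOT_SCORED
        assert not got["is_hit"]
        assert np.isnan(got["z_k8_only"])

    def test_direction_restriction(self):
        df = _control_scores([2.0, 4.0, 6.0])
        row = df.iloc[0].copy()
        row["construct_id"] = "g1-sh1"
        row["role"] = "treatment"
        row["pct_k5_only"] = 50.0
        scores = pd.concat([df, row.to_frame().T], ignore_index=True)
        cs = bl.control_statistics(scores)
        both = bl.call_hits(scores, cs, direction="both")
        k8 = bl.call_hits(scores, cs, direction="k8_only")
        assert both.set_index("construct_id").loc["g1-sh1", "is_hit"]
        assert not k8.set_index("construct_id").loc["g1-sh1", "is_hit"]


def _hit_calls(gene_hits):
    """gene_hits: mapping gene -> list of (hit_k8, hit_k5) per construct."""
    rows = []
    for gene, flags in gene_hits.items():
        for i, (h8, h5) in enumerate(flags):
            rows.append({
                "construct_id": f"{gene}-sh{i + 1}", "gene_id": gene,
                "role": "treatment", "status": STATUS_SCORED,
                "z_k8_only": 3.0 if h8 else 0.0,
                "z_k5_only": 3.0 if h5 else 0.0,
                "hit_k8_only": h8, "hit_k5_only": h5,
                "is_hit": h8 or h5,
                "direction": "toward_K8_only" if h8 else None,
            })
    return pd.DataFrame(rows)


class TestCallGenes:
    def test_two_constructs_same_direction_is_gene_hit(self):
        calls = _hit_calls({"g1": [(True, False), (True, False),
                                   (False, False)]})
        genes = bl.call_genes(calls)
        assert genes.loc[0, "is_gene_hit"]
        assert genes.loc[0, "direction"] == "toward_K8_only"

    def test_single_construct_not_gene_hit(self):
        calls = _hit_calls({"g1": [(True, False), (False, False)]})
        assert not bl.call_genes(calls).loc[0, "is_gene_hit"]

    def test_two_hits_in_different_directions_not_gene_hit(self):
        calls = _hit_calls({"g1": [(True, False), (False, True)]})
        assert not bl.call_genes(calls).loc[0, "is_gene_hit"]

    def test_unscored_gene_flagged(self):
        calls = _hit_calls({"g1": [(False, False)]})
        calls.loc[0, "status"] = STATUS_NOT_SCORED
        calls.loc[0, ["hit_k8_only", "hit_k5_only", "is_hit"]] = False
        genes = bl.call_genes(calls)
        assert genes.loc[0, "status"] == STATUS_NOT_SCORED
        assert not genes.loc[0, "is_gene_hit"]


class TestScreenFrequencies:
    def test_published_arithmetic(self):
        """p = 0.0237 -> p^2 = 0.00056169; 11/420 -> 0.0261905."""
        assert bl.chance_double_hit(0.0237) == pytest.approx(0.00056169)
        assert round(bl.chance_double_hit(0.0237), 5) == 0.00056
        assert 11 / 420 == pytest.approx(0.0261905, abs=5e-8)

    @pytest.mark.parametrize("p", np.linspace(0.0, 1.0, 21).tolist())
    def test_chance_double_is_exactly_p_squared(self, p):
        assert bl.chance_double_hit(p) - p * p == 0.0

    def test_counts_behind_frequencies(self):
        hit_calls = pd.DataFrame([
            {"construct_id": f"ctrl-{i}", "gene_id": None,
             "role": "control_gfp", "status": STATUS_SCORED,
             "is_hit": i == 0, "hit_k8_only": i == 0, "hit_k5_only": False,
             "z_k8_only": 3.0, "z_k5_only": 0.0, "direction": None}
            for i in range(4)])
        gene_calls = pd.DataFrame([
            {"gene_id": "g1", "is_gene_hit": True},
            {"gene_id": "g2", "is_gene_hit": False},
        ])
        freq = bl.screen_frequencies(hit_calls, gene_calls,
                                     n_genes_targeted=10)
        assert freq.background_hit_frequency == pytest.approx(0.25)
        assert freq.chance_double_hit_probability == pytest.approx(0.0625)
        assert freq.gene_hit_frequency == pytest.approx(0.1)
        assert freq.n_control_constructs_scored == 4
        assert freq.n_gene_hits == 1

    def test_no_scored_controls_raises(self):
        hit_calls = pd.DataFrame([{
            "construct_id": "g1-sh1", "gene_id": "g1", "role": "treatment",
            "status": STATUS_SCORED, "is_hit": False,
            "hit_k8_only": False, "hit_k5_only": False,
            "z_k8_only": 0.0, "z_k5_only": 0.0, "direction": None}])
        with pytest.raises(CalibrationError, match="control"):
            bl.screen_frequencies(hit_calls, pd.DataFrame({
                "gene_id": [], "is_gene_hit": []}), 10)


class TestAbsoluteCountCheck:
    def _stats(self, mean_count):
        return bl.ControlStats(
            mean={"pct_k8_only": 4.0, "pct_k5_only": 6.0,
                  "mean_count_k8_only": mean_count},
            sd={"pct_k8_only": 1.0, "pct_k5_only": 1.0,
                "mean_count_k8_only": 5.0},
            n_constructs=3)

    def test_increase_and_tie(self):
        scores = _control_scores([4.0, 4.0])
        scores.loc[0, "mean_count_k8_only"] = 120.0
        scores.loc[1, "mean_count_k8_only"] = 100.0
        check = bl.absolute_count_check(scores, self._stats(100.0))
        assert check.loc[0, "count_increased"]
        assert not check.loc[1, "count_increased"]   # equal -> strict

    def test_percentage_hit_with_fewer_absolute_cells(self):
        """A %-hit well can still have fewer K5-K8+ cells than controls."""
        # control: 1000 analyzable cells, 4% K8_only -> 40 cells
        summaries = pd.DataFrame(
            [_summary_row(f"cw{i}", pct_k8=4.0 + i, n=1000)
             for i in range(3)]
            # construct: only 250 analyzable cells but 12% -> 30 cells
            + [_summary_row(f"tw{i}", pct_k8=12.0, n=250) for i in range(3)])
        ann = pd.DataFrame(
            [_annotation_row(f"cw{i}", role="control_empty",
                             construct=f"ctrl-{i}", gene=None, rep=1)
             for i in range(3)]
            + [_annotation_row(f"tw{i}", construct="g1-sh1", rep=i + 1)
               for i in range(3)])
        scores = bl.score_constructs(summaries, ann)
        cs = bl.control_statistics(scores)
        calls = bl.call_hits(scores, cs).set_index("construct_id")
        check = bl.absolute_count_check(scores, cs).set_index("construct_id")
        assert calls.loc["g1-sh1", "is_hit"]
        assert not check.loc["g1-sh1", "count_increased"]


class TestOracleEquivalence:
    def test_small_screens_match_brute_force(self):
        """Scoring -> hits -> genes equals pure-python recomputation."""
        design = bl.ScreenDesign(
            n_genes=4, constructs_per_gene=(2, 5),
            replicates_per_construct=3, cells_per_well_mean=80,
            controls_per_plate=9, wells_per_plate=96,
            n_gating_control_wells_per_line=2)
        for seed in range(3):
            cells, ann, _ = bl.generate_screen(design, seed=seed)
            th = bl.calibrate_from_tables(cells, ann)
            summ = bl.summarize_wells(cells, th, min_cells=20)
            scores = bl.score_constructs(summ, ann)
            cs = bl.control_statistics(scores)
            calls = bl.call_hits(scores, cs)
            genes = bl.call_genes(calls)
            expected = oracle_pipeline(cells, ann, min_cells=20)
            assert th.k5_threshold == pytest.approx(
                expected["thresholds"][0], rel=1e-12)
            got_hits = calls.set_index("construct_id")
            for cid, exp in expected["hit_calls"].items():
                assert (got_hits.loc[cid, "hit_k8_only"]
                        == exp["hit_k8_only"]), cid
                assert (got_hits.loc[cid, "hit_k5_only"]
                        == exp["hit_k5_only"]), cid
            assert (set(genes.loc[genes["is_gene_hit"], "gene_id"])
                    == expected["gene_hits"])
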
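import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuraxprot.io import CASE, CONTROL, AnalysisThresholds
from neuraxprot.regulation import (
    bh_adjust,
    call_regulated,
    compute_peptide_ratios,
    cross_model_venn,
    direction_map,
    protein_regulation,
    regulate_tissue,
)
from neuraxprot.simulate import SimulationConfig, simulate_study

from conftest import cell_block, make_measurements
from oracles import bh_oracle, one_sample_t_oracle


def paired_study(case_vals, control_vals, protein="P1", peptide="a", tissue="DRG"):
    rows = cell_block(protein, peptide, tissue, control_vals)
    rows += cell_block(protein, peptide, tissue, case_vals, condition=CASE)
    return make_measurements(rows)


class TestPeptideRatios:
    def test_doubling_gives_log2_ratio_one_per_pair(self):
        m = paired_study([200.0] * 3, [100.0] * 3)
        out = compute_peptide_ratios(m, "DRG")
        assert list(out["log2_ratio"]) == [1.0, 1.0, 1.0]
        assert list(out["pair_index"]) == [1, 2, 3]

    def test_powers_of_two_per_replicate_pairing(self):
        m = paired_study([100.0, 200.0, 400.0], [100.0] * 3)
        out = compute_peptide_ratios(m, "DRG")
        assert list(out["log2_ratio"]) == [0.0, 1.0, 2.0]

    def test_peptide_missing_one_cell_contributes_nothing(self):
        m = paired_study([200.0] * 3, [100.0] * 3)
        m = m[~((m.condition == CONTROL) & (m.replicate == 2))]
        out = compute_peptide_ratios(m, "DRG")
        assert out.empty

    def test_protein_absent_from_tissue_yields_no_record(self):
        # mirrors NA cells in per-tissue report tables
        m = paired_study([200.0] * 3, [100.0] * 3, tissue="SN")
        m = pd.concat(
            [m, make_measurements(cell_block("P2", "a", "DRG", [1.0] * 3))],
            ignore_index=True,
        )
        ratios = compute_peptide_ratios(m, "SN")
        records = protein_regulation(ratios)
        assert set(records["protein_id"]) == {"P1"}


class TestProteinRegulation:
    def test_textbook_one_sample_t(self):
        ratios = pd.DataFrame(
            {
                "protein_id": "P1",
                "peptide_id": "a",
                "tissue": "DRG",
                "pair_index": [1, 2, 3],
                "log2_ratio": [0.5, 0.6, 0.7],
            }
        )
        out = protein_regulation(ratios)
        assert out.loc[0, "mean_log2fc"] == pytest.approx(0.6)
        t0, df0, p0 = one_sample_t_oracle([0.5, 0.6, 0.7])
        assert t0 == pytest.approx(10.392, abs=1e-3)
        assert df0 == 2
        assert out.loc[0, "p_value"] == pytest.approx(0.00913, abs=1e-4)
        assert out.loc[0, "p_value"] == pytest.approx(p0, abs=1e-12)

    def test_symmetric_ratios_give_p_one(self):
        ratios = pd.DataFrame(
            {
                "protein_id": "P1", "peptide_id": "a", "tissue": "DRG",
                "pair_index": [1, 2, 3], "log2_ratio": [-1.0, 0.0, 1.0],
            }
        )
        out = protein_regulation(ratios)
        assert out.loc[0, "mean_log2fc"] == 0.0
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_all_zero_ratios_give_p_one_not_regulated(self):
        out = regulate_tissue(paired_study([100.0] * 3, [100.0] * 3), "DRG")
        assert out.loc[0, "p_value"] == 1.0
        assert not out.loc[0, "regulated"]

    def test_constant_nonzero_ratios_untestable_and_out_of_bh_family(self):
        out = regulate_tissue(paired_study([200.0] * 3, [100.0] * 3), "DRG")
        assert out.loc[0, "untestable"]
        assert math.isnan(out.loc[0, "p_value"])
        assert math.isnan(out.loc[0, "q_value"])
        assert not out.loc[0, "regulated"]

    def test_pooled_vs_pair_means_sample_unit(self):
        rows = cell_block("P1", "a", "DRG", [100.0] * 3)
        rows += cell_block("P1", "a", "DRG", [150.0, 210.0, 290.0], condition=CASE)
        rows += cell_block("P1", "b", "DRG", [100.0] * 3)
        rows += cell_block("P1", "b", "DRG", [160.0, 190.0, 310.0], condition=CASE)
        m = make_measurements(rows)
        ratios = compute_peptide_ratios(m, "DRG")
        pooled = protein_regulation(ratios, sample_unit="pooled")
        pair_means = protein_regulation(ratios, sample_unit="pair_means")
        assert pooled.loc[0, "n_ratios"] == 6
        # same point estimate, different test granularity
        assert pooled.loc[0, "mean_log2fc"] == pytest.approx(
            pair_means.loc[0, "mean_log2fc"]
        )
        assert pooled.loc[0, "p_value"] != pair_means.loc[0, "p_value"]

    def test_n_ratios_is_three_per_peptide(self, simple_study):
        ratios = compute_peptide_ratios(simple_study, "DRG")
        records = protein_regulation(ratios)
        by_id = records.set_index("protein_id")
        assert by_id.loc["P1", "n_ratios"] == 3 * by_id.loc["P1", "n_peptides"]

    def test_swapping_case_and_control_negates_fc_keeps_p_and_q(self):
        rng = np.random.default_rng(5)
        rows = []
        for prot in ("P1", "P2", "P3"):
            for pep in ("a", "b"):
                rows += cell_block(prot, f"{prot}_{pep}", "DRG",
                                   rng.lognormal(10, 0.2, 3))
                rows += cell_block(prot, f"{prot}_{pep}", "DRG",
                                   rng.lognormal(10.5, 0.2, 3), condition=CASE)
        m = make_measurements(rows)
        fwd = regulate_tissue(m, "DRG").set_index("protein_id")
        rev = regulate_tissue(
            m, "DRG", control=CASE, case=CONTROL
        ).set_index("protein_id")
        assert np.allclose(fwd["mean_log2fc"], -rev["mean_log2fc"])
        assert np.allclose(fwd["p_value"], rev["p_value"])
        assert np.allclose(fwd["q_value"], rev["q_value"])


class TestBHAdjust:
    def test_hand_step_up_examples(self):
        assert np.allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        assert np.allclose(bh_adjust([0.03]), [0.03])
        assert np.allclose(bh_adjust([0.005, 0.05]), [0.01, 0.05])

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_q_dominates_p_and_preserves_order(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all()
        assert (q <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_nan_entries_excluded_from_family(self):
        q = bh_adjust([0.01, math.nan, 0.04])
        assert math.isnan(q[1])
        # family size m=2, not 3
        assert np.allclose([q[0], q[2]], bh_oracle([0.01, 0.04]))


class TestCallRegulated:
    def records(self, q_values):
        n = len(q_values)
        base = pd.DataFrame(
            {
                "protein_id": [f"P{i}" for i in range(n)],
                "tissue": "DRG",
                "mean_log2fc": 0.28,
                "p_value": q_values,  # single-tissue family: q == p when sorted flat
                "n_peptides": 2,
                "n_ratios": 6,
                "untestable": False,
            }
        )
        return base

    def test_q_below_threshold_regulated(self):
        out = call_regulated(self.records([0.001]))
        assert bool(out.loc[0, "regulated"])
        assert not out.loc[0, "low_confidence"]

    def test_q_above_threshold_not_regulated(self):
        out = call_regulated(self.records([0.265]))
        assert not out.loc[0, "regulated"]

    def test_q_exactly_at_threshold_not_regulated(self):
        out = call_regulated(self.records([0.05]))
        assert out.loc[0, "q_value"] == pytest.approx(0.05)
        assert not out.loc[0, "regulated"]

    def test_single_peptide_regulated_is_low_confidence(self):
        rec = self.records([0.001])
        rec["n_peptides"] = 1
        out = call_regulated(rec)
        assert bool(out.loc[0, "low_confidence"])

    def test_bh_family_is_per_tissue(self):
        rec = pd.concat(
            [
                self.records([0.01, 0.04]),
                self.records([0.03]).assign(tissue="SN"),
            ],
            ignore_index=True,
        )
        out = call_regulated(rec)
        drg = out[out.tissue == "DRG"]
        assert np.allclose(sorted(drg["q_value"]), [0.02, 0.04])
        assert out.loc[out.tissue == "SN", "q_value"].iloc[0] == 0.03


class TestCrossModelVenn:
    def test_shared_proteins_carry_both_directions(self):
        out = cross_model_venn(
            {"A": {"P1": "up", "P2": "down"}, "B": {"P2": "up", "P3": "up"}}
        )
        by_id = out.set_index("protein_id")
        assert by_id.loc["P2", "membership"] == "A&B"
        assert by_id.loc["P2", "direction_A"] == "down"
        assert by_id.loc["P2", "direction_B"] == "up"
        assert by_id.loc["P1", "membership"] == "A"
        assert by_id.loc["P3", "membership"] == "B"

    def test_disjoint_and_identical_sets(self):
        disjoint = cross_model_venn({"A": {"P1": "up"}, "B": {"P2": "up"}})
        assert not (disjoint["membership"] == "A&B").any()
        same = cross_model_venn({"A": {"P1": "up"}, "B": {"P1": "up"}})
        assert list(same["membership"]) == ["A&B"]

    def test_direction_map_sign_convention(self):
        records = pd.DataFrame(
            {
                "protein_id": ["P1", "P2", "P3"],
                "mean_log2fc": [0.5, -0.5, 0.2],
                "regulated": [True, True, False],
            }
        )
        assert direction_map(records) == {"P1": "up", "P2": "down"}


class TestPlantedEffectRecovery:
    def test_planted_log2_effect_estimated_and_detected(self):
        errors, detected = [], 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                n_proteins=20, peptides_per_protein=3, replicate_cv=0.1,
                planted_regulated=((0, "SN", 1.0),), seed=seed,
            )
            m, _, _ = simulate_study(cfg)
            out = regulate_tissue(m, "SN").set_index("protein_id")
            errors.append(abs(out.loc["P0000", "mean_log2fc"] - 1.0))
            detected += bool(out.loc["P0000", "regulated"])
        assert np.mean(errors) <= 0.15
        assert detected / n_seeds >= 0.8
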
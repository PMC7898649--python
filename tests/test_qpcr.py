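"""Plate calibration, reference stability, relative quantification, rank tests."""

import numpy as np
import pandas as pd
import pytest

import casteseq as cs
from casteseq import qpcr as qp
from conftest import mannwhitney_two_sided_oracle


def plate_rows(plate_id, gene_values, ipc_cq):
    """gene_values: {(gene, sample): cq}"""
    rows = [
        {"plate_id": plate_id, "well": f"W{i}", "gene_id": g, "sample_id": s,
         "Cq": cq, "is_IPC": False}
        for i, ((g, s), cq) in enumerate(gene_values.items())
    ]
    rows.append({"plate_id": plate_id, "well": "IPC", "gene_id": "IPC",
                 "sample_id": "IPC", "Cq": ipc_cq, "is_IPC": True})
    return rows


class TestCalibration:
    def test_single_plate_identity(self):
        plates = pd.DataFrame(plate_rows("p1", {("g", "s1"): 24.0}, ipc_cq=20.0))
        out = qp.calibrate_plates(plates)
        pd.testing.assert_frame_equal(out, plates)

    def test_two_plate_shift(self):
        # IPC Cq 20 and 22: plate means move to the grand mean 21
        plates = pd.DataFrame(
            plate_rows("p1", {("g", "s1"): 24.0}, ipc_cq=20.0)
            + plate_rows("p2", {("g", "s2"): 24.0}, ipc_cq=22.0)
        )
        out = qp.calibrate_plates(plates).set_index("sample_id")
        assert out.loc["s1", "Cq"] == pytest.approx(25.0)  # +1
        assert out.loc["s2", "Cq"] == pytest.approx(23.0)  # -1

    def test_calibrated_ipc_equal_across_plates(self, small_design):
        plates, _, _ = cs.simulate_cq_plates(small_design, seed=5, noise_scale=0.0)
        out = qp.calibrate_plates(plates)
        ipc = out[out["is_IPC"]]
        assert ipc["Cq"].std() == pytest.approx(0.0, abs=1e-9)

    def test_within_plate_differences_preserved(self):
        plates = pd.DataFrame(
            plate_rows("p1", {("g", "s1"): 24.0, ("g", "s2"): 26.5}, ipc_cq=20.0)
            + plate_rows("p2", {("g", "s3"): 30.0}, ipc_cq=23.0)
        )
        out = qp.calibrate_plates(plates).set_index("sample_id")
        assert out.loc["s2", "Cq"] - out.loc["s1", "Cq"] == pytest.approx(2.5)

    def test_missing_ipc_is_error(self):
        rows = plate_rows("p1", {("g", "s1"): 24.0}, ipc_cq=20.0)
        bad = pd.DataFrame(rows[:-1] + plate_rows("p2", {("g", "s2"): 25.0}, 21.0))
        with pytest.raises(ValueError, match="p1"):
            qp.calibrate_plates(bad)


class TestGeNorm:
    def make_calibrated(self, cq_by_gene):
        rows = []
        for g, cqs in cq_by_gene.items():
            for i, cq in enumerate(cqs):
                rows.append({"plate_id": "p", "well": f"{g}{i}", "gene_id": g,
                             "sample_id": f"s{i}", "Cq": cq, "is_IPC": False})
        rows.append({"plate_id": "p", "well": "IPC", "gene_id": "IPC",
                     "sample_id": "IPC", "Cq": 20.0, "is_IPC": True})
        return pd.DataFrame(rows)

    def test_proportional_pair_beats_noisy_gene(self):
        # constant Cq difference -> SD of pairwise log-ratio 0 for the pair
        cal = self.make_calibrated({
            "A": [20.0, 21.0, 22.0, 23.0],
            "B": [21.5, 22.5, 23.5, 24.5],
            "C": [20.0, 25.0, 19.0, 27.0],
        })
        rep = qp.genorm_stability(cal, ["A", "B", "C"], {"A": 2.0, "B": 2.0, "C": 2.0})
        assert rep.m_values["A"] < rep.m_values["C"]
        assert rep.m_values["B"] < rep.m_values["C"]
        assert rep.exclusion_order[0] == "C"

    def test_all_identical_gives_zero_m(self):
        cal = self.make_calibrated({g: [20.0, 20.0, 20.0] for g in "ABC"})
        rep = qp.genorm_stability(cal, ["A", "B", "C"])
        assert all(m == pytest.approx(0.0) for m in rep.m_values.values())
        assert len(rep.recommended_references) == 2

    def test_bestkeeper_sd_is_cq_sd(self):
        cal = self.make_calibrated({
            "A": [20.0, 22.0, 24.0],
            "B": [20.0, 20.0, 20.0],
            "C": [18.0, 26.0, 19.0],
        })
        rep = qp.genorm_stability(cal, ["A", "B", "C"])
        assert rep.bestkeeper_sd["A"] == pytest.approx(np.std([20, 22, 24], ddof=1))
        assert rep.bestkeeper_sd["B"] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_generator_stability_ranking_recovered(self, seed, small_design):
        """The two most stable simulated references rank 1-2 by geNorm M."""
        plates, _, truth = cs.simulate_cq_plates(small_design, seed=seed)
        cal = qp.calibrate_plates(plates)
        candidates = sorted(truth.reference_sigmas)
        rep = qp.genorm_stability(cal, candidates, truth.efficiencies)
        ranked = sorted(rep.m_values, key=rep.m_values.get)
        assert set(ranked[:2]) == {"REF1", "REF2"}

    @pytest.mark.parametrize("seed", range(10))
    def test_excluding_worst_never_raises_mean_m(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(6)]
        cal = self.make_calibrated(
            {g: list(20 + rng.normal(0, rng.uniform(0.05, 1.0), 8)) for g in genes}
        )
        rep = qp.genorm_stability(cal, genes)
        from casteseq.qpcr import _cq_wide, _genorm_m, relative_quantities

        log_rq = np.log2(relative_quantities(_cq_wide(cal).loc[genes]))
        remaining = list(genes)
        while len(remaining) > 2:
            m = _genorm_m(log_rq.loc[remaining])
            worst = m.idxmax()
            rest = [g for g in remaining if g != worst]
            assert _genorm_m(log_rq.loc[rest]).mean() <= m.mean() + 1e-12
            remaining = rest


class TestRelativeQuantify:
    def flat_calibrated(self, genes, samples, cq=24.0):
        rows = [
            {"plate_id": "p", "well": f"{g}{s}", "gene_id": g, "sample_id": s,
             "Cq": cq, "is_IPC": False}
            for g in genes for s in samples
        ]
        rows.append({"plate_id": "p", "well": "IPC", "gene_id": "IPC",
                     "sample_id": "IPC", "Cq": 20.0, "is_IPC": True})
        return pd.DataFrame(rows)

    def test_all_equal_cq_gives_unit_ratios(self):
        cal = self.flat_calibrated(["T", "R1", "R2"], ["s1", "s2", "s3"])
        out = cs.relative_quantify(cal, ["T"], ["R1", "R2"])
        assert np.allclose(out["ratio"], 1.0)

    def test_one_cycle_below_mean_doubles_ratio(self):
        cal = self.flat_calibrated(["T", "R1", "R2"], ["s1", "s2", "s3"])
        # target one cycle lower in s1, references at gene mean in every sample
        idx = (cal["gene_id"] == "T") & (cal["sample_id"] == "s1")
        cal.loc[idx, "Cq"] = 23.0
        cal.loc[(cal["gene_id"] == "T") & (cal["sample_id"] != "s1"), "Cq"] = 24.5
        out = cs.relative_quantify(cal, ["T"], ["R1", "R2"], {"T": 2.0, "R1": 2.0, "R2": 2.0})
        s1 = out[out["sample_id"] == "s1"]["ratio"].iloc[0]
        mean_cq = (23.0 + 24.5 + 24.5) / 3
        assert s1 == pytest.approx(2.0 ** (mean_cq - 23.0))

    def test_invariance_to_constant_gene_shift(self):
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(5)]
        cal = self.flat_calibrated(["T", "R1", "R2"], samples)
        cal["Cq"] += rng.normal(0, 1, len(cal))
        out1 = cs.relative_quantify(cal, ["T"], ["R1", "R2"])
        shifted = cal.copy()
        shifted.loc[shifted["gene_id"] == "R1", "Cq"] += 3.7
        out2 = cs.relative_quantify(shifted, ["T"], ["R1", "R2"])
        assert np.allclose(out1["ratio"], out2["ratio"])

    def test_requires_two_references(self):
        cal = self.flat_calibrated(["T", "R1"], ["s1", "s2"])
        with pytest.raises(ValueError, match="two reference"):
            cs.relative_quantify(cal, ["T"], ["R1"])

    def test_missing_reference_sample_dropped_with_warning(self):
        cal = self.flat_calibrated(["T", "R1", "R2"], ["s1", "s2", "s3"])
        cal = cal[~((cal["gene_id"] == "R1") & (cal["sample_id"] == "s3"))]
        with pytest.warns(UserWarning, match="s3"):
            out = cs.relative_quantify(cal, ["T"], ["R1", "R2"])
        assert set(out["sample_id"]) == {"s1", "s2"}

    @pytest.mark.parametrize("seed", range(10))
    def test_simulated_fourfold_difference_recovered(self, seed, small_design):
        """A 4-fold Q-up mid-stage target recovers a MQ/MW ratio within 25%."""
        plates, meta, truth = cs.simulate_cq_plates(small_design, seed=100 + seed)
        cal = qp.calibrate_plates(plates)
        rep = qp.genorm_stability(cal, sorted(truth.reference_sigmas), truth.efficiencies)
        refs = sorted(rep.m_values, key=rep.m_values.get)[:3]
        out = cs.relative_quantify(cal, ["TQ4X"], refs, truth.efficiencies)
        out = out.set_index("sample_id")
        mq = out.loc[[s for s in out.index if s.startswith("MQ")], "ratio"].mean()
        mw = out.loc[[s for s in out.index if s.startswith("MW")], "ratio"].mean()
        assert mq / mw == pytest.approx(4.0, rel=0.25)


class TestCasteRankTest:
    def ratios_frame(self, q_vals, w_vals):
        rows = [{"gene_id": "T", "sample_id": f"MQ_s{i}", "ratio": v}
                for i, v in enumerate(q_vals)]
        rows += [{"gene_id": "T", "sample_id": f"MW_s{i}", "ratio": v}
                 for i, v in enumerate(w_vals)]
        meta = pd.DataFrame(
            {"sample_id": [r["sample_id"] for r in rows], "stage": "mid",
             "caste": ["Q"] * len(q_vals) + ["W"] * len(w_vals)}
        ).set_index("sample_id")
        return pd.DataFrame(rows), meta

    def test_fully_separated_groups_exact_p(self):
        ratios, meta = self.ratios_frame([1, 2, 3, 4, 5, 6], [7, 8, 9, 10, 11, 12])
        res = cs.caste_rank_test(ratios, meta, "mid").iloc[0]
        assert res["U"] == 0.0
        assert res["p"] == pytest.approx(2 / 924)
        assert res["method"] == "exact"

    def test_identical_groups_p_near_one(self):
        ratios, meta = self.ratios_frame([1, 2, 3, 9, 10, 11], [1.5, 2.5, 3.5, 8.5, 9.5, 10.5])
        res = cs.caste_rank_test(ratios, meta, "mid").iloc[0]
        assert res["p"] >= 0.6

    def test_label_swap_preserves_p(self):
        rng = np.random.default_rng(4)
        q, w = rng.normal(0, 1, 6), rng.normal(0.5, 1, 6)
        r1, m1 = self.ratios_frame(q, w)
        r2, m2 = self.ratios_frame(w, q)
        p1 = cs.caste_rank_test(r1, m1, "mid")["p"].iloc[0]
        p2 = cs.caste_rank_test(r2, m2, "mid")["p"].iloc[0]
        assert p1 == pytest.approx(p2)

    def test_ties_fall_back_to_approximation_and_flagged(self):
        ratios, meta = self.ratios_frame([1, 1, 2, 3], [1, 2, 2, 4])
        with pytest.raises(ValueError):
            cs.caste_rank_test(ratios, meta.iloc[:5], "mid")  # <3 per caste after filter
        res = cs.caste_rank_test(ratios, meta, "mid").iloc[0]
        assert res["method"] == "asymptotic"

    @pytest.mark.parametrize("n1,n2,seed", [(3, 3, 0), (4, 5, 1), (6, 6, 2), (7, 5, 3)])
    def test_matches_enumeration_oracle(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        q = list(rng.normal(0, 1, n1))
        w = list(rng.normal(0.8, 1, n2))
        ratios, meta = self.ratios_frame(q, w)
        # pad to satisfy the >=3-per-caste precondition in the 3,3 case
        p = cs.caste_rank_test(ratios, meta, "mid")["p"].iloc[0]
        assert p == pytest.approx(mannwhitney_two_sided_oracle(q, w), rel=1e-9)


class TestPlatformCongruence:
    def test_accounting_and_match_rules(self):
        calls = pd.DataFrame(
            {"feature_id": ["T1", "T2"], "stage": "mid",
             "is_deg": [True, False], "direction": ["Q", "none"],
             "ofc": [2.0, np.nan], "is_hdeg": [True, False]}
        )
        tests = pd.DataFrame(
            {"gene_id": ["T1", "T2", "T3"], "stage": "mid",
             "p": [0.01, 0.5, 0.01], "U": [0, 5, 1],
             "median_Q": [3.0, 1.0, 0.2], "median_W": [1.0, 1.1, 1.0],
             "method": "exact"}
        )
        records = cs.platform_congruence(tests, {"mid": calls}, ["T1", "T2", "T3"])
        by_gene = {r.gene_id: r for r in records}
        assert by_gene["T1"].match  # HDEG Q-up, qPCR significant Q-up
        assert by_gene["T2"].match  # both non-significant
        assert by_gene["T3"].missing  # absent from the sequencing calls
        n = len(records)
        assert n == 3  # 3 genes x 1 stage

    def test_directional_mismatch(self):
        calls = pd.DataFrame(
            {"feature_id": ["T1"], "stage": "mid", "is_deg": [True],
             "direction": ["Q"], "ofc": [2.0], "is_hdeg": [True]}
        )
        tests = pd.DataFrame(
            {"gene_id": ["T1"], "stage": "mid", "p": [0.01], "U": [0],
             "median_Q": [0.5], "median_W": [2.0], "method": "exact"}
        )
        rec = cs.platform_congruence(tests, {"mid": calls}, ["T1"])[0]
        assert rec.seq_result == "sig_up_Q" and rec.pcr_result == "sig_up_W"
        assert not rec.match
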
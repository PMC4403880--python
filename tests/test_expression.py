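"""Hormone-regulation calls, dependence-ratio rule (strict boundaries),
label symmetry, BH behavior, and fold-induction arithmetic."""

import numpy as np
import pandas as pd
import pytest

from relochip.expression import (
    ExpressionMatrix,
    call_hormone_regulated,
    chd8_dependence,
    fold_induction,
    proximity_enrichment,
    regulation_change_summary,
)
from relochip.synthetic_data import SimConfig, Simulation


def make_matrix(gene_fcs: dict, fc_kd: dict | None = None, base: float = 8.0,
                jitter: float = 1e-3) -> ExpressionMatrix:
    """Noise-free design with a deterministic per-replicate jitter so the
    Welch test is defined but effectively exact."""
    genes = list(gene_fcs)
    cols, data = [], {}
    eps = np.array([-jitter, 0.0, jitter])
    for kd in ("siCt", "siCHD8"):
        for trt in ("EtOH", "R5020"):
            for i, rep in enumerate((1, 2, 3)):
                name = f"{trt}_{kd}_r{rep}"
                vals = []
                for g in genes:
                    fc = gene_fcs[g] if kd == "siCt" else (fc_kd or gene_fcs)[g]
                    effect = np.log2(fc) if trt == "R5020" else 0.0
                    vals.append(base + effect + eps[i])
                data[name] = vals
                cols.append((name, trt, kd, rep))
    values = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    samples = pd.DataFrame(
        [(t, k, r) for _, t, k, r in cols],
        index=pd.Index([c[0] for c in cols], name="sample"),
        columns=["treatment", "knockdown", "replicate"],
    )
    return ExpressionMatrix(values, samples)


class TestExpressionMatrix:
    def test_missing_values_rejected(self):
        m = make_matrix({"g1": 2.0})
        vals = m.values.copy()
        vals.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            ExpressionMatrix(vals, m.samples)

    def test_incomplete_design_rejected(self):
        m = make_matrix({"g1": 2.0})
        keep = [c for c in m.values.columns if c != "EtOH_siCt_r1" and c != "EtOH_siCt_r2"]
        with pytest.raises(ValueError, match="replicates"):
            ExpressionMatrix(m.values[keep], m.samples.loc[keep])

    def test_tsv_round_trip(self, tmp_path):
        m = make_matrix({"g1": 2.0, "g2": 0.5})
        m.to_tsv(tmp_path / "v.tsv", tmp_path / "s.tsv")
        back = ExpressionMatrix.from_tsv(tmp_path / "v.tsv", tmp_path / "s.tsv")
        assert np.allclose(back.values.values, m.values.values)


class TestCallHormoneRegulated:
    def test_up_down_none(self):
        m = make_matrix({"up": 2.0, "down": 0.4, "flat": 1.0})
        calls = call_hormone_regulated(m)
        assert calls.loc["up", "regulated"] == "up"
        assert calls.loc["down", "regulated"] == "down"
        assert calls.loc["flat", "regulated"] == "none"

    def test_fc_exactly_threshold_not_called(self):
        # strict inequality: FC exactly 1.5 (or 1/1.5) is never regulated
        m = make_matrix({"g1": 1.5, "g2": 1 / 1.5, "g3": 1.6})
        calls = call_hormone_regulated(m)
        assert calls.loc["g1", "regulated"] == "none"
        assert calls.loc["g2", "regulated"] == "none"
        assert calls.loc["g3", "regulated"] == "up"

    def test_significant_but_small_fc_not_called(self):
        m = make_matrix({"g1": 1.2})
        calls = call_hormone_regulated(m)
        assert calls.loc["g1", "p_value"] < 0.01
        assert calls.loc["g1", "regulated"] == "none"

    def test_treatment_relabel_symmetry(self):
        fcs = {"a": 2.5, "b": 0.3, "c": 1.0, "d": 4.0}
        m = make_matrix(fcs)
        swapped_samples = m.samples.copy()
        swapped_samples["treatment"] = swapped_samples["treatment"].map(
            {"EtOH": "R5020", "R5020": "EtOH"}
        )
        m_swapped = ExpressionMatrix(m.values, swapped_samples)
        c1 = call_hormone_regulated(m)
        c2 = call_hormone_regulated(m_swapped)
        assert np.allclose(c2["fc_ct"], 1.0 / c1["fc_ct"])
        flip = {"up": "down", "down": "up", "none": "none"}
        assert list(c2["regulated"]) == [flip[x] for x in c1["regulated"]]

    def test_bh_qvalues_dominate_p_and_are_monotone(self):
        sim = Simulation(SimConfig(seed=2))
        m, _ = sim.simulate_expression()
        calls = call_hormone_regulated(m)
        assert (calls["q_value"] >= calls["p_value"] - 1e-12).all()
        by_p = calls.sort_values("p_value")
        assert (np.diff(by_p["q_value"]) >= -1e-12).all()

    def test_criterion_flag_changes_gate_not_fc(self):
        sim = Simulation(SimConfig(seed=2))
        m, _ = sim.simulate_expression()
        c_fdr = call_hormone_regulated(m, criterion="fdr")
        c_p = call_hormone_regulated(m, criterion="pvalue")
        assert np.allclose(c_fdr["fc_ct"], c_p["fc_ct"])
        n_fdr = (c_fdr["regulated"] != "none").sum()
        n_p = (c_p["regulated"] != "none").sum()
        assert n_p >= n_fdr


class TestDependence:
    def test_ratio_rule_instance(self):
        m = make_matrix({"g1": 4.0}, fc_kd={"g1": 2.0})
        calls = chd8_dependence(call_hormone_regulated(m), m)
        assert calls.loc["g1", "dependence_ratio"] == pytest.approx(0.5, rel=1e-6)
        assert bool(calls.loc["g1", "dependent"])

    def test_equal_arms_not_dependent(self):
        m = make_matrix({"g1": 4.0})
        calls = chd8_dependence(call_hormone_regulated(m), m)
        assert calls.loc["g1", "dependence_ratio"] == pytest.approx(1.0, rel=1e-6)
        assert not bool(calls.loc["g1", "dependent"])

    def test_boundary_ratios_not_dependent(self):
        # R exactly 1.20 and exactly 0.8: strict inequalities, never called
        m = make_matrix(
            {"hi": 2.0, "lo": 2.0},
            fc_kd={"hi": 2.0 * 1.20, "lo": 2.0 * 0.8},
        )
        calls = chd8_dependence(call_hormone_regulated(m), m)
        assert calls.loc["hi", "dependence_ratio"] == pytest.approx(1.20, rel=1e-9)
        assert calls.loc["lo", "dependence_ratio"] == pytest.approx(0.8, rel=1e-9)
        assert not calls["dependent"].any()

    def test_unregulated_gene_never_dependent(self):
        m = make_matrix({"g1": 1.0}, fc_kd={"g1": 3.0})
        calls = chd8_dependence(call_hormone_regulated(m), m)
        assert not bool(calls.loc["g1", "dependent"])

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_recovery_f1_against_truth(self, seed):
        """Planted FC 2.5, noise 0.15, attenuation 0.5, 3 replicates:
        regulated and dependent labels recovered at F1 >= 0.9 using the
        raw p < 0.01 significance rule."""
        sim = Simulation(SimConfig(seed=seed, fc_range=(2.5, 2.5)))
        m, truth = sim.simulate_expression()
        calls = chd8_dependence(call_hormone_regulated(m, criterion="pvalue"), m)

        def f1(pred, true):
            tp = (pred & true).sum()
            fp = (pred & ~true).sum()
            fn = (~pred & true).sum()
            return 2 * tp / (2 * tp + fp + fn)

        assert f1((calls.regulated != "none").values, (truth.regulated != "none").values) >= 0.9
        assert f1(calls.dependent.values, truth.dependent.values) >= 0.9


class TestProximityEnrichment:
    def test_disjoint_sets_p_one(self):
        t = proximity_enrichment({"a"}, {"b"}, 100)
        assert t.p_value == 1.0

    def test_planted_dependent_genes_near_peaks(self, default_sim):
        from relochip.expression import call_hormone_regulated as chr_

        m, _ = default_sim.simulate_expression()
        calls = chd8_dependence(chr_(m, criterion="pvalue"), m)
        dep = set(calls.index[calls.dependent])
        targets = set(default_sim.peak_target_genes.values())
        t = proximity_enrichment(dep, targets, len(default_sim.genes))
        assert t.p_value < 1e-6

    def test_matches_enumeration_small_universe(self):
        import itertools

        t = proximity_enrichment({"g1", "g2", "g3"}, {"g1", "g2", "g4"}, 10)
        # N=10, K=3 targets, n=3 dependent, k=2
        total = hits = 0
        for draw in itertools.combinations(range(10), 3):
            total += 1
            if sum(1 for x in draw if x < 3) >= 2:
                hits += 1
        assert t.p_value == pytest.approx(hits / total, rel=1e-12)


class TestRegulationChangeSummary:
    def test_identical_arms_identical_summaries(self):
        m = make_matrix({f"g{i}": fc for i, fc in enumerate([2.0, 3.0, 0.4, 0.5])})
        calls = chd8_dependence(call_hormone_regulated(m), m)
        s = regulation_change_summary(calls)
        for d in ("up", "down"):
            assert s.loc[(d, "siCt"), "median"] == pytest.approx(
                s.loc[(d, "siCHD8"), "median"], rel=1e-6
            )

    def test_attenuation_orders_medians(self, default_sim):
        m, _ = default_sim.simulate_expression()
        calls = chd8_dependence(call_hormone_regulated(m, criterion="pvalue"), m)
        s = regulation_change_summary(calls)
        # attenuated up genes: lower induction; attenuated down genes:
        # weaker repression (median FC closer to 1 from below)
        assert s.loc[("up", "siCHD8"), "median"] < s.loc[("up", "siCt"), "median"]
        assert s.loc[("down", "siCHD8"), "median"] > s.loc[("down", "siCt"), "median"]

    def test_single_gene_group(self):
        m = make_matrix({"g1": 2.0, "g2": 1.0})
        calls = chd8_dependence(call_hormone_regulated(m), m)
        s = regulation_change_summary(calls)
        assert s.loc[("up", "siCt"), "n"] == 1
        assert s.loc[("up", "siCt"), "median"] == pytest.approx(2.0, rel=1e-3)
        assert s.loc[("up", "siCt"), "q1"] == pytest.approx(s.loc[("up", "siCt"), "q3"], rel=1e-6)
        assert s.loc[("down", "siCt"), "n"] == 0


class TestFoldInduction:
    def test_treated_equals_vehicle(self):
        t = pd.DataFrame({"condition": ["EtOH", "EtOH", "R5020", "R5020"],
                          "normalized": [0.1, 0.1, 0.1, 0.1]})
        assert fold_induction(t)["R5020"] == pytest.approx(1.0)

    def test_normalized_quantity_arithmetic(self):
        t = pd.DataFrame({"condition": ["EtOH", "R5020"], "normalized": [0.1, 0.4]})
        folds = fold_induction(t)
        assert folds["R5020"] == pytest.approx(4.0)
        assert folds["EtOH"] == 1.0

    def test_cq_mode(self):
        # ddCq: target-ref = 3 cycles in vehicle vs 1 in treated -> fold 4
        t = pd.DataFrame(
            {
                "condition": ["EtOH", "R5020"],
                "target_cq": [25.0, 24.0],
                "reference_cq": [22.0, 23.0],
            }
        )
        assert fold_induction(t)["R5020"] == pytest.approx(4.0)

    def test_missing_reference_rejected(self):
        t = pd.DataFrame(
            {"condition": ["EtOH", "R5020"], "target_cq": [25.0, 24.0],
             "reference_cq": [22.0, np.nan]}
        )
        with pytest.raises(ValueError, match="missing"):
            fold_induction(t)

    def test_missing_vehicle_rejected(self):
        t = pd.DataFrame({"condition": ["R5020"], "normalized": [0.4]})
        with pytest.raises(ValueError, match="vehicle"):
            fold_induction(t)
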
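"""NB GLM fitting, dispersion estimation, LRT, BH and gene calls."""

import numpy as np
import pandas as pd
import pytest

from utrzga import (
    SimulationConfig,
    bh_adjust,
    call_genes,
    estimate_dispersion,
    fit_nb_glm,
    lrt,
    run_consecutive_contrasts,
    simulate_expression,
)


def _two_group_sheet(n=3):
    rows = []
    for stage in ("oocyte", "zygote"):
        for r in range(1, n + 1):
            rows.append({"sample_id": f"{stage}_rep{r}", "stage": stage, "replicate": r})
    return pd.DataFrame(rows)


class TestBH:
    def test_hand_worked_example(self):
        adj = bh_adjust([0.01, 0.04, 0.03, 0.20])
        assert np.allclose(adj, [0.04, 0.0533333333, 0.0533333333, 0.20])

    def test_equal_and_single(self):
        assert np.allclose(bh_adjust([0.07, 0.07, 0.07]), 0.07)
        assert bh_adjust([0.3]).tolist() == [0.3]

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            mine = bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(mine, ref)
            assert (mine <= 1).all() and (mine >= p - 1e-12).all()


class TestGLMFit:
    def test_equal_counts_zero_stage_effects(self):
        sheet = _two_group_sheet()
        fit = fit_nb_glm([50] * 6, sheet["stage"], np.zeros(6), dispersion=0.1)
        assert np.allclose(fit.stage_effects(), 0.0)

    def test_closed_form_logfc_two_groups(self):
        # stage MLE means are group means; logFC = log2(20/10) = 1 exactly
        sheet = _two_group_sheet()
        y = [10, 10, 10, 20, 20, 20]
        fit = fit_nb_glm(y, sheet["stage"], np.zeros(6), dispersion=0.1)
        eff = fit.stage_effects() / np.log(2)
        assert eff["zygote"] == pytest.approx(1.0, abs=1e-8)

    def test_poisson_limit_matches_statsmodels(self):
        """With dispersion forced to 0 the LRT equals an independent Poisson
        GLM's likelihood-ratio statistic to 1e-6, on 100 random genes."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        sheet = _two_group_sheet()
        stages = sheet["stage"]
        offsets = np.log(rng.uniform(0.8, 1.2, size=6))
        design = np.column_stack([np.ones(6), (stages == "zygote").to_numpy(float)])
        for _ in range(100):
            y = rng.poisson(rng.uniform(5, 200), size=6)
            full = fit_nb_glm(y, stages, offsets, dispersion=0.0)
            reduced = fit_nb_glm(y, ["all"] * 6, offsets, dispersion=0.0)
            stat, _ = lrt(full, reduced)

            m_full = sm.GLM(y, design, family=sm.families.Poisson(), offset=offsets).fit()
            m_red = sm.GLM(y, design[:, :1], family=sm.families.Poisson(), offset=offsets).fit()
            ref = 2 * (m_full.llf - m_red.llf)
            assert stat == pytest.approx(ref, abs=1e-6)

    def test_lrt_identical_fits(self):
        sheet = _two_group_sheet()
        y = [30, 31, 29, 30, 31, 29]
        full = fit_nb_glm(y, sheet["stage"], np.zeros(6), dispersion=0.1)
        with pytest.raises(ValueError, match="fewer parameters"):
            lrt(full, full)
        reduced = fit_nb_glm(y, ["all"] * 6, np.zeros(6), dispersion=0.1)
        stat, p = lrt(full, reduced)
        assert stat >= 0 and 0 <= p <= 1


class TestDispersion:
    def test_poisson_data_gives_tiny_common(self):
        cfg = SimulationConfig(
            seed=21, n_genes=2000, archetype_mix={"constitutive": 1.0},
            stage_design=(("oocyte", 3), ("zygote", 3)), dispersion=1e-8,
            lib_size_range=(500_000.0, 500_000.0),
        )
        counts, sheet, _ = simulate_expression(cfg)
        est = estimate_dispersion(counts, sheet)
        assert est.common <= 0.02

    def test_recovers_planted_dispersion(self):
        cfg = SimulationConfig(
            seed=22, n_genes=2000, archetype_mix={"constitutive": 1.0},
            stage_design=(("oocyte", 3), ("zygote", 3)), dispersion=0.1,
            lib_size_range=(500_000.0, 800_000.0),
        )
        counts, sheet, _ = simulate_expression(cfg)
        est = estimate_dispersion(counts, sheet)
        assert 0.08 <= est.common <= 0.12
        assert 0.05 <= est.tagwise.median() <= 0.15

    def test_all_zero_matrix_errors(self):
        sheet = _two_group_sheet()
        counts = pd.DataFrame(
            0, index=["g1", "g2"], columns=sheet["sample_id"]
        )
        with pytest.raises(ValueError, match="all-zero"):
            estimate_dispersion(counts, sheet)

    def test_identical_replicates_clamp_at_floor(self):
        sheet = _two_group_sheet()
        counts = pd.DataFrame(
            [[100] * 6], index=["g1"], columns=sheet["sample_id"]
        )
        est = estimate_dispersion(counts, sheet)
        assert est.tagwise.loc["g1"] >= 1e-8


class TestCalls:
    @pytest.mark.parametrize(
        "fdr, logfc, expected",
        [
            (0.01, 2.0, "up"),
            (0.01, -2.0, "down"),
            (0.01, 0.5, "unchanged"),
            (0.20, 3.0, "not_significant"),
        ],
    )
    def test_call_thresholds(self, fdr, logfc, expected):
        df = pd.DataFrame({"fdr": [fdr], "logFC": [logfc]})
        assert call_genes(df)["call"].iloc[0] == expected


class TestConsecutiveContrasts:
    def test_six_contrasts_on_full_design(self, bundle):
        table = run_consecutive_contrasts(bundle.counts, bundle.samples)
        assert table["contrast"].nunique() == 6
        assert len(table) == 6 * len(bundle.counts)
        # FDR >= p always
        assert (table["fdr"] >= table["pvalue"] - 1e-12).all()

    def test_full_likelihood_dominates_reduced(self, bundle):
        # LR statistics are non-negative for every converged gene
        table = run_consecutive_contrasts(bundle.counts, bundle.samples)
        assert (table.loc[table["converged"], "LR"] >= 0).all()

    def test_within_stage_label_permutation_invariance(self, bundle):
        table1 = run_consecutive_contrasts(bundle.counts, bundle.samples)
        sheet2 = bundle.samples.copy()
        # swap replicate 1 and 3 of the oocyte stage (same stage labels)
        ids = sheet2.loc[sheet2["stage"] == "oocyte", "sample_id"].tolist()
        order = {ids[0]: ids[2], ids[2]: ids[0]}
        sheet2["sample_id"] = sheet2["sample_id"].map(lambda s: order.get(s, s))
        cols = [order.get(c, c) for c in bundle.counts.columns]
        counts2 = bundle.counts.copy()
        counts2.columns = cols
        table2 = run_consecutive_contrasts(counts2, sheet2)
        assert np.allclose(table1["LR"], table2["LR"], atol=1e-9)

    def test_planted_zga1_recovery(self):
        cfg = SimulationConfig(seed=33, n_genes=600)
        counts, sheet, truth = simulate_expression(cfg)
        table = run_consecutive_contrasts(counts, sheet)
        sub = table[table["contrast"] == "oocyte_vs_zygote"].set_index("gene_id")
        z = truth.genes.query("archetype == 'zga1'").index
        assert (sub.loc[z, "call"] == "up").mean() >= 0.9
        null = truth.genes.query("archetype == 'constitutive'").index
        assert (sub.loc[null, "call"].isin(["up", "down"])).mean() <= 0.1
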
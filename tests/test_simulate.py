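"""Synthetic-cohort generator: distributions, determinism, closed-form truth."""

import math

import numpy as np
import pytest

from localadapt import (
    ConfigError,
    GeneratorConfig,
    derive_true_effects,
    generate_cohort,
    write_cohort,
    ztnb_mean,
)


def small_config(seed=None, n=20):
    return GeneratorConfig.default(seed=seed).with_n_per_cell(n)


class TestGenerateCohort:
    def test_cell_sizes_match_config(self):
        cfg = GeneratorConfig.default(seed=0)
        cohort = generate_cohort(cfg)
        counts = cohort.data.groupby(["site", "soil", "ecotype"]).size()
        for cell in cfg.cells():
            assert counts[cell] == cfg.n_per_cell[cell]

    def test_zero_survival_cell_is_all_dead(self):
        cfg = small_config(seed=1)
        cell = ("Italy", "Italy", "Sweden")
        cfg.surv_prob[cell] = 0.0
        df = generate_cohort(cfg).data
        g = df[(df.site == "Italy") & (df.soil == "Italy") & (df.ecotype == "Sweden")]
        assert not g["survived"].any()
        assert (g["fruits"] == 0).all()
        assert g["seeds_per_fruit"].isna().all()

    def test_full_survival_and_measurement_gives_seed_count_everywhere(self):
        cfg = small_config(seed=2)
        cfg.measure_prob = 1.0
        for cell in cfg.cells():
            cfg.surv_prob[cell] = 1.0
        df = generate_cohort(cfg).data
        assert df["survived"].all()
        assert (df["fruits"] >= 1).all()
        assert df["seeds_per_fruit"].notna().all()

    def test_same_seed_same_cohort_bytes(self, tmp_path):
        a = generate_cohort(GeneratorConfig.default(), seed=7)
        b = generate_cohort(GeneratorConfig.default(), seed=7)
        assert a.equals(b)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(a, pa)
        write_cohort(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self):
        a = generate_cohort(GeneratorConfig.default(), seed=7)
        b = generate_cohort(GeneratorConfig.default(), seed=8)
        assert not a.equals(b)

    def test_fruit_mean_matches_truncated_not_raw_mean(self):
        # 10000 guaranteed survivors in one cell with raw fruit mean 8:
        # the sample mean must match the zero-truncated mean, which is
        # strictly larger than 8.
        cfg = small_config(seed=11, n=4)
        cell = ("Italy", "Italy", "Italy")
        cfg.n_per_cell[cell] = 10_000
        cfg.surv_prob[cell] = 1.0
        cfg.fruit_mean[cell] = 8.0
        df = generate_cohort(cfg).data
        g = df[(df.site == "Italy") & (df.soil == "Italy") & (df.ecotype == "Italy")]
        fruits = g["fruits"].to_numpy(dtype=float)
        truth = ztnb_mean(8.0, cfg.fruit_dispersion)
        se = fruits.std(ddof=1) / math.sqrt(len(fruits))
        assert truth > 8.0
        assert abs(fruits.mean() - truth) < 3 * se
        assert abs(fruits.mean() - 8.0) > 3 * se  # distinguishes raw mean

    def test_all_generated_records_are_non_edge(self):
        df = generate_cohort(small_config(seed=3)).data
        assert not df["edge"].any()


class TestDeriveTrueEffects:
    def test_identical_cells_imply_zero_selection(self):
        cfg = small_config()
        for cell in cfg.cells():
            cfg.surv_prob[cell] = 0.5
            cfg.fruit_mean[cell] = 6.0
            cfg.seed_mean[cell] = 10.0
        truth = derive_true_effects(cfg)
        assert all(v == 0.0 for v in truth.s_true.values())
        assert all(v == 0.0 for v in truth.delta_s_true.values())

    def test_tenfold_overall_ratio_gives_s_09(self):
        cfg = small_config()
        # make the non-local cells exactly 10x weaker through seed mean
        truth0 = derive_true_effects(cfg)
        for site in cfg.sites:
            eco_n = [e for e in cfg.sites if e != site][0]
            for soil in cfg.sites:
                w_l = truth0.cell_means[(site, soil, site, "overall")]
                w_n = truth0.cell_means[(site, soil, eco_n, "overall")]
                cfg.seed_mean[(site, soil, eco_n)] *= (w_l / 10.0) / w_n
        truth = derive_true_effects(cfg)
        for site in cfg.sites:
            for soil in cfg.sites:
                assert truth.s_true[(site, soil, "overall")] == pytest.approx(0.9)

    def test_fold_difference_of_4_4_gives_s_0773(self):
        # a 4.4-fold local:non-local overall ratio corresponds to
        # s = 1 - 1/4.4 = 0.772727...
        cfg = small_config()
        truth0 = derive_true_effects(cfg)
        site, soil = "Italy", "Italy"
        w_l = truth0.cell_means[(site, soil, "Italy", "overall")]
        w_n = truth0.cell_means[(site, soil, "Sweden", "overall")]
        cfg.seed_mean[(site, soil, "Sweden")] *= (w_l / 4.4) / w_n
        truth = derive_true_effects(cfg)
        assert truth.s_true[(site, soil, "overall")] == pytest.approx(
            1 - 1 / 4.4, abs=1e-12
        )

    def test_soil_symmetric_default_has_exactly_zero_delta(self):
        truth = derive_true_effects(GeneratorConfig.default())
        assert truth.delta_s_true == {"Italy": 0.0, "Sweden": 0.0}

    def test_component_truth_structure(self):
        cfg = GeneratorConfig.default()
        truth = derive_true_effects(cfg)
        cell = ("Sweden", "Italy", "Sweden")
        assert truth.cell_means[cell + ("survival",)] == cfg.surv_prob[cell]
        assert truth.cell_means[cell + ("seeds_per_fruit",)] == cfg.seed_mean[cell]
        assert truth.cell_means[cell + ("fecundity",)] == pytest.approx(
            ztnb_mean(cfg.fruit_mean[cell], cfg.fruit_dispersion)
        )
        assert truth.cell_means[cell + ("overall",)] == pytest.approx(
            cfg.surv_prob[cell]
            * ztnb_mean(cfg.fruit_mean[cell], cfg.fruit_dispersion)
            * cfg.seed_mean[cell]
        )

    def test_point_estimates_converge_to_truth_at_large_n(self):
        # estimator consistency: at 20000 plants per cell the overall
        # selection estimate must sit within 3 bootstrap SEs of the
        # closed-form truth
        from localadapt import ResamplingPlan, SelectionModel

        cfg = GeneratorConfig.default().with_n_per_cell(20_000)
        truth = derive_true_effects(cfg)
        cohort = generate_cohort(cfg, seed=12345)
        res = SelectionModel(cohort).fit(ResamplingPlan(n_boot=200, n_perm=0, seed=1))
        for row in res.estimates.itertuples(index=False):
            se = (row.ci_high - row.ci_low) / (2 * 1.959964)
            s_true = truth.s_true[(row.site, row.soil, row.component)]
            assert abs(row.s_hat - s_true) < 3 * se + 1e-12


class TestConfigValidation:
    @pytest.mark.parametrize(
        "mutate, fragment",
        [
            (lambda c: c.surv_prob.update({("Italy", "Italy", "Italy"): 1.5}), "surv_prob"),
            (lambda c: c.fruit_mean.update({("Italy", "Italy", "Italy"): 0.0}), "fruit_mean"),
            (lambda c: c.seed_mean.update({("Italy", "Italy", "Italy"): -2.0}), "seed_mean"),
            (lambda c: setattr(c, "fruit_dispersion", 0.0), "fruit_dispersion"),
            (lambda c: setattr(c, "measure_prob", 1.2), "measure_prob"),
            (lambda c: c.n_per_cell.pop(("Italy", "Italy", "Italy")), "n_per_cell"),
        ],
    )
    def test_invalid_field_named_in_error(self, mutate, fragment):
        cfg = GeneratorConfig.default()
        mutate(cfg)
        with pytest.raises(ConfigError, match=fragment):
            cfg.validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig.default(seed=5)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = GeneratorConfig.from_yaml(path)
        assert back.sites == cfg.sites
        assert back.n_per_cell == cfg.n_per_cell
        assert back.surv_prob == cfg.surv_prob
        assert back.fruit_mean == cfg.fruit_mean
        assert back.seed_mean == cfg.seed_mean
        assert back.measure_prob == cfg.measure_prob
        assert back.seed == 5

    def test_malformed_yaml_raises_config_error(self):
        with pytest.raises(ConfigError):
            GeneratorConfig.from_yaml("sites: [A, B]\ncells: {A: 3}\n")
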
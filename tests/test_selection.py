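"""Selection coefficients, bootstrap CIs, contrasts and the permutation test."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from localadapt import (
    Cohort,
    ConfigurationError,
    GeneratorConfig,
    ResamplingPlan,
    SelectionModel,
    estimate_selection,
    generate_cohort,
    selection_coefficient,
    soil_contrast,
)

from conftest import make_record, two_site_cohort

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


class TestSelectionCoefficient:
    @pytest.mark.parametrize(
        "w_local, w_nonlocal, expected",
        [(10, 5, 0.5), (7, 7, 0.0), (5, 10, -1.0), (4, 0, 1.0)],
    )
    def test_formula(self, w_local, w_nonlocal, expected):
        assert selection_coefficient(w_local, w_nonlocal) == expected

    @pytest.mark.parametrize("w_nonlocal", [0.0, 3.0])
    def test_zero_local_fitness_is_undefined(self, w_nonlocal):
        assert math.isnan(selection_coefficient(0.0, w_nonlocal))

    def test_negative_fitness_is_a_domain_error(self):
        with pytest.raises(ValueError):
            selection_coefficient(-1.0, 2.0)
        with pytest.raises(ValueError):
            selection_coefficient(2.0, -1.0)

    @given(w_local=positive, w_a=positive, w_b=positive)
    def test_strictly_decreasing_in_nonlocal_fitness(self, w_local, w_a, w_b):
        if w_a == w_b:
            return
        lo, hi = sorted((w_a, w_b))
        assert selection_coefficient(w_local, lo) > selection_coefficient(w_local, hi)

    @given(w_local=positive, w_nonlocal=positive, c=positive)
    def test_scale_invariance(self, w_local, w_nonlocal, c):
        s1 = selection_coefficient(w_local, w_nonlocal)
        s2 = selection_coefficient(c * w_local, c * w_nonlocal)
        assert s2 == pytest.approx(s1, rel=1e-9, abs=1e-9)

    @given(w_local=positive, w_nonlocal=positive)
    def test_bounded_above_by_one(self, w_local, w_nonlocal):
        assert selection_coefficient(w_local, w_nonlocal) <= 1.0


class TestEstimateSelection:
    def test_zero_variance_strata_collapse_the_interval(self):
        # every plant within a stratum identical -> every bootstrap
        # resample reproduces the point estimate exactly
        cohort = two_site_cohort(
            values={
                cell: [(True, 3 + i, 6)] * 4
                for i, cell in enumerate(
                    (s, so, e)
                    for s in ("Italy", "Sweden")
                    for so in ("Italy", "Sweden")
                    for e in ("Italy", "Sweden")
                )
            }
        )
        for est in estimate_selection(cohort, plan=ResamplingPlan(n_boot=50, n_perm=0, seed=0)):
            assert est.ci_low == est.s_hat == est.ci_high
            assert est.n_boot_dropped == 0

    def test_equal_cell_means_give_exactly_zero_s(self, balanced_cohort):
        for est in estimate_selection(
            balanced_cohort, plan=ResamplingPlan(n_boot=0, n_perm=0)
        ):
            assert est.s_hat == 0.0

    def test_no_bootstrap_gives_nan_interval(self, balanced_cohort):
        for est in estimate_selection(
            balanced_cohort, plan=ResamplingPlan(n_boot=0, n_perm=0)
        ):
            assert math.isnan(est.ci_low) and math.isnan(est.ci_high)
            assert est.n_boot_used == 0

    def test_fit_is_reproducible_under_seed(self):
        cohort = generate_cohort(GeneratorConfig.default().with_n_per_cell(40), seed=5)
        plan = ResamplingPlan(n_boot=100, n_perm=100, seed=21)
        r1 = SelectionModel(cohort).fit(plan)
        r2 = SelectionModel(cohort).fit(plan)
        assert r1.estimates.equals(r2.estimates)
        assert r1.contrasts.equals(r2.contrasts)

    def test_dropped_replicates_are_counted_and_flagged(self):
        # local cell with a single survivor among many dead: resamples
        # frequently contain no survivor, leaving s undefined
        values = {}
        for s in ("Italy", "Sweden"):
            for so in ("Italy", "Sweden"):
                values[(s, so, s)] = [(True, 5, 10)] + [(False, 0, None)] * 5
                values[(s, so, "Sweden" if s == "Italy" else "Italy")] = [
                    (True, 4, 8)
                ] * 6
        cohort = two_site_cohort(values=values)
        with pytest.warns(UserWarning, match="unreliable"):
            ests = estimate_selection(
                cohort, plan=ResamplingPlan(n_boot=200, n_perm=0, seed=3)
            )
        fec = [e for e in ests if e.component == "fecundity"]
        assert any(e.n_boot_dropped > 0 for e in fec)
        for e in fec:
            assert e.n_boot_used + e.n_boot_dropped == 200

    def test_missing_required_cell_is_a_configuration_error(self, balanced_cohort):
        df = balanced_cohort.data
        df = df[~((df.site == "Italy") & (df.soil == "Italy") & (df.ecotype == "Sweden"))]
        with pytest.raises(ConfigurationError, match="empty required cell"):
            SelectionModel(Cohort(df.reset_index(drop=True)))

    def test_unknown_local_ecotype_is_a_configuration_error(self, balanced_cohort):
        with pytest.raises(ConfigurationError, match="local ecotype"):
            SelectionModel(balanced_cohort, local_ecotype={"Italy": "Spain", "Sweden": "Sweden"})

    def test_more_than_two_labels_rejected(self):
        records = [
            make_record(i, site=s, soil=s, ecotype=s, fruits=2, seeds=4)
            for i, s in enumerate(["Italy", "Sweden", "Spain"])
        ]
        with pytest.raises(ConfigurationError, match="two-label"):
            SelectionModel(Cohort.from_records(records))


class TestSoilContrast:
    def test_identical_soils_give_zero_delta_and_p_one(self):
        # records on the two soils literally identical within site
        cohort = two_site_cohort()
        contrasts = soil_contrast(
            cohort, plan=ResamplingPlan(n_boot=0, n_perm=200, seed=2)
        )
        for c in contrasts:
            assert c.delta_s == 0.0
            assert c.p_value == 1.0

    def test_antisymmetry_under_soil_relabelling(self):
        cohort = generate_cohort(GeneratorConfig.default().with_n_per_cell(30), seed=9)
        plan = ResamplingPlan(n_boot=0, n_perm=300, seed=17)
        swapped = {"Italy": "Sweden", "Sweden": "Italy"}
        base = soil_contrast(cohort, plan=plan)
        flipped = soil_contrast(cohort, plan=plan, local_soil=swapped)
        for b, f in zip(base, flipped):
            assert f.delta_s == pytest.approx(-b.delta_s, abs=1e-15)
            assert f.p_value == b.p_value

    def test_absolute_tail_convention(self):
        cohort = generate_cohort(GeneratorConfig.default().with_n_per_cell(30), seed=9)
        contrasts = soil_contrast(
            cohort, plan=ResamplingPlan(n_boot=0, n_perm=200, seed=5, tail="absolute")
        )
        for c in contrasts:
            assert c.tail_convention == "absolute"
            assert 0.0 < c.p_value <= 1.0

    def test_plain_proportion_flag(self):
        cohort = generate_cohort(GeneratorConfig.default().with_n_per_cell(30), seed=9)
        add_one = soil_contrast(
            cohort, plan=ResamplingPlan(n_boot=0, n_perm=100, seed=5)
        )
        plain = soil_contrast(
            cohort, plan=ResamplingPlan(n_boot=0, n_perm=100, seed=5, add_one=False)
        )
        for a, p in zip(add_one, plain):
            assert a.p_value >= p.p_value  # the correction is conservative

    def test_p_values_lie_in_unit_interval(self):
        cohort = generate_cohort(GeneratorConfig.default().with_n_per_cell(25), seed=13)
        for c in soil_contrast(cohort, plan=ResamplingPlan(n_boot=0, n_perm=99, seed=1)):
            assert 0.0 < c.p_value <= 1.0
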
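import numpy as np
import pytest
from scipy import stats

from glynorm.normalize import (
    NormalizationSpec,
    apply_per_subclass,
    apply_strategy,
    enumerate_strategies,
    log_transform,
    median_center,
    probabilistic_quotient,
    quantile_normalize,
    rank_transform,
    spec_from_label,
    ta_quotient,
    total_area,
)
from glynorm.simulate import SimulationConfig, apply_artifacts, sample_abundances

TABLE_BASE_LABELS = [
    "Raw", "Quantile", "Rank", "TA", "Median", "Quotient", "TAQuotient",
    "Raw log", "Quantile log", "Rank log", "TA log", "Quotient log",
    "TAQuotient log",
]
TABLE_SUBCLASS_LABELS = [
    "Quantile subclass", "Rank subclass", "TA subclass", "Quotient subclass",
    "TAQuotient subclass", "Quantile log subclass", "Rank log subclass",
    "TA log subclass", "Quotient log subclass", "TAQuotient log subclass",
]


class TestTotalArea:
    def test_rows_become_relative_intensities(self, dataset_factory):
        d = dataset_factory([[2.0, 3.0, 5.0], [1.0, 1.0, 2.0]])
        out = total_area(d)
        np.testing.assert_allclose(out.values[0], [0.2, 0.3, 0.5])
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-12)

    def test_idempotent_on_closed_data(self, dataset_factory):
        d = dataset_factory([[0.2, 0.3, 0.5], [0.25, 0.25, 0.5]])
        np.testing.assert_allclose(total_area(d).values, d.values, atol=1e-15)

    def test_zero_row_sum_names_sample(self, dataset_factory):
        d = dataset_factory([[0.0, 0.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="s0"):
            total_area(d)

    def test_closure_induces_negative_covariance_rows(self, dataset_factory):
        # compositional artifact: every covariance row gains a negative entry
        rng = np.random.default_rng(0)
        for _ in range(50):
            d = dataset_factory(rng.lognormal(0, 1, size=(10, 6)))
            cov = np.cov(total_area(d).values, rowvar=False)
            assert (cov < 0).any(axis=1).all()


class TestMedianCenter:
    def test_per_sample_subtracts_row_median(self, dataset_factory):
        out = median_center(dataset_factory([[1.0, 2.0, 9.0]]), mode="per_sample")
        np.testing.assert_allclose(out.values[0], [-1.0, 0.0, 7.0])

    def test_per_glycan_subtracts_column_median(self, dataset_factory):
        out = median_center(dataset_factory([[1.0], [3.0], [5.0]]), mode="per_glycan")
        np.testing.assert_allclose(out.values[:, 0], [-2.0, 0.0, 2.0])

    @pytest.mark.parametrize("mode", ["per_sample", "per_glycan"])
    def test_constant_matrix_maps_to_zero(self, dataset_factory, mode):
        out = median_center(dataset_factory(np.full((4, 3), 7.0)), mode=mode)
        np.testing.assert_array_equal(out.values, 0.0)


class TestProbabilisticQuotient:
    def test_sample_at_twice_reference_gets_factor_two(self, dataset_factory):
        base = np.array([[1.0, 2.0, 4.0], [1.0, 2.0, 4.0], [1.0, 2.0, 4.0]])
        base[2] = 2 * base[0]
        out, factors = probabilistic_quotient(dataset_factory(base), return_factors=True)
        assert factors[2] == pytest.approx(2.0)
        np.testing.assert_allclose(out.values[2], [1.0, 2.0, 4.0])

    def test_identity_when_all_samples_equal_reference(self, dataset_factory):
        d = dataset_factory(np.tile([1.0, 2.0, 3.0], (4, 1)))
        out, factors = probabilistic_quotient(d, return_factors=True)
        np.testing.assert_allclose(factors, 1.0)
        np.testing.assert_allclose(out.values, d.values)

    def test_recovers_injected_dilution_factors(self, igg1_pathway):
        cfg = SimulationConfig(
            pathway=igg1_pathway, n=200, sigma=0.05, sigma_dilution=0.5, seed=7
        )
        clean, _ = sample_abundances(cfg)
        dirty, truth = apply_artifacts(clean, cfg)
        _, fhat = probabilistic_quotient(dirty, return_factors=True)
        rho = stats.spearmanr(fhat, truth["dilution_factors"]).statistic
        assert rho >= 0.99

    def test_zero_reference_median_rejected(self, dataset_factory):
        d = dataset_factory([[0.0, 1.0], [0.0, 2.0], [0.0, 3.0]])
        with pytest.raises(ValueError, match="g0"):
            probabilistic_quotient(d)


class TestTaQuotient:
    def test_single_sample_quotient_is_identity_after_closure(self, dataset_factory):
        out = ta_quotient(dataset_factory([[2.0, 3.0, 5.0]]))
        np.testing.assert_allclose(out.values[0], [0.2, 0.3, 0.5])

    def test_invariant_to_per_sample_rescaling(self, dataset_factory):
        rng = np.random.default_rng(1)
        x = rng.lognormal(0, 1, size=(8, 5))
        scaled = x.copy()
        scaled[3] *= 10.0
        a = ta_quotient(dataset_factory(x)).values
        b = ta_quotient(dataset_factory(scaled)).values
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_equals_manual_two_step_composition(self, dataset_factory):
        rng = np.random.default_rng(2)
        d = dataset_factory(rng.lognormal(0, 1, size=(10, 6)))
        np.testing.assert_allclose(
            ta_quotient(d).values, probabilistic_quotient(total_area(d)).values
        )


class TestQuantileNormalize:
    def test_two_columns_share_rank_means(self, dataset_factory):
        d = dataset_factory([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        out = quantile_normalize(d)
        np.testing.assert_allclose(out.values[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out.values[:, 1], [2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self, dataset_factory):
        col = np.array([3.0, 1.0, 2.0])
        d = dataset_factory(np.column_stack([col, col]))
        np.testing.assert_allclose(quantile_normalize(d).values, d.values)

    def test_ties_get_average_of_tied_position_means(self, dataset_factory):
        d = dataset_factory([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = quantile_normalize(d)
        # sorted means: (1+10)/2=5.5, (1+20)/2=10.5, (5+30)/2=17.5; the two
        # tied 1.0s share (5.5+10.5)/2
        np.testing.assert_allclose(out.values[:, 0], [8.0, 8.0, 17.5])

    def test_column_distributions_identical_after_op(self, dataset_factory):
        rng = np.random.default_rng(3)
        out = quantile_normalize(dataset_factory(rng.lognormal(0, 1, (50, 8))))
        ref = np.sort(out.values[:, 0])
        for j in range(1, 8):
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref, atol=1e-12)


class TestRankTransform:
    def test_ranks_across_samples(self, dataset_factory):
        out = rank_transform(dataset_factory([[10.0], [30.0], [20.0]]))
        np.testing.assert_array_equal(out.values[:, 0], [1.0, 3.0, 2.0])

    def test_ties_receive_average_ranks(self, dataset_factory):
        out = rank_transform(dataset_factory([[5.0], [5.0], [1.0]]))
        np.testing.assert_array_equal(out.values[:, 0], [2.5, 2.5, 1.0])

    def test_ranks_invariant_to_monotone_column_transform(self, dataset_factory):
        # a strictly monotone transform leaves rank output identical and the
        # rank pattern of the quantile-normalized output unchanged (its
        # values shift with the transformed rank-mean distribution)
        rng = np.random.default_rng(4)
        x = rng.lognormal(0, 1, size=(30, 4))
        mono = np.exp(x / x.max())
        np.testing.assert_allclose(
            rank_transform(dataset_factory(x)).values,
            rank_transform(dataset_factory(mono)).values,
            atol=1e-12,
        )
        qa = quantile_normalize(dataset_factory(x)).values
        qb = quantile_normalize(dataset_factory(mono)).values
        np.testing.assert_array_equal(np.argsort(qa, axis=0), np.argsort(qb, axis=0))


class TestLogTransform:
    def test_known_values(self, dataset_factory):
        out = log_transform(dataset_factory([[1.0, np.e, np.e**2]]))
        np.testing.assert_allclose(out.values[0], [0.0, 1.0, 2.0], atol=1e-15)

    def test_nonpositive_value_names_cell(self, dataset_factory):
        d = dataset_factory([[1.0, -2.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="'s0'.*'g1'"):
            log_transform(d)

    def test_changes_correlation_on_skewed_data(self, dataset_factory):
        rng = np.random.default_rng(5)
        z = rng.standard_normal((200, 2)) @ np.linalg.cholesky([[1, 0.5], [0.5, 1]]).T
        d = dataset_factory(np.exp(3 * z))
        before = np.corrcoef(d.values, rowvar=False)[0, 1]
        after = np.corrcoef(log_transform(d).values, rowvar=False)[0, 1]
        assert abs(after - before) > 0.05


class TestPerSubclass:
    @pytest.fixture
    def subclass_dataset(self, dataset_factory):
        rng = np.random.default_rng(6)
        meta = {"subclass": ["IgG1"] * 3 + ["IgG2/3"] * 2 + ["IgG4"] * 2}
        return dataset_factory(rng.lognormal(0, 0.5, size=(12, 7)), glycan_meta=meta)

    def test_total_area_closes_each_block(self, subclass_dataset):
        out = apply_per_subclass(NormalizationSpec("ta", per_subclass=True), subclass_dataset)
        np.testing.assert_allclose(out.values[:, :3].sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(out.values[:, 3:5].sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(out.values[:, 5:].sum(axis=1), 1.0, atol=1e-12)

    def test_single_subclass_equals_whole_dataset_application(self, dataset_factory):
        rng = np.random.default_rng(7)
        d = dataset_factory(
            rng.lognormal(0, 0.5, size=(10, 4)), glycan_meta={"subclass": ["IgG1"] * 4}
        )
        spec = NormalizationSpec("quotient", per_subclass=True)
        np.testing.assert_allclose(
            apply_per_subclass(spec, d).values, probabilistic_quotient(d).values
        )

    def test_equal_dilution_blocks_match_whole_dataset_quotient(self, dataset_factory):
        # same per-sample dilution in both blocks => per-subclass quotient
        # removes the same factor as the whole-dataset quotient
        rng = np.random.default_rng(8)
        base = np.tile(rng.lognormal(0, 0.3, size=4), (20, 1))
        x = np.hstack([base[:, :2], base[:, 2:]])
        f = rng.lognormal(0, 0.5, size=20)
        x = x * f[:, None]
        d = dataset_factory(x, glycan_meta={"subclass": ["IgG1", "IgG1", "IgG4", "IgG4"]})
        per = apply_per_subclass(NormalizationSpec("quotient", per_subclass=True), d)
        whole = probabilistic_quotient(d)
        np.testing.assert_allclose(per.values, whole.values, rtol=1e-10)

    def test_missing_subclass_labels_rejected(self, dataset_factory):
        d = dataset_factory(np.ones((3, 2)))
        with pytest.raises(ValueError, match="subclass"):
            apply_per_subclass(NormalizationSpec("ta", per_subclass=True), d)


class TestSpecAndEnumeration:
    def test_median_log_disallowed(self):
        with pytest.raises(ValueError):
            NormalizationSpec("median", log=True)

    @pytest.mark.parametrize("base", ["raw", "median"])
    def test_per_subclass_restricted(self, base):
        with pytest.raises(ValueError):
            NormalizationSpec(base, per_subclass=True)

    @pytest.mark.parametrize("platform", ["uhplc-fld", "maldi-fticr-ms", "generic"])
    def test_thirteen_base_strategies(self, platform):
        labels = [s.label for s in enumerate_strategies(platform)]
        assert labels == TABLE_BASE_LABELS

    def test_subclass_platform_gets_twenty_three(self):
        labels = [s.label for s in enumerate_strategies("lc-esi-ms")]
        assert labels == TABLE_BASE_LABELS + TABLE_SUBCLASS_LABELS
        assert len(labels) == 23

    def test_labels_roundtrip_through_parser(self):
        for spec in enumerate_strategies("lc-esi-ms"):
            assert spec_from_label(spec.label) == spec


class TestApplyStrategy:
    def test_raw_is_identity(self, dataset_factory):
        d = dataset_factory([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_array_equal(apply_strategy(spec_from_label("Raw"), d).values, d.values)

    def test_ta_log_composition(self, dataset_factory):
        d = dataset_factory([[2.0, 3.0, 5.0]])
        out = apply_strategy(spec_from_label("TA log"), d)
        np.testing.assert_allclose(out.values[0], np.log([0.2, 0.3, 0.5]))

    def test_log_variant_equals_log_of_base_variant(self, dataset_factory):
        rng = np.random.default_rng(9)
        d = dataset_factory(rng.lognormal(0, 0.5, size=(15, 5)))
        for label in ["Raw", "Quantile", "Rank", "TA", "Quotient", "TAQuotient"]:
            base = apply_strategy(spec_from_label(label), d)
            logged = apply_strategy(spec_from_label(f"{label} log"), d)
            np.testing.assert_allclose(logged.values, log_transform(base).values)

    def test_all_23_strategies_produce_finite_output(self, dataset_factory):
        rng = np.random.default_rng(10)
        meta = {"subclass": ["IgG1"] * 8 + ["IgG2/3"] * 8 + ["IgG4"] * 4}
        d = dataset_factory(
            rng.lognormal(5, 0.5, size=(30, 20)), glycan_meta=meta, platform="lc-esi-ms"
        )
        for spec in enumerate_strategies("lc-esi-ms"):
            out = apply_strategy(spec, d)
            assert np.isfinite(out.values).all(), spec.label
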
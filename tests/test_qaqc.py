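import numpy as np
import pandas as pd
import pytest

from metabopipe.errors import PipelineError
from metabopipe.models import Feature, FeatureTable
from metabopipe.qaqc import (
    acquisition_metrics,
    blank_mask,
    combat_correct,
    correlation_clustermap_data,
    detect_failed_acquisitions,
    drop_rare_features,
    impute_missing,
    pca_summary,
    tic_normalize,
)
from metabopipe.synthetic import generate_batch_matrix, generate_feature_experiment


def table_from_matrix(values, sample_names=None, feature_prefix="F"):
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    samples = sample_names or [f"s{j + 1}" for j in range(n_samp)]
    feats = [
        Feature(
            f"{feature_prefix}{i + 1:03d}",
            100.0 + i,
            10.0 * (i + 1),
            {s: float(values[i, j]) for j, s in enumerate(samples)},
        )
        for i in range(n_feat)
    ]
    return FeatureTable(features=feats, acquisitions=samples, provenance_tag="test")


class TestAcquisitionMetrics:
    def test_identical_samples(self):
        t = table_from_matrix(np.tile([[10.0], [20.0], [30.0]], (1, 4)))
        m = acquisition_metrics(t)
        assert np.allclose(m.table["median_correlation"], 1.0)
        assert np.allclose(m.table["z_feature_count"], 0.0)

    def test_low_count_sample_z(self):
        # counts 1000, 1010, 990, 100 planted via nonzero cells
        rng = np.random.default_rng(0)
        values = np.zeros((1010, 4))
        for j, n in enumerate([1000, 1010, 990, 100]):
            idx = rng.choice(1010, size=n, replace=False)
            values[idx, j] = rng.lognormal(10, 1, size=n)
        t = table_from_matrix(values)
        m = acquisition_metrics(t)
        zs = m.table["z_feature_count"]
        assert zs.idxmin() == "s4"
        assert zs["s4"] < -1.4

    def test_constant_shift_leaves_counts(self):
        values = np.array([[10.0, 20.0], [5.0, 0.0]])
        t0 = table_from_matrix(values)
        t1 = table_from_matrix(values + 7.0)
        c0 = acquisition_metrics(t0).table["feature_count"]
        c1 = acquisition_metrics(t1).table["feature_count"]
        # zero cells became nonzero, otherwise counts saturate at n_features
        assert (c1 >= c0).all()

    def test_zscores_standardized(self):
        t, _, _ = generate_feature_experiment(n_compounds=10, n_samples=8, seed=3)
        m = acquisition_metrics(t)
        for col in ("z_feature_count", "z_tic", "z_median_correlation"):
            z = m.table[col]
            if z.std(ddof=0) > 0:
                assert abs(z.mean()) < 1e-9
                assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_single_acquisition_error(self):
        t = table_from_matrix([[1.0], [2.0]])
        with pytest.raises(PipelineError):
            acquisition_metrics(t)


class TestFailedInjectionDetection:
    def test_planted_dropout_flagged(self):
        t, _, truth = generate_feature_experiment(
            n_compounds=30, n_samples=20, seed=2, n_failed=1, failed_fraction=0.9
        )
        flagged = detect_failed_acquisitions(acquisition_metrics(t))
        assert [a for a, _ in flagged] == truth.failed_acquisitions
        assert flagged[0][1] < -2

    def test_homogeneous_none_flagged(self):
        t = table_from_matrix(np.tile([[10.0], [20.0]], (1, 6)))
        assert detect_failed_acquisitions(acquisition_metrics(t)) == []

    def test_extreme_threshold_none_flagged(self):
        t, _, _ = generate_feature_experiment(
            n_compounds=30, n_samples=20, seed=2, n_failed=1, failed_fraction=0.9
        )
        assert detect_failed_acquisitions(acquisition_metrics(t), z_threshold=-10) == []


class TestTicNormalize:
    def test_two_sample_factors(self):
        t = table_from_matrix([[60.0, 200.0], [40.0, 100.0]])  # TICs 100, 300
        out, factors = tic_normalize(t)
        assert factors == {"s1": 2.0, "s2": pytest.approx(2 / 3)}
        tics = out.intensity_matrix().sum(axis=0)
        assert np.allclose(tics, 200.0, rtol=1e-9)

    def test_equal_tics_identity(self):
        t = table_from_matrix([[50.0, 50.0], [50.0, 50.0]])
        _, factors = tic_normalize(t)
        assert all(f == pytest.approx(1.0) for f in factors.values())

    def test_idempotent(self):
        t, _, _ = generate_feature_experiment(n_compounds=8, n_samples=5, seed=1)
        once, _ = tic_normalize(t)
        twice, factors2 = tic_normalize(once)
        assert all(f == pytest.approx(1.0, rel=1e-9) for f in factors2.values())
        m1, m2 = once.intensity_matrix(), twice.intensity_matrix()
        assert np.allclose(m1.values, m2.values, rtol=1e-9)

    def test_zero_tic_error_names_sample(self):
        t = table_from_matrix([[0.0, 10.0], [0.0, 20.0]])
        with pytest.raises(PipelineError, match="s1"):
            tic_normalize(t)

    def test_input_untouched(self):
        t = table_from_matrix([[60.0, 200.0]])
        before = t.intensity_matrix().copy()
        tic_normalize(t)
        assert t.intensity_matrix().equals(before)


class TestBlankMask:
    def test_arithmetic_example(self):
        # blank mean 100, study mean 250, k=3 -> dropped (250 < 300)
        t = table_from_matrix([[250.0, 250.0, 100.0], [900.0, 900.0, 100.0]])
        out, dropped = blank_mask(t, ["s3"], ratio_k=3.0)
        assert dropped == ["F001"]
        assert out.feature_ids() == ["F002"]
        assert out.acquisitions == ["s1", "s2"]  # blanks removed

    def test_absent_in_blanks_kept(self):
        t = table_from_matrix([[250.0, 250.0, 0.0]])
        out, dropped = blank_mask(t, ["s3"], ratio_k=3.0)
        assert dropped == [] and out.feature_ids() == ["F001"]

    def test_k_zero_drops_nothing(self):
        t = table_from_matrix([[1.0, 1.0, 1e9]])
        out, dropped = blank_mask(t, ["s3"], ratio_k=0.0)
        assert dropped == []

    def test_monotone_in_k(self):
        t, _, _ = generate_feature_experiment(
            n_compounds=15, n_samples=6, seed=8, n_blanks=2, blank_carryover=0.3
        )
        blanks = [a for a in t.acquisitions if a.startswith("B")]
        kept = []
        for k in (1.0, 3.0, 10.0):
            out, _ = blank_mask(t, blanks, ratio_k=k)
            kept.append(len(out.features))
        assert kept == sorted(kept, reverse=True)

    def test_no_blanks_error(self):
        t = table_from_matrix([[1.0, 2.0]])
        with pytest.raises(PipelineError):
            blank_mask(t, [])


class TestDropRare:
    def test_one_in_ten_dropped(self):
        values = np.zeros((1, 10))
        values[0, 0] = 5.0
        t = table_from_matrix(values)
        out = drop_rare_features(t, min_fraction=0.25)  # ceil(2.5)=3 > 1
        assert out.features == []

    def test_zero_fraction_identity(self):
        t, _, _ = generate_feature_experiment(n_compounds=5, n_samples=4, seed=0)
        out = drop_rare_features(t, min_fraction=0.0)
        assert out.feature_ids() == t.feature_ids()

    def test_full_fraction_requires_ubiquity(self):
        values = np.array([[1.0, 1.0, 1.0], [1.0, 0.0, 1.0]])
        t = table_from_matrix(values)
        out = drop_rare_features(t, min_fraction=1.0)
        assert out.feature_ids() == ["F001"]

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(4)
        values = (rng.random((30, 8)) > 0.5) * rng.lognormal(8, 1, (30, 8))
        t = table_from_matrix(values)
        kept = [len(drop_rare_features(t, f).features) for f in (0.0, 0.25, 0.5, 1.0)]
        assert kept == sorted(kept, reverse=True)


class TestImpute:
    def test_half_min_example(self):
        t = table_from_matrix([[0.0, 10.0, 20.0]])
        out = impute_missing(t)
        assert out.features[0].intensities == {"s1": 5.0, "s2": 10.0, "s3": 20.0}

    def test_no_zero_identity(self):
        t = table_from_matrix([[1.0, 2.0], [3.0, 4.0]])
        out = impute_missing(t)
        assert out.intensity_matrix().equals(t.intensity_matrix())

    def test_interaction_with_drop_rare(self):
        t = table_from_matrix([[0.0, 10.0, 20.0], [1.0, 2.0, 0.0]])
        imputed = impute_missing(t)
        out = drop_rare_features(imputed, min_fraction=1.0)
        assert out.feature_ids() == imputed.feature_ids()

    def test_all_zero_feature_error(self):
        t = table_from_matrix([[0.0, 0.0]])
        with pytest.raises(PipelineError):
            impute_missing(t)


class TestCombat:
    def test_between_batch_difference_reduced(self):
        t, labels, planted = generate_batch_matrix(
            n_features=50, n_samples=20, shift=1.0, scale=1.5, seed=7
        )
        out, model = combat_correct(t, labels, return_model=True)
        log0 = np.log10(t.intensity_matrix() + 1)
        log1 = np.log10(out.intensity_matrix() + 1)
        b1 = [s for s in t.acquisitions if labels[s] == "1"]
        b2 = [s for s in t.acquisitions if labels[s] == "2"]
        d0 = (log0[b2].mean(axis=1) - log0[b1].mean(axis=1)).abs().mean()
        d1 = (log1[b2].mean(axis=1) - log1[b1].mean(axis=1)).abs().mean()
        assert d1 <= 0.1 * d0

    def test_location_effects_recovered(self):
        t, labels, planted = generate_batch_matrix(seed=7)
        _, model = combat_correct(t, labels, return_model=True)
        est = (model.location_effect("2") - model.location_effect("1")).values
        want = np.array([planted[f.id] for f in t.features])
        assert np.corrcoef(est, want)[0, 1] > 0.9

    def test_delta_positive(self):
        t, labels, _ = generate_batch_matrix(seed=3)
        _, model = combat_correct(t, labels, return_model=True)
        assert (model.delta_sq_star > 0).all().all()

    def test_single_batch_error(self):
        t, labels, _ = generate_batch_matrix(seed=0)
        with pytest.raises(PipelineError):
            combat_correct(t, {s: "1" for s in t.acquisitions})

    def test_tiny_batch_error(self):
        t, labels, _ = generate_batch_matrix(seed=0)
        labels = dict(labels)
        labels[t.acquisitions[0]] = "3"
        with pytest.raises(PipelineError):
            combat_correct(t, labels)

    def test_null_batch_effect_near_identity(self):
        t, labels, _ = generate_batch_matrix(shift=0.0, shift_spread=0.0, scale=1.0, seed=5)
        out = combat_correct(t, labels)
        log0 = np.log10(t.intensity_matrix() + 1)
        log1 = np.log10(out.intensity_matrix() + 1)
        sd = log0.values.std()
        assert np.abs(log1.values - log0.values).max() < 0.25 * sd

    def test_constant_feature_passthrough(self):
        t, labels, _ = generate_batch_matrix(n_features=10, seed=1)
        const = Feature("FCONST", 500.0, 50.0, {s: 42.0 for s in t.acquisitions})
        t2 = FeatureTable(
            features=t.features + [const], acquisitions=t.acquisitions
        )
        with pytest.warns(UserWarning, match="constant"):
            out = combat_correct(t2, labels)
        assert out.get_feature("FCONST").intensities == const.intensities


class TestPCA:
    def test_single_discriminating_feature(self):
        values = np.ones((3, 4)) * 100.0
        values[0] = [10.0, 10.0, 10000.0, 10000.0]
        t = table_from_matrix(values)
        coords, evr = pca_summary(t, n_components=2)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_duplicate_samples_coincide(self):
        rng = np.random.default_rng(0)
        half = rng.lognormal(8, 1, (10, 3))
        t = table_from_matrix(np.hstack([half, half]))
        coords, _ = pca_summary(t)
        assert np.allclose(coords.values[:3], coords.values[3:], atol=1e-8)

    def test_explained_variance_monotone(self):
        t, _, _ = generate_feature_experiment(n_compounds=15, n_samples=8, seed=2)
        _, evr = pca_summary(t, n_components=5)
        assert all(a >= b - 1e-12 for a, b in zip(evr, evr[1:]))
        assert evr.sum() <= 1.0 + 1e-9

    def test_full_rank_gram_reconstruction(self):
        rng = np.random.default_rng(10)
        values = rng.lognormal(8, 1, (50, 10))
        t = table_from_matrix(values)
        coords, _ = pca_summary(t, n_components=10)
        log = np.log10(values + 1).T
        centered = log - log.mean(axis=0)
        # scores preserve the full geometry of the centered data
        assert np.allclose(coords.values @ coords.values.T, centered @ centered.T, atol=1e-8)

    def test_deterministic_signs(self):
        t, _, _ = generate_feature_experiment(n_compounds=10, n_samples=6, seed=3)
        c1, _ = pca_summary(t)
        c2, _ = pca_summary(t)
        assert c1.equals(c2)


class TestClustermap:
    def test_identical_pair_adjacent(self):
        rng = np.random.default_rng(1)
        a = rng.lognormal(8, 1, (20, 1))
        b = a.copy()
        trend = np.linspace(1, 2, 20).reshape(-1, 1) * 1000
        t = table_from_matrix(np.hstack([a, trend, b]))
        corr, order = correlation_clustermap_data(t)
        ia, ib = order.index("s1"), order.index("s3")
        assert abs(ia - ib) == 1

    def test_identical_samples_matrix_of_ones(self):
        t = table_from_matrix(np.tile([[10.0], [50.0], [90.0]], (1, 4)))
        corr, _ = correlation_clustermap_data(t)
        assert np.allclose(corr.values, 1.0)

    def test_symmetry_and_unit_diagonal(self):
        t, _, _ = generate_feature_experiment(n_compounds=10, n_samples=6, seed=4)
        corr, _ = correlation_clustermap_data(t)
        assert np.allclose(corr.values, corr.values.T)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_leaf_order_deterministic(self):
        t, _, _ = generate_feature_experiment(n_compounds=10, n_samples=6, seed=4)
        _, o1 = correlation_clustermap_data(t)
        _, o2 = correlation_clustermap_data(t)
        assert o1 == o2


class TestProvenanceAndPurity:
    def test_tags_updated_and_input_untouched(self):
        t, _, _ = generate_feature_experiment(
            n_compounds=8, n_samples=6, seed=0, n_blanks=1
        )
        before = t.intensity_matrix().copy()
        out, _ = tic_normalize(t)
        assert "tic_normalized" in out.provenance_tag
        out2, _ = blank_mask(out, [a for a in t.acquisitions if a.startswith("B")])
        assert "blank_masked" in out2.provenance_tag
        out3 = drop_rare_features(out2)
        out4 = impute_missing(out3)
        assert "imputed" in out4.provenance_tag
        assert t.intensity_matrix().equals(before)
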
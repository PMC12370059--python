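import numpy as np
import pytest

from tempocode.embeddings import (
    MissingModelError,
    NormalizationError,
    RescaleError,
    codon_features,
    cpd_fit,
    cpd_weights,
    feature_matrix,
    fpca_fit,
    normalize_tensor_per_drug,
    quadrature_weights,
    r2x,
    rescale_temporal,
    trajectory_features,
)
from tempocode.embeddings.cpd import CPDModel


def rank1_tensor(seed=0, shape=(4, 3, 5, 6, 24)):
    rng = np.random.default_rng(seed)
    vecs = [rng.uniform(0.5, 2.0, s) for s in shape]
    return np.einsum("i,j,k,l,t->ijklt", *vecs), vecs


class TestNormalizeTensorPerDrug:
    def test_halves_slab_with_max_two(self):
        t = np.ones((2, 2, 2, 2, 4))
        t[:, :, 0] *= 2.0
        out = normalize_tensor_per_drug(t)
        assert out[:, :, 0].max() == pytest.approx(1.0)
        assert out[:, :, 1].max() == pytest.approx(1.0)
        assert np.allclose(out[:, :, 0], t[:, :, 0] / 2.0)

    def test_unit_max_slab_unchanged(self):
        rng = np.random.default_rng(1)
        t = rng.random((2, 2, 3, 2, 4))
        t /= t.max(axis=(0, 1, 3, 4), keepdims=True)
        assert np.allclose(normalize_tensor_per_drug(t), t)

    def test_decouples_drug_scales(self):
        rng = np.random.default_rng(2)
        t = rng.random((2, 2, 2, 2, 4)) + 0.1
        t[:, :, 0] *= 1.0 / t[:, :, 0].max()
        t[:, :, 1] *= 10.0 / t[:, :, 1].max()
        out = normalize_tensor_per_drug(t)
        for k in range(2):
            assert out[:, :, k].max() == pytest.approx(1.0)

    def test_zero_slab_raises_naming_drug(self):
        t = np.ones((2, 2, 2, 2, 4))
        t[:, :, 1] = 0.0
        with pytest.raises(NormalizationError, match="drugB"):
            normalize_tensor_per_drug(t, drug_labels=["drugA", "drugB"])


class TestCpdFit:
    def test_exact_rank1_recovery(self):
        tensor, _ = rank1_tensor()
        model = cpd_fit(tensor, rank=1, seed=0, max_iter=300, restarts=2)
        assert model.r2x >= 0.999

    def test_rank2_at_least_as_good_as_rank1(self):
        tensor, _ = rank1_tensor(seed=3)
        r1 = cpd_fit(tensor, rank=1, seed=0, max_iter=200, restarts=2)
        r2 = cpd_fit(tensor, rank=2, seed=0, max_iter=200, restarts=2)
        assert r2.r2x >= r1.r2x - 1e-9

    def test_rank_zero_invalid(self):
        tensor, _ = rank1_tensor()
        with pytest.raises(ValueError):
            cpd_fit(tensor, rank=0)

    def test_negative_tensor_invalid(self):
        with pytest.raises(ValueError):
            cpd_fit(-np.ones((2, 2, 2)), rank=1)

    def test_time_permutation_leaves_r2x_invariant(self):
        # CPD ignores timepoint order; fPCA does not
        rng = np.random.default_rng(8)
        tensor = rng.random((3, 2, 2, 2, 12))
        perm = np.r_[6:12, 0:6]
        a = cpd_fit(tensor, rank=2, seed=1, max_iter=400, restarts=3)
        b = cpd_fit(tensor[..., perm], rank=2, seed=1, max_iter=400, restarts=3)
        assert a.r2x == pytest.approx(b.r2x, abs=5e-3)

        times = np.arange(12.0)
        X = tensor.reshape(-1, 12)
        fa = fpca_fit(X, 2, times)
        fb = fpca_fit(X[:, perm], 2, times)
        assert not np.allclose(fa.eigenfunctions, fb.eigenfunctions)


class TestRescaleTemporal:
    def _fitted(self, seed=0):
        tensor, _ = rank1_tensor(seed=seed)
        return tensor, cpd_fit(
            tensor, rank=1, seed=0, max_iter=300, restarts=1,
            time_minutes=np.arange(24.0) * 20,
        )

    def test_area_forty_halves_and_rho_two(self):
        _, model = self._fitted()
        t_hours = model.time_minutes / 60.0
        # force the temporal factor to area 40
        area = np.trapezoid(model.temporal_factors[:, 0], x=t_hours)
        model.factors[-1] *= 40.0 / area
        model.lambdas *= area / 40.0
        rescaled = rescale_temporal(model, target_area=20.0)
        assert np.allclose(
            rescaled.temporal_factors, model.temporal_factors / 2.0
        )
        assert rescaled.rho[0] == pytest.approx(2.0)

    def test_factor_already_at_target_gets_unit_rho(self):
        _, model = self._fitted(seed=5)
        t_hours = model.time_minutes / 60.0
        area = np.trapezoid(model.temporal_factors[:, 0], x=t_hours)
        model.factors[-1] *= 20.0 / area
        model.lambdas *= area / 20.0
        rescaled = rescale_temporal(model, target_area=20.0)
        assert rescaled.rho[0] == pytest.approx(1.0)

    def test_reconstruction_preserved_to_1e10(self):
        tensor, model = self._fitted(seed=9)
        rescaled = rescale_temporal(model)
        diff = np.max(np.abs(model.reconstruct() - rescaled.reconstruct()))
        assert diff <= 1e-10
        assert rescaled.r2x == model.r2x  # R2X invariant under rescale

    def test_rescaled_areas_are_target(self):
        tensor, _ = rank1_tensor(seed=11)
        model = cpd_fit(tensor, rank=2, seed=0, max_iter=300, restarts=2,
                        time_minutes=np.arange(24.0) * 20)
        rescaled = rescale_temporal(model)
        areas = np.trapezoid(
            rescaled.temporal_factors, x=rescaled.time_minutes / 60.0, axis=0
        )
        assert np.allclose(areas, 20.0, rtol=1e-6)


class TestCpdWeights:
    def test_direct_product(self):
        factors = [np.ones((2, 1)) for _ in range(5)]
        model = CPDModel(rank=1, factors=factors, lambdas=np.array([2.0]),
                         rho=np.array([0.5]))
        assert cpd_weights(model, 0, 0, 0, 0)[0] == pytest.approx(1.0)

    def test_zero_factor_entry_zeroes_weight(self):
        factors = [np.ones((2, 1)) for _ in range(5)]
        factors[2][1, 0] = 0.0
        model = CPDModel(rank=1, factors=factors, lambdas=np.array([3.0]))
        assert cpd_weights(model, 0, 0, 1, 0)[0] == 0.0

    def test_rank1_weights_reproduce_trajectories(self):
        tensor, _ = rank1_tensor(seed=13)
        model = cpd_fit(tensor, rank=1, seed=0, max_iter=400, restarts=2,
                        time_minutes=np.arange(24.0))
        model = rescale_temporal(model)
        for idx in [(0, 0, 0, 0), (3, 2, 4, 5), (1, 1, 2, 3)]:
            w = model.weights(*idx)
            approx = w @ model.temporal_factors.T
            assert np.allclose(approx, tensor[idx], rtol=1e-6, atol=1e-8)

    def test_index_out_of_range(self):
        tensor, _ = rank1_tensor()
        model = cpd_fit(tensor, rank=1, seed=0, max_iter=50, restarts=1)
        with pytest.raises(IndexError):
            model.weights(99, 0, 0, 0)


class TestFpca:
    def test_single_pattern_explains_everything(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 480, 161)
        mu = 0.3 + 0.1 * np.sin(t / 80)
        phi = np.cos(t / 60)
        c = rng.normal(size=50)
        X = mu[None, :] + c[:, None] * phi[None, :]
        model = fpca_fit(X, 3, t)
        assert model.explained_variance_ratio[0] >= 0.999

    def test_eigenfunction_orthonormality_under_quadrature(self):
        rng = np.random.default_rng(6)
        t = np.linspace(0, 480, 97)
        X = rng.random((40, 97))
        model = fpca_fit(X, 5, t)
        w = quadrature_weights(t)
        gram = (model.eigenfunctions * w[None, :]) @ model.eigenfunctions.T
        assert np.max(np.abs(gram - np.eye(5))) < 1e-6

    def test_reconstruction_error_decreases_with_components(self):
        rng = np.random.default_rng(10)
        t = np.linspace(0, 480, 49)
        X = rng.random((30, 49))
        errors = []
        for r in range(1, 6):
            model = fpca_fit(X, r, t)
            errors.append(float(np.sum((model.reconstruct() - X) ** 2)))
        assert np.all(np.diff(errors) < 0)

    def test_mean_trajectory_has_zero_scores(self):
        rng = np.random.default_rng(12)
        t = np.linspace(0, 480, 49)
        X = rng.random((30, 49))
        model = fpca_fit(X, 4, t)
        assert np.max(np.abs(model.transform(X.mean(axis=0)))) < 1e-8

    def test_full_rank_variance_sums_to_one(self):
        rng = np.random.default_rng(14)
        X = rng.random((10, 25))
        model = fpca_fit(X, 10, np.arange(25.0))
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)

    def test_invalid_component_count(self):
        with pytest.raises(ValueError):
            fpca_fit(np.random.default_rng(0).random((5, 8)), 9, np.arange(8.0))


class TestFeatureMatrix:
    def test_codon_space_is_15_by_6(self, full_run):
        fm = codon_features(
            full_run["norm"], "untreated", full_run["tset"].stimulus_order
        )
        assert fm.values.shape == (15, 6)
        assert fm.stimulus_order[0] == "TNF_L"

    def test_trajectory_space_shape(self, full_run):
        tset = full_run["tset"]
        fm = trajectory_features(tset, "untreated")
        assert fm.values.shape == (15, tset.grid.n_points)

    def test_fpca5_space_is_15_by_5(self, full_run):
        tset = full_run["tset"]
        X = np.vstack([
            tset.trajectories[rid][s].values
            for rid in tset.regime_ids for s in tset.stimulus_order
        ])
        model = fpca_fit(X, 5, tset.grid.times)
        fm = feature_matrix("fpca5", "untreated", tset=tset, fpca_model=model)
        assert fm.values.shape == (15, 5)
        assert fm.space == "fpca5"

    def test_missing_model_raises_state_error(self):
        with pytest.raises(MissingModelError):
            feature_matrix("fpca5", "untreated")
        with pytest.raises(MissingModelError):
            feature_matrix("cpd7", "untreated")
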
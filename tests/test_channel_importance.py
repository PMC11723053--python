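"""Importance suite: mutual information, CSP, permutation, random search,
attention gates — unit-level oracles and invariants."""

import numpy as np
import pytest

from mieog.channel_importance import (
    ImportanceResult,
    attention_importance,
    csp_fit,
    csp_from_covariances,
    csp_pattern_activation,
    entropy,
    mi_matrix,
    mutual_information,
    permutation_importance,
    random_search,
)
from mieog.data_model import Modality

from conftest import make_dataset


class TestEntropy:
    @pytest.mark.parametrize("p,expected", [
        ([0.25, 0.25, 0.25, 0.25], 2.0),
        ([1.0, 0.0, 0.0], 0.0),
        ([0.5, 0.25, 0.25], 1.5),
    ])
    def test_closed_forms(self, p, expected):
        assert entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_invalid_distributions_rejected(self):
        with pytest.raises(ValueError):
            entropy([-0.1, 1.1])
        with pytest.raises(ValueError):
            entropy([0.5, 0.4])


class TestMutualInformation:
    def test_identity_equals_binned_entropy(self):
        x = np.random.default_rng(0).standard_normal(10_000)
        hist, _ = np.histogram(x, bins=64)
        hx = entropy(hist / hist.sum())
        assert mutual_information(x, x, n_bins=64) == pytest.approx(hx, abs=1e-12)

    def test_exact_two_by_two_joint(self):
        # joint {0.4, 0.1; 0.1, 0.4} sampled exactly: I = 0.278072 bits
        x = np.repeat([0, 0, 1, 1], [400, 100, 100, 400]).astype(float)
        y = np.repeat([0, 1, 0, 1], [400, 100, 100, 400]).astype(float)
        got = mutual_information(x, y, n_bins=2)
        # independent brute-force plug-in over the 4 cells
        pxy = np.array([[0.4, 0.1], [0.1, 0.4]])
        brute = sum(
            pxy[i, j] * np.log2(pxy[i, j] / (pxy[i].sum() * pxy[:, j].sum()))
            for i in range(2) for j in range(2)
        )
        assert got == pytest.approx(brute, abs=1e-12)
        assert got == pytest.approx(0.2780719051, abs=1e-9)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=200_000)
        y = rng.uniform(size=200_000)
        assert mutual_information(x, y, n_bins=16) < 0.01

    def test_symmetry_and_bound(self):
        rng = np.random.default_rng(2)
        for _ in range(3):
            x = rng.standard_normal(5_000)
            y = 0.5 * x + rng.standard_normal(5_000)
            ixy = mutual_information(x, y)
            iyx = mutual_information(y, x)
            assert ixy == pytest.approx(iyx, abs=1e-12)
            hx = mutual_information(x, x)
            hy = mutual_information(y, y)
            assert ixy <= min(hx, hy) + 1e-9

    def test_constant_input_warns_and_returns_zero(self):
        x = np.zeros(100)
        y = np.random.default_rng(3).standard_normal(100)
        with pytest.warns(UserWarning, match="single bin"):
            assert mutual_information(x, y, n_bins=8) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros(10), np.zeros(11), n_bins=4)


class TestMiMatrix:
    def test_duplicated_eog_channel_attains_row_maximum(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((6, 4, 200))
        data[:, 1, :] = data[:, 3, :]  # EEG1 duplicates the EOG channel
        ds = make_dataset(data, [0, 1] * 3, eog_names=("EOG0",))
        result = mi_matrix(ds, n_bins=32)
        assert result.matrix.shape == (1, 3)
        assert np.argmax(result.matrix[0]) == 1

    def test_independent_channels_near_zero(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((10, 3, 12_000))
        ds = make_dataset(data, [0, 1] * 5, eog_names=("EOG0",))
        result = mi_matrix(ds, n_bins=16)
        assert np.all(result.matrix < 0.01)

    def test_requires_eog(self, small_dataset):
        from mieog.data_model import select_channels

        eeg_only = select_channels(small_dataset, [f"EEG{i}" for i in range(5)])
        with pytest.raises(ValueError, match="EOG"):
            mi_matrix(eeg_only)

    def test_bound_holds_on_real_matrix(self, small_dataset):
        result = mi_matrix(small_dataset, n_bins=32)
        assert np.all(result.matrix >= 0)
        for i, eog in enumerate(result.eog_names):
            for j, eeg in enumerate(result.eeg_names):
                bound = min(result.marginal_entropies[eog],
                            result.marginal_entropies[eeg])
                assert result.matrix[i, j] <= bound + 1e-9


class TestCsp:
    def test_injected_diagonal_covariances(self):
        S, R = np.diag([4.0, 1.0]), np.diag([1.0, 4.0])
        res = csp_from_covariances(S, R)
        assert np.allclose(res.eigenvalues_lambda, [4.0, 0.25], atol=1e-10)
        # filters align with coordinate axes
        for col in res.filters_w.T:
            col = np.abs(col / np.abs(col).max())
            assert np.allclose(sorted(col), [0.0, 1.0], atol=1e-8)
        # generalized eigenproblem satisfied: S w = lam R w
        for lam, w in zip(res.eigenvalues_lambda, res.filters_w.T):
            assert np.allclose(S @ w, lam * (R @ w), atol=1e-8)
        assert np.allclose(res.patterns.T @ res.filters_w, np.eye(2), atol=1e-6)

    def test_identical_covariances_unit_eigenvalues(self):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((3, 3))
        S = A @ A.T + np.eye(3)
        res = csp_from_covariances(S, S.copy())
        assert np.allclose(res.eigenvalues_lambda, 1.0, atol=1e-6)

    def test_swapping_classes_inverts_eigenvalues(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((3, 3))
        B = rng.standard_normal((3, 3))
        S, R = A @ A.T + np.eye(3), B @ B.T + np.eye(3)
        fwd = csp_from_covariances(S, R)
        rev = csp_from_covariances(R, S)
        assert np.allclose(
            np.sort(rev.eigenvalues_lambda), np.sort(1.0 / fwd.eigenvalues_lambda),
            rtol=1e-8,
        )

    @pytest.mark.parametrize("dim", [2, 3])
    def test_eigenvalues_match_rayleigh_grid_oracle(self, dim):
        rng = np.random.default_rng(8 + dim)
        A = rng.standard_normal((dim, dim))
        B = rng.standard_normal((dim, dim))
        S, R = A @ A.T + 0.5 * np.eye(dim), B @ B.T + 0.5 * np.eye(dim)
        res = csp_from_covariances(S, R)
        if dim == 2:
            theta = np.linspace(0, np.pi, 20_000, endpoint=False)
            ws = np.stack([np.cos(theta), np.sin(theta)])
        else:
            n = 200_000
            idx = np.arange(n)
            phi = np.arccos(1 - 2 * (idx + 0.5) / n)
            ang = np.pi * (1 + 5 ** 0.5) * idx
            ws = np.stack([np.sin(phi) * np.cos(ang), np.sin(phi) * np.sin(ang), np.cos(phi)])
        rayleigh = np.einsum("dn,de,en->n", ws, S, ws) / np.einsum("dn,de,en->n", ws, R, ws)
        assert rayleigh.max() == pytest.approx(res.eigenvalues_lambda[0], rel=0.01)
        assert rayleigh.min() == pytest.approx(res.eigenvalues_lambda[-1], rel=0.01)

    def test_projected_variance_ratio_matches_eigenvalue(self):
        rng = np.random.default_rng(11)
        n, L = 300, 200
        sd_a, sd_b = np.array([2.0, 1.0]), np.array([1.0, 2.0])
        data = np.concatenate([
            rng.standard_normal((n, 2, L)) * sd_a[None, :, None],
            rng.standard_normal((n, 2, L)) * sd_b[None, :, None],
        ])
        ds = make_dataset(data, [0] * n + [1] * n)
        res = csp_fit(ds, 0, 1)
        for j, w in enumerate(res.filters_w.T):
            proj = np.einsum("c,ncl->nl", w, ds.data)
            var_a = proj[:n].var(axis=1).mean()
            var_b = proj[n:].var(axis=1).mean()
            # trace normalization rescales both classes identically here
            assert var_a / var_b == pytest.approx(res.eigenvalues_lambda[j], rel=0.15)

    def test_orthonormal_filters_patterns_equal_filters(self):
        theta = 0.4
        Q = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        from mieog.channel_importance import CSPResult

        res = CSPResult(filters_w=Q, eigenvalues_lambda=np.array([2.0, 0.5]),
                        patterns=np.linalg.inv(Q).T, class_pair="toy")
        assert np.allclose(res.patterns, Q, atol=1e-12)
        imp = csp_pattern_activation(res, n_patterns=2)
        assert np.allclose(imp.metadata["activation"], np.abs(Q), atol=1e-12)

    def test_missing_class_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="class"):
            csp_fit(small_dataset, 99)

    def test_n_patterns_validated(self):
        res = csp_from_covariances(np.eye(2), np.eye(2))
        with pytest.raises(ValueError, match="n_patterns"):
            csp_pattern_activation(res, n_patterns=5)


class _ChannelZeroModel:
    """Predicts from channel 0's mean only; ignores every other channel."""

    n_channels = 3

    def predict(self, data):
        return (data[:, 0, :].mean(axis=1) > 0).astype(int)


class TestPermutationImportance:
    def _dataset(self, rng):
        data = rng.standard_normal((40, 3, 32))
        labels = (data[:, 0, :].mean(axis=1) > 0).astype(int)
        data[:, 2, :] = 1.0  # constant channel
        return make_dataset(data, labels)

    def test_ignored_and_constant_channels_score_zero(self):
        rng = np.random.default_rng(12)
        ds = self._dataset(rng)
        result = permutation_importance(_ChannelZeroModel(), ds, n_repeats=5, seed=0)
        assert result.scores[1] == 0.0  # model invariant to channel 1
        assert result.scores[2] == 0.0  # permuting a constant is a no-op
        assert result.scores[0] > 0.2   # the informative channel drops accuracy
        assert result.metadata["baseline_accuracy"] == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        ds = self._dataset(rng)
        r1 = permutation_importance(_ChannelZeroModel(), ds, n_repeats=3, seed=5)
        r2 = permutation_importance(_ChannelZeroModel(), ds, n_repeats=3, seed=5)
        assert np.array_equal(r1.scores, r2.scores)

    def test_channel_count_mismatch_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="channels"):
            permutation_importance(_ChannelZeroModel(), small_dataset)


class TestRandomSearch:
    def test_hand_computed_equation_scores(self):
        rng = np.random.default_rng(14)
        ds = make_dataset(rng.standard_normal((8, 3, 16)), [0, 1] * 4)
        weights = {frozenset({"EEG0", "EEG1"}): 0.6,
                   frozenset({"EEG1", "EEG2"}): 0.8,
                   frozenset({"EEG0", "EEG2"}): 0.7}

        def trainer(sub, seed):
            return weights[frozenset(sub.channel_names)]

        result = random_search(ds, subset_size=2, n_iterations=200,
                               trainer=trainer, seed=0)
        # each channel's score is the mean accuracy over its occurrences;
        # with only two distinct weights per channel the mean depends on the
        # occurrence counts, so force one occurrence each via explicit subsets
        result = random_search(ds, subset_size=2, n_iterations=3,
                               trainer=trainer, seed=0,
                               subsets=[(0, 1), (1, 2), (0, 2)])
        assert np.allclose(result.scores, [0.65, 0.70, 0.75], atol=1e-12)

    def test_constant_weights_give_constant_scores(self):
        rng = np.random.default_rng(15)
        ds = make_dataset(rng.standard_normal((8, 4, 16)), [0, 1] * 4)
        result = random_search(ds, subset_size=2, n_iterations=40,
                               trainer=lambda sub, seed: 0.42, seed=1)
        seen = ~np.isnan(result.scores)
        assert np.allclose(result.scores[seen], 0.42)

    def test_score_invariant_to_subset_order(self):
        rng = np.random.default_rng(16)
        ds = make_dataset(rng.standard_normal((8, 3, 16)), [0, 1] * 4)
        subsets = [(0, 1), (1, 2), (0, 2), (0, 1)]

        def trainer(sub, seed):
            return float(len(sub.channel_names[0]))  # deterministic per subset

        fwd = random_search(ds, subset_size=2, n_iterations=4, trainer=trainer,
                            seed=0, subsets=subsets)
        rev = random_search(ds, subset_size=2, n_iterations=4, trainer=trainer,
                            seed=0, subsets=subsets[::-1])
        assert np.allclose(fwd.scores, rev.scores)

    def test_planted_oracle_trainer(self):
        rng = np.random.default_rng(17)
        ds = make_dataset(rng.standard_normal((8, 6, 16)), [0, 1] * 4)

        def oracle(sub, seed):
            return 1.0 if "EEG2" in sub.channel_names else 0.5

        result = random_search(ds, subset_size=3, n_iterations=200,
                               trainer=oracle, seed=2)
        assert result.scores[2] == 1.0
        others = np.delete(result.scores, 2)
        assert np.all(others[~np.isnan(others)] < 1.0)
        assert result.ranking[0] == 2

    def test_never_selected_channel_flagged(self):
        rng = np.random.default_rng(18)
        ds = make_dataset(rng.standard_normal((8, 3, 16)), [0, 1] * 4)
        with pytest.warns(UserWarning, match="never selected"):
            result = random_search(ds, subset_size=2, n_iterations=2,
                                   trainer=lambda sub, seed: 0.5, seed=0,
                                   subsets=[(0, 1), (0, 1)])
        assert np.isnan(result.scores[2])
        assert result.ranking[-1] == 2  # NaN ranks last


class TestAttentionImportance:
    def test_model_without_attention_rejected(self, small_dataset):
        from mieog.neural_model import ModelConfig, build_model

        model = build_model(ModelConfig(
            n_channels=small_dataset.n_channels, n_samples=small_dataset.n_samples,
            n_classes=small_dataset.n_classes, filters_per_kernel=2, pool_size=8,
        ))
        with pytest.raises(ValueError, match="attention"):
            attention_importance(model, small_dataset)

    def test_zero_initialized_gates_are_half(self, small_dataset):
        from mieog.neural_model import ModelConfig, build_model

        model = build_model(ModelConfig(
            n_channels=small_dataset.n_channels, n_samples=small_dataset.n_samples,
            n_classes=small_dataset.n_classes, filters_per_kernel=2, pool_size=8,
            attention_enabled=True,
        ))
        for p in model.attention.params():
            p.value[...] = 0.0
        result = attention_importance(model, small_dataset)
        assert np.allclose(result.scores, 0.5, atol=1e-12)

    def test_gates_strictly_inside_unit_interval(self, small_dataset):
        from mieog.neural_model import ModelConfig, build_model

        model = build_model(ModelConfig(
            n_channels=small_dataset.n_channels, n_samples=small_dataset.n_samples,
            n_classes=small_dataset.n_classes, filters_per_kernel=2, pool_size=8,
            attention_enabled=True,
        ), seed=3)
        gates = model.attention_gates(small_dataset.data)
        assert np.all(gates > 0.0) and np.all(gates < 1.0)


class TestRankingConvention:
    def test_ties_broken_by_ascending_index(self):
        result = ImportanceResult("toy", np.array([0.5, 0.9, 0.5, 0.9]))
        assert result.ranking.tolist() == [1, 3, 0, 2]
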
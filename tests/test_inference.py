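import numpy as np
import pytest

from metnetbench import inference as inf
from metnetbench.synthetic_data import SampleMatrix
from tests.conftest import assoc_from, names


def samples_from(values) -> SampleMatrix:
    """Wrap an array as concentrations, shifting columns to be nonnegative.

    Every estimator under test is invariant to per-column shifts, so the
    shift never changes an expected value.
    """
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        values = values - values.min(axis=0, keepdims=True)
    return SampleMatrix(names(values.shape[1]), values)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def clr_two_loop(a: np.ndarray) -> np.ndarray:
    """Direct two-loop z-score CLR, the oracle for clr_transform."""
    a = np.abs(a)
    n = a.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            row_i = np.delete(a[i], i)
            row_j = np.delete(a[j], j)
            zi = (a[i, j] - row_i.mean()) / row_i.std() if row_i.std() > 0 else 0.0
            zj = (a[j, i] - row_j.mean()) / row_j.std() if row_j.std() > 0 else 0.0
            out[i, j] = np.sqrt(max(0.0, zi) ** 2 + max(0.0, zj) ** 2)
    return out


def mrmr_greedy_oracle(a: np.ndarray) -> np.ndarray:
    """Plain-list greedy MRMR recursion, the oracle for mrnet."""
    n = a.shape[0]
    directed = np.zeros((n, n))
    for t in range(n):
        remaining = [f for f in range(n) if f != t]
        chosen: list[int] = []
        while remaining:
            best_f, best_s = None, -np.inf
            for f in remaining:
                red = sum(a[f, s] for s in chosen) / len(chosen) if chosen else 0.0
                s = a[f, t] - red
                if s > best_s:
                    best_f, best_s = f, s
            directed[best_f, t] = max(0.0, best_s)
            remaining.remove(best_f)
            chosen.append(best_f)
    out = np.maximum(directed, directed.T)
    np.fill_diagonal(out, 0.0)
    return out


def pcor_residual_oracle(x: np.ndarray, i: int, j: int) -> float:
    """Partial correlation of columns i, j given the rest, by regressing each
    on the remaining columns and correlating the residuals."""
    others = [k for k in range(x.shape[1]) if k not in (i, j)]
    z = np.column_stack([np.ones(len(x)), x[:, others]])
    ri = x[:, i] - z @ np.linalg.lstsq(z, x[:, i], rcond=None)[0]
    rj = x[:, j] - z @ np.linalg.lstsq(z, x[:, j], rcond=None)[0]
    return float(np.corrcoef(ri, rj)[0, 1])


# ---------------------------------------------------------------------------
# correlation family
# ---------------------------------------------------------------------------


class TestCorrelation:
    @pytest.mark.parametrize("method", ["pearson", "spearman", "kendall", "bicor"])
    def test_perfect_linear_pair(self, method):
        s = samples_from([[1, 2], [2, 4], [3, 6]])
        a = inf.correlation_association(s, method)
        assert a.values[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert a.family == inf.SIGNED

    def test_monotone_nonlinear_separates_rank_from_linear(self):
        x = np.arange(1, 8, dtype=float)
        s = samples_from(np.column_stack([x, x**2]))
        spearman = inf.correlation_association(s, "spearman").values[0, 1]
        pearson = inf.correlation_association(s, "pearson").values[0, 1]
        assert spearman == pytest.approx(1.0)
        assert pearson < 1.0

    def test_bicor_close_to_pearson_without_outliers(self, rng):
        cov = [[1.0, 0.8], [0.8, 1.0]]
        x = rng.multivariate_normal([0, 0], cov, size=200)
        s = samples_from(x)
        bicor = inf.correlation_association(s, "bicor").values[0, 1]
        pearson = inf.correlation_association(s, "pearson").values[0, 1]
        assert bicor == pytest.approx(pearson, abs=0.1)

    def test_bicor_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.standard_normal((50, 3))
        x[:, 1] += 0.5 * x[:, 0]
        ours = inf.correlation_association(samples_from(x), "bicor").values
        for i in range(3):
            for j in range(i + 1, 3):
                ref = pingouin.corr(x[:, i], x[:, j], method="bicor")["r"].iloc[0]
                assert ours[i, j] == pytest.approx(ref, abs=1e-10)

    def test_too_few_samples(self):
        with pytest.raises(inf.SampleSizeError):
            inf.correlation_association(samples_from([[1, 2], [3, 4]]), "pearson")

    def test_constant_column_yields_zero(self):
        s = samples_from([[1, 5], [2, 5], [3, 5]])
        a = inf.correlation_association(s, "pearson")
        assert a.values[0, 1] == 0.0


class TestPartialCorrelation:
    def test_collider_made_negative(self, rng):
        x = rng.standard_normal(300)
        y = rng.standard_normal(300)
        z = x + y + 0.05 * rng.standard_normal(300)
        s = samples_from(np.column_stack([x, y, z]))
        pcor = inf.partial_correlation(s).values
        pearson = inf.correlation_association(s, "pearson").values
        assert pcor[0, 1] < -0.9
        assert abs(pearson[0, 1]) < 0.2

    def test_matches_regression_residual_oracle(self, rng):
        x = rng.standard_normal((200, 4))
        x[:, 1] += 0.6 * x[:, 0]
        x[:, 2] += 0.3 * x[:, 1]
        pcor = inf.partial_correlation(samples_from(x)).values
        for i in range(4):
            for j in range(i + 1, 4):
                assert pcor[i, j] == pytest.approx(pcor_residual_oracle(x, i, j), abs=1e-6)

    def test_independent_columns_near_zero(self, rng):
        x = rng.standard_normal((500, 5))
        pcor = inf.partial_correlation(samples_from(x)).values
        off = pcor[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.2

    def test_singular_covariance_does_not_crash(self, rng):
        x = rng.standard_normal((4, 10))  # n << p
        pcor = inf.partial_correlation(samples_from(x))
        assert np.isfinite(pcor.values).all()


class TestMutualInformation:
    def test_independent_uniforms_near_zero(self, rng):
        x = rng.uniform(size=(500, 2))
        mi = inf.mutual_information(samples_from(x), seed=0)
        assert mi.values[0, 1] < 0.05

    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.9])
    def test_gaussian_closed_form(self, rho):
        rng = np.random.default_rng(7)
        cov = [[1.0, rho], [rho, 1.0]]
        x = rng.multivariate_normal([0, 0], cov, size=2000)
        mi = inf.mutual_information(samples_from(x), seed=0).values[0, 1]
        expected = -0.5 * np.log(1 - rho**2)
        assert mi == pytest.approx(expected, abs=0.1)

    def test_diagonal_zero_and_nonnegative(self, rng):
        x = rng.uniform(size=(50, 4))
        mi = inf.mutual_information(samples_from(x), seed=0)
        assert np.all(np.diag(mi.values) == 0)
        assert (mi.values >= 0).all()

    def test_sample_size_gate(self):
        with pytest.raises(inf.SampleSizeError):
            inf.mutual_information(samples_from(np.ones((3, 2))), inf.MIEstimatorConfig(3))


class TestCLR:
    def test_uniform_background_maps_to_zero(self):
        a = np.full((4, 4), 0.5)
        np.fill_diagonal(a, 0.0)
        out = inf.clr_transform(assoc_from(a))
        assert np.all(out.values == 0)

    def test_toy_ranking(self):
        a = np.array([[0, 0.9, 0.1], [0.9, 0, 0.1], [0.1, 0.1, 0]], dtype=float)
        out = inf.clr_transform(assoc_from(a)).values
        pairs = {(0, 1): out[0, 1], (0, 2): out[0, 2], (1, 2): out[1, 2]}
        assert max(pairs, key=pairs.get) == (0, 1)

    def test_matches_two_loop_oracle(self, rng):
        for _ in range(5):
            a = rng.random((6, 6))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            out = inf.clr_transform(assoc_from(a)).values
            assert np.allclose(out, clr_two_loop(a), atol=1e-12)

    def test_symmetric_nonnegative(self, rng):
        a = rng.random((8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        out = inf.clr_transform(assoc_from(a)).values
        assert np.array_equal(out, out.T)
        assert (out >= 0).all()


class TestMRNET:
    def test_matches_exhaustive_oracle_small(self, rng):
        for n in (3, 4):
            for _ in range(10):
                a = rng.random((n, n))
                a = (a + a.T) / 2
                np.fill_diagonal(a, 0.0)
                out = inf.mrnet(assoc_from(a)).values
                assert np.allclose(out, mrmr_greedy_oracle(a), atol=1e-12)

    def test_first_selection_scores_equal_relevance(self, rng):
        # the first feature chosen per target has zero redundancy, so the
        # strongest pair's output equals its raw association
        a = rng.random((5, 5))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        out = inf.mrnet(assoc_from(a)).values
        i, j = np.unravel_index(np.argmax(a), a.shape)
        assert out[i, j] == pytest.approx(a[i, j])

    def test_symmetric(self, rng):
        a = rng.random((6, 6))
        a = (a + a.T) / 2
        out = inf.mrnet(assoc_from((a + a.T) / 2)).values
        assert np.array_equal(out, out.T)


class TestTreeImportance:
    def test_planted_signal_recovered(self, rng):
        x = rng.standard_normal((200, 6))
        x[:, 1] = 2 * x[:, 0] + 0.01 * rng.standard_normal(200)
        x = x - x.min() + 0.1  # concentrations are nonnegative
        out = inf.tree_importance(samples_from(x), n_trees=50, seed=0).values
        assert np.argmax(out[:, 1]) == 0

    def test_deterministic(self, small_samples):
        a = inf.tree_importance(small_samples, n_trees=20, seed=3)
        b = inf.tree_importance(small_samples, n_trees=20, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_symmetric_nonnegative(self, small_samples):
        out = inf.tree_importance(small_samples, n_trees=20, seed=3).values
        assert np.array_equal(out, out.T)
        assert (out >= 0).all()


class TestPCLRC:
    def test_degenerate_full_subsample(self, small_samples):
        cfg = inf.PCLRCConfig(subsample_fraction=1.0, top_fraction=0.30, iterations=5, seed=0)
        out = inf.pclrc(small_samples, cfg).values
        iu, ju = np.triu_indices(out.shape[0], k=1)
        flat = out[iu, ju]
        assert set(np.unique(flat)) <= {0.0, 1.0}
        k = int(round(0.30 * flat.size))
        assert int(flat.sum()) == k

    def test_frequencies_bounded_and_mean_matches_top_fraction(self, small_samples):
        cfg = inf.PCLRCConfig(subsample_fraction=0.75, top_fraction=0.30, iterations=50, seed=1)
        out = inf.pclrc(small_samples, cfg).values
        iu, ju = np.triu_indices(out.shape[0], k=1)
        flat = out[iu, ju]
        assert (flat >= 0).all() and (flat <= 1).all()
        k = int(round(0.30 * flat.size))
        assert flat.mean() == pytest.approx(k / flat.size, abs=1e-12)

    def test_deterministic(self, small_samples):
        cfg = inf.PCLRCConfig(iterations=10, seed=5)
        a = inf.pclrc(small_samples, cfg).values
        b = inf.pclrc(small_samples, cfg).values
        assert np.array_equal(a, b)


class TestInvariants:
    def test_rank_methods_invariant_under_monotone_transform(self, rng):
        x = rng.uniform(0.1, 2.0, size=(30, 4))
        transformed = x.copy()
        transformed[:, 0] = np.exp(transformed[:, 0])
        transformed[:, 2] = transformed[:, 2] ** 3
        for method in ("spearman", "kendall"):
            a = inf.correlation_association(samples_from(x), method).values
            b = inf.correlation_association(samples_from(transformed), method).values
            assert np.allclose(a, b, atol=1e-12)

    def test_row_permutation_equivariance(self, rng):
        x = rng.uniform(0.1, 2.0, size=(40, 5))
        perm = rng.permutation(40)
        for method in ("pearson", "spearman", "kendall", "bicor", "pcor"):
            a = inf.infer(samples_from(x), method).values
            b = inf.infer(samples_from(x[perm]), method).values
            assert np.allclose(a, b, atol=1e-10)

    def test_all_outputs_symmetric_zero_diagonal(self, small_samples):
        for method in ("pearson", "bicor", "pcor", "clr_pearson", "genie3"):
            kwargs = {"n_trees": 20} if method == "genie3" else {}
            out = inf.infer(small_samples, method, seed=0, **kwargs).values
            assert np.array_equal(out, out.T)
            assert np.all(np.diag(out) == 0)


class TestRegistry:
    def test_min_samples_gates_resampled_mi(self):
        # PCLRC over MI needs a subsample large enough for the kNN estimator,
        # which rules it out at the smallest benchmark size
        assert inf.min_samples("pclrc_mi") > 5
        assert inf.min_samples("pearson") == 3

    def test_unknown_method_rejected(self, small_samples):
        with pytest.raises(ValueError, match="unknown inference method"):
            inf.infer(small_samples, "nope")
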
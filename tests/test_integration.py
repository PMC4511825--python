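import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import traitgrad as tg
from traitgrad.data_model import MORPHOLOGICAL_TRAITS, ValidationError
from traitgrad.integration import DegenerateDataError

from .conftest import single_zone_simulation


def random_correlation_matrix(rng, k=5, n=8):
    """Sample correlation matrix of random data: always a valid input."""
    data = rng.standard_normal((n, k)) @ rng.standard_normal((k, k))
    return tg.CorrelationMatrix(tuple(f"t{i}" for i in range(k)),
                                np.corrcoef(data, rowvar=False))


class TestCorrelationMatrixType:
    def test_invariants_enforced(self):
        with pytest.raises(ValidationError, match="symmetric"):
            tg.CorrelationMatrix(("a", "b"), np.array([[1.0, 0.5], [0.2, 1.0]]))
        with pytest.raises(ValidationError, match="diagonal"):
            tg.CorrelationMatrix(("a", "b"), np.array([[2.0, 0.5], [0.5, 1.0]]))
        with pytest.raises(ValidationError, match="<= 1"):
            tg.CorrelationMatrix(("a", "b"), np.array([[1.0, 1.5], [1.5, 1.0]]))

    def test_upper_triangle_round_trip(self, tmp_path, zone_matrices):
        R = zone_matrices["leeward"]
        path = tmp_path / "lee.csv"
        R.write_upper_triangle_csv(path)
        again = tg.CorrelationMatrix.read_upper_triangle_csv(path)
        assert again.trait_names == R.trait_names
        assert np.allclose(again.r, R.r)


class TestCorrelationMatrixFromData:
    def test_proportional_traits_r_one(self):
        import pandas as pd
        idx = pd.MultiIndex.from_tuples(
            [("P", "core", f"t{i}") for i in range(5)],
            names=["patch_id", "zone", "tree_id"])
        df = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 4, 6, 8, 10]}, index=idx)
        m = tg.TreeTraitMatrix(df, {"P": "large"})
        R = tg.correlation_matrix(m, "core", ["a", "b"])
        assert R.r[0, 1] == pytest.approx(1.0)

    def test_independent_traits_near_zero_at_n2000(self):
        rng = np.random.default_rng(8)
        import pandas as pd
        idx = pd.MultiIndex.from_tuples(
            [("P", "core", f"t{i}") for i in range(2000)],
            names=["patch_id", "zone", "tree_id"])
        df = pd.DataFrame({"a": rng.lognormal(0, 0.3, 2000),
                           "b": rng.lognormal(0, 0.3, 2000)}, index=idx)
        m = tg.TreeTraitMatrix(df, {"P": "large"})
        R = tg.correlation_matrix(m, "core", ["a", "b"])
        assert abs(R.r[0, 1]) < 0.05

    def test_symmetric_unit_diagonal_by_construction(self):
        cfg = single_zone_simulation(30, seed=3)
        m = tg.tree_level_means(tg.generate_trait_data(cfg))
        R = tg.correlation_matrix(m, "leeward", MORPHOLOGICAL_TRAITS)
        assert np.allclose(R.r, R.r.T)
        assert np.allclose(np.diag(R.r), 1.0)

    def test_constant_trait_error_names_it(self):
        import pandas as pd
        idx = pd.MultiIndex.from_tuples(
            [("P", "core", f"t{i}") for i in range(5)],
            names=["patch_id", "zone", "tree_id"])
        df = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [7.0] * 5}, index=idx)
        m = tg.TreeTraitMatrix(df, {"P": "large"})
        with pytest.raises(DegenerateDataError, match="'b'"):
            tg.correlation_matrix(m, "core", ["a", "b"])


class TestIntegrationIndex:
    def test_identity_matrix_zero(self):
        R = tg.CorrelationMatrix(tuple("abcde"), np.eye(5))
        assert tg.integration_index(R) == pytest.approx(0.0, abs=1e-12)

    def test_all_ones_matrix_is_k(self):
        R = tg.CorrelationMatrix(tuple("abcde"), np.ones((5, 5)))
        assert tg.integration_index(R) == pytest.approx(5.0)

    @pytest.mark.parametrize("perm", [(4, 3, 2, 1, 0), (1, 0, 3, 4, 2)])
    def test_permutation_invariant(self, zone_matrices, perm):
        R = zone_matrices["leeward"]
        assert tg.integration_index(R.permuted(perm)) == pytest.approx(
            tg.integration_index(R), rel=1e-9)

    @given(seed=st.integers(0, 10_000), k=st.integers(2, 8))
    @settings(max_examples=60, deadline=None)
    def test_eigen_route_equals_closed_form(self, seed, k):
        """Eigenvalue variance equals 2*sum(r^2)/(k-1) for random valid
        correlation matrices."""
        R = random_correlation_matrix(np.random.default_rng(seed), k=k, n=k + 3)
        eig = np.var(np.linalg.eigvalsh(R.r), ddof=1)
        closed = 2 * np.sum(R.offdiagonal() ** 2) / (R.k - 1)
        assert eig == pytest.approx(closed, rel=1e-9, abs=1e-10)
        assert 0 <= tg.integration_index(R) <= R.k

    def test_mean_r_squared_identity_with_int(self, zone_matrices):
        """mean r^2 = INT*(k-1)/(2*n_pairs), exactly."""
        for R in zone_matrices.values():
            n_pairs = R.k * (R.k - 1) / 2
            assert tg.mean_r_squared(R) == pytest.approx(
                tg.integration_index(R) * (R.k - 1) / (2 * n_pairs), rel=1e-12)

    def test_mean_r_squared_simple_cases(self):
        assert tg.mean_r_squared(
            tg.CorrelationMatrix(tuple("abcde"), np.eye(5))) == 0.0
        R2 = tg.CorrelationMatrix.from_upper_triangle(["a", "b"], [0.5])
        assert tg.mean_r_squared(R2) == pytest.approx(0.25)


class TestIntegrationCI:
    def test_duplicated_rows_zero_noise_degenerates_ci(self):
        import pandas as pd
        # two distinct rows duplicated: any resample holding both rows has
        # |r| = 1 for every pair, so every replicate has the same INT
        base = np.array([[1.0, 2.0, 4.0], [2.0, 3.0, 1.0]])
        rows = np.tile(base, (20, 1))
        idx = pd.MultiIndex.from_tuples(
            [("P", "core", f"t{i}") for i in range(40)],
            names=["patch_id", "zone", "tree_id"])
        m = tg.TreeTraitMatrix(pd.DataFrame(rows, columns=["a", "b", "c"], index=idx),
                               {"P": "large"})
        res = tg.integration_ci(m, "core", ["a", "b", "c"], B=200, seed=1)
        assert res.integration == pytest.approx(3.0)  # k=3, all |r|=1
        assert res.ci_low == pytest.approx(res.integration, rel=1e-9)
        assert res.ci_high == pytest.approx(res.integration, rel=1e-9)

    def test_tiny_b_warns_but_returns_bounds(self):
        cfg = single_zone_simulation(30, seed=4)
        m = tg.tree_level_means(tg.generate_trait_data(cfg))
        with pytest.warns(UserWarning, match="B="):
            res = tg.integration_ci(m, "leeward", MORPHOLOGICAL_TRAITS, B=2, seed=1)
        assert res.ci_low <= res.ci_high

    def test_ci_contains_generating_int_at_n1000(self, zone_matrices):
        target = tg.integration_index(zone_matrices["leeward"])
        cfg = single_zone_simulation(1000, seed=10)
        m = tg.tree_level_means(tg.generate_trait_data(cfg))
        res = tg.integration_ci(m, "leeward", MORPHOLOGICAL_TRAITS, B=400, seed=2)
        assert res.ci_low <= target <= res.ci_high
        assert res.n_individuals == 1000

    def test_deterministic_under_seed(self):
        cfg = single_zone_simulation(40, seed=4)
        m = tg.tree_level_means(tg.generate_trait_data(cfg))
        a = tg.integration_ci(m, "leeward", MORPHOLOGICAL_TRAITS, B=300, seed=9)
        b = tg.integration_ci(m, "leeward", MORPHOLOGICAL_TRAITS, B=300, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


class TestMatrixSimilarity:
    def test_self_similarity_is_one(self, zone_matrices):
        R = zone_matrices["core"]
        res = tg.matrix_similarity(R, R)
        assert res.index == pytest.approx(1.0)

    def test_trait_list_mismatch_rejected(self, zone_matrices):
        other = tg.CorrelationMatrix(tuple("vwxyz"), zone_matrices["core"].r)
        with pytest.raises(ValidationError, match="trait lists"):
            tg.matrix_similarity(zone_matrices["windward"], other)

    def test_identity_matrix_similarity_undefined(self):
        eye = tg.CorrelationMatrix(tuple("abcde"), np.eye(5))
        with pytest.raises(DegenerateDataError, match="zero variance"):
            tg.matrix_similarity(eye, eye)

    def test_exact_p_is_multiple_of_1_over_120(self, zone_matrices):
        res = tg.matrix_similarity(zone_matrices["leeward"], zone_matrices["core"])
        assert res.exact and res.n_permutations == 120
        assert (res.p_value * 120) == pytest.approx(round(res.p_value * 120))
        assert res.p_value > 0

    def test_monte_carlo_close_to_exact(self, zone_matrices):
        a, b = zone_matrices["leeward"], zone_matrices["core"]
        exact = tg.matrix_similarity(a, b)
        mc = tg.matrix_similarity(a, b, exhaustive=False, n_permutations=4999, seed=3)
        assert mc.index == pytest.approx(exact.index)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_published_pairwise_indices(self, zone_matrices):
        """Windward is the divergent zone (near-zero similarity to both
        others); leeward and core align strongly."""
        w, c, l = (zone_matrices[z] for z in ("windward", "core", "leeward"))
        assert tg.matrix_similarity(w, c).index == pytest.approx(0.11, abs=0.005)
        assert tg.matrix_similarity(w, l).index == pytest.approx(-0.11, abs=0.005)
        assert tg.matrix_similarity(l, c).index == pytest.approx(0.72, abs=0.005)
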
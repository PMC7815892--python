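import numpy as np
import pytest

import mvbench as mb
from mvbench.amputate import MaskedDataset, MissingnessSpec
from mvbench.impute import METHODS, ImputationConfig, impute
from mvbench.impute.local import impute_knn

FAST_OVERRIDES = {"RF": dict(ntree=10)}  # unit tests exercise the algorithm, not the forest size


def _cfg(method, **kwargs):
    merged = {**FAST_OVERRIDES.get(method, {}), **kwargs}
    return ImputationConfig(method=method, **merged)


def _masked(values, mask):
    """Wrap raw arrays into a MaskedDataset (log2 scale by convention)."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n, m = values.shape
    return MaskedDataset(
        observed=np.where(mask, np.nan, values),
        mask=mask,
        provenance=mask.astype(np.int8),  # call everything MNAR; irrelevant here
        truth=values,
        protein_ids=np.array([f"p{i}" for i in range(n)], dtype=object),
        protein_species=np.repeat("human", n),
        sample_ids=np.array([f"A_{j}" for j in range(m)], dtype=object),
        sample_group=np.repeat("A", m),
        dropped_rows=np.array([], dtype=object),
        spec=MissingnessSpec(alpha=0.0, beta=0.0, seed=0),
        n_entries_predrop=values.size,
        n_missing_predrop=int(mask.sum()),
        n_mnar_predrop=int(mask.sum()),
    )


@pytest.mark.parametrize("method", METHODS)
class TestContracts:
    def test_observed_passthrough(self, method, masked_small):
        imp = impute(masked_small, _cfg(method, seed=1))
        assert np.array_equal(
            imp.values[~masked_small.mask], masked_small.observed[~masked_small.mask]
        )
        assert not np.isnan(imp.values).any()

    def test_determinism(self, method, masked_small):
        a = impute(masked_small, _cfg(method, seed=7))
        b = impute(masked_small, _cfg(method, seed=7))
        assert np.array_equal(a.values, b.values)

    def test_nothing_to_impute(self, method, rng):
        values = rng.normal(20, 2, (12, 6))
        md = _masked(values, np.zeros_like(values, dtype=bool))
        imp = impute(md, _cfg(method, npcs=2, seed=0))
        assert np.array_equal(imp.values, values)


class TestLOD:
    def test_direct_rule(self):
        md = _masked(
            [[5.0, 7.0, 9.0], [6.0, 8.0, 10.0]],
            [[False, True, False], [True, False, False]],
        )
        imp = impute(md, _cfg("LOD"))
        assert imp.values[0, 1] == 5.0 and imp.values[1, 0] == 5.0

    def test_minimum_unchanged(self, rng):
        for _ in range(10):
            values = rng.normal(20, 3, (20, 8))
            mask = rng.random((20, 8)) < 0.2
            mask[:, 0] = False  # keep every row partly observed
            md = _masked(values, mask)
            imp = impute(md, _cfg("LOD"))
            assert imp.values.min() == md.observed[~mask].min()


class TestND:
    def test_downshifted_stats(self, rng):
        # 150 x 100 matrix: first 33 columns observed, rest missing
        values = np.zeros((150, 100))
        values[:, :33] = rng.normal(20, 1, (150, 33))
        mask = np.zeros((150, 100), dtype=bool)
        mask[:, 33:] = True
        md = _masked(values, mask)
        obs = values[:, :33].ravel()
        mu_m, sigma_m = obs.mean(), obs.std(ddof=1)
        imp = impute(md, _cfg("ND", seed=4))
        filled = imp.values[mask]
        assert filled.mean() == pytest.approx(mu_m - 2.2 * sigma_m, abs=3 * 0.3 * sigma_m / 100)
        assert filled.std(ddof=1) == pytest.approx(0.3 * sigma_m, rel=0.05)
        # the imputed distribution sits in the left tail
        assert np.quantile(filled, 0.99) < mu_m

    def test_degenerate_width_limit(self, rng):
        values = rng.normal(20, 1, (30, 10))
        mask = rng.random((30, 10)) < 0.2
        mask[:, 0] = False
        md = _masked(values, mask)
        obs = values[~mask]
        imp = impute(md, _cfg("ND", nd_width=1e-12, seed=0))
        expected = obs.mean() - 2.2 * obs.std(ddof=1)
        assert np.allclose(imp.values[mask], expected, atol=1e-9)

    def test_per_column_variant(self, rng):
        # two columns with very different scales: per-column draws track each
        # column's own statistics, the global variant does not
        values = np.column_stack(
            [rng.normal(10, 1, 200), rng.normal(30, 1, 200), rng.normal(10, 1, 200)]
        )
        mask = np.zeros_like(values, dtype=bool)
        mask[:50, 1] = True
        md = _masked(values, mask)
        imp = impute(md, _cfg("ND", nd_per_column=True, seed=0))
        col_obs = values[50:, 1]
        expected = col_obs.mean() - 2.2 * col_obs.std(ddof=1)
        assert imp.values[:50, 1].mean() == pytest.approx(expected, abs=0.5)
        glob = impute(md, _cfg("ND", seed=0))
        assert abs(glob.values[:50, 1].mean() - expected) > 2.0

    def test_left_censoring_ordering(self, masked_small):
        """mean(LOD) <= mean(ND) < mean(observed) on any data with sigma_m > 0."""
        obs_mean = masked_small.observed[~masked_small.mask].mean()
        lod = impute(masked_small, _cfg("LOD"))
        nd = impute(masked_small, _cfg("ND", seed=2))
        assert lod.values[masked_small.mask].mean() <= nd.values[masked_small.mask].mean()
        assert nd.values[masked_small.mask].mean() < obs_mean


def _brute_force_knn(values, mask, i, j, k):
    """Independent enumeration of the kNN rule for entry (i, j)."""
    n, m = values.shape
    obs = ~mask
    scored = []
    for r in range(n):
        if r == i or not obs[r, j]:
            continue
        co = obs[r] & obs[i]
        if not co.any():
            continue
        d = np.sqrt(((values[r, co] - values[i, co]) ** 2).sum() * m / co.sum())
        scored.append((d, r))
    scored.sort()
    nearest = [r for _, r in scored[:k]]
    return np.mean([values[r, j] for r in nearest])


class TestKNN:
    def test_identical_twin(self):
        values = np.array(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 9.0, 9.0], [8.0, 1.0, 5.0]]
        )
        mask = np.zeros_like(values, dtype=bool)
        mask[0, 2] = True
        md = _masked(values, mask)
        imp = impute(md, _cfg("KNN", k_neighbors=1))
        assert imp.values[0, 2] == 3.0  # the zero-distance twin's value

    def test_against_brute_force(self, rng):
        values = rng.normal(10, 2, (5, 3))
        mask = np.zeros_like(values, dtype=bool)
        mask[2, 1] = True
        md = _masked(values, mask)
        imp = impute(md, _cfg("KNN", k_neighbors=2))
        expected = _brute_force_knn(values, mask, 2, 1, 2)
        assert imp.values[2, 1] == pytest.approx(expected, rel=1e-12)

    def test_constant_matrix(self):
        values = np.full((6, 4), 7.0)
        mask = np.zeros_like(values, dtype=bool)
        mask[3, 2] = True
        imp = impute(_masked(values, mask), _cfg("KNN", k_neighbors=3))
        assert imp.values[3, 2] == 7.0

    def test_no_candidate_fallback(self):
        # column 2 observed only in the target-missing row's column -> no
        # candidate observed at that column: fall back to the row mean
        values = np.array([[1.0, 2.0, 6.0], [3.0, 4.0, 5.0]])
        mask = np.array([[False, False, True], [False, False, True]])
        imp = impute(_masked(values, mask), _cfg("KNN", k_neighbors=1))
        assert imp.values[0, 2] == pytest.approx(1.5)
        assert imp.diagnostics["fallback_entries"] == 2


class TestLLS:
    def test_exact_linear_recovery(self):
        # every row lies in a rank-2 latent span, so a consistent linear
        # system over the observed columns extends exactly to the missing one
        rng = np.random.default_rng(0)
        base = rng.normal(size=(2, 6))
        coeffs = rng.normal(size=(5, 2))
        target = 2.0 * base[0] - 0.5 * base[1]
        values = np.vstack([target, coeffs @ base])
        mask = np.zeros_like(values, dtype=bool)
        mask[0, 5] = True
        imp = impute(_masked(values, mask), _cfg("LLS", k_similar=4))
        assert imp.values[0, 5] == pytest.approx(target[5], abs=1e-8)

    def test_against_normal_equations(self, rng):
        values = rng.normal(10, 2, (6, 4))
        mask = np.zeros_like(values, dtype=bool)
        mask[1, 3] = True
        md = _masked(values, mask)
        imp = impute(md, _cfg("LLS", k_similar=3))

        # independent oracle: pick top-3 |pearson| rows over observed cols,
        # solve the normal equations, predict
        oc, mc = [0, 1, 2], 3
        y = values[1, oc]
        corrs = []
        for r in range(6):
            if r == 1:
                continue
            c = abs(np.corrcoef(values[r, oc], y)[0, 1])
            corrs.append((c, r))
        corrs.sort(key=lambda t: (-t[0], t[1]))
        top = [r for _, r in corrs[:3]]
        A = values[np.ix_(top, oc)].T
        coef = np.linalg.pinv(A) @ y
        expected = values[top, mc] @ coef
        assert imp.values[1, 3] == pytest.approx(expected, rel=1e-9)

    def test_identical_rows(self):
        values = np.tile(np.array([3.0, 5.0, 7.0, 9.0]), (5, 1))
        mask = np.zeros_like(values, dtype=bool)
        mask[0, 1] = True
        imp = impute(_masked(values, mask), _cfg("LLS"))
        # all rows identical: correlations are degenerate, row-mean fallback
        # or exact reconstruction both return a value consistent with the row
        assert imp.values[0, 1] == pytest.approx(np.mean([3.0, 7.0, 9.0]), rel=0.5)


class TestRF:
    def test_beats_mean_imputation_on_structure(self, rng):
        x = rng.normal(0, 1, 500)
        col2 = np.sin(x) + rng.normal(0, 0.01, 500)
        values = np.column_stack([x, col2, x + 1.0, 2.0 - x])
        mask = np.zeros_like(values, dtype=bool)
        mask[:, 1] = rng.random(500) < 0.05
        md = _masked(values, mask)
        imp = impute(md, _cfg("RF", ntree=30, seed=0))
        truth = values[mask]
        rf_rmse = np.sqrt(np.mean((imp.values[mask] - truth) ** 2))
        mean_rmse = np.sqrt(np.mean((values[~mask[:, 1], 1].mean() - truth) ** 2))
        assert rf_rmse < 0.3 * mean_rmse

    def test_predictions_within_observed_range(self, masked_small):
        imp = impute(masked_small, _cfg("RF", seed=5))
        for j in range(masked_small.n_samples):
            col_obs = masked_small.observed[~masked_small.mask[:, j], j]
            filled = imp.values[masked_small.mask[:, j], j]
            if filled.size:
                assert filled.min() >= col_obs.min() - 1e-9
                assert filled.max() <= col_obs.max() + 1e-9

    def test_single_column_rejected(self, rng):
        values = rng.normal(size=(10, 1))
        mask = np.zeros_like(values, dtype=bool)
        mask[0, 0] = True
        mask_ok = mask.copy()
        md = _masked(np.hstack([values, values]), np.hstack([mask_ok, np.zeros_like(mask_ok)]))
        impute(md, _cfg("RF", seed=0))  # two columns fine
        with pytest.raises(ValueError, match="two samples"):
            from mvbench.impute.forest import impute_rf
            impute_rf(np.where(mask, np.nan, values), mask, _cfg("RF"))


class TestSVD:
    def test_rank_one_recovery(self):
        u = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        v = np.array([2.0, 1.0, 0.5, 4.0])
        values = np.outer(u, v)
        mask = np.zeros_like(values, dtype=bool)
        mask[2, 1] = True
        imp = impute(_masked(values, mask), _cfg("SVD", npcs=1, tol=1e-9, max_iter=500))
        assert imp.values[2, 1] == pytest.approx(values[2, 1], rel=1e-6)

    def test_trace_monotone_on_low_rank(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            values = r.normal(size=(30, 2)) @ r.normal(size=(2, 8)) + r.normal(
                0, 0.01, (30, 8)
            )
            mask = r.random((30, 8)) < 0.1
            mask[:, 0] = False
            imp = impute(_masked(values, mask), _cfg("SVD", npcs=2))
            trace = imp.diagnostics["trace"]
            assert all(b <= a * (1 + 1e-9) for a, b in zip(trace[1:], trace[2:]))

    def test_terminates_at_full_rank(self, rng):
        values = rng.normal(size=(8, 5))
        mask = np.zeros_like(values, dtype=bool)
        mask[0, 0] = True
        imp = impute(_masked(values, mask), _cfg("SVD", npcs=4, max_iter=20))
        assert imp.diagnostics["iterations"] <= 20
        assert not np.isnan(imp.values).any()


class TestBPCA:
    def test_low_rank_completion_accuracy(self, rng):
        values = rng.normal(size=(80, 2)) @ rng.normal(size=(2, 10))
        values += rng.normal(0, 0.05, values.shape)
        mask = rng.random(values.shape) < 0.1
        mask[:, 0] = False
        md = _masked(values, mask)
        imp = impute(md, _cfg("BPCA", npcs=2))
        nrmse = mb.nrmse_abundance(imp.values, md.truth, md.mask)
        assert nrmse < 0.2

    def test_ard_shrinks_spurious_components(self, rng):
        values = rng.normal(size=(100, 2)) @ rng.normal(size=(2, 12))
        values += rng.normal(0, 0.01, values.shape)
        mask = rng.random(values.shape) < 0.05
        mask[:, 0] = False
        imp = impute(_masked(values, mask), _cfg("BPCA", npcs=5, max_iter=200))
        norms = np.sort(imp.diagnostics["loading_norms"])[::-1]
        assert (norms[2:] < 0.1 * norms[1]).sum() >= 3


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(method="nope"),
            dict(method="KNN", k_neighbors=0),
            dict(method="ND", nd_width=0.0),
            dict(method="SVD", npcs=0),
            dict(method="RF", ntree=0),
        ],
    )
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ValueError):
            ImputationConfig(**kwargs)

    def test_npcs_bound_checked_at_dispatch(self, masked_small):
        with pytest.raises(ValueError, match="npcs"):
            impute(masked_small, _cfg("SVD", npcs=32))
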
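import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from permscreen.nb_glm import fit_null_glm
from permscreen.pairs import PairSpec
from permscreen.resampling import (
    AdaptiveConfig,
    ResampleBank,
    empirical_p,
    permute_indicators,
    run_batch,
    test_pair,
    universe_key,
)
from permscreen.score import DegenerateTreatmentError


@pytest.fixture
def bank():
    return ResampleBank(n=20, seed=1, ukey=12345)


class TestResampleBank:
    def test_reproducible(self, bank):
        other = ResampleBank(n=20, seed=1, ukey=12345)
        for b in (0, 3, 17):
            np.testing.assert_array_equal(bank.ordering(b), other.ordering(b))

    def test_complement_of_full_prefix(self, bank):
        idx = permute_indicators(bank, 19, 5)
        assert len(idx) == 19
        missing = set(range(20)) - set(idx.tolist())
        assert len(missing) == 1

    def test_prefix_nesting(self, bank):
        for b in range(5):
            small = set(permute_indicators(bank, 4, b).tolist())
            large = set(permute_indicators(bank, 9, b).tolist())
            assert small <= large

    def test_uniform_over_subsets(self):
        """n=6, t=2: all 15 subsets equally likely (exact enumeration oracle)."""
        n, t, B = 6, 2, 60_000
        bank = ResampleBank(n=n, seed=7, ukey=99)
        subsets = list(itertools.combinations(range(n), t))
        counts = dict.fromkeys(subsets, 0)
        for b in range(B):
            counts[tuple(permute_indicators(bank, t, b))] += 1
        expected = B / len(subsets)
        se = np.sqrt(B * (1 / 15) * (14 / 15))
        for c in counts.values():
            assert abs(c - expected) < 3 * se

    def test_degenerate_size_rejected(self, bank):
        with pytest.raises(DegenerateTreatmentError):
            permute_indicators(bank, 20, 0)


class TestEmpiricalP:
    def test_extreme_right(self):
        z_null = np.arange(99, dtype=float)
        assert empirical_p(1000.0, z_null, "right") == pytest.approx(1 / 100)

    def test_all_ties(self):
        z_null = np.full(50, 1.5)
        assert empirical_p(1.5, z_null, "right") == 1.0
        assert empirical_p(1.5, z_null, "left") == 1.0

    def test_brute_force_oracle(self, rng):
        for _ in range(20):
            z_null = rng.standard_normal(rng.integers(5, 50))
            z_obs = rng.standard_normal()
            B = len(z_null)
            right = (1 + sum(1 for z in z_null if z >= z_obs)) / (B + 1)
            left = (1 + sum(1 for z in z_null if z <= z_obs)) / (B + 1)
            two = min(1.0, 2 * min(left, right))
            assert empirical_p(z_obs, z_null, "right") == pytest.approx(right)
            assert empirical_p(z_obs, z_null, "left") == pytest.approx(left)
            assert empirical_p(z_obs, z_null, "two") == pytest.approx(two)

    @given(st.floats(-5, 5), st.lists(st.floats(-5, 5), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_validity_floor_and_sidedness(self, z_obs, z_null):
        z_null = np.asarray(z_null)
        pl = empirical_p(z_obs, z_null, "left")
        pr = empirical_p(z_obs, z_null, "right")
        p2 = empirical_p(z_obs, z_null, "two")
        B = len(z_null)
        assert pl >= 1 / (B + 1) and pr >= 1 / (B + 1)
        assert min(pl, pr) <= p2 <= min(1.0, 2 * min(pl, pr)) + 1e-12

    def test_two_sided_monotone_in_abs_z(self, rng):
        z_null = rng.standard_normal(500)
        zg = np.linspace(0, 5, 40)
        ps = [empirical_p(z, z_null, "two") for z in zg]
        # not strictly monotone (discrete), but nonincreasing
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


def _null_pair_data(rng, n=300, t=40):
    Z = np.column_stack([np.ones(n), rng.standard_normal(n)])
    mu = np.exp(1.0 + 0.2 * Z[:, 1])
    y = rng.negative_binomial(4.0, 4.0 / (4.0 + mu))
    cells = rng.permutation(n)
    return y, Z, np.sort(cells[:t]), np.sort(cells[t:])


class TestTestPair:
    def test_default_adaptive_config(self):
        cfg = AdaptiveConfig()
        assert (cfg.B1, cfg.p_thresh, cfg.B2) == (500, 0.01, 5000)

    def test_central_statistic_large_p(self, rng):
        y, Z, t_idx, c_idx = _null_pair_data(rng)
        res = test_pair(y, Z, t_idx, c_idx, seed=0)
        assert res.qc_pass
        if res.stage == 1:
            assert res.p_two > 0.01

    def test_overlapping_sets_rejected(self, rng):
        y, Z, t_idx, c_idx = _null_pair_data(rng)
        with pytest.raises(ValueError):
            test_pair(y, Z, t_idx, np.concatenate([c_idx, t_idx[:1]]))

    def test_result_invariants(self, rng):
        for seed in range(5):
            y, Z, t_idx, c_idx = _null_pair_data(rng)
            res = test_pair(y, Z, t_idx, c_idx, seed=seed, cfg=AdaptiveConfig(B1=200, B2=400))
            assert min(res.p_left, res.p_right) <= res.p_two + 1e-12
            assert res.p_two <= min(1.0, 2 * min(res.p_left, res.p_right)) + 1e-12
            assert res.n_treatment == len(t_idx)
            assert 0 <= res.ess <= res.n_treatment

    def test_stage2_only_after_promising_stage1(self, rng):
        """The adaptive scheme never promotes a pair whose stage-1 p exceeds
        the threshold (recompute stage-1 p from the shared bank)."""
        rng2 = np.random.default_rng(5)
        n, t = 200, 30
        Z = np.ones((n, 1))
        for rep in range(6):
            mu = 2.0
            y = rng2.poisson(mu, size=n)
            shift = rng2.choice([0, 3])
            cells = rng2.permutation(n)
            t_idx, c_idx = np.sort(cells[:t]), np.sort(cells[t:])
            y = y.copy()
            y[t_idx] += rng2.poisson(shift, size=t)
            cfg = AdaptiveConfig(B1=200, B2=400)
            res = test_pair(y, Z, t_idx, c_idx, cfg=cfg, seed=rep, family="poisson")
            universe = np.sort(np.concatenate([t_idx, c_idx]))
            bank = ResampleBank(n, rep, universe_key(universe))
            fit = fit_null_glm(y[universe], Z[universe], family="poisson")
            from permscreen.score import precompute, score_stat, score_stat_many

            pc = precompute(fit, Z[universe])
            z_obs = score_stat(np.searchsorted(universe, t_idx), pc)
            z1 = score_stat_many(bank.orderings_block(0, 200)[:, :t], pc)
            from permscreen.resampling import _pvalues

            _, _, p1, _, _ = _pvalues(z_obs, z1[np.isfinite(z1)], cfg.gof_threshold)
            if res.stage == 2:
                assert p1 <= cfg.p_thresh
            else:
                assert p1 > cfg.p_thresh

    def test_signal_detected(self, rng):
        n, t = 400, 60
        Z = np.ones((n, 1))
        y = rng.poisson(2.0, size=n)
        cells = rng.permutation(n)
        t_idx, c_idx = np.sort(cells[:t]), np.sort(cells[t:])
        y[t_idx] += rng.poisson(4.0, size=t)
        res = test_pair(y, Z, t_idx, c_idx, seed=0, family="poisson")
        assert res.stage == 2
        assert res.p_two < 1e-4
        assert res.lfc > 0.5

    def test_null_calibration_small(self):
        """Cheap uniformity check; the full-scale version is in acceptance."""
        rng = np.random.default_rng(21)
        ps = []
        cfg = AdaptiveConfig(B1=150, B2=300)
        for rep in range(300):
            y, Z, t_idx, c_idx = _null_pair_data(rng, n=150, t=25)
            res = test_pair(y, Z, t_idx, c_idx, cfg=cfg, seed=rep)
            if res.qc_pass:
                ps.append(res.p_two)
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestRunBatch:
    def test_single_pair_matches_direct_call(self, small_screen):
        from permscreen.data_model import build_covariate_matrix
        from permscreen.pairs import resolve_cells

        spec = PairSpec("tg_1", "g3")
        cfg = AdaptiveConfig(B1=100, B2=200)
        [res] = run_batch(small_screen, [spec], cfg=cfg, seed=4)
        t_idx, c_idx = resolve_cells(small_screen, spec)
        Z = build_covariate_matrix(small_screen, ["library_size"]).to_numpy()
        y = small_screen.response_row("g3")
        direct = test_pair(
            y, Z, t_idx, c_idx, cfg=cfg, seed=4, pair_id=spec.pair_id,
            lib=small_screen.library_sizes(),
        )
        assert res.p_two == pytest.approx(direct.p_two)
        assert res.z_obs == pytest.approx(direct.z_obs)
        assert res.lfc == pytest.approx(direct.lfc)

    def test_order_invariance(self, small_screen, rng):
        specs = [
            PairSpec(g, r)
            for g in ("tg_1", "tg_2", "nt_a")
            for r in ("g1", "g2", "g7")
        ]
        cfg = AdaptiveConfig(B1=100, B2=200)
        res_fwd = run_batch(small_screen, specs, cfg=cfg, seed=9)
        shuffled = [specs[i] for i in rng.permutation(len(specs))]
        res_shuf = run_batch(small_screen, shuffled, cfg=cfg, seed=9)
        by_id = {r.pair_id: r for r in res_shuf}
        for r in res_fwd:
            assert by_id[r.pair_id].p_two == pytest.approx(r.p_two)
            assert by_id[r.pair_id].z_obs == pytest.approx(r.z_obs, nan_ok=True)

    def test_worker_count_irrelevant(self, small_screen):
        specs = [PairSpec("tg_1", r) for r in ("g1", "g2")]
        cfg = AdaptiveConfig(B1=100, B2=200)
        r1 = run_batch(small_screen, specs, cfg=cfg, seed=2, workers=1)
        r4 = run_batch(small_screen, specs, cfg=cfg, seed=2, workers=4)
        for a, b in zip(r1, r4):
            assert a.p_two == b.p_two
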
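import numpy as np
import pytest

from imdforest import ForestConfig, fit_forest
from imdforest.imd import IMDProfile, forest_imd
from imdforest.selection import (
    FilterConfig,
    filter_kept_mask,
    filter_select,
    fit_imd_mixture,
    transform_select,
    _em_two_component,
)


def make_profile(fimd, per_tree=None, B=20):
    fimd = np.asarray(fimd, dtype=float)
    if per_tree is None:
        per_tree = np.tile(fimd, (B, 1))
    per_tree = np.asarray(per_tree, dtype=float)
    return IMDProfile(
        per_tree_imd=per_tree,
        forest_imd=fimd,
        mu=float(fimd.mean()),
        sigma_m=float(fimd.std(ddof=1)) if fimd.size > 1 else 0.0,
        se=per_tree.std(axis=0, ddof=1) / np.sqrt(per_tree.shape[0]),
        side="predictor",
    )


class TestFilter:
    def test_threshold_hand_values(self):
        prof = make_profile([0.0, 0.0, 0.0, 0.6])
        assert prof.sigma_m == pytest.approx(0.3)
        kept = filter_kept_mask(prof, 1.0)
        assert kept.tolist() == [False, False, False, True]

    def test_tau_zero_keeps_all_nonzero(self):
        prof = make_profile([0.0, 0.1, 0.5, 0.0, 0.02])
        kept = filter_kept_mask(prof, 0.0)
        assert kept.tolist() == [False, True, True, False, True]

    def test_selected_set_shrinks_with_tau(self):
        rng = np.random.default_rng(0)
        prof = make_profile(rng.uniform(0, 1, size=50))
        sizes = [filter_kept_mask(prof, tau).sum() for tau in np.arange(0, 3.1, 0.1)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_end_to_end_deterministic_and_recovers_signal(self):
        rng = np.random.default_rng(21)
        n = 80
        u = rng.normal(size=n)
        X = rng.normal(size=(n, 15))
        Y = rng.normal(size=(n, 15))
        for j in range(4):
            X[:, j] = u + 0.3 * rng.normal(size=n)
            Y[:, j] = u**2 + 0.3 * rng.normal(size=n)
        f = fit_forest(X, Y, ForestConfig(n_trees=60, seed=2))
        px = forest_imd(f, "predictor")
        py = forest_imd(f, "response")
        cfg = FilterConfig(repeats=2, tune_trees=30)
        res1 = filter_select(px, py, X, Y, cfg, seed=7)
        res2 = filter_select(px, py, X, Y, cfg, seed=7)
        assert np.array_equal(res1.selected_mask, res2.selected_mask)
        assert res1.params["tau"] == res2.params["tau"]
        sel = set(res1.selected)
        signal = {f"x{j}" for j in range(4)} | {f"y{j}" for j in range(4)}
        assert len(sel & signal) >= 4  # most of the planted features survive

    def test_all_filtered_out_raises(self):
        prof = make_profile([0.0, 0.0, 0.0])
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ValueError):
            filter_select(prof, prof, X, X, FilterConfig(repeats=1, tune_trees=5))


class TestMixtureEM:
    def test_loglik_monotone(self):
        rng = np.random.default_rng(4)
        x = np.concatenate(
            [rng.normal(0.05, 0.02, 300), rng.normal(0.4, 0.08, 80)]
        ).clip(1e-4)
        *_, history, converged, _ = _em_two_component(x, "gaussian", seed=0)
        diffs = np.diff(history)
        assert np.all(diffs > -1e-6)
        assert converged

    @pytest.mark.parametrize("seed", range(20))
    def test_parameter_recovery(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = 2000
        lab = rng.random(n) < 0.9
        x = np.where(
            lab, rng.normal(0.02, 0.01, n), rng.normal(0.30, 0.05, n)
        )
        p, mu1, s1, mu2, s2, gamma, *_ = _em_two_component(x, "gaussian", seed=0)
        assert abs(mu1 - 0.02) < 0.02
        assert abs(mu2 - 0.30) < 0.02
        # selected set ~ the high-component draws
        high = gamma[:, 0] < 0.05
        assert np.mean(high == ~lab) > 0.95

    def test_posteriors_and_mass_identities(self):
        prof = make_profile(
            np.concatenate([np.zeros(5), np.full(30, 0.05), np.full(15, 0.5)])
            + np.concatenate([np.zeros(5), np.linspace(0, 0.01, 45)])
        )
        fit, res = fit_imd_mixture(prof, pr=0.05, seed=0)
        assert fit.p0 == pytest.approx(0.1)
        assert fit.p0 + fit.p1 + fit.p2 == pytest.approx(1.0)
        assert np.allclose(fit.posteriors.sum(axis=1), 1.0)
        assert fit.mu1 < fit.mu2

    def test_all_zero_imd_short_circuits(self):
        fit, res = fit_imd_mixture(make_profile(np.zeros(30)))
        assert fit.p0 == 1.0
        assert res.model_size == 0
        assert res.flags.get("empty_nonzero")

    def test_too_few_nonzeros_rejected(self):
        with pytest.raises(ValueError, match="10 nonzero"):
            fit_imd_mixture(make_profile([0.0] * 20 + [0.5] * 5))

    def test_truncated_family_orders_components(self):
        rng = np.random.default_rng(6)
        fimd = np.concatenate(
            [rng.normal(0.05, 0.02, 200).clip(1e-4), rng.normal(0.5, 0.05, 50)]
        )
        fit, res = fit_imd_mixture(make_profile(fimd), family="truncated_normal")
        assert fit.mu1 < fit.mu2
        assert res.model_size > 0

    def test_separated_mixture_selects_high_component(self):
        rng = np.random.default_rng(9)
        fimd = np.concatenate(
            [np.zeros(50), rng.normal(0.03, 0.01, 400).clip(1e-4), rng.normal(0.35, 0.04, 50)]
        )
        fit, res = fit_imd_mixture(make_profile(fimd), pr=0.05)
        sel = res.selected_mask
        assert sel[:450].sum() <= 10
        assert sel[450:].sum() >= 45


class TestTransformation:
    def test_identical_imd_selects_nothing(self):
        prof = make_profile(np.full(20, 0.3))
        res = transform_select(prof)
        assert res.model_size == 0

    def test_threshold_uses_tree_count_df(self):
        prof = make_profile(np.linspace(0, 1, 10), B=30)
        res = transform_select(prof, alpha=0.05)
        assert res.params["df"] == 29

    def test_null_calibration_small(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(120, 250))
        Y = rng.normal(size=(120, 250))
        f = fit_forest(X, Y, ForestConfig(n_trees=60, seed=3))
        res = transform_select(forest_imd(f, "predictor"), alpha=0.05)
        assert res.model_size / 250 <= 2 * 0.05

    def test_strong_variables_selected(self):
        rng = np.random.default_rng(14)
        B, p = 50, 40
        per_tree = rng.uniform(0.0, 0.2, size=(B, p))
        per_tree[:, :5] = rng.uniform(0.6, 1.0, size=(B, 5))
        fimd = per_tree.mean(axis=0)
        prof = make_profile(fimd, per_tree=per_tree)
        res = transform_select(prof)
        assert set(np.nonzero(res.selected_mask)[0]) == set(range(5))
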
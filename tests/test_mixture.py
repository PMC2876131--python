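import itertools

import numpy as np
import pandas as pd
import pytest

from mvpfilter import (
    MixtureModel,
    fit_mixture,
    posteriors,
    scan_class_counts,
    select_probes,
)


def _pct_from_values(values, defined=None):
    values = np.asarray(values, dtype=float)
    if defined is None:
        defined = np.isfinite(values)
    return pd.DataFrame(
        {"r": values, "defined": defined, "n_pairs": 100,
         "total_var": 0.01, "mean_meth": 0.5},
        index=pd.Index([f"p{i}" for i in range(len(values))], name="probe_id"),
    )


def grid_search_ll(x, n_grid=40):
    """Dense grid search over (pi, mu1, mu2) with pooled variance.

    Independent lower-bound oracle for the EM fit: both components share
    the pooled sample variance, so its best log-likelihood can never
    exceed the EM optimum over the richer per-component-variance family.
    """
    var = max(np.var(x), 1e-6)
    mus = np.linspace(x.min(), x.max(), n_grid)
    pis = np.linspace(0.05, 0.95, 19)
    best = -np.inf
    const = -0.5 * np.log(2 * np.pi * var)
    for mu1, mu2 in itertools.combinations_with_replacement(mus, 2):
        d1 = const - 0.5 * (x - mu1) ** 2 / var
        d2 = const - 0.5 * (x - mu2) ** 2 / var
        for pi in pis:
            ll = np.logaddexp(np.log(pi) + d1, np.log1p(-pi) + d2).sum()
            if ll > best:
                best = ll
    return best


class TestFitMixture:
    def test_single_component_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.3, 0.1, 500)
        m = fit_mixture(x, 1)
        assert m.means[0] == pytest.approx(x.mean(), abs=1e-12)
        assert m.variances[0] == pytest.approx(np.var(x), abs=1e-12)
        assert m.weights[0] == 1.0
        assert m.converged

    def test_separated_point_masses(self):
        x = np.concatenate([np.full(300, 0.1), np.full(700, 0.6)])
        m = fit_mixture(x, 2, seed=1)
        assert m.weights[0] == pytest.approx(0.3, abs=1e-6)
        assert m.means[0] == pytest.approx(0.1, abs=1e-6)
        assert m.means[1] == pytest.approx(0.6, abs=1e-6)
        # variance floor engaged on degenerate point masses
        np.testing.assert_allclose(m.variances, 1e-6)

    def test_log_likelihood_monotone_every_iteration(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0.1, 0.08, 600), rng.normal(0.5, 0.07, 400)])
        m = fit_mixture(x, 2, seed=2)
        hist = np.array(m.ll_history)
        assert len(hist) >= 2
        assert (np.diff(hist) >= -1e-9 * np.abs(hist[:-1])).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0.1, 0.05, 200), rng.normal(0.6, 0.05, 200)])
        m1 = fit_mixture(x, 2, seed=5)
        m2 = fit_mixture(rng.permutation(x), 2, seed=5)
        np.testing.assert_allclose(m1.means, m2.means, atol=1e-6)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-6)
        assert m1.log_likelihood == pytest.approx(m2.log_likelihood, abs=1e-6)

    def test_em_beats_grid_search_oracle(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            n = int(rng.integers(10, 51))
            x = np.concatenate(
                [rng.normal(0.1, 0.05, n // 2), rng.normal(0.5, 0.08, n - n // 2)]
            )
            em = fit_mixture(x, 2, seed=trial)
            assert em.log_likelihood >= grid_search_ll(x) - 1e-6

    def test_parameter_recovery_well_separated(self):
        # true means 4+ pooled SDs apart: fitted means within 2 MC SEs
        true_mu = np.array([0.1, 0.5])
        sd = 0.07
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            x = np.concatenate(
                [rng.normal(true_mu[0], sd, 600), rng.normal(true_mu[1], sd, 400)]
            )
            m = fit_mixture(x, 2, seed=seed)
            errs.append(m.means - true_mu)
        errs = np.array(errs)
        mc_se = errs.std(axis=0, ddof=1) / np.sqrt(len(errs))
        assert (np.abs(errs.mean(axis=0)) < 2 * mc_se + 1e-3).all()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_mixture(np.full(100, 0.3), 2)
        with pytest.raises(ValueError, match="need >="):
            fit_mixture([0.1, 0.2, 0.3], 2)
        with pytest.raises(ValueError, match="NaN"):
            fit_mixture([0.1, np.nan, 0.3, 0.4], 1)

    def test_weights_on_simplex_and_means_sorted(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0.2, 0.1, 300), rng.normal(0.7, 0.1, 300)])
        m = fit_mixture(x, 3, seed=6)
        assert m.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(m.means) >= 0).all()
        assert (m.variances >= 1e-6).all()

    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0.1, 0.05, 200), rng.normal(0.6, 0.05, 200)])
        m = fit_mixture(x, 2, seed=7)
        path = tmp_path / "model.json"
        m.to_json(path)
        m2 = MixtureModel.from_json(path)
        np.testing.assert_allclose(m.means, m2.means)
        np.testing.assert_allclose(m.weights, m2.weights)
        assert m2.k == 2 and m2.converged == m.converged

    def test_agrees_with_sklearn_reference(self):
        sklearn_mixture = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0.09, 0.08, 870), rng.normal(0.51, 0.07, 630)])
        ours = fit_mixture(x, 2, seed=8)
        ref = sklearn_mixture.GaussianMixture(
            2, covariance_type="diag", n_init=5, random_state=0, tol=1e-8,
            reg_covar=1e-6,
        ).fit(x[:, None])
        ref_means = np.sort(ref.means_.ravel())
        np.testing.assert_allclose(ours.means, ref_means, atol=5e-3)
        assert ours.log_likelihood == pytest.approx(
            ref.score(x[:, None]) * len(x), rel=1e-4
        )


class TestScanClassCounts:
    def test_loglik_non_decreasing_in_k(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(0.1, 0.08, 500), rng.normal(0.5, 0.07, 400)])
        tab = scan_class_counts(x, k_range=range(1, 5), seed=9, n_restarts=10)
        ll = tab["log_likelihood"].to_numpy()
        assert (np.diff(ll) >= -1e-6 * np.abs(ll[:-1])).all()

    def test_bic_prefers_one_class_for_single_normal(self):
        hits = 0
        reps = 50
        for seed in range(reps):
            rng = np.random.default_rng(2000 + seed)
            x = rng.normal(0.3, 0.1, 400)
            tab = scan_class_counts(x, k_range=range(1, 4), seed=seed, n_restarts=4)
            if tab.loc[tab["bic"].idxmin(), "k"] == 1:
                hits += 1
        assert hits >= 0.9 * reps

    def test_bimodal_correlations_favor_two_classes(self, default_dataset):
        from mvpfilter import probe_correlations

        bm, design, _ = default_dataset
        pct = probe_correlations(bm, design)
        x = pct.loc[pct["defined"], "r"].to_numpy()
        tab = scan_class_counts(x, k_range=range(1, 7), seed=0).set_index("k")
        drop12 = tab.loc[1, "bic"] - tab.loc[2, "bic"]
        assert drop12 > 0
        later_gain = tab.loc[2, "bic"] - tab.loc[2:, "bic"].min()
        assert later_gain < 0.01 * drop12


class TestPosteriorsAndSelection:
    def test_single_class_posterior_is_one(self):
        pct = _pct_from_values(np.linspace(0.05, 0.9, 12))
        model = fit_mixture(pct["r"].to_numpy(), 1)
        post = posteriors(model, pct)
        np.testing.assert_allclose(post["post_1"], 1.0)

    def test_symmetric_midpoint_splits_evenly(self):
        model = MixtureModel(
            k=2, weights=np.array([0.5, 0.5]), means=np.array([0.0, 0.5]),
            variances=np.array([0.01, 0.01]), log_likelihood=0.0, aic=0.0,
            bic=0.0, n_iterations=0, converged=True, n_restarts_used=0, seed=0,
        )
        post = posteriors(model, _pct_from_values([0.25]))
        assert post.loc["p0", "post_1"] == pytest.approx(0.5)
        assert post.loc["p0", "post_2"] == pytest.approx(0.5)

    def test_undefined_probes_forced_to_nonvariable_class(self):
        values = np.array([0.1, np.nan, 0.6])
        pct = _pct_from_values(values)
        model = fit_mixture(np.array([0.1, 0.12, 0.6, 0.62]), 2, seed=0)
        post = posteriors(model, pct)
        assert post.loc["p1", "post_1"] == 1.0
        assert post.loc["p1", "assigned"] == 1
        sums = post[["post_1", "post_2"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-10)

    def test_selection_threshold_semantics(self):
        post = pd.DataFrame(
            {"post_1": [0.0, 0.5, 1.0], "post_2": [1.0, 0.5, 0.0],
             "assigned": [2, 1, 1], "defined": [True, True, True]},
            index=pd.Index(["a", "b", "c"], name="probe_id"),
        )
        sel = select_probes(post, threshold=0.5)
        # ties at exactly the threshold are selected
        assert sel.selected_ids == ["a", "b"]
        assert sel.n_selected + sel.n_excluded == 3
        with pytest.raises(ValueError):
            select_probes(post, threshold=0.0)

    def test_selection_count_monotone_in_threshold(self, default_dataset):
        from mvpfilter import probe_correlations

        bm, design, _ = default_dataset
        pct = probe_correlations(bm, design)
        model = fit_mixture(pct.loc[pct["defined"], "r"].to_numpy(), 2, seed=0)
        post = posteriors(model, pct)
        taus = np.linspace(0.01, 1.0, 25)
        counts = [select_probes(post, t).n_selected for t in taus]
        assert (np.diff(counts) <= 0).all()
        # vanishing threshold admits every defined probe
        eps = np.finfo(float).tiny
        assert select_probes(post, eps).n_selected == int(post["defined"].sum())
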
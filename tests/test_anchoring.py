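"""Loess anchoring, parametric bootstrap, uncertainty-interval summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import spearmanr

import disweights as dw
from disweights.anchoring import AnchorError, AnchorModel, BootstrapEnsemble
from disweights.probit_engine import ProbitFit


def make_fit(betas: dict, ses: dict | None = None, reference=None) -> ProbitFit:
    """Hand-built probit fit for anchoring tests."""
    index = pd.Index(list(betas), name="state_id")
    reference = reference or list(betas)[0]
    return ProbitFit(
        coefficients=pd.Series(betas, index=index, dtype=float),
        standard_errors=pd.Series(ses or {k: 0.0 for k in betas},
                                  index=index, dtype=float),
        reference_state=reference,
        log_likelihood=0.0, n_responses=0, converged=True, n_iterations=0,
    )


def linear_anchor_setup(n=20, a=-2.0, b=0.8, se=0.0):
    """Anchors generated exactly on logitDW = a + b * beta."""
    betas = np.linspace(0.0, 4.0, n)
    states = [f"s{k}" for k in range(n)]
    catalog = [
        dw.HealthState(s, s, "Other", reference_dw=float(expit(a + b * x)))
        for s, x in zip(states, betas)
    ]
    fit = make_fit(dict(zip(states, betas)),
                   ses={s: se for s in states})
    return fit, catalog, (a, b)


class TestLogit:
    def test_midpoint(self):
        assert dw.inverse_logit(0.0) == 0.5

    def test_round_trip(self):
        assert dw.inverse_logit(dw.logit(0.741)) == pytest.approx(0.741)

    def test_formula(self):
        assert dw.logit(0.103) == pytest.approx(math.log(0.103 / 0.897),
                                                abs=1e-12)
        assert dw.logit(0.103) == pytest.approx(-2.164, abs=1e-3)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_domain_error(self, p):
        with pytest.raises(AnchorError):
            dw.logit(p)


class TestFitAnchor:
    def test_exact_on_collinear_anchors(self):
        """Local linear regression reproduces a line through the anchors."""
        fit, catalog, (a, b) = linear_anchor_setup()
        model = dw.fit_anchor(fit, catalog, span=0.75, degree=1)
        pred, extrapolated = model.predict(model.anchor_beta)
        assert np.allclose(pred, a + b * model.anchor_beta, atol=1e-8)
        assert not extrapolated.any()

    def test_degree_two_exact_on_quadratic(self):
        betas = np.linspace(-1, 3, 25)
        states = [f"s{k}" for k in range(25)]
        y = -1.5 + 0.9 * betas - 0.1 * betas ** 2
        catalog = [dw.HealthState(s, s, "Other", reference_dw=float(expit(v)))
                   for s, v in zip(states, y)]
        fit = make_fit(dict(zip(states, betas)))
        model = dw.fit_anchor(fit, catalog, span=0.6, degree=2)
        pred, _ = model.predict(betas)
        assert np.allclose(pred, y, atol=1e-8)

    def test_monotone_anchors_preserve_ordering(self, study_fit,
                                                fixture_catalog):
        model = dw.fit_anchor(study_fit, fixture_catalog)
        betas = np.sort(study_fit.coefficients.to_numpy())
        pred, _ = model.predict(betas)
        dws = expit(pred)
        assert (np.diff(dws) > -1e-9).all()

    def test_extrapolation_flagged(self):
        fit, catalog, _ = linear_anchor_setup()
        model = dw.fit_anchor(fit, catalog)
        _, flags = model.predict(np.array([-1.0, 2.0, 5.0]))
        assert list(flags) == [True, False, True]

    def test_too_few_anchors(self):
        fit, catalog, _ = linear_anchor_setup(n=20)
        with pytest.raises(AnchorError, match=">= 10"):
            dw.fit_anchor(fit, catalog[:1])
        with pytest.raises(AnchorError, match=">= 10"):
            dw.fit_anchor(fit, catalog[:9])

    def test_degenerate_beta_spread(self):
        states = [f"s{k}" for k in range(12)]
        catalog = [dw.HealthState(s, s, "Other", reference_dw=0.2)
                   for s in states]
        fit = make_fit({s: 1.0 for s in states})
        with pytest.raises(AnchorError, match="degenerate"):
            dw.fit_anchor(fit, catalog)

    def test_parameter_validation(self):
        fit, catalog, _ = linear_anchor_setup()
        with pytest.raises(AnchorError):
            dw.fit_anchor(fit, catalog, span=0.0)
        with pytest.raises(AnchorError):
            dw.fit_anchor(fit, catalog, degree=3)

    def test_boundary_reference_weights_are_clipped(self):
        # reference weights at the closed boundary pass through the
        # documented 1e-6 clip instead of producing infinite logits
        states = [f"s{k}" for k in range(12)]
        betas = np.linspace(0, 2, 12)
        refs = [1e-9] + [0.1 * (k + 1) / 12 for k in range(10)] + [1 - 1e-9]
        catalog = [dw.HealthState(s, s, "Other", reference_dw=r)
                   for s, r in zip(states, refs)]
        model = dw.fit_anchor(make_fit(dict(zip(states, betas))), catalog)
        assert np.isfinite(model.anchor_logit_dw).all()


class TestBootstrap:
    def test_zero_spread_gives_zero_width_intervals(self):
        fit, catalog, (a, b) = linear_anchor_setup(se=0.0)
        model = dw.fit_anchor(fit, catalog)
        ensemble = dw.bootstrap_weights(fit, model, n_replicates=50, seed=1)
        estimates = dw.summarize_weights(ensemble)
        for est, beta in zip(estimates, model.anchor_beta):
            expected = float(expit(a + b * beta))
            assert est.dw == pytest.approx(expected, abs=1e-8)
            assert est.ui_low == pytest.approx(est.ui_high, abs=1e-12)

    def test_determinism_under_fixed_seed(self):
        fit, catalog, _ = linear_anchor_setup(se=0.1)
        model = dw.fit_anchor(fit, catalog)
        e1 = dw.bootstrap_weights(fit, model, n_replicates=100, seed=7)
        e2 = dw.bootstrap_weights(fit, model, n_replicates=100, seed=7)
        assert np.array_equal(e1.logit_replicates, e2.logit_replicates)
        e3 = dw.bootstrap_weights(fit, model, n_replicates=100, seed=8)
        assert not np.array_equal(e1.logit_replicates, e3.logit_replicates)

    def test_replicate_mean_tracks_point_prediction(self):
        fit, catalog, _ = linear_anchor_setup(se=0.15)
        model = dw.fit_anchor(fit, catalog)
        ensemble = dw.bootstrap_weights(fit, model, n_replicates=1000, seed=3)
        point, _ = model.predict(fit.coefficients.to_numpy())
        reps = ensemble.logit_replicates
        # refitting on redrawn anchors smooths, so the replicate mean can
        # carry a small bias; it must stay well inside the ensemble spread
        assert np.all(np.abs(reps.mean(axis=1) - point) < reps.std(axis=1))

    def test_nonfinite_standard_error_names_state(self):
        fit, catalog, _ = linear_anchor_setup()
        fit.standard_errors.iloc[3] = np.nan
        model = dw.fit_anchor(fit, catalog)
        with pytest.raises(AnchorError, match="s3"):
            dw.bootstrap_weights(fit, model, n_replicates=10, seed=0)

    def test_replicate_count_validation(self):
        fit, catalog, _ = linear_anchor_setup()
        model = dw.fit_anchor(fit, catalog)
        with pytest.raises(AnchorError):
            dw.bootstrap_weights(fit, model, n_replicates=1, seed=0)


class TestSummarize:
    def test_degenerate_ensemble(self):
        v = 0.271
        reps = np.full((3, 40), dw.logit(v))
        ensemble = BootstrapEnsemble(["a", "b", "c"], reps, seed=0)
        for est in dw.summarize_weights(ensemble):
            assert est.dw == pytest.approx(v)
            assert est.ui_low == pytest.approx(v)
            assert est.ui_high == pytest.approx(v)

    def test_symmetric_logit_ensemble_centres_at_half(self):
        reps = np.tile(np.array([-1.0, 1.0]), (2, 25))
        ensemble = BootstrapEnsemble(["a", "b"], reps, seed=0)
        estimates = dw.summarize_weights(ensemble)
        assert all(est.dw == pytest.approx(0.5) for est in estimates)
        # the sensitivity option averages on the weight scale instead
        dw_scale = dw.summarize_weights(ensemble, mean_scale="dw")
        assert all(est.dw == pytest.approx(0.5) for est in dw_scale)

    def test_interval_bounds_ordered_inside_unit(self, study_fit,
                                                 fixture_catalog):
        model = dw.fit_anchor(study_fit, fixture_catalog)
        ensemble = dw.bootstrap_weights(study_fit, model, n_replicates=200,
                                        seed=5)
        for est in dw.summarize_weights(ensemble):
            assert 0 < est.ui_low <= est.ui_high < 1


class TestCoverage:
    def test_interval_coverage_on_small_catalogs(self):
        """95% UIs contain the truth for >= 80% of state x simulation cells.

        Anchoring bias makes exact nominal coverage unattainable; this is
        the loose sanity bound over 50 seeded small surveys of a 20-state
        catalog spanning the published severity range.
        """
        full = dw.table2_catalog()
        idx = np.linspace(0, len(full) - 1, 20).astype(int)
        catalog = [full[int(k)] for k in sorted(set(idx))]
        states = [s.state_id for s in catalog]
        truth = np.array([s.true_dw for s in catalog])
        hits = total = 0
        for seed in range(50):
            config = dw.SimulationConfig(n_respondents=120, seed=seed)
            _, responses = dw.simulate_survey(catalog, config)
            fit = dw.fit_probit(dw.build_design(responses, states=states))
            model = dw.fit_anchor(fit, catalog)
            ensemble = dw.bootstrap_weights(fit, model, n_replicates=300,
                                            seed=seed)
            by_id = {e.state_id: e for e in dw.summarize_weights(ensemble)}
            for sid, t in zip(states, truth):
                if sid in by_id:
                    hits += by_id[sid].ui_low <= t <= by_id[sid].ui_high
                    total += 1
        assert total >= 900
        assert hits / total >= 0.80


class TestEndToEndRecovery:
    def test_small_survey_recovers_truth_ranking(self, fixture_catalog):
        """Seeded pipeline on a modest survey rank-correlates >= 0.95."""
        config = dw.SimulationConfig(n_respondents=500, seed=21)
        _, responses = dw.simulate_survey(fixture_catalog, config)
        fit = dw.fit_probit(dw.build_design(
            responses, states=[s.state_id for s in fixture_catalog]))
        model = dw.fit_anchor(fit, fixture_catalog)
        estimates = dw.summarize_weights(
            dw.bootstrap_weights(fit, model, n_replicates=300, seed=22))
        truth = {s.state_id: s.true_dw for s in fixture_catalog}
        rho = spearmanr([e.dw for e in estimates],
                        [truth[e.state_id] for e in estimates]).statistic
        assert rho >= 0.95
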
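"""Dose-response curve families, lognormal likelihood, and ML fitting."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from bmdrisk import (
    CovariateStructure,
    DoseResponseDataset,
    DoseResponseRecord,
    GroupSummary,
    ModelParams,
    fit_single_structure,
    log_likelihood,
    predict_response,
)
from bmdrisk.models import (
    ConfigurationError,
    DataSupportError,
    DeclaredLevelError,
    IdentifiabilityError,
)

from conftest import make_individual, on_curve_dataset


def mk_params(family, a, b, c, d, var=1.0, level="m"):
    return ModelParams(family=family, a={level: a}, b={level: b}, c=c, d=d, var={level: var})


class TestPredictResponse:
    @pytest.mark.parametrize(
        "family,a,b,c,d,dose,expected",
        [
            # hand evaluation: 0.1*(3 - 2*exp(-ln2)) = 0.1*(3-1) = 0.2
            ("exponential", 0.1, math.log(2), 3.0, 1.0, 1.0, 0.2),
            # hand evaluation: 1*(1 + 1*2/(2+2)) = 1.5
            ("hill", 1.0, 2.0, 2.0, 1.0, 2.0, 1.5),
            ("exponential", 0.37, 1.0, 4.0, 2.0, 0.0, 0.37),
            ("hill", 0.37, 1.0, 4.0, 2.0, 0.0, 0.37),
        ],
    )
    def test_point_values(self, family, a, b, c, d, dose, expected):
        p = mk_params(family, a, b, c, d)
        assert predict_response(p, "m", dose) == pytest.approx(expected, rel=1e-12)

    @given(
        family=st.sampled_from(["exponential", "hill"]),
        a=st.floats(0.01, 10),
        b=st.floats(0.01, 10),
        c=st.floats(1.001, 500),
        d=st.floats(0.25, 4),
    )
    def test_monotone_with_background_and_plateau(self, family, a, b, c, d):
        """m is non-decreasing for c > 1, starts at a and approaches a*c."""
        p = mk_params(family, a, b, c, d)
        doses = np.geomspace(1e-4, 1e4, 60)
        m = predict_response(p, "m", doses)
        assert np.all(np.diff(m) >= -1e-9 * np.abs(m[1:]))
        assert predict_response(p, "m", 0.0) == pytest.approx(a, rel=1e-12)
        assert np.all(m <= a * c * (1 + 1e-9))

    def test_unknown_level_and_family(self):
        p = mk_params("exponential", 1, 1, 2, 1)
        with pytest.raises(DeclaredLevelError):
            predict_response(p, "nope", 1.0)
        with pytest.raises(ConfigurationError):
            mk_params("weibull", 1, 1, 2, 1)


class TestLogLikelihood:
    def test_zero_residual_unit_variance(self):
        p = mk_params("exponential", 0.1, math.log(2), 3.0, 1.0, var=1.0)
        m = predict_response(p, "m", 1.0)
        data = make_individual([("m", 1.0, m)])
        assert log_likelihood(data, p) == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-6)

    def test_additive_and_order_invariant(self, exp_params):
        d_a = on_curve_dataset(exp_params, [0, 1, 4], rel_jitter=0.3, seed=3)
        d_b = on_curve_dataset(exp_params, [0, 2, 8], rel_jitter=0.3, seed=4)
        combined = make_individual(
            [("m", r.dose, r.response) for r in (d_a.records + d_b.records)]
        )
        shuffled = make_individual(
            [("m", r.dose, r.response) for r in reversed(d_a.records + d_b.records)]
        )
        ll = log_likelihood(combined, exp_params)
        assert ll == pytest.approx(
            log_likelihood(d_a, exp_params) + log_likelihood(d_b, exp_params), rel=1e-12
        )
        assert ll == pytest.approx(log_likelihood(shuffled, exp_params), rel=1e-12)

    def test_matches_per_observation_normal_density(self):
        """Brute-force oracle: sum of normal log-densities of the log-responses."""
        p = ModelParams(
            family="hill",
            a={"f": 0.2, "m": 0.3}, b={"f": 3.0, "m": 1.5},
            c=4.0, d=1.2, var={"f": 0.09, "m": 0.25},
        )
        rng = np.random.default_rng(11)
        rows = [
            (lvl, dose, predict_response(p, lvl, dose) * math.exp(rng.normal(0, 0.4)))
            for lvl in ("f", "m")
            for dose in (0.0, 1.0, 5.0, 20.0)
            for _ in range(3)
        ]
        data = make_individual(rows)
        expected = sum(
            norm.logpdf(
                math.log(resp),
                loc=math.log(predict_response(p, lvl, dose)),
                scale=math.sqrt(p.var[lvl]),
            )
            for lvl, dose, resp in rows
        )
        assert log_likelihood(data, p) == pytest.approx(expected, rel=1e-10)

    def test_summary_moment_map_recovers_log_scale(self):
        """Exact lognormal arithmetic moments invert to the log-scale parameters."""
        mu, sigma2 = 0.7, 0.2
        mean = math.exp(mu + sigma2 / 2)
        sd = mean * math.sqrt(math.expm1(sigma2))
        g = GroupSummary(dose=1.0, n=5, mean=mean, sd=sd, covariate_level="m")
        logmean, logvar = g.log_scale_stats()
        assert logmean == pytest.approx(mu, rel=1e-10)
        assert logvar == pytest.approx(sigma2, rel=1e-10)

    def test_rejects_nonpositive_response(self):
        with pytest.raises(DataSupportError):
            DoseResponseRecord("d", "m", 1.0, 0.0)


class TestFit:
    def test_recovers_noise_free_parameters(self, exp_params):
        data = on_curve_dataset(exp_params, [0, 1, 2, 4, 8, 16], rel_jitter=1e-2, seed=5)
        fit = fit_single_structure(data, "exponential")
        assert fit.converged
        p = fit.params
        for got, true in [
            (p.a["m"], exp_params.a["m"]),
            (p.b["m"], exp_params.b["m"]),
            (p.c, exp_params.c),
            (p.d, exp_params.d),
        ]:
            assert got == pytest.approx(true, rel=0.05)

    def test_flat_data_flagged(self):
        rng = np.random.default_rng(2)
        rows = [
            ("m", dose, 1.0 * math.exp(rng.normal(0, 0.1)))
            for dose in (0.0, 1.0, 5.0, 25.0)
            for _ in range(5)
        ]
        fit = fit_single_structure(make_individual(rows), "exponential")
        assert fit.diagnostics["flat_model"]
        # downstream: a 50% effect size is never reached by the fitted curve
        from bmdrisk import compute_bmd

        assert math.isinf(compute_bmd(fit.params, "m", 0.5))

    def test_loglik_beats_coarse_grid_search(self):
        """MLE oracle: exhaustive lattice over (a, b, c, d) with var profiled."""
        true = ModelParams(
            family="exponential", a={"f": 0.4, "m": 0.5}, b={"f": 0.25, "m": 0.25},
            c=4.0, d=1.0, var={"f": 0.05, "m": 0.05},
        )
        data = on_curve_dataset(true, [0, 2, 10], n_per_group=4, rel_jitter=0.2, seed=8)
        fit = fit_single_structure(data, "exponential", CovariateStructure())

        def grid_ll(a, b, c, d):
            logs = np.array([math.log(r.response) for r in data.records])
            mus = np.array(
                [math.log(predict_response(mk_params("exponential", a, b, c, d), "m", r.dose))
                 for r in data.records]
            )
            var = float(np.mean((logs - mus) ** 2))
            return float(np.sum(norm.logpdf(logs, mus, math.sqrt(var))))

        best_grid = max(
            grid_ll(a, b, c, d)
            for a in np.linspace(0.3, 0.7, 5)
            for b in np.geomspace(0.05, 1.0, 6)
            for c in (2.0, 4.0, 8.0)
            for d in (0.5, 1.0, 2.0)
        )
        assert fit.loglik >= best_grid - 1e-4

    def test_all_shared_equals_pooled_single_level(self, garriott_data):
        shared = fit_single_structure(garriott_data, "exponential", CovariateStructure())
        pooled = fit_single_structure(
            garriott_data.relabel("pooled"), "exponential", CovariateStructure()
        )
        assert shared.loglik == pytest.approx(pooled.loglik, abs=1e-6)

    def test_nested_structures_never_lose_loglik(self, garriott_data):
        chain = [
            CovariateStructure(),
            CovariateStructure(frozenset({"a"})),
            CovariateStructure(frozenset({"a", "b"})),
            CovariateStructure(frozenset({"a", "b", "var"})),
        ]
        prev = None
        for structure in chain:
            fit = fit_single_structure(
                garriott_data, "exponential", structure,
                init_params=prev.params if prev else None,
            )
            if prev is not None:
                assert fit.loglik >= prev.loglik - 1e-6
            prev = fit

    def test_too_few_doses_rejected(self):
        rows = [("m", d, r) for d, r in [(0, 1.0), (0, 1.1), (2, 2.0), (2, 2.2)]]
        with pytest.raises(IdentifiabilityError):
            fit_single_structure(make_individual(rows), "exponential")

    def test_structure_rejects_shape_parameters(self):
        with pytest.raises(ConfigurationError):
            CovariateStructure(frozenset({"c"}))

    def test_dataset_form_is_exclusive(self):
        with pytest.raises(ValueError):
            DoseResponseDataset(records=[], summaries=[])
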
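"""Benchmark-dose computation, profile CIs, LR structure selection, combination."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize
from scipy.stats import norm

from bmdrisk import (
    BmdEstimate,
    ModelParams,
    SimulationConfig,
    ci_ratio_report,
    combine_families,
    compute_bmd,
    generate_dataset,
    loglik_ratio_threshold,
    predict_response,
    profile_bmd_ci,
    select_covariate_structure,
)
from bmdrisk.models import ConfigurationError

from conftest import on_curve_dataset


def mk_params(family, a, b, c, d, var=0.1, level="m"):
    return ModelParams(family=family, a={level: a}, b={level: b}, c=c, d=d, var={level: var})


def random_params(rng, family):
    return mk_params(
        family,
        a=float(rng.uniform(0.05, 5.0)),
        b=float(rng.uniform(0.01, 10.0)),
        c=float(rng.uniform(1.6, 200.0)),
        d=float(rng.uniform(0.25, 4.0)),
    )


class TestComputeBmd:
    def test_likelihood_ratio_threshold_1df(self):
        # half of the 95th chi-square percentile with 1 df (3.8415)
        assert loglik_ratio_threshold(0.05, 1) == pytest.approx(1.9207, abs=2e-4)

    def test_exponential_closed_form_unit_case(self):
        # (c-1-ces)/(c-1) = 0.5 and b = ln 2 give BMD = 1 exactly
        p = mk_params("exponential", 1.0, math.log(2), 2.0, 1.0)
        assert compute_bmd(p, "m", 0.5) == pytest.approx(1.0, rel=1e-12)

    def test_unreachable_effect_size_is_infinite(self):
        p = mk_params("exponential", 1.0, 1.0, 1.4, 1.0)
        assert math.isinf(compute_bmd(p, "m", 0.5))

    def test_vanishes_with_effect_size(self):
        p = mk_params("hill", 1.0, 2.0, 3.0, 1.0)
        assert compute_bmd(p, "m", 1e-9) < 1e-6

    @pytest.mark.parametrize("family", ["exponential", "hill"])
    def test_curve_passes_through_benchmark_response(self, family):
        """m(BMD) = a*(1+CES) to 1e-8 relative, over random valid parameters."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            p = random_params(rng, family)
            ces = float(rng.uniform(0.05, min(3.0, p.c - 1.0 - 1e-6)))
            bmd = compute_bmd(p, "m", ces)
            assert predict_response(p, "m", bmd) == pytest.approx(
                p.a["m"] * (1 + ces), rel=1e-8
            )

    @given(
        family=st.sampled_from(["exponential", "hill"]),
        b=st.floats(0.01, 10),
        c=st.floats(1.8, 300),
        d=st.floats(0.25, 4),
        ces_pair=st.tuples(st.floats(0.01, 0.7), st.floats(0.01, 0.7)),
    )
    def test_strictly_increasing_in_ces(self, family, b, c, d, ces_pair):
        lo, hi = sorted(ces_pair)
        if hi - lo < 1e-6:
            return
        p = mk_params(family, 1.0, b, c, d)
        assert compute_bmd(p, "m", lo) < compute_bmd(p, "m", hi)

    def test_dose_scale_equivariance_through_fit(self, exp_params):
        """Multiplying all doses by k multiplies BMD/BMDL/BMDU by k."""
        doses = [0, 1, 2, 4, 8, 16]
        k = 7.0
        base = on_curve_dataset(exp_params, doses, rel_jitter=0.05, seed=9)
        scaled = on_curve_dataset(exp_params, doses, rel_jitter=0.05, seed=9)
        from conftest import make_individual

        scaled = make_individual([("m", r.dose * k, r.response) for r in base.records])
        e1 = profile_bmd_ci(base, "exponential", ces=0.5)
        e2 = profile_bmd_ci(scaled, "exponential", ces=0.5)
        assert e2.bmd == pytest.approx(k * e1.bmd, rel=1e-3)
        assert e2.bmdl == pytest.approx(k * e1.bmdl, rel=5e-3)
        assert e2.bmdu == pytest.approx(k * e1.bmdu, rel=5e-3)

    def test_response_unit_invariance_through_fit(self, exp_params):
        """Multiplying all responses by k only rescales a; BMD bounds unchanged."""
        from conftest import make_individual

        base = on_curve_dataset(exp_params, [0, 1, 2, 4, 8, 16], rel_jitter=0.05, seed=9)
        scaled = make_individual([("m", r.dose, r.response * 100.0) for r in base.records])
        e1 = profile_bmd_ci(base, "exponential", ces=0.5)
        e2 = profile_bmd_ci(scaled, "exponential", ces=0.5)
        assert e2.bmd == pytest.approx(e1.bmd, rel=1e-3)
        assert e2.bmdl == pytest.approx(e1.bmdl, rel=5e-3)
        assert e2.bmdu == pytest.approx(e1.bmdu, rel=5e-3)


class TestProfileCi:
    def test_interval_contains_mle(self, garriott_data, garriott_fit):
        structure, fit = garriott_fit
        for level in garriott_data.levels:
            est = profile_bmd_ci(
                garriott_data, "exponential", structure, level=level, fit=fit
            )
            assert est.bmdl <= est.bmd <= est.bmdu
            assert est.ci_ratio >= 1.0

    def test_matches_exhaustive_grid_profile(self, exp_params):
        """Oracle: scan log-BMD on a grid, maximizing the plain likelihood over
        (a, c) with b eliminated by the closed form, independently of the
        profiling code under test."""
        data = on_curve_dataset(exp_params, [0, 0.5, 1, 3, 9, 27], n_per_group=4,
                                rel_jitter=0.1, seed=13)
        ces, ci_level = 0.5, 0.90
        est = profile_bmd_ci(data, "exponential", ces=ces, ci_level=ci_level)

        logs = np.array([math.log(r.response) for r in data.records])
        doses = np.array([r.dose for r in data.records])

        def profiled_ll(log_bmd):
            def nll(theta):
                a, cm1, d = math.exp(theta[0]), math.exp(theta[1]), theta[2]
                c = 1.0 + cm1
                if ces >= cm1 or not (0.25 <= d <= 4.0):
                    return 1e9
                b = -math.log((cm1 - ces) / cm1) / math.exp(log_bmd) ** d
                m = a * (c - (c - 1) * np.exp(-b * doses ** d))
                mus = np.log(m)
                var = float(np.mean((logs - mus) ** 2))
                return -float(np.sum(norm.logpdf(logs, mus, math.sqrt(var))))

            best = min(
                minimize(nll, x0, method="Nelder-Mead",
                         options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000}).fun
                for x0 in ([math.log(0.5), math.log(4), 1.0],
                           [math.log(0.5), math.log(1.5), 0.5],
                           [math.log(1.0), math.log(50), 2.0])
            )
            return -best

        grid = np.linspace(math.log(est.bmd) - 1.5, math.log(est.bmd) + 1.5, 61)
        lls = np.array([profiled_ll(g) for g in grid])
        from scipy.stats import chi2

        target = lls.max() - 0.5 * chi2.ppf(ci_level, 1)
        inside = grid[lls >= target]
        step = grid[1] - grid[0]
        assert math.log(est.bmdl) == pytest.approx(inside.min(), abs=2 * step)
        assert math.log(est.bmdu) == pytest.approx(inside.max(), abs=2 * step)


class TestStructureSelection:
    def test_single_level_is_trivially_all_shared(self, exp_params):
        data = on_curve_dataset(exp_params, [0, 1, 4, 16], rel_jitter=0.2, seed=21)
        structure, fit = select_covariate_structure(data, "exponential")
        assert structure.level_specific == frozenset()
        assert fit.diagnostics["selection"]["note"] == "single level"

    def test_detects_strong_potency_difference(self):
        """Two levels generated with 10-fold different b: b must be selected."""
        true = ModelParams(
            family="exponential",
            a={"f": 0.5, "m": 0.5}, b={"f": 0.03, "m": 0.3},
            c=5.0, d=1.0, var={"f": 0.05, "m": 0.05},
        )
        hits = 0
        n_reps = 10
        for r in range(n_reps):
            data = generate_dataset(
                SimulationConfig(doses=(0, 1, 4, 16), true_params=true,
                                 n_per_group=20, seed=500 + r)
            )
            structure, _ = select_covariate_structure(data, "exponential")
            hits += structure.is_specific("b")
        assert hits >= 9

    def test_mixed_ces_rejected_in_combination(self):
        e1 = BmdEstimate("exponential", "m", 0.5, 3.0, 2.0, 5.0)
        e2 = BmdEstimate("hill", "m", 0.1, 3.0, 2.0, 5.0)
        with pytest.raises(ConfigurationError):
            combine_families([e1, e2])


class TestCombination:
    def test_min_bmdl_max_bmdu_per_level(self):
        ests = [
            BmdEstimate("exponential", "male", 0.5, 4.0, 2.9, 7.0),
            BmdEstimate("hill", "male", 0.5, 4.1, 3.1, 7.42),
        ]
        (pod,) = combine_families(ests)
        assert (pod.pod_bmdl, pod.pod_bmdu) == (2.9, 7.42)
        assert set(pod.contributing_families) == {"exponential", "hill"}

    def test_single_family_passthrough(self):
        (pod,) = combine_families([BmdEstimate("hill", "m", 0.5, 4.0, 3.0, 8.0)])
        assert (pod.pod_bmdl, pod.pod_bmdu) == (3.0, 8.0)

    def test_infinite_bmdu_dominates(self):
        ests = [
            BmdEstimate("exponential", "m", 0.5, 4.0, 3.0, math.inf),
            BmdEstimate("hill", "m", 0.5, 4.0, 2.5, 8.0),
        ]
        (pod,) = combine_families(ests)
        assert pod.pod_bmdl == 2.5 and math.isinf(pod.pod_bmdu)

    def test_ci_ratio_report_values(self):
        ests = [
            BmdEstimate("exponential", "m", 0.5, 4.0, 2.0, 8.0),
            BmdEstimate("hill", "m", 0.5, 4.0, 3.0, math.inf),
        ]
        df = ci_ratio_report(ests)
        by = {(r["covariate_level"], r["family"]): r["ci_ratio"] for _, r in df.iterrows()}
        assert by[("m", "exponential")] == pytest.approx(4.0)
        assert math.isinf(by[("m", "hill")])
        assert math.isinf(by[("m", "combined")])
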
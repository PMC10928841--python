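"""Likelihood, single and covariate fitting, model selection, profile intervals."""

import math

import numpy as np
import pytest

from amesbmd import family, inference, synthetic
from amesbmd.family import ExponentialParams
from amesbmd.inference import (
    ExponentialDoseResponse,
    FitData,
    concat_fit_data,
    fit_covariate,
    fit_single,
    log_likelihood,
    select_model,
    test_subgroup_dependence as lr_subgroup_dependence,
)
from amesbmd.plate_io import Design

DESIGN = Design("SYN", "pre_incubation", "hamster", "water", "TA100")


def simulate_data(truth, seed):
    rng = np.random.default_rng(seed)
    doses, resp = [], []
    for _ in range(truth.n_control):
        doses.append(0.0)
        resp.append(math.exp(rng.normal(math.log(truth.params.a), truth.sigma)))
    for dose in truth.doses:
        mu = family.mean_response(truth.params, dose)
        for _ in range(truth.n_treated):
            doses.append(dose)
            resp.append(math.exp(rng.normal(math.log(mu), truth.sigma)))
    return FitData(np.array(doses), np.array(resp))


class TestLogLikelihood:
    def test_single_plate_at_model_mean_unit_variance(self):
        data = FitData(np.array([10.0]), np.array([100.0 * math.e]))
        params = ExponentialParams("m2", a=100.0, b=0.1)  # mean = 100*e at dose 10
        ll = log_likelihood(data, params, log_var=1.0)
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_profiled_variance_maximizes_likelihood(self, rng):
        truth = synthetic.saturating_truth(DESIGN, ced=300.0)
        data = simulate_data(truth, 3)
        params = truth.params
        mu = family.mean_response(params, data.doses)
        rss = float(np.mean((np.log(data.responses) - np.log(mu)) ** 2))
        best = log_likelihood(data, params, rss)
        for v in np.geomspace(rss / 10, rss * 10, 41):
            assert log_likelihood(data, params, v) <= best + 1e-9

    def test_scale_equivariance_on_log_scale(self):
        truth = synthetic.saturating_truth(DESIGN, ced=300.0)
        data = simulate_data(truth, 4)
        doubled = FitData(data.doses, 2.0 * data.responses)
        p = truth.params
        p2 = ExponentialParams("m5", a=2 * p.a, b=p.b, c=p.c, d=p.d)
        # shape of the likelihood in b is unchanged when counts and a double
        for b_scale in (0.5, 1.0, 2.0):
            pa = ExponentialParams("m5", a=p.a, b=p.b * b_scale, c=p.c, d=p.d)
            pb = ExponentialParams("m5", a=2 * p.a, b=p.b * b_scale, c=p.c, d=p.d)
            assert log_likelihood(data, pa, 0.02) == pytest.approx(
                log_likelihood(doubled, pb, 0.02)
            )
        assert log_likelihood(doubled, p2, 0.02) == pytest.approx(
            log_likelihood(data, p, 0.02)
        )

    def test_positive_responses_required(self):
        with pytest.raises(ValueError):
            FitData(np.array([0.0, 10.0]), np.array([0.0, 5.0]))


class TestFitSingle:
    def test_recovers_ced_from_m3_truth(self):
        truth = synthetic.TruthSpec(
            design=DESIGN,
            params=ExponentialParams("m3", a=100.0, b=math.log(2) / 2500.0**2, d=2.0),
            sigma=0.05,
        )
        data = simulate_data(truth, 11)
        res = fit_single(data, "m3")
        est = res.ced()
        assert est.reached
        assert est.ced == pytest.approx(2500.0, rel=0.25)

    def test_flat_data_drives_b_to_bound(self, rng):
        data = FitData(
            np.tile([0.0, 50.0, 150.0, 500.0, 1500.0, 5000.0], 3),
            rng.lognormal(math.log(100.0), 0.1, 18),
        )
        r1 = fit_single(data, "m1")
        r2 = fit_single(data, "m2")
        assert r2.loglik >= r1.loglik - 1e-9
        assert 2 * (r2.loglik - r1.loglik) < 3.841
        b_scaled = r2.estimates[r2.groups[0]].params.b * 5000.0
        assert b_scaled < 0.5  # negligible slope over the dose range

    def test_permutation_invariance(self, rng):
        truth = synthetic.saturating_truth(DESIGN, ced=400.0)
        data = simulate_data(truth, 5)
        perm = rng.permutation(len(data.doses))
        shuffled = FitData(data.doses[perm], data.responses[perm])
        a, b = fit_single(data, "m4"), fit_single(shuffled, "m4")
        assert a.loglik == pytest.approx(b.loglik, abs=1e-8)

    def test_deterministic_given_seed(self):
        truth = synthetic.saturating_truth(DESIGN, ced=400.0)
        data = simulate_data(truth, 6)
        r1 = fit_single(data, "m5", seed=77)
        r2 = fit_single(data, "m5", seed=77)
        assert r1.loglik == r2.loglik
        assert r1.estimates[r1.groups[0]].params == r2.estimates[r2.groups[0]].params


class TestSelectModel:
    def test_strong_m2_signal_beats_flat_model(self):
        truth = synthetic.TruthSpec(
            design=DESIGN,
            params=ExponentialParams("m2", a=100.0, b=math.log(8) / 5000.0),
            sigma=0.1,
        )
        data = simulate_data(truth, 21)
        res = select_model(data)
        assert res.model_id != "m1"
        lls = res.selection_trail
        assert 2 * (lls["m2"][0] - lls["m1"][0]) > 3.841

    def test_saturating_truth_selects_plateau_model_mostly(self):
        hits = 0
        for seed in range(10):
            truth = synthetic.saturating_truth(DESIGN, ced=150.0, plateau_fold=8.0)
            data = simulate_data(truth, 100 + seed)
            res = select_model(data, seed=seed)
            if res.model_id in ("m4", "m5"):
                hits += 1
        assert hits >= 6

    def test_ladder_likelihoods_monotone_along_true_nestings(self):
        truth = synthetic.saturating_truth(DESIGN, ced=800.0)
        data = simulate_data(truth, 31)
        model = ExponentialDoseResponse(data)
        fits = {m: model.fit(m) for m in ("m1", "m2")}
        fits["m3"] = model.fit("m3", warm=model._warm("m3", fits))
        fits["m4"] = model.fit("m4", warm=model._warm("m4", fits))
        fits["m5"] = model.fit("m5", warm=model._warm("m5", fits))
        tol = 1e-6
        assert fits["m2"].loglik >= fits["m1"].loglik - tol
        assert fits["m3"].loglik >= fits["m2"].loglik - tol
        assert fits["m4"].loglik >= fits["m1"].loglik - tol
        assert fits["m5"].loglik >= fits["m4"].loglik - tol


class TestCovariate:
    def _two_group_data(self, b_ratio=1.0, seed=0):
        datasets = []
        for i, label in enumerate(("g1", "g2")):
            b = family.b_from_ced("m5", 300.0, 1.0, c=30.0, d=1.0)
            if i == 1:
                b *= b_ratio
            truth = synthetic.TruthSpec(
                design=DESIGN,
                params=ExponentialParams("m5", a=100.0, b=b, c=30.0, d=1.0),
            )
            d = simulate_data(truth, seed + i)
            datasets.append(
                FitData(d.doses, d.responses, np.array([label] * len(d.doses)))
            )
        return datasets

    def test_identical_subgroups_get_similar_estimates(self):
        data = concat_fit_data(self._two_group_data(b_ratio=1.0, seed=8))
        res = fit_covariate(data, "m4")
        e1, e2 = (res.estimates[g] for g in res.groups)
        ced1, ced2 = (family.ced(e.params).ced for e in (e1, e2))
        assert ced1 == pytest.approx(ced2, rel=0.5)
        # shared shape parameters are literally equal
        assert e1.params.c == e2.params.c

    def test_single_subgroup_reduces_to_fit_single(self):
        truth = synthetic.saturating_truth(DESIGN, ced=250.0)
        data = simulate_data(truth, 41)
        single = fit_single(data, "m4")
        cov = fit_covariate(data, "m4")
        assert cov.loglik == pytest.approx(single.loglik, abs=1e-6)

    def test_potency_ratio_recovered_within_intervals(self):
        data = concat_fit_data(self._two_group_data(b_ratio=10.0, seed=12))
        res = fit_covariate(data, "m5")
        (g1, g2) = res.groups
        ced1 = res.ced(subgroup=g1)
        ced2 = res.ced(subgroup=g2)
        assert ced1.reached and ced2.reached
        ci2 = res.profile_ci(subgroup=g2)
        assert ci2.contains(30.0)  # true CED of the 10x-potent subgroup
        assert ced2.ced < ced1.ced

    def test_small_subgroup_rejected(self):
        data = FitData(
            np.array([0.0, 50.0, 0.0, 50.0, 500.0]),
            np.array([100.0, 150.0, 90.0, 140.0, 200.0]),
            np.array(["a", "a", "a", "a", "b"]),
        )
        with pytest.raises(ValueError, match="fewer than 3"):
            fit_covariate(data, "m2")


class TestSubgroupDependence:
    def test_single_group_undefined(self):
        truth = synthetic.saturating_truth(DESIGN, ced=250.0)
        data = simulate_data(truth, 3)
        with pytest.raises(ValueError, match="2 subgroups"):
            lr_subgroup_dependence(data, "b", model_id="m4")

    def test_hundredfold_potency_difference_detected(self):
        datasets = []
        for label, ced_true in (("lo", 50.0), ("hi", 5000.0)):
            truth = synthetic.saturating_truth(DESIGN, ced=ced_true)
            d = simulate_data(truth, 7 if label == "lo" else 8)
            datasets.append(
                FitData(d.doses, d.responses, np.array([label] * len(d.doses)))
            )
        result = lr_subgroup_dependence(datasets, "b", model_id="m4")
        assert result.keep_specific
        assert result.statistic > 3.841
        assert result.df == 1

    def test_parameter_name_validated(self):
        with pytest.raises(ValueError):
            lr_subgroup_dependence([], "c")


class TestProfileCI:
    def test_interval_contains_mle_and_shrinks_with_noise(self):
        ceds, widths = [], []
        for sigma in (0.15, 0.02):
            truth = synthetic.saturating_truth(DESIGN, ced=400.0, sigma=sigma)
            data = simulate_data(truth, 51)
            res = fit_single(data, "m4")
            est = res.ced()
            ci = res.profile_ci()
            assert ci.cedl <= est.ced <= ci.cedu
            ceds.append(est.ced)
            widths.append(math.log(ci.cedu) - math.log(ci.cedl))
        assert widths[1] < widths[0]

    def test_more_replicates_narrow_the_interval(self):
        widths = []
        for n_rep in (3, 12):
            truth = synthetic.TruthSpec(
                design=DESIGN,
                params=synthetic.saturating_truth(DESIGN, ced=400.0).params,
                n_treated=n_rep,
            )
            data = simulate_data(truth, 61)
            res = fit_single(data, "m4")
            ci = res.profile_ci()
            widths.append(math.log(ci.cedu / ci.cedl))
        assert widths[1] < widths[0]

    def test_flat_model_has_no_ced_to_profile(self, rng):
        data = FitData(
            np.tile([0.0, 50.0, 500.0, 5000.0], 3),
            rng.lognormal(math.log(50.0), 0.1, 12),
        )
        res = fit_single(data, "m1")
        with pytest.raises(ValueError):
            res.profile_ci()


class TestDiagnostics:
    def test_perfect_fit_residuals_zero(self):
        params = ExponentialParams("m2", a=100.0, b=math.log(2) / 5000.0)
        doses = np.tile([0.0, 50.0, 500.0, 1500.0, 5000.0], 3)
        data = FitData(doses, family.mean_response(params, doses))
        res = fit_single(data, "m2")
        assert np.allclose(res.residuals(), 0.0, atol=1e-6)

    def test_residual_sd_matches_generator_sigma(self):
        truth = synthetic.TruthSpec(
            design=DESIGN,
            params=synthetic.saturating_truth(DESIGN, ced=300.0).params,
            sigma=0.1,
            n_treated=30,
            n_control=60,
        )
        data = simulate_data(truth, 71)
        res = fit_single(data, "m5")
        assert float(np.std(res.residuals())) == pytest.approx(0.1, rel=0.25)

    def test_tables_have_one_row_per_plate(self):
        truth = synthetic.saturating_truth(DESIGN, ced=300.0)
        data = simulate_data(truth, 81)
        res = fit_single(data, "m4")
        qq, by_dose = res.residual_diagnostics()
        assert len(qq) == len(by_dose) == len(data.doses)
        assert (qq["residual"].to_numpy() == np.sort(res.residuals())).all()


class TestGridOracle:
    def test_optimizer_matches_exhaustive_grid_on_small_instance(self):
        """Coarse grid over (a, b) with analytically profiled variance."""
        truth = synthetic.TruthSpec(
            design=DESIGN,
            params=ExponentialParams("m2", a=100.0, b=math.log(4) / 5000.0),
            doses=(50.0, 500.0, 5000.0, 50.5, 500.5),  # small instance
            sigma=0.1,
        )
        data = simulate_data(truth, 91)
        res = fit_single(data, "m2")
        ll_grid = grid_loglik_m2(data)
        assert res.loglik >= ll_grid - 1e-6
        assert res.loglik == pytest.approx(ll_grid, abs=0.05)


def grid_loglik_m2(data, n_a=120, n_b=400):
    """Independent exhaustive-search oracle for the m2 lognormal fit."""
    logy = np.log(data.responses)
    best = -np.inf
    n = len(logy)
    for lna in np.linspace(logy.min() - 0.5, logy.max() + 0.5, n_a):
        for b in np.geomspace(1e-7, 1e-2, n_b):
            r = logy - (lna + b * data.doses)
            var = max(float(np.mean(r**2)), 1e-12)
            ll = -0.5 * n * (math.log(2 * math.pi * var) + 1.0)
            if ll > best:
                best = ll
    return best


class TestSummary:
    def test_summary_mentions_model_and_subgroups(self):
        truth = synthetic.saturating_truth(DESIGN, ced=300.0)
        data = simulate_data(truth, 95)
        res = fit_single(data, "m4")
        text = res.summary()
        assert "m4" in text and "log-likelihood" in text and "ced" in text
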
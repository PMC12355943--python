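"""Calibration machinery: chain filtering, posterior summaries, ML mode,
and an independent ensemble-sampler cross-check of the posterior."""

import numpy as np
import pytest

from bufferguts import (
    CalibrationResult,
    LogNormalPrior,
    LogUniformPrior,
    ModelSpec,
    ParamSet,
    SamplerSettings,
    calibrate,
    calibrate_ml,
    filter_chains,
)
from bufferguts.likelihood import LikelihoodEvaluator
from bufferguts.sampling import prior_from_config
from bufferguts.synth import DesignTemplate, default_true_params, generate


def _result(means, sds, n_params=2, n_draws=50, seed=0):
    """Synthesize a CalibrationResult with prescribed chain statistics."""
    rng = np.random.default_rng(seed)
    n_chains = len(means)
    draws = np.empty((n_chains, n_draws, n_params))
    lls = np.empty((n_chains, n_draws))
    for c, (m, sd) in enumerate(zip(means, sds)):
        draws[c] = np.exp(rng.normal(0.0, max(sd, 0.0), (n_draws, n_params)))
        if sd == 0.0:
            draws[c] = 1.0
        lls[c] = m  # mean log-likelihood exactly m
    return CalibrationResult(
        param_names=[f"p{i}" for i in range(n_params)],
        draws=draws,
        chain_logliks=lls,
        kept_chains=np.ones(n_chains, dtype=bool),
    )


class TestChainFilter:
    def test_identical_healthy_chains_all_kept(self):
        res = filter_chains(_result([-100.0] * 4, [0.3] * 4))
        assert res.kept_chains.all()

    def test_stuck_chain_dropped(self):
        res = filter_chains(_result([-100.0, -100.0, -100.0], [0.3, 0.0, 0.3]))
        assert list(res.kept_chains) == [True, False, True]

    def test_hundred_percent_worse_rule(self):
        # best mean logL -100: chains at -150 are within 100% worse (>=
        # -200) and stay; a chain at -250 is beyond and is dropped
        res = filter_chains(_result([-100.0, -150.0, -150.0, -250.0], [0.3] * 4))
        assert list(res.kept_chains) == [True, True, True, False]

    def test_best_chain_always_retained(self):
        res = filter_chains(_result([-50.0, -60.0], [0.0, 0.0]))
        assert res.kept_chains.sum() == 1
        assert res.kept_chains[0]

    def test_quantiles_use_only_kept_chains(self):
        res = _result([-100.0, -300.0], [0.4, 0.4], seed=3)
        res.draws[1] = 1000.0  # junk chain values would distort quantiles
        filtered = filter_chains(res)
        assert not filtered.kept_chains[1]
        q = filtered.quantiles()
        assert (q["q97.5"] < 100).all()
        assert (q["q2.5"] <= q["q50"]).all() and (q["q50"] <= q["q97.5"]).all()

    def test_quantiles_permutation_invariant(self):
        res = _result([-100.0, -101.0, -99.0], [0.3, 0.5, 0.4], seed=5)
        perm = [2, 0, 1]
        res_perm = CalibrationResult(
            param_names=res.param_names,
            draws=res.draws[perm],
            chain_logliks=res.chain_logliks[perm],
            kept_chains=res.kept_chains[perm],
        )
        assert np.allclose(
            filter_chains(res).quantiles().to_numpy(),
            filter_chains(res_perm).quantiles().to_numpy(),
        )


class TestPriors:
    def test_config_parsing(self):
        p = prior_from_config({"dist": "lognormal", "median": 2.0, "sigma": 0.5})
        assert isinstance(p, LogNormalPrior) and p.median == 2.0
        q = prior_from_config({"dist": "loguniform", "low": 0.1, "high": 10.0})
        assert isinstance(q, LogUniformPrior)
        with pytest.raises(ValueError, match="unknown prior"):
            prior_from_config({"dist": "cauchy"})

    def test_loguniform_support(self):
        p = LogUniformPrior(0.1, 10.0)
        assert p.logpdf_logx(np.log(1.0)) > -np.inf
        assert p.logpdf_logx(np.log(100.0)) == -np.inf


@pytest.fixture(scope="module")
def toy_problem():
    """Small identifiable one-route CA-SD problem with known truth."""
    spec = ModelSpec("CA", "SD", 1)
    truth = default_true_params(spec)
    template = DesignTemplate(
        design="acute_contact",
        levels=(0.0, 0.05, 0.1, 0.2, 0.4, 0.8),
        n_batches=4,
    )
    dataset = generate(spec, truth, [template], seed=5)
    priors = {
        "kd": LogNormalPrior(1.0, 1.5),
        "z": LogNormalPrior(0.01, 1.5),
        "kk": LogNormalPrior(50.0, 1.5),
    }
    return spec, truth, dataset, priors


class TestCalibrate:
    def test_missing_prior_rejected(self, toy_problem):
        spec, _, dataset, priors = toy_problem
        with pytest.raises(ValueError, match="missing priors"):
            calibrate(spec, dataset, {"kd": priors["kd"]}, fixed_hb=0.0)

    def test_ml_mode_matches_mcmc_posterior_mode(self, toy_problem):
        spec, truth, dataset, priors = toy_problem
        ml = calibrate_ml(spec, dataset, priors, n_starts=6, seed=1, fixed_hb=0.0)
        mcmc = calibrate(
            spec, dataset, priors,
            SamplerSettings(n_chains=4, warmup=400, draws=400), seed=1, fixed_hb=0.0,
        )
        q = mcmc.quantiles()
        # the MLE lies inside the central posterior mass for every parameter
        for name, value in zip(ml.param_names, ml.theta):
            assert q.loc[name, "q2.5"] * 0.8 <= value <= q.loc[name, "q97.5"] * 1.2
        ev = LikelihoodEvaluator(spec, dataset)
        assert ml.loglik >= ev.loglik(truth) - 1e-6  # MLE beats the truth in-sample

    def test_flat_data_pushes_to_no_effect(self):
        # no deaths anywhere: the posterior predictive survival stays ~1
        spec = ModelSpec("CA", "SD", 1)
        template = DesignTemplate(
            design="acute_contact", levels=(0.0, 0.1, 0.2), n_batches=2
        )
        no_effect = ParamSet(kd=(0.5,), z=50.0, kk=0.001, hb=0.0)
        dataset = generate(spec, no_effect, [template], seed=2)
        assert all(tr.n_alive[-1] == tr.n_start for tr in dataset.treatments)
        priors = {
            "kd": LogNormalPrior(1.0, 1.0),
            "z": LogNormalPrior(0.1, 2.0),
            "kk": LogNormalPrior(1.0, 2.0),
        }
        res = calibrate(
            spec, dataset, priors,
            SamplerSettings(n_chains=2, warmup=300, draws=300), seed=3, fixed_hb=0.0,
        )
        med = res.quantiles()["q50"]
        params = ParamSet(kd=(med["kd"],), z=med["z"], kk=med["kk"], hb=0.0)
        ev = LikelihoodEvaluator(spec, dataset)
        for S in ev.predicted_survival(params):
            assert S.min() > 0.9

    def test_posterior_matches_ensemble_sampler(self, toy_problem):
        # independent cross-check: emcee's affine-invariant ensemble run on
        # the identical log-posterior should give the same central quantiles
        emcee = pytest.importorskip("emcee")
        spec, _, dataset, priors = toy_problem
        from bufferguts.core import free_param_names
        from bufferguts.sampling import _make_logpost

        names = free_param_names(spec, include_hb=False)
        ev = LikelihoodEvaluator(spec, dataset)
        logpost = _make_logpost(ev, priors, names, fixed_hb=0.0)

        ours = calibrate(
            spec, dataset, priors,
            SamplerSettings(n_chains=4, warmup=500, draws=500), seed=7, fixed_hb=0.0,
        )
        rng = np.random.default_rng(7)
        nwalkers, ndim = 12, len(names)
        p0 = np.array(
            [[priors[n].sample_log(rng) for n in names] for _ in range(nwalkers)]
        )
        sampler = emcee.EnsembleSampler(nwalkers, ndim, lambda x: logpost(x)[0])
        np.random.seed(7)  # emcee 3.x draws from the global legacy RNG
        sampler.run_mcmc(p0, 1500, progress=False)
        chain = np.exp(sampler.get_chain(discard=700, flat=True))
        q_ours = ours.quantiles()
        for i, name in enumerate(names):
            med_ref = np.median(chain[:, i])
            spread = np.quantile(chain[:, i], 0.975) - np.quantile(chain[:, i], 0.025)
            assert abs(q_ours.loc[name, "q50"] - med_ref) < 0.35 * spread + 0.05 * med_ref

    def test_seeded_runs_are_reproducible(self, toy_problem):
        spec, _, dataset, priors = toy_problem
        s = SamplerSettings(n_chains=2, warmup=100, draws=100)
        a = calibrate(spec, dataset, priors, s, seed=9, fixed_hb=0.0)
        b = calibrate(spec, dataset, priors, s, seed=9, fixed_hb=0.0)
        assert np.array_equal(a.draws, b.draws)
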
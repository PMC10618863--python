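"""Design construction, the joint density, and sampler contracts."""

import math

import numpy as np
import pytest
from scipy import stats

from stresstherm import meta_model as mm
from stresstherm import synthetic_data as synth
from stresstherm.io_schema import Dataset, ValidationFailure
from tests.conftest import make_record


def small_sim(seed=2, **overrides):
    kw = dict(n_obs=40, n_studies=12, n_species=6)
    kw.update(overrides)
    return synth.simulate_dataset(synth.reference_scenario(seed=seed, **kw))


@pytest.fixture(scope="module")
def small_spec():
    res = small_sim()
    spec = mm.build_design(res.dataset, res.rel_map, phylo=res.phylo)
    return res, spec


class TestBuildDesign:
    def test_centring(self):
        recs = [
            make_record(group_id="g1", air_temp=0.0),
            make_record(group_id="g2", air_temp=40.0),
        ]
        ds = Dataset(recs)
        spec = mm.build_design(ds, {"mus_musculus": 0})
        assert np.allclose(spec.air_obs, [-20.0, 20.0])
        assert spec.centring["air_mean"] == 20.0

    def test_constant_column_flagged(self):
        recs = [
            make_record(group_id=f"g{i}", air_temp=22.0) for i in range(3)
        ]
        spec = mm.build_design(Dataset(recs), {"mus_musculus": 0})
        assert any("air_temp" in w for w in spec.warnings)

    def test_interaction_columns_are_products(self, small_spec):
        _, spec = small_spec
        X = spec.design_matrix()
        assert np.allclose(X[:, 4], X[:, 1] * X[:, 2])
        assert np.allclose(X[:, 5], X[:, 1] * X[:, 3])
        assert np.allclose(X[:, 7], X[:, 6] ** 2)

    def test_missing_rel_rmr_category_errors(self):
        ds = Dataset([make_record()])
        with pytest.raises(ValidationFailure, match="relative-RMR"):
            mm.build_design(ds, {})

    def test_latency_standardized(self, small_spec):
        _, spec = small_spec
        assert abs(spec.latency.mean()) < 1e-12
        assert spec.latency.std() == pytest.approx(1.0, abs=1e-12)


def default_params(spec, rng=None):
    rng = rng or np.random.default_rng(0)
    return {
        "beta": np.zeros(len(mm.COEF_NAMES)),
        "t_air": spec.air_obs.copy(),
        "t_lnm": spec.lnm_obs.copy(),
        "u_species": np.zeros(spec.n_species),
        "u_phylo": np.zeros(spec.n_species),
        "u_study": np.zeros(spec.n_studies),
        "sd_species": 0.02,
        "sd_phylo": 0.02,
        "sd_study": 0.02,
        "sigma": 0.02,
    }


class TestLogDensity:
    def test_duplicating_a_record_doubles_its_likelihood_term(self, small_spec):
        """Appending an exact copy of row 0 to the spec arrays shifts the
        joint density by exactly that row's data terms (likelihood +
        measurement submodel + latent hyperprior)."""
        import copy

        res, spec = small_spec
        params = default_params(spec)
        base = mm.log_density(spec, params)

        spec2 = copy.deepcopy(spec)
        for fld in ("y", "se", "air_obs", "air_sd", "lnm_obs", "lnm_sd",
                    "rel_rmr", "latency", "technique", "age_class",
                    "species_idx", "study_idx"):
            arr = getattr(spec2, fld)
            setattr(spec2, fld, np.append(arr, arr[0]))
        params2 = dict(params)
        params2["t_air"] = np.append(params["t_air"], params["t_air"][0])
        params2["t_lnm"] = np.append(params["t_lnm"], params["t_lnm"][0])
        got = mm.log_density(spec2, params2)

        mu0 = float(
            spec.design_matrix(params["t_air"], params["t_lnm"])[0]
            @ params["beta"]
            + params["u_species"][spec.species_idx[0]]
            + params["u_phylo"][spec.species_idx[0]]
            + params["u_study"][spec.study_idx[0]]
        )
        row_terms = float(
            stats.norm.logpdf(
                spec.y[0], mu0,
                math.sqrt(spec.se[0] ** 2 + params["sigma"] ** 2),
            )
            + stats.norm.logpdf(spec.air_obs[0], params["t_air"][0],
                                spec.air_sd[0])
            + stats.norm.logpdf(spec.lnm_obs[0], params["t_lnm"][0],
                                spec.lnm_sd[0])
            + stats.norm.logpdf(params["t_air"][0], 0.0, spec.air_hyper_sd)
            + stats.norm.logpdf(params["t_lnm"][0], 0.0, spec.lnm_hyper_sd)
        )
        assert got - base == pytest.approx(row_terms, rel=1e-9, abs=1e-9)

    def test_zero_sd_is_rejected(self, small_spec):
        _, spec = small_spec
        params = default_params(spec)
        params["sigma"] = 0.0
        assert mm.log_density(spec, params) == -math.inf

    def test_prior_decomposition_with_empty_data(self):
        """With no observations the joint density reduces to the sum of
        the prior log densities."""
        res = small_sim()
        spec = mm.build_design(res.dataset, res.rel_map, phylo=res.phylo)
        # strip the data: zero-length observation vectors
        spec.y = spec.y[:0]
        spec.se = spec.se[:0]
        spec.air_obs = spec.air_obs[:0]
        spec.air_sd = spec.air_sd[:0]
        spec.lnm_obs = spec.lnm_obs[:0]
        spec.lnm_sd = spec.lnm_sd[:0]
        spec.rel_rmr = spec.rel_rmr[:0]
        spec.latency = spec.latency[:0]
        spec.technique = spec.technique[:0]
        spec.age_class = spec.age_class[:0]
        spec.species_idx = spec.species_idx[:0]
        spec.study_idx = spec.study_idx[:0]
        params = default_params(spec)
        params["t_air"] = np.zeros(0)
        params["t_lnm"] = np.zeros(0)
        got = mm.log_density(spec, params)

        expected = 0.0
        for name, b in zip(mm.COEF_NAMES, params["beta"]):
            p = spec.priors[name]
            if p[0] == "normal":
                expected += stats.norm.logpdf(b, 0, p[1])
            else:
                expected += stats.skewnorm.logpdf(b, p[2], 0, p[1])
        for name, v in zip(
            mm.GROUP_NAMES,
            (params["sd_species"], params["sd_phylo"], params["sd_study"],
             params["sigma"]),
        ):
            a, rate = spec.priors[name][1], spec.priors[name][2]
            expected += stats.gamma.logpdf(v, a, scale=1 / rate)
        expected += float(
            np.sum(stats.norm.logpdf(params["u_species"], 0,
                                     params["sd_species"]))
            + np.sum(stats.norm.logpdf(params["u_study"], 0,
                                       params["sd_study"]))
            + stats.multivariate_normal.logpdf(
                params["u_phylo"],
                mean=np.zeros(spec.n_species),
                cov=params["sd_phylo"] ** 2
                * (spec.phylo_corr + 1e-10 * np.eye(spec.n_species)),
                allow_singular=True,
            )
        )
        assert got == pytest.approx(expected, rel=1e-9)

    def test_gibbs_conditional_consistent_with_joint(self, small_spec):
        """The sampler's conjugate beta conditional must match the joint
        density: the log-density difference between two beta values
        equals the conditional's own log-ratio (normal-prior coordinates)."""
        res, spec = small_spec
        rng = np.random.default_rng(3)
        params = default_params(spec)
        params["beta"] = rng.normal(0, 0.01, len(mm.COEF_NAMES))
        b2 = params["beta"].copy()
        b2[1] += 0.005  # air_temp: Gaussian prior coordinate
        p2 = dict(params, beta=b2)
        delta_joint = mm.log_density(spec, p2) - mm.log_density(spec, params)

        X = spec.design_matrix(params["t_air"], params["t_lnm"])
        mu_resid = (
            spec.y
            - params["u_species"][spec.species_idx]
            - params["u_phylo"][spec.species_idx]
            - params["u_study"][spec.study_idx]
        )
        var = spec.se**2 + params["sigma"] ** 2

        def cond_logpost(beta):
            ll = np.sum(stats.norm.logpdf(mu_resid, X @ beta, np.sqrt(var)))
            lp = stats.norm.logpdf(beta[1], 0, spec.priors["air_temp"][1])
            return float(ll + lp)

        delta_cond = cond_logpost(b2) - cond_logpost(params["beta"])
        assert delta_joint == pytest.approx(delta_cond, rel=1e-9, abs=1e-9)


class TestSamplePosterior:
    def test_same_seed_identical_summaries(self):
        res = small_sim()
        spec = mm.build_design(
            res.dataset, res.rel_map, phylo=res.phylo,
            sampler=mm.SamplerConfig(2, 100, 200, 2),
        )
        a = mm.sample_posterior(spec, seed=5)
        b = mm.sample_posterior(spec, seed=5)
        for name in mm.COEF_NAMES:
            assert a.coefficients[name].mode == b.coefficients[name].mode
            assert a.coefficients[name].hpdi95 == b.coefficients[name].hpdi95
        c = mm.sample_posterior(spec, seed=6)
        assert any(
            a.coefficients[n].mode != c.coefficients[n].mode
            for n in mm.COEF_NAMES
        )

    def test_conjugate_oracle_fixed_covariates(self):
        """With measurement error off and the variance components pinned
        to negligible values, the model is linear-Gaussian and the
        posterior must match the closed-form conjugate update."""
        scn = synth.null_scenario(
            seed=9, n_obs=60, n_studies=20, n_species=6,
            sd_species=1e-7, sd_phylo=1e-7, sd_study=1e-7, sigma=1e-7,
            air_meas_sd=0.0, mass_cv=1e-12, se_ln_median=0.01, se_ln_sd=0.0,
            beta=tuple([0.02] + [0.0] * 9),
        )
        res = synth.simulate_dataset(scn)
        spec = mm.build_design(
            res.dataset, res.rel_map, phylo=res.phylo,
            sampler=mm.SamplerConfig(2, 400, 1200, 2),
        )
        s = mm.sample_posterior(
            spec, seed=1,
            fixed_vc={"sd_species": 1e-7, "sd_phylo": 1e-7,
                      "sd_study": 1e-7, "sigma": 1e-7},
        )
        # oracle: weighted normal-normal update for the intercept given
        # the other fixed effects are ~0 and group effects negligible
        X = spec.design_matrix()
        w = 1.0 / spec.se**2
        # project out other columns via weighted least squares posterior
        prior_prec = np.array(
            [1.0 / mm.DEFAULT_PRIORS[n][1] ** 2 for n in mm.COEF_NAMES]
        )
        G = (X.T * w) @ X + np.diag(prior_prec)
        mean = np.linalg.solve(G, (X.T * w) @ spec.y)
        sd = math.sqrt(np.linalg.inv(G)[0, 0])
        c = s.coefficients["intercept"]
        post_mean = float(np.mean(s.beta_draws[:, 0]))
        post_sd = float(np.std(s.beta_draws[:, 0]))
        assert post_mean == pytest.approx(mean[0], abs=4.0 * sd / 30)
        assert post_sd == pytest.approx(sd, rel=0.15)
        assert c.hpdi95[0] < mean[0] < c.hpdi95[1]

    def test_hpdi_nesting(self):
        res = small_sim(seed=12)
        spec = mm.build_design(
            res.dataset, res.rel_map, phylo=res.phylo,
            sampler=mm.SamplerConfig(2, 150, 300, 2),
        )
        s = mm.sample_posterior(spec, seed=2)
        for c in {**s.coefficients, **s.group_sds}.values():
            assert c.hpdi95[0] <= c.hpdi80[0] <= c.hpdi80[1] <= c.hpdi95[1]

    def test_latent_consistency_as_measurement_error_vanishes(self):
        """With measurement sds ~1e-6 the posterior matches the
        fixed-covariate model (KS distance of pooled beta draws < 0.05)."""
        res = small_sim(seed=21, air_meas_sd=1e-6, mass_cv=1e-6)
        cfg = mm.SamplerConfig(2, 300, 1600, 1)
        spec_latent = mm.build_design(
            res.dataset, res.rel_map, phylo=res.phylo, sampler=cfg
        )
        spec_fixed = mm.build_design(
            res.dataset, res.rel_map, phylo=res.phylo, sampler=cfg
        )
        spec_fixed.air_sd = np.zeros(spec_fixed.n)  # pin the latents
        spec_fixed.lnm_sd = np.zeros(spec_fixed.n)
        a = mm.sample_posterior(spec_latent, seed=4)
        b = mm.sample_posterior(spec_fixed, seed=8)
        for j in (1, 2):  # air_temp and ln_mass slopes
            ks = stats.ks_2samp(a.beta_draws[:, j], b.beta_draws[:, j])
            assert ks.statistic < 0.05


@pytest.fixture(scope="module")
def fitted():
    # a strong, clearly recoverable interaction so sign checks are about
    # the machinery, not statistical power at small n
    beta = (1.67e-2, 2.0e-3, 4.25e-3, -3.98e-3, -6.0e-3, 1.38e-3,
            -3.61e-2, -5.04e-2, 4.80e-4, -6.97e-3)
    res = small_sim(seed=31, n_obs=80, n_studies=25, n_species=10, beta=beta)
    spec = mm.build_design(
        res.dataset, res.rel_map, phylo=res.phylo,
        sampler=mm.SamplerConfig(2, 200, 600, 2),
    )
    return res, spec, mm.sample_posterior(spec, seed=3)


class TestMarginalEffects:

    def test_prediction_at_means_is_intercept(self, fitted):
        _, spec, s = fitted
        df = mm.marginal_effects(
            s, spec,
            air_temp=[s.centring["air_mean"]],
            ln_mass=[s.centring["lnm_mean"]],
        )
        c = s.coefficients["intercept"]
        assert df.loc[0, "lrr_mean"] == pytest.approx(
            float(np.mean(s.beta_draws[:, 0])), abs=1e-12
        )
        assert df.loc[0, "hpdi95_lo"] == pytest.approx(c.hpdi95[0], abs=1e-12)

    def test_interaction_flattens_slope_for_large_masses(self, fitted):
        """The generating interaction is negative, so the air-temperature
        slope of predicted lRR must decrease with mass."""
        _, spec, s = fitted
        am, lm = s.centring["air_mean"], s.centring["lnm_mean"]
        df = mm.marginal_effects(
            s, spec, air_temp=[am - 10, am + 10], ln_mass=[lm - 2, lm + 2]
        )
        piv = df.pivot(index="air_temp", columns="ln_mass", values="lrr_mean")
        slope_small = piv[lm - 2].diff().iloc[-1]
        slope_large = piv[lm + 2].diff().iloc[-1]
        assert slope_large < slope_small

    def test_delta_t_conversion_of_modes(self, fitted):
        _, spec, s = fitted
        df = mm.marginal_effects(
            s, spec, air_temp=[s.centring["air_mean"]], rel_rmr=[0]
        )
        assert df.loc[0, "delta_t"] == pytest.approx(
            38.0 * (math.exp(df.loc[0, "lrr_mode"]) - 1.0)
        )

    def test_extrapolation_flagged(self, fitted):
        _, spec, s = fitted
        df = mm.marginal_effects(s, spec, air_temp=[999.0], rel_rmr=[0])
        assert bool(df.loc[0, "extrapolated"])

    def test_query_must_pick_one_axis(self, fitted):
        _, spec, s = fitted
        with pytest.raises(ValidationFailure, match="exactly one"):
            mm.marginal_effects(s, spec, air_temp=[0.0])


def test_prior_predictive_intercept_window(rng):
    """At average covariates the fixed-effect prior predictive stays
    inside the stated lRR plausibility window [-1, 0.5]."""
    draws = rng.normal(0.0, mm.DEFAULT_PRIORS["intercept"][1], size=20_000)
    lo, hi = np.quantile(draws, [0.025, 0.975])
    assert lo > -1.0
    assert hi < 0.5
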
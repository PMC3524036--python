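"""Bayesian MTC models: sampler correctness, recovery, nesting, node-split."""

import math
import warnings

import numpy as np
import pytest

from nmasim import (
    MCMCSettings,
    MTCData,
    PriorSpec,
    ScenarioConfig,
    Trial,
    fit_consistency_bmtc,
    fit_ibma,
    fit_random_inconsistency_bmtc,
    fixed_effect_pool,
    node_split_inconsistency,
    simulate_network,
    table_logor,
)
from nmasim.bayes import MTCFit
from nmasim.oracles import oracle_exact_posterior_grid


def _quiet_fit(fitter, data, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fitter(data, check_ess=False, **kw)


@pytest.fixture(scope="module")
def high_info_network():
    """3x20 trials of 10,000 patients/arm, tau2 = 0, OR12=0.8, OR13=0.6."""
    sc = ScenarioConfig(
        n_per_arm=10_000, true_logor_13=math.log(0.6), tau2=0.0, seed=11
    )
    return simulate_network(sc, 0)


class TestMTCData:
    def test_from_network_maps_base_to_lower_treatment(self, high_info_network):
        data = MTCData.from_network(high_info_network)
        assert data.n_studies == 60
        assert (data.base_treat < data.other_treat).all()
        assert data.contrasts_present() == {(1, 2), (1, 3), (2, 3)}
        assert data.is_connected()

    def test_ibma_requires_closed_loop(self):
        trials = [Trial("a", (1, 2), 20, 100, 15, 100)]
        data = MTCData.from_trials(trials)
        with pytest.raises(ValueError, match="three contrasts"):
            _quiet_fit(fit_ibma, data, settings=MCMCSettings(100, 100, 1, 1, 0))

    def test_reference_treatment_required(self):
        trials = [Trial("a", (2, 3), 20, 100, 15, 100)]
        data = MTCData.from_trials(trials)
        with pytest.raises(ValueError, match="reference treatment"):
            _quiet_fit(
                fit_consistency_bmtc, data, settings=MCMCSettings(100, 100, 1, 1, 0)
            )


class TestSamplerCorrectness:
    def test_posterior_matches_grid_integration(self):
        """Fixed-effect posterior of a single trial's log OR agrees with
        numerical grid integration of the binomial-logit posterior."""
        grid = oracle_exact_posterior_grid(30, 100, 20, 100)
        data = MTCData.from_trials([Trial("s", (1, 2), 30, 100, 20, 100)])
        fit = _quiet_fit(
            fit_consistency_bmtc,
            data,
            settings=MCMCSettings(2000, 40000, 5, 1, 3),
            model="fixed",
        )
        s = fit.summary("d_AB")
        assert s.mean == pytest.approx(grid["mean"], abs=0.02)
        assert s.sd == pytest.approx(grid["sd"], rel=0.02)

    def test_large_n_matches_normal_approximation(self):
        """At large arm sizes the posterior approaches Normal(sample log OR,
        Woolf variance) within 5%."""
        trial = Trial("s", (1, 2), 2000, 10000, 1600, 10000)
        woolf = table_logor(trial)
        data = MTCData.from_trials([trial])
        fit = _quiet_fit(
            fit_consistency_bmtc,
            data,
            settings=MCMCSettings(2000, 20000, 2, 1, 5),
            model="fixed",
        )
        s = fit.summary("d_AB")
        assert s.mean == pytest.approx(woolf.logor, abs=0.05 * abs(woolf.logor))
        assert s.sd == pytest.approx(math.sqrt(woolf.variance), rel=0.05)

    def test_determinism_with_fixed_seed(self):
        data = MTCData.from_trials(
            [
                Trial("a", (1, 2), 20, 100, 15, 100),
                Trial("b", (1, 3), 22, 100, 12, 100),
                Trial("c", (2, 3), 18, 100, 13, 100),
            ]
        )
        st = MCMCSettings(200, 600, 1, 2, 42)
        f1 = _quiet_fit(fit_consistency_bmtc, data, settings=st)
        f2 = _quiet_fit(fit_consistency_bmtc, data, settings=st)
        for q in f1.summaries:
            assert f1.summary(q).mean == f2.summary(q).mean
            assert np.array_equal(f1.draws[q], f2.draws[q])


class TestParameterRecovery:
    def test_consistency_mtc_recovers_effects(self, high_info_network):
        data = MTCData.from_network(high_info_network)
        fit = _quiet_fit(
            fit_consistency_bmtc,
            data,
            settings=MCMCSettings(500, 2000, 1, 1, 2),
            model="fixed",
        )
        assert fit.summary("d_AB").mean == pytest.approx(math.log(0.8), abs=0.05)
        assert fit.summary("d_AC").mean == pytest.approx(math.log(0.6), abs=0.05)
        assert fit.summary("d_BC").mean == pytest.approx(math.log(0.75), abs=0.05)

    def test_ibma_matches_fixed_effect_pooling_at_large_n(self, high_info_network):
        data = MTCData.from_network(high_info_network)
        fit = _quiet_fit(
            fit_ibma,
            data,
            settings=MCMCSettings(500, 3000, 1, 1, 4),
            model="fixed",
        )
        for contrast, q in (((1, 2), "d_AB"), ((1, 3), "d_AC"), ((2, 3), "d_BC")):
            pooled = fixed_effect_pool(
                [table_logor(t) for t in high_info_network.trials_for(contrast)]
            )
            assert fit.summary(q).mean == pytest.approx(pooled.logor, abs=0.02)


@pytest.fixture(scope="module")
def biased_direct_network():
    """Direct 2-3 trials biased by ROR 0.8; 3x20 of 2,000/arm."""
    sc = ScenarioConfig(
        n_per_arm=2000, true_logor_13=math.log(0.6), tau2=0.0, ror_23=0.8, seed=13
    )
    return simulate_network(sc, 0)


class TestRandomInconsistencyModel:
    def test_omega_recovers_injected_inconsistency(self, biased_direct_network):
        data = MTCData.from_network(biased_direct_network)
        fit = _quiet_fit(
            fit_random_inconsistency_bmtc,
            data,
            settings=MCMCSettings(500, 3000, 1, 1, 6),
            model="fixed",
        )
        om = fit.summary("omega_BC")
        assert om.mean == pytest.approx(math.log(0.8), abs=0.08)

    def test_omega_interval_wider_than_z_test(self):
        """At the moderate-information scenario the posterior interval of
        omega is wider than the frequentist Z-test interval."""
        from nmasim import bucher_indirect, from_meta, inconsistency_z_test, pool

        sc = ScenarioConfig(
            tau2=0.10, true_logor_13=math.log(0.6), ror_23=0.8, seed=29
        )
        net = simulate_network(sc, 0)
        data = MTCData.from_network(net)
        fit = _quiet_fit(
            fit_random_inconsistency_bmtc,
            data,
            settings=MCMCSettings(500, 3000, 1, 1, 8),
            model="random",
        )
        om = fit.summary("omega_BC")
        bayes_width = om.ci_high - om.ci_low
        pooled = {
            c: from_meta(pool([table_logor(t) for t in net.trials_for(c)], "random"))
            for c in ((1, 2), (1, 3), (2, 3))
        }
        z = inconsistency_z_test(
            pooled[(2, 3)], bucher_indirect(pooled[(1, 2)], pooled[(1, 3)])
        )
        freq_width = 2 * 1.96 * math.sqrt(z.variance)
        assert bayes_width > freq_width

    def test_nests_to_consistency_model_as_sigma_prior_shrinks(self):
        sc = ScenarioConfig(tau2=0.0, true_logor_13=math.log(0.6), seed=31)
        net = simulate_network(sc, 0)
        data = MTCData.from_network(net)
        st = MCMCSettings(500, 6000, 1, 1, 9)
        tight = PriorSpec(sigma_omega_prior_upper=1e-3)
        rib = _quiet_fit(
            fit_random_inconsistency_bmtc, data, priors=tight, settings=st,
            model="fixed",
        )
        cons = _quiet_fit(fit_consistency_bmtc, data, settings=st, model="fixed")
        assert rib.summary("d_BC").mean == pytest.approx(
            cons.summary("d_BC").mean, abs=0.03
        )
        assert abs(rib.summary("omega_BC").mean) < 2e-3


class TestNodeSplit:
    @staticmethod
    def _fit_with_draws(draws):
        return MTCFit(
            kind="ibma",
            model="fixed",
            summaries={},
            draws={k: np.asarray(v, dtype=float) for k, v in draws.items()},
            settings=MCMCSettings(1, 1, 1, 1, 0),
            priors=PriorSpec(),
        )

    def test_degenerate_posterior_gives_zero(self):
        z = np.zeros((1, 100))
        fit = self._fit_with_draws({"d_AB": z, "d_AC": z, "d_BC": z})
        assert node_split_inconsistency(fit).mean == 0.0

    def test_constant_shift_recovered_exactly(self):
        rng = np.random.default_rng(0)
        d_ab = rng.normal(-0.2, 0.1, (1, 500))
        d_ac = rng.normal(-0.5, 0.1, (1, 500))
        d_bc = (d_ac - d_ab) + 0.223
        fit = self._fit_with_draws({"d_AB": d_ab, "d_AC": d_ac, "d_BC": d_bc})
        assert node_split_inconsistency(fit).mean == pytest.approx(0.223, abs=1e-12)

    def test_missing_draws_rejected(self):
        fit = self._fit_with_draws({"d_AB": np.zeros((1, 10))})
        with pytest.raises(ValueError, match="draws"):
            node_split_inconsistency(fit)

    def test_requires_ibma_fit(self):
        fit = self._fit_with_draws(
            {"d_AB": np.zeros((1, 10)), "d_AC": np.zeros((1, 10)),
             "d_BC": np.zeros((1, 10))}
        )
        fit.kind = "consistency"
        with pytest.raises(ValueError, match="IBMA"):
            node_split_inconsistency(fit)


class TestSingleStudyDegeneracy:
    def test_vague_priors_dominate_singleton_random_effects(self):
        """With one trial per contrast, the random-effects posterior of the
        2-3 effect is prior-dominated and its 95% interval spans zero."""
        sc = ScenarioConfig(
            n_studies_12=1, n_studies_13=1, n_studies_23=1,
            true_logor_13=math.log(0.6), tau2=0.0, seed=37,
        )
        data = MTCData.from_network(simulate_network(sc, 0))
        fit = _quiet_fit(
            fit_consistency_bmtc,
            data,
            settings=MCMCSettings(500, 2000, 1, 1, 10),
            model="random",
        )
        s = fit.summary("d_BC")
        assert s.ci_low < 0.0 < s.ci_high
        assert not s.significant
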
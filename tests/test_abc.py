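import numpy as np
import pytest
from scipy.stats import kstest

from ssrdem.abc_demography import (
    DemographicScenario,
    _apply_params,
    abc_fit,
    default_scenario,
    posterior_r_report,
    simulate_scenario,
    summary_statistics,
)
from ssrdem.diversity import locus_summary
from ssrdem.differentiation import pairwise_fst
from ssrdem.io_formats import Partition


class TestScenario:
    def test_ratio_accessor(self):
        s = default_scenario(ratios={"C1": 0.1, "C2": 1.0, "C3": 1.0,
                                     "C4": 10.0, "C5": 1.0})
        r = s.ratios()
        assert r["C1"] == pytest.approx(0.1)
        assert r["C4"] == pytest.approx(10.0)

    def test_inconsistent_event_times_rejected(self):
        s = default_scenario()
        bad_splits = [(5000.0, ("C1", "C2"), "A12")] + s.splits[1:]
        bad_splits[-1] = (4000.0, ("A12", "A345", "BASAL"), "ROOT")
        with pytest.raises(ValueError, match="after"):
            DemographicScenario(
                populations=s.populations, sample_sizes=s.sample_sizes,
                splits=bad_splits, n_present=s.n_present, n_past=s.n_past,
                t_change=s.t_change, admixture=s.admixture,
                ancestral_sizes=s.ancestral_sizes,
            )

    def test_admixture_proportion_domain(self):
        s = default_scenario()
        with pytest.raises(ValueError, match="admixture"):
            DemographicScenario(
                populations=s.populations, sample_sizes=s.sample_sizes,
                splits=s.splits, n_present=s.n_present, n_past=s.n_past,
                t_change=s.t_change,
                admixture=[(500.0, "C5", "C1", 1.5)],
                ancestral_sizes=s.ancestral_sizes,
            )


class TestSimulateScenario:
    def test_panmictic_population_has_near_zero_fis(self):
        s = DemographicScenario(
            populations=("P",), sample_sizes={"P": 100}, splits=[],
            n_present={"P": 10_000.0}, n_past={"P": 10_000.0},
            t_change={"P": 500.0},
        )
        g, p = simulate_scenario(s, 25, seed=1)
        _, avg = locus_summary(g, rarefaction_g=None)
        assert abs(avg["F_IS"]) < 0.05

    def test_deep_split_gives_high_fst(self):
        s = DemographicScenario(
            populations=("X", "Y"), sample_sizes={"X": 50, "Y": 50},
            splits=[(60_000.0, ("X", "Y"), "ANC")],
            n_present={"X": 5_000.0, "Y": 5_000.0},
            n_past={"X": 5_000.0, "Y": 5_000.0},
            t_change={"X": 100.0, "Y": 100.0},
            ancestral_sizes={"ANC": 5_000.0},
            mu=1e-4,  # moderate diversity; homoplasy at high theta caps F_ST
        )
        g, p = simulate_scenario(s, 25, seed=2)
        _, _, theta = pairwise_fst(g, p)
        assert theta > 0.2

    def test_reproducible_under_seed(self):
        s = default_scenario(sample_size=8)
        g1, _ = simulate_scenario(s, 5, seed=9)
        g2, _ = simulate_scenario(s, 5, seed=9)
        assert g1 == g2


class TestSummaryStatistics:
    def test_vector_layout_for_five_populations(self):
        s = default_scenario(sample_size=8)
        g, p = simulate_scenario(s, 6, seed=3)
        v = summary_statistics(g, p)
        assert len(v) == 5 * 4 + 2 * 10  # 40 for 5 populations
        assert v.index[0] == "C1_mean_k"
        assert v.index[-1] == "C4_C5_das"

    def test_individual_order_invariance(self):
        s = default_scenario(sample_size=8)
        g, p = simulate_scenario(s, 6, seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(g.n_individuals)
        g2 = g.subset_individuals(perm)
        v1 = summary_statistics(g, p)
        v2 = summary_statistics(g2, p)
        assert np.allclose(v1.to_numpy(), v2.to_numpy())

    def test_identical_populations_show_no_differentiation(self):
        # two "populations" drawn by splitting one panmictic sample
        s = DemographicScenario(
            populations=("P",), sample_sizes={"P": 200}, splits=[],
            n_present={"P": 10_000.0}, n_past={"P": 10_000.0},
            t_change={"P": 500.0},
        )
        g, _ = simulate_scenario(s, 20, seed=5)
        half = g.n_individuals // 2
        p2 = Partition({ind: ("A" if i < half else "B")
                        for i, ind in enumerate(g.individuals)})
        v = summary_statistics(g, p2)
        assert abs(v["A_B_fst"]) < 0.01


@pytest.fixture(scope="module")
def small_fit():
    scen = default_scenario(sample_size=10)
    g, p = simulate_scenario(scen, 8, seed=42)
    obs = summary_statistics(g, p)
    return abc_fit(obs, scen, n_sims=150, n_loci=8, accept_rate=1.0,
                   adjust="none", seed=7)


class TestAbcFit:
    def test_accept_all_returns_prior(self, small_fit):
        res = small_fit
        assert res.n_accept == len(res.prior_draws)
        for name in res.param_names:
            a = np.sort(res.accepted[name].to_numpy())
            b = np.sort(res.prior_draws[name].to_numpy())
            assert np.array_equal(a, b)
        # prior draws of log10(r) are Uniform(-2, 2)
        u = (res.prior_draws["log10_r_C1"].to_numpy() + 2) / 4
        assert kstest(u, "uniform").pvalue > 0.01

    def test_summary_has_modes_and_intervals(self, small_fit):
        s = small_fit.summary(adjusted=False)
        assert {"mode", "ci_low", "ci_high"} <= set(s.columns)
        assert (s["ci_low"] <= s["ci_high"]).all()

    def test_adjusted_proportions_stay_in_unit_interval(self):
        scen = default_scenario(sample_size=10)
        g, p = simulate_scenario(scen, 6, seed=1)
        obs = summary_statistics(g, p)
        res = abc_fit(obs, scen, n_sims=150, n_loci=6, accept_rate=0.2,
                      adjust="loclinear", seed=3)
        for name in res.param_names:
            if name.startswith("admix_"):
                x = res.adjusted[name].to_numpy()
                assert np.all((x >= 0) & (x <= 1))


class TestPosteriorReport:
    def _fake_result(self, modes):
        from ssrdem.abc_demography import ABCResult
        import pandas as pd

        rng = np.random.default_rng(0)
        names = list(modes)
        prior = pd.DataFrame({n: rng.uniform(-2, 2, 400) for n in names})
        post = pd.DataFrame({
            n: np.clip(rng.normal(m, 0.1, 400), -2, 2) for n, m in modes.items()
        })
        return ABCResult(param_names=names, prior_draws=prior, accepted=post,
                         adjusted=post, distances=np.zeros(400), threshold=1.0,
                         n_accept=400)

    def test_classification_by_mode(self):
        res = self._fake_result({
            "log10_r_A": 0.0, "log10_r_B": -1.2, "log10_r_C": 1.0,
        })
        rep = posterior_r_report(res)
        assert rep.loc["log10_r_A", "classification"] == "stable"
        assert rep.loc["log10_r_B", "classification"] == "bottleneck"
        assert rep.loc["log10_r_C", "classification"] == "expansion"
        assert not rep["uninformative"].any()

    def test_posterior_equal_to_prior_flagged_uninformative(self):
        from ssrdem.abc_demography import ABCResult
        import pandas as pd

        rng = np.random.default_rng(1)
        draws = rng.uniform(-2, 2, 500)
        prior = pd.DataFrame({"log10_r_A": draws})
        post = pd.DataFrame({"log10_r_A": rng.uniform(-2, 2, 500)})
        res = ABCResult(param_names=["log10_r_A"], prior_draws=prior,
                        accepted=post, adjusted=post,
                        distances=np.zeros(500), threshold=1.0, n_accept=500)
        rep = posterior_r_report(res)
        assert rep.loc["log10_r_A", "uninformative"]
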
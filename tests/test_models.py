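"""Model fitting, LRT/AIC machinery and hypothesis ranking."""

import numpy as np
import pytest

import ccmphylo as cp
from ccmphylo.likelihood import SiteClassMixture
from ccmphylo.models import (
    CodonModel,
    CodonModelResults,
    HypothesisSet,
    aic_score,
    fit_branch_site_A,
    fit_model,
    foreground_site_fraction,
    likelihood_ratio_test,
    rank_hypotheses,
)
from ccmphylo.ratematrix import CodonModelParams


@pytest.fixture(scope="module")
def small_data(uniform_pi):
    """6-taxon, 150-codon alignment simulated under M1a."""
    tree = cp.simulate_tree(6, seed=21)
    params = CodonModelParams(2.0, 1.0, uniform_pi)
    aln, _ = cp.simulate_codon_alignment(
        tree, SiteClassMixture.m1a(0.6, 0.15), params, 150, seed=22
    )
    return aln, tree


@pytest.fixture(scope="module")
def fits(small_data):
    """The nested chain M0 -> M1a -> M2a / model A on one dataset."""
    aln, tree = small_data
    m0 = CodonModel(aln, tree, model="M0").fit(seed=0)
    m1a = CodonModel(aln, tree, model="M1a").fit(seed=0, m0_result=m0)
    m2a = CodonModel(aln, tree, model="M2a").fit(seed=0, m0_result=m0, warm_start=m1a)
    fg = ["t1", "t2"]
    ma = CodonModel(aln, tree, model="modelA", foreground=fg).fit(
        seed=0, m0_result=m0, warm_start=m1a
    )
    ma_null = CodonModel(
        aln, tree, model="modelA", foreground=fg, fix_omega2=True
    ).fit(seed=0, m0_result=m0, warm_start=m1a)
    return {"M0": m0, "M1a": m1a, "M2a": m2a, "A": ma, "A0": ma_null}


class TestLRT:
    def test_closed_form(self):
        res = likelihood_ratio_test(-100.0, -98.0, df=2)
        assert np.isclose(res.statistic, 4.0)
        assert np.isclose(res.pvalue, np.exp(-2.0), atol=1e-4)  # chi2(2): p=e^-s/2

    def test_clamped_when_alternative_is_worse(self):
        res = likelihood_ratio_test(-98.0, -100.0, df=2)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(-10.0, -9.0, df=0)


class TestAIC:
    def test_zero_case(self):
        assert aic_score(llf=0.0, k=0) == 0.0

    def test_accepts_fit_objects_and_pairs(self, fits):
        m0 = fits["M0"]
        assert aic_score(m0) == aic_score(llf=m0.llf, k=m0.k)
        assert aic_score((m0.llf, m0.k)) == m0.aic

    def test_consistent_with_llf_and_k_for_every_fit(self, fits):
        for res in fits.values():
            assert np.isclose(res.aic, 2 * res.k - 2 * res.llf, atol=1e-6)


class TestNestingAndCounting:
    def test_loglikelihood_nesting_chain(self, fits):
        tol = 1e-4
        assert fits["M0"].llf <= fits["M1a"].llf + tol
        assert fits["M1a"].llf <= fits["M2a"].llf + tol
        assert fits["M1a"].llf <= fits["A"].llf + tol
        assert fits["A0"].llf <= fits["A"].llf + tol

    def test_free_parameter_differences(self, fits):
        assert fits["M2a"].k - fits["M1a"].k == 2
        assert fits["A"].k - fits["M1a"].k == 2
        assert fits["A"].k - fits["A0"].k == 1

    def test_proportions_sum_to_one(self, fits):
        for res in fits.values():
            assert np.isclose(sum(res.proportions.values()), 1.0, atol=1e-8)

    def test_null_fixes_omega2_at_one(self, fits):
        assert fits["A0"].omegas["w2"] == 1.0

    def test_summary_mentions_key_quantities(self, fits):
        text = fits["A"].summary()
        assert "modelA" in text and "AIC" in text and "kappa" in text


class TestReproducibility:
    def test_same_seed_same_fit(self, small_data):
        aln, tree = small_data
        a = CodonModel(aln, tree, model="M1a", branch_lengths="fixed").fit(seed=7)
        b = CodonModel(aln, tree, model="M1a", branch_lengths="fixed").fit(seed=7)
        assert a.llf == b.llf
        assert a.kappa == b.kappa
        assert a.proportions == b.proportions


class TestRecovery:
    def test_purifying_omega_recovered_below_one(self, uniform_pi):
        """M0 fits of data simulated at omega = 0.1 estimate omega < 1."""
        tree = cp.simulate_tree(6, seed=31)
        params = CodonModelParams(2.0, 1.0, uniform_pi)
        for rep in range(3):
            aln, _ = cp.simulate_codon_alignment(
                tree, SiteClassMixture.m0(0.1), params, 200, seed=40 + rep
            )
            res = fit_model(aln, tree, "M0", seed=0)
            assert res.omegas["w"] < 1.0

    def test_estimation_error_shrinks_with_alignment_length(self, uniform_pi):
        """Median |omega_hat - omega| at 1000 codons is smaller than at
        100 codons (consistency of the ML fit)."""
        tree = cp.simulate_tree(6, seed=55)
        params = CodonModelParams(2.0, 1.0, uniform_pi)
        medians = {}
        for n in (100, 1000):
            errs = []
            for rep in range(5):
                aln, _ = cp.simulate_codon_alignment(
                    tree, SiteClassMixture.m0(0.3), params, n, seed=70 + rep
                )
                fit = fit_model(aln, tree, "M0", seed=0)
                errs.append(abs(fit.omegas["w"] - 0.3))
            medians[n] = np.median(errs)
        assert medians[1000] < medians[100]

    def test_omega_ordering_preserved_in_fits(self, uniform_pi):
        """Fits of omega=0.2 vs omega=5 simulations keep their order."""
        tree = cp.simulate_tree(4, seed=33)
        params = CodonModelParams(2.0, 1.0, uniform_pi)
        for rep in range(2):
            low, _ = cp.simulate_codon_alignment(
                tree, SiteClassMixture.m0(0.2), params, 150, seed=50 + rep
            )
            high, _ = cp.simulate_codon_alignment(
                tree, SiteClassMixture.m0(5.0), params, 150, seed=60 + rep
            )
            w_low = fit_model(low, tree, "M0", seed=0).omegas["w"]
            w_high = fit_model(high, tree, "M0", seed=0).omegas["w"]
            assert w_low < w_high


class TestForegroundHandling:
    def test_empty_hypothesis_rejected(self):
        with pytest.raises(ValueError, match="no foreground"):
            HypothesisSet("empty")

    def test_unknown_branch_rejected(self, small_data):
        aln, tree = small_data
        with pytest.raises(KeyError):
            fit_branch_site_A(aln, tree, ["not_a_branch"], branch_lengths="fixed")

    def test_model_a_without_foreground_rejected(self, small_data):
        aln, tree = small_data
        with pytest.raises(ValueError, match="foreground"):
            CodonModel(aln, tree, model="modelA")

    def test_clade_expansion_includes_stem(self):
        tree = cp.simulate_tree(6, seed=21)
        members = tree.leaves_below(tree.children[tree.root][0])
        tree.clades["grp"] = frozenset(members)
        fg = tree.with_foreground(clades=["grp"])
        # every branch inside the clade plus its stem
        assert fg.foreground.sum() == 2 * len(members) - 2 + 1 or members == set()


class TestForegroundSiteFraction:
    def make_fit(self, p0, p1):
        mix = SiteClassMixture.model_a(p0, p1, 0.1, 1.5)
        props = {
            "p0": mix.classes[0][0],
            "p1": mix.classes[1][0],
            "p2a": mix.classes[2][0],
            "p2b": mix.classes[3][0],
        }
        return CodonModelResults(
            model_tag="modelA", llf=-1.0, k=5, kappa=2.0,
            omegas={"w0": 0.1, "w1": 1.0, "w2": 1.5}, proportions=props,
            branch_lengths={}, pi=np.full(61, 1 / 61), mixture=mix,
        )

    def test_reporting_convention(self):
        assert np.isclose(foreground_site_fraction(self.make_fit(0.6, 0.232)), 0.168)

    def test_zero_when_no_foreground_class(self):
        assert np.isclose(foreground_site_fraction(self.make_fit(0.7, 0.3)), 0.0)

    def test_wrong_model_rejected(self, fits):
        with pytest.raises(ValueError):
            foreground_site_fraction(fits["M1a"])


@pytest.fixture(scope="module")
def ranking(small_data):
    aln, tree = small_data
    hyps = [
        HypothesisSet("one_tip", branches=("t1",)),
        HypothesisSet("two_tips", branches=("t1", "t2")),
    ]
    return rank_hypotheses(aln, tree, hyps, include_site_models=True, seed=0)


class TestRanking:
    def test_sorted_ascending_by_aic(self, ranking):
        aic = ranking["AIC"].to_numpy()
        assert np.all(np.diff(aic) >= -1e-9)
        assert np.allclose(ranking["dAIC"], aic - aic.min())

    def test_contains_baselines_and_hypotheses(self, ranking):
        assert set(ranking["model"]) >= {"M1a", "M2a", "modelA"}
        assert {"one_tip", "two_tips"} <= set(ranking["foreground"])

    def test_permutation_invariance(self, small_data, ranking):
        aln, tree = small_data
        hyps = [
            HypothesisSet("two_tips", branches=("t1", "t2")),
            HypothesisSet("one_tip", branches=("t1",)),
        ]
        other = rank_hypotheses(aln, tree, hyps, include_site_models=True, seed=0)
        a = ranking[["model", "foreground", "lnL", "AIC"]].reset_index(drop=True)
        b = other[["model", "foreground", "lnL", "AIC"]].reset_index(drop=True)
        assert a.equals(b)

    def test_failure_isolation(self, small_data):
        aln, tree = small_data
        hyps = [
            HypothesisSet("good", branches=("t1",)),
            HypothesisSet("bad", branches=("missing_branch",)),
        ]
        df = rank_hypotheses(aln, tree, hyps, include_site_models=False, seed=0)
        bad = df[df["foreground"] == "bad"].iloc[0]
        assert bad["error"] != "" and np.isnan(bad["AIC"])
        good = df[df["foreground"] == "good"].iloc[0]
        assert np.isfinite(good["AIC"])
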
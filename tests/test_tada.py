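"""Bayes factors against quadrature oracles; q-value arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist
from scipy.stats import poisson

from nddprio.tada import (
    TadaHyperparams,
    bayesian_qvalues,
    cc_bayes_factor,
    combine_evidence,
    dn_bayes_factor,
    log_dn_bayes_factor,
    prioritize,
)
from nddprio.variants import GeneCountTable


def dn_bf_oracle(x: int, n_trios: int, mu: float, gamma_bar: float, beta: float) -> float:
    """Independent oracle: 1-D quadrature of the Poisson-Gamma marginal."""
    lam = 2 * n_trios * mu
    a = gamma_bar * beta
    upper = a / beta + 20 * max(1.0, math.sqrt(a)) / beta
    integrand = lambda g: poisson.pmf(x, lam * g) * gamma_dist.pdf(g, a, scale=1 / beta)
    num = quad(integrand, 0, upper, limit=400, epsabs=0, epsrel=1e-12)[0]
    num += quad(integrand, upper, np.inf, limit=400, epsabs=0, epsrel=1e-10)[0]
    return num / poisson.pmf(x, lam)


def cc_bf_oracle(
    x_case: int, x_ctrl: int, n_case: int, n_ctrl: int,
    gamma_bar: float, beta: float, rho: float, nu: float,
) -> float:
    """Independent oracle: 2-D quadrature over (q, gamma).

    The q integral substitutes u = q**rho so the Gamma(rho, nu) density's
    singularity at 0 becomes a smooth integrand.
    """

    def marginal(g: float) -> float:
        def inner(u: float) -> float:
            q = u ** (1.0 / rho)
            return (
                poisson.pmf(x_ctrl, n_ctrl * q)
                * poisson.pmf(x_case, n_case * q * g)
                * math.exp(-nu * q)
            )

        val = quad(inner, 0, np.inf, limit=400)[0]
        return val * nu**rho / math.gamma(rho) / rho

    a = gamma_bar * beta
    upper = a / beta + 20 * max(1.0, math.sqrt(a)) / beta
    num = quad(
        lambda g: marginal(g) * gamma_dist.pdf(g, a, scale=1 / beta), 0, upper, limit=400
    )[0]
    return num / marginal(1.0)


class TestDeNovoBayesFactor:
    def test_x0_closed_form(self):
        # for x = 0 the BF collapses to exp(lambda) * (beta/(lambda+beta))**alpha
        lam = 2 * 1000 * 1e-5
        expected = math.exp(lam) * (1.0 / (lam + 1.0)) ** 20
        assert dn_bayes_factor(0, 1000, 1e-5, 20, 1) == pytest.approx(expected, rel=1e-12)

    def test_single_count_value(self):
        # frozen from the quadrature oracle (rel err < 1e-8)
        assert dn_bayes_factor(1, 1000, 1e-5, 20, 1) == pytest.approx(13.4620834, rel=1e-7)

    def test_matches_quadrature_grid(self):
        # lambda spans 1e-4..1 via (n_trios, mu) combinations
        for x in range(6):
            for lam in (1e-4, 1e-2, 0.1, 0.5, 1.0):
                for alpha in (1.0, 5.0, 20.0, 40.0):
                    beta = 1.0
                    mu = lam / (2 * 1000)
                    cf = dn_bayes_factor(x, 1000, mu, alpha / beta, beta)
                    oracle = dn_bf_oracle(x, 1000, mu, alpha / beta, beta)
                    assert cf == pytest.approx(oracle, rel=1e-8)

    def test_null_prior_limit(self):
        # gamma_bar = 1 with huge beta pins gamma at 1: H1 == H0
        for x in (0, 1, 3):
            assert dn_bayes_factor(x, 1000, 1e-4, 1.0, 1e6) == pytest.approx(1.0, rel=1e-3)

    def test_monotone_in_count(self):
        bfs = [log_dn_bayes_factor(x, 1000, 1e-5, 20, 1) for x in range(6)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_zero_mu_handling(self):
        assert dn_bayes_factor(0, 1000, 0.0, 20, 1) == 1.0
        with pytest.raises(ValueError, match="impossible count"):
            dn_bayes_factor(1, 1000, 0.0, 20, 1)
        with pytest.raises(ValueError):
            dn_bayes_factor(1.5, 1000, 1e-5, 20, 1)


class TestCaseControlBayesFactor:
    params = TadaHyperparams()

    def test_no_data_near_one(self):
        bf = cc_bayes_factor(0, 0, 1000, 3000, self.params, "PTV")
        assert 0.5 < bf < 1.05

    def test_case_excess_supports_risk(self):
        bf = cc_bayes_factor(5, 0, 1000, 3000, self.params, "PTV")
        assert bf > 1.0

    @pytest.mark.parametrize(
        "x_case,x_ctrl", [(0, 0), (1, 0), (5, 0), (2, 3), (0, 4), (8, 2)]
    )
    def test_matches_2d_quadrature(self, x_case, x_ctrl):
        bf = cc_bayes_factor(x_case, x_ctrl, 1000, 3000, self.params, "PTV")
        oracle = cc_bf_oracle(x_case, x_ctrl, 1000, 3000, 2.3, 4.0, 0.1, 200.0)
        assert bf == pytest.approx(oracle, rel=1e-6)

    def test_monotone_in_case_count(self):
        bfs = [cc_bayes_factor(x, 0, 1000, 3000, self.params, "PTV") for x in range(6)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_null_prior_limit(self):
        p = TadaHyperparams(
            gamma_bar_cc={"PTV": 1.0, "Dmis": 1.0}, beta_cc={"PTV": 1e6, "Dmis": 1e6}
        )
        for xc, xn in ((0, 0), (3, 1), (0, 5)):
            assert cc_bayes_factor(xc, xn, 1000, 3000, p, "PTV") == pytest.approx(1.0, rel=1e-3)


class TestCombineAndQvalues:
    def test_combine(self):
        assert combine_evidence({"PTV": 10.0, "Dmis": 2.0}) == pytest.approx(20.0)
        assert combine_evidence({"PTV": 1.0}, {"PTV": 1.0, "Dmis": 1.0}) == pytest.approx(1.0)
        assert combine_evidence({"PTV": 0.0, "Dmis": 5.0}) == 0.0
        with pytest.raises(ValueError):
            combine_evidence({"PTV": -1.0})

    def test_single_gene(self):
        pi = 0.05
        # choose BF so that pp = 0.9 exactly
        bf = 0.9 / 0.1 * (1 - pi) / pi
        out = bayesian_qvalues(pd.Series({"G": bf}), pi)
        assert out.loc["G", "pp"] == pytest.approx(0.9)
        assert out.loc["G", "qvalue"] == pytest.approx(0.1)

    def test_flat_bf(self):
        out = bayesian_qvalues(pd.Series({"A": 1.0, "B": 1.0, "C": 1.0}), pi=0.05)
        assert np.allclose(out["pp"], 0.05)
        assert np.allclose(out["qvalue"], 0.95)

    def test_two_gene_hand_example(self):
        pi = 0.5  # with pi=0.5, pp = BF/(BF+1); invert pp=(0.95, 0.55)
        bfs = pd.Series({"A": 0.95 / 0.05, "B": 0.55 / 0.45})
        out = bayesian_qvalues(bfs, pi)
        assert out.loc["A", "qvalue"] == pytest.approx(0.05)
        assert out.loc["B", "qvalue"] == pytest.approx(0.25)

    def test_monotone_and_relabel_invariant(self):
        rng = np.random.default_rng(7)
        bfs = pd.Series(rng.lognormal(0, 2, size=40), index=[f"g{i:02d}" for i in range(40)])
        out = bayesian_qvalues(bfs, 0.05)
        ranked = out.loc[bfs.sort_values(ascending=False).index, "qvalue"]
        assert (np.diff(ranked.to_numpy()) >= -1e-12).all()
        # relabeling genes permutes rows but not the (bf -> qvalue) mapping
        relabeled = bfs.copy()
        relabeled.index = [f"h{i:02d}" for i in reversed(range(40))]
        out2 = bayesian_qvalues(relabeled, 0.05)
        merged = pd.DataFrame({
            "q1": out["qvalue"].to_numpy()[np.argsort(bfs.to_numpy(), kind="stable")],
            "q2": out2["qvalue"].to_numpy()[np.argsort(relabeled.to_numpy(), kind="stable")],
        })
        assert np.allclose(merged["q1"], merged["q2"])


class TestPrioritize:
    def _counts(self, data, n_trios=1000, n_cases=0, n_controls=0):
        df = pd.DataFrame(data).T
        df.index.name = "gene"
        return GeneCountTable(df, n_trios=n_trios, n_cases=n_cases, n_controls=n_controls)

    def _mu(self, genes, mu=1e-5):
        return pd.DataFrame(
            {"mu_PTV": mu, "mu_Dmis": mu}, index=pd.Index(list(genes), name="gene")
        )

    def test_all_zero_counts_no_candidates(self):
        counts = self._counts({g: {"dn_PTV": 0} for g in "ABCD"})
        res = prioritize(counts, self._mu("ABCD"))
        assert not res["candidate"].any()
        assert (res["qvalue"] >= 0.95 - 1e-9).all()  # 1 - pi

    def test_recurrent_gene_prioritized(self):
        counts = self._counts({"HIT": {"dn_PTV": 3}, **{g: {"dn_PTV": 0} for g in "ABCDEFGH"}})
        res = prioritize(counts, self._mu(list("ABCDEFGH") + ["HIT"]))
        assert res.index[0] == "HIT"
        assert res.loc["HIT", "candidate"]

    def test_missing_mutation_rate_raises(self):
        counts = self._counts({"A": {"dn_PTV": 1}, "B": {"dn_PTV": 0}})
        with pytest.raises(KeyError, match="B"):
            prioritize(counts, self._mu(["A"]))

    def test_ordering_deterministic(self):
        counts = self._counts({g: {"dn_PTV": 1} for g in "DBCA"})
        res = prioritize(counts, self._mu("ABCD"))
        assert list(res.index) == sorted(res.index)  # equal q: symbol order
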
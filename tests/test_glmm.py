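"""ZTNB mixed model: oracle fits, identities, EMM contrasts, ranks, BLUPs."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from myxindic import glmm
from myxindic.ztnb import ztnb_logpmf

from conftest import simulate_model_frame


def plain_ztnb_regression(frame, reference):
    """Independent fixed-effects-only ZTNB fit (direct likelihood optimisation),
    the oracle for the zero-random-variance limit."""
    subs = [reference] + sorted(s for s in frame["substrateCategory"].unique() if s != reference)
    X = np.column_stack(
        [np.ones(len(frame))]
        + [(frame["substrateCategory"] == s).to_numpy(float) for s in subs[1:]]
    )
    y = frame["y"].to_numpy(float)
    off = frame["log_offset"].to_numpy(float)

    def nll(par):
        beta, logk = par[:-1], par[-1]
        mu = np.exp(np.clip(X @ beta + off, -30, 30))
        return -np.sum(ztnb_logpmf(y, mu, np.exp(logk)))

    x0 = np.zeros(X.shape[1] + 1)
    x0[0] = np.log(y.mean()) - off.mean()
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-10})
    return dict(zip(["(Intercept)"] + subs[1:], res.x[:-1])), float(np.exp(res.x[-1]))


class TestFit:
    def test_zero_re_variance_matches_plain_ztnb(self):
        """With no simulated random-effect variance the mixed fit collapses to
        the plain fixed-effects ZTNB regression."""
        rng = np.random.default_rng(8)
        frame = simulate_model_frame(
            rng, n_countries=4, n_species=30, sigma_country=0.0, sigma_species=0.0,
            substrate_betas=(0.4, -0.3), base=-3.0,
        )
        fit = glmm.fit(frame, glmm.ModelSpec(reference="S0"))
        oracle_beta, oracle_k = plain_ztnb_regression(frame, "S0")
        for name in ("S1", "S2"):
            assert fit.beta[name] == pytest.approx(oracle_beta[name], abs=1e-3)
        assert fit.k == pytest.approx(oracle_k, rel=0.05)

    def test_offset_shift_identity(self):
        """Adding a constant to every offset shifts the intercept by its
        negative and leaves substrate contrasts unchanged."""
        rng = np.random.default_rng(3)
        frame = simulate_model_frame(rng, n_countries=6, n_species=30)
        fit1 = glmm.fit(frame, glmm.ModelSpec(reference="S0"))
        shifted = frame.copy()
        shifted["log_offset"] = shifted["log_offset"] + 1.7
        fit2 = glmm.fit(shifted, glmm.ModelSpec(reference="S0"))
        assert fit2.beta["(Intercept)"] == pytest.approx(
            fit1.beta["(Intercept)"] - 1.7, abs=2e-3
        )
        for s in fit1.substrates[1:]:
            assert fit2.beta[s] == pytest.approx(fit1.beta[s], abs=2e-3)

    def test_deterministic_given_data(self, small_model_frame):
        f1 = glmm.fit(small_model_frame, glmm.ModelSpec(reference="S0"))
        f2 = glmm.fit(small_model_frame, glmm.ModelSpec(reference="S0"))
        assert (f1.beta == f2.beta).all()
        assert f1.k == f2.k

    def test_input_validation(self, small_model_frame):
        with pytest.raises(ValueError):
            glmm.fit(small_model_frame.iloc[:0], glmm.ModelSpec(reference="S0"))
        bad = small_model_frame.copy()
        bad.loc[bad.index[0], "y"] = 0
        with pytest.raises(ValueError):
            glmm.fit(bad, glmm.ModelSpec(reference="S0"))
        bad2 = small_model_frame.copy()
        bad2.loc[bad2.index[0], "log_offset"] = np.inf
        with pytest.raises(ValueError):
            glmm.fit(bad2, glmm.ModelSpec(reference="S0"))
        with pytest.raises(ValueError):
            glmm.fit(small_model_frame, glmm.ModelSpec(reference="NOPE"))


@pytest.fixture(scope="module")
def fitted(small_model_frame):
    return glmm.fit(small_model_frame, glmm.ModelSpec(reference="S0"))


class TestRateRatios:
    def test_reference_row_identity(self, fitted):
        rr = glmm.rate_ratios(fitted).set_index("substrateCategory")
        assert rr.loc["S0", "rate_ratio"] == 1.0
        assert np.isnan(rr.loc["S0", "ci_lower"])

    def test_ci_wald_duality(self, fitted):
        rr = glmm.rate_ratios(fitted)
        for _, row in rr.iterrows():
            if np.isnan(row.se):
                continue
            z = abs(row.log_ratio / row.se)
            excludes_one = row.ci_lower > 1 or row.ci_upper < 1
            assert excludes_one == (z > stats.norm.ppf(0.975))

    def test_doubling_rate_recovered(self):
        rng = np.random.default_rng(12)
        frame = simulate_model_frame(
            rng, n_countries=10, n_species=60, substrate_betas=(np.log(2.0),),
            base=-3.5,
        )
        fit = glmm.fit(frame, glmm.ModelSpec(reference="S0"))
        rr = glmm.rate_ratios(fit).set_index("substrateCategory")
        assert rr.loc["S1", "ci_lower"] <= 2.0 <= rr.loc["S1", "ci_upper"]
        assert rr.loc["S1", "rate_ratio"] == pytest.approx(2.0, rel=0.3)


class TestEmmPairwise:
    def test_two_substrate_equivalence(self):
        rng = np.random.default_rng(5)
        frame = simulate_model_frame(rng, n_countries=6, n_species=30, substrate_betas=(0.5,))
        fit = glmm.fit(frame, glmm.ModelSpec(reference="S0"))
        emm = glmm.emm_pairwise(fit)
        rr = glmm.rate_ratios(fit).set_index("substrateCategory")
        assert emm.iloc[0]["ratio"] == pytest.approx(1 / rr.loc["S1", "rate_ratio"])
        # with a single contrast the adjustment is a no-op up to MC error
        assert emm.iloc[0]["p_adjusted"] == pytest.approx(emm.iloc[0]["p_value"], abs=0.01)

    def test_adjusted_ge_raw_and_transitivity(self, small_model_frame):
        fit = glmm.fit(small_model_frame, glmm.ModelSpec(reference="S0"))
        emm = glmm.emm_pairwise(fit).set_index("contrast")
        assert (emm["p_adjusted"] >= emm["p_value"] - 1e-12).all()
        r01 = emm.loc["S0 / S1", "ratio"]
        r12 = emm.loc["S1 / S2", "ratio"]
        r02 = emm.loc["S0 / S2", "ratio"]
        assert r01 * r12 == pytest.approx(r02, rel=1e-9)

    def test_max_abs_z_adjustment_against_genz_oracle(self, small_model_frame):
        """The Monte-Carlo max-|z| adjusted p matches the Genz rectangle
        probability of the same multivariate normal (independent oracle)."""
        fit = glmm.fit(small_model_frame, glmm.ModelSpec(reference="S0"))
        emm = glmm.emm_pairwise(fit, n_mc=200_000, seed=1)
        subs = fit.substrates
        p = len(fit.beta)
        L = np.zeros((len(subs), p))
        L[:, 0] = 1.0
        for i in range(1, len(subs)):
            L[i, i] = 1.0
        pairs = [(i, j) for i in range(len(subs)) for j in range(i + 1, len(subs))]
        C = np.array([L[i] - L[j] for i, j in pairs])
        cov = C @ fit.vcov_beta.to_numpy() @ C.T
        se = np.sqrt(np.diag(cov))
        corr = cov / np.outer(se, se)
        z = (C @ fit.beta.to_numpy()) / se
        mvn = stats.multivariate_normal(mean=np.zeros(len(pairs)), cov=corr, allow_singular=True)
        for row_i in range(len(pairs)):
            za = abs(z[row_i])
            oracle = 1.0 - mvn.cdf(np.full(len(pairs), za), lower_limit=np.full(len(pairs), -za))
            got = emm.iloc[row_i]["p_adjusted"]
            assert got == pytest.approx(max(oracle, emm.iloc[row_i]["p_value"]), abs=0.02)


class TestBootstrapRanks:
    def test_separation_gives_degenerate_top_rank(self):
        rng = np.random.default_rng(21)
        frame = simulate_model_frame(
            rng, n_countries=6, n_species=25, substrate_betas=(3.0, 0.1), base=-4.0,
        )
        fit = glmm.fit(frame, glmm.ModelSpec(reference="S0"))
        ranks = glmm.bootstrap_ranks(fit, B=30, rarity_threshold=0, seed=2)
        top = ranks.set_index("substrateCategory").loc["S1"]
        assert top["median_rank"] == 1
        assert top["rank_2.5"] == 1 and top["rank_97.5"] == 1

    def test_intervals_nested_and_reference_lowest(self):
        rng = np.random.default_rng(22)
        frame = simulate_model_frame(
            rng, n_countries=8, n_species=30, substrate_betas=(1.6, 1.8, 2.0), base=-4.5,
        )
        fit = glmm.fit(frame, glmm.ModelSpec(reference="S0"))
        ranks = glmm.bootstrap_ranks(fit, B=30, rarity_threshold=0, seed=3)
        for _, row in ranks.iterrows():
            assert row["rank_2.5"] <= row["rank_25"] <= row["median_rank"]
            assert row["median_rank"] <= row["rank_75"] <= row["rank_97.5"]
        # the reference (lowest true rate) collapses at the bottom rank
        bottom = ranks.set_index("substrateCategory").loc["S0"]
        assert bottom["median_rank"] == len(ranks)
        assert bottom["rank_2.5"] == bottom["rank_97.5"] == len(ranks)

    def test_rarity_threshold_excludes(self, small_model_frame):
        fit = glmm.fit(small_model_frame, glmm.ModelSpec(reference="S0"))
        totals = small_model_frame.groupby("substrateCategory")["y"].sum()
        thr = int(totals.median())
        ranks = glmm.bootstrap_ranks(fit, B=5, rarity_threshold=thr, seed=0)
        assert set(ranks["substrateCategory"]) == set(totals[totals >= thr].index)


class TestOrderDeviations:
    def test_planted_deviation_recovered_in_most_replicates(self):
        """A strongly deviating order's slope BLUP interval should cover the
        planted deviation and exclude 0 in most replicates (informative
        design, heterogeneous slopes across orders)."""
        covered = 0
        excluded = 0
        R = 6
        for r in range(R):
            rng = np.random.default_rng(300 + r)
            n_orders = 10
            slopes = rng.normal(0, 0.3, (n_orders, 3))
            slopes[0, 0] = 0.9
            frame = simulate_model_frame(
                rng, n_countries=12, n_species=n_orders, substrate_betas=(0.2, -0.2, 0.4),
                sigma_species=0.4, base=-2.5, effort_range=(300, 1000), slopes=slopes,
                k=4.0,
            ).rename(columns={"species": "order"})
            tab, _ = glmm.order_deviations(frame, reference="S0")
            row = tab[(tab["order"] == "G000") & (tab["substrateCategory"] == "S1")].iloc[0]
            # target: realised deviation from the across-order mean slope
            target = 0.9 - slopes[:, 0].mean()
            covered += row.ci_lower <= target <= row.ci_upper
            excluded += bool(row.excludes_zero)
        assert covered >= R // 2 + 1
        assert excluded >= R // 2 + 1

    def test_zero_variance_simulation_shrinks_to_zero(self):
        rng = np.random.default_rng(31)
        frame = simulate_model_frame(
            rng, n_countries=8, n_species=8, sigma_species=0.3, substrate_betas=(0.3, -0.2),
            base=-2.5, effort_range=(100, 300), slopes=np.zeros((8, 2)),
        ).rename(columns={"species": "order"})
        tab, fit = glmm.order_deviations(frame, reference="S0")
        assert tab["deviation"].abs().max() < 0.2

    def test_blup_near_sum_to_zero_balanced(self):
        rng = np.random.default_rng(33)
        slopes = rng.normal(0, 0.4, (10, 2))
        frame = simulate_model_frame(
            rng, n_countries=10, n_species=10, substrate_betas=(0.2, -0.3),
            base=-2.5, effort_range=(200, 600), slopes=slopes, k=4.0,
        ).rename(columns={"species": "order"})
        tab, _ = glmm.order_deviations(frame, reference="S0")
        for s, part in tab.groupby("substrateCategory"):
            assert abs(part["deviation"].mean()) < 0.15
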
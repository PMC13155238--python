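"""IndVal E, blocked resampling, presence scores: oracles and invariants."""

import itertools

import numpy as np
import pandas as pd
import pytest

from myxindic import indicators as ind
from myxindic.indicators import SiteTaxonMatrix


def make_matrix(sites, presence, efforts=None, weighted=True, min_sites=1):
    """Hand-build a SiteTaxonMatrix; sites is a list of (block, group)."""
    sdf = pd.DataFrame(sites, columns=["block", "group"])
    X = pd.DataFrame(presence).astype(np.int8)
    sdf["effort"] = efforts if efforts is not None else np.ones(len(sdf))
    return SiteTaxonMatrix(sites=sdf, X=X, min_sites=min_sites, weighted=weighted)


class TestBuildSites:
    def test_one_site_per_observed_block_group(self):
        rows = [
            {"country": f"C{i:02d}", "substrateCategory": "LIG", "species": "sp1", "y": 2}
            for i in range(16)
        ]
        frame = pd.DataFrame(rows)
        M = ind.build_sites(frame, min_sites=1)
        assert len(M.sites) == 16
        assert (M.sites["group"] == "LIG").all()

    def test_min_sites_filter(self):
        rows = []
        for i in range(4):
            rows.append({"country": f"C{i}", "substrateCategory": "LIG", "species": "common", "y": 1})
        rows.append({"country": "C0", "substrateCategory": "COR", "species": "rare", "y": 1})
        rows.append({"country": "C1", "substrateCategory": "COR", "species": "rare", "y": 1})
        frame = pd.DataFrame(rows)
        M = ind.build_sites(frame, min_sites=3)
        assert "common" in M.taxa
        assert "rare" not in M.taxa

    def test_effort_is_site_total(self):
        frame = pd.DataFrame(
            [
                {"country": "A", "substrateCategory": "LIG", "species": "x", "y": 3},
                {"country": "A", "substrateCategory": "LIG", "species": "y", "y": 5},
            ]
        )
        M = ind.build_sites(frame, min_sites=1)
        assert M.sites["effort"].iloc[0] == 8.0


class TestIndvalE:
    def test_perfect_indicator(self):
        sites = [("B1", "LIG"), ("B1", "COR"), ("B2", "LIG"), ("B2", "COR")]
        M = make_matrix(sites, {"t": [1, 0, 1, 0]})
        a, b, stat = ind.indval_E(M, "t", "LIG")
        assert (a, b, stat) == (1.0, 1.0, 1.0)

    def test_uniform_taxon_indifference(self):
        sites = [("B1", g) for g in ("LIG", "COR", "TER")] + [
            ("B2", g) for g in ("LIG", "COR", "TER")
        ]
        M = make_matrix(sites, {"t": [1] * 6})
        a, _, _ = ind.indval_E(M, "t", "LIG")
        assert a == pytest.approx(1 / 3)

    def test_weighted_six_site_oracle(self):
        """Direct spreadsheet-style weighted-mean computation on an unequal-
        weight toy matrix."""
        sites = [("B1", "LIG"), ("B1", "COR"), ("B2", "LIG"), ("B2", "COR"),
                 ("B3", "LIG"), ("B3", "COR")]
        w = [10.0, 2.0, 5.0, 8.0, 1.0, 4.0]
        x = [1, 1, 1, 0, 0, 1]
        M = make_matrix(sites, {"t": x}, efforts=w)
        m_lig = (10 * 1 + 5 * 1 + 1 * 0) / 16
        m_cor = (2 * 1 + 8 * 0 + 4 * 1) / 14
        A = m_lig / (m_lig + m_cor)
        a, b, stat = ind.indval_E(M, "t", "LIG")
        assert a == pytest.approx(A)
        assert b == pytest.approx(m_lig)
        assert stat == pytest.approx(np.sqrt(A * m_lig))

    def test_unweighted_limit_matches_presence_quantities(self):
        """With equal weights and equally many sites per group, group-equalised
        specificity coincides with the presence-based share of presences."""
        sites = [("B1", "LIG"), ("B2", "LIG"), ("B1", "COR"), ("B2", "COR")]
        M = make_matrix(sites, {"t": [1, 1, 1, 0]}, weighted=False)
        a, b, stat = ind.indval_E(M, "t", "LIG")
        ps = ind.presence_score(M).loc["t"]
        # equal site counts: weighted group means reduce to presence fractions
        assert b == ps["B"] == 1.0
        assert a == pytest.approx(1.0 / 1.5)  # group-equalised
        assert ps["A"] == pytest.approx(2 / 3)


class TestBlockedPermutation:
    def test_invariant_statistic_p_is_one(self):
        sites = [("B1", "LIG"), ("B1", "COR"), ("B2", "LIG"), ("B2", "COR")]
        M = make_matrix(sites, {"t": [1, 1, 1, 1]})
        out = ind.blocked_permutation_test(M, n_perm=99, seed=0)
        assert out.loc["t", "p_value"] == pytest.approx(1.0)

    def test_planted_indicator_hits_resolution_floor(self):
        # 3 groups x 10 blocks: the chance of any permutation re-achieving a
        # perfect indicator is 3 * (1/3)^10 ~ 5e-5, so the sampled p sits at
        # the (1 + x)/(1 + n_perm) resolution floor
        groups = ("LIG", "COR", "TER")
        sites = [(f"B{i}", g) for i in range(10) for g in groups]
        pres = [1 if g == "LIG" else 0 for i in range(10) for g in groups]
        M = make_matrix(sites, {"t": pres})
        out = ind.blocked_permutation_test(M, n_perm=999, seed=1)
        assert out.loc["t", "p_value"] == pytest.approx(1 / 1000)

    def test_matches_exhaustive_enumeration_two_blocks(self):
        """On a 4-site / 2-block toy the sampled p converges to the exhaustive
        within-block enumeration (all 2 x 2 label arrangements)."""
        sites = [("B1", "LIG"), ("B1", "COR"), ("B2", "LIG"), ("B2", "COR")]
        pres = {"t": [1, 0, 1, 1]}
        M = make_matrix(sites, pres)
        obs = ind.indval_E(M).max(axis=1)["t"]
        exceed = 0
        arrangements = list(itertools.product([0, 1], repeat=2))
        for flip1, flip2 in arrangements:
            groups = ["LIG", "COR", "LIG", "COR"]
            if flip1:
                groups[0], groups[1] = groups[1], groups[0]
            if flip2:
                groups[2], groups[3] = groups[3], groups[2]
            Mp = M.with_groups(pd.Series(groups))
            stat = ind.indval_E(Mp).max(axis=1)["t"]
            exceed += stat >= obs - 1e-12
        p_exact = exceed / len(arrangements)
        n_perm = 999
        out = ind.blocked_permutation_test(M, n_perm=n_perm, seed=7)
        p_hat = out.loc["t", "p_value"]
        mc_se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_hat - p_exact) <= 3 * mc_se + 1 / (1 + n_perm)

    def test_superuniform_under_null(self):
        """Within-block exchangeable null: permutation p-values are
        super-uniform (P(p <= a) <= a up to MC error)."""
        rng = np.random.default_rng(5)
        pvals = []
        for r in range(40):
            sites = [(f"B{i}", g) for i in range(4) for g in ("LIG", "COR")]
            pres = {f"t{j}": rng.integers(0, 2, 8).tolist() for j in range(3)}
            M = make_matrix(sites, pres)
            keep = M.X.columns[(M.X.sum(axis=0) > 0) & (M.X.sum(axis=0) < 8)]
            if len(keep) == 0:
                continue
            M = SiteTaxonMatrix(M.sites, M.X[keep], 1, True)
            out = ind.blocked_permutation_test(M, n_perm=99, seed=100 + r)
            pvals.extend(out["p_value"].tolist())
        pvals = np.asarray(pvals)
        for a in (0.05, 0.1, 0.25, 0.5):
            assert (pvals <= a).mean() <= a + 2 * np.sqrt(a * (1 - a) / len(pvals))


def brute_force_bh(pvals):
    """Step-up BH oracle for short p-vectors."""
    p = np.asarray(pvals, dtype=float)
    mtot = len(p)
    order = np.argsort(p)
    adj = np.empty(mtot)
    running = 1.0
    for rank_i in range(mtot - 1, -1, -1):
        idx = order[rank_i]
        running = min(running, p[idx] * mtot / (rank_i + 1))
        adj[idx] = running
    return adj


class TestBenjaminiHochberg:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for length in (1, 3, 7, 10):
            p = rng.uniform(0, 1, length)
            from statsmodels.stats.multitest import multipletests

            got = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(got, brute_force_bh(p))


class TestBootstrapCI:
    def test_constant_statistic_degenerate_interval(self):
        sites = [(f"B{i}", g) for i in range(5) for g in ("LIG", "COR")]
        pres = [1 if g == "LIG" else 0 for i in range(5) for g in ("LIG", "COR")]
        M = make_matrix(sites, {"t": pres})
        out = ind.bootstrap_ci(M, B=200, seed=0)
        assert out.loc["t", "ci_lower"] == out.loc["t", "ci_upper"] == 1.0

    def test_planted_indicator_bounds(self, small_archive):
        from myxindic import archive

        records, _ = small_archive
        frame = archive.aggregate_counts(records)
        M = ind.build_sites(frame)
        out = ind.bootstrap_ci(M, B=200, seed=1)
        row = out.loc["Planted_A"]
        assert row["ci_upper"] <= 1.0
        assert row["ci_lower"] > 0.5

    def test_interval_contains_observed_typically(self, small_archive):
        from myxindic import archive

        records, _ = small_archive
        frame = archive.aggregate_counts(records)
        M = ind.build_sites(frame)
        out = ind.bootstrap_ci(M, B=100, seed=2)
        ok = out.dropna(subset=["ci_lower", "ci_upper"])
        inside = (ok["ci_lower"] <= ok["stat"] + 1e-9) & (ok["stat"] <= ok["ci_upper"] + 1e-9)
        assert inside.mean() >= 0.95


class TestBlockedKfold:
    def test_perfect_alignment_held_out_one(self):
        sites = [(f"B{i}", g) for i in range(10) for g in ("LIG", "COR")]
        pres = [1 if g == "LIG" else 0 for i in range(10) for g in ("LIG", "COR")]
        M = make_matrix(sites, {"t": pres})
        out = ind.blocked_kfold(M, K=5, seed=0)
        assert out.loc["t", "held_out_A"] == pytest.approx(1.0)
        assert out.loc["t", "held_out_B"] == pytest.approx(1.0)

    def test_single_block_taxon_unavailable(self):
        sites = [(f"B{i}", g) for i in range(4) for g in ("LIG", "COR")]
        pres = [0] * 8
        pres[0] = 1  # only in block B0
        M = make_matrix(sites, {"t": pres})
        out = ind.blocked_kfold(M, K=4, seed=0)
        assert np.isnan(out.loc["t", "held_out_A"])

    def test_k_exceeding_blocks_errors(self):
        sites = [("B1", "LIG"), ("B1", "COR")]
        M = make_matrix(sites, {"t": [1, 0]})
        with pytest.raises(ValueError):
            ind.blocked_kfold(M, K=3)

    def test_label_noise_degrades_held_out(self):
        """A noisily expressed planted indicator (present with probability
        0.5 on its substrate, 0.35 elsewhere) has held-out A/B below the
        in-sample values on average: the in-sample best-group selection is
        optimistic."""
        rng = np.random.default_rng(9)
        groups = ("LIG", "COR", "TER", "BRY")
        diffs_a, diffs_b = [], []
        for r in range(40):
            sites = [(f"B{i}", g) for i in range(12) for g in groups]
            p = [0.5 if g == "LIG" else 0.35 for i in range(12) for g in groups]
            pres = (rng.random(len(p)) < np.array(p)).astype(int)
            M = make_matrix(sites, {"t": pres.tolist()})
            if M.X["t"].sum() == 0:
                continue
            tab = ind.indval_table(M)
            out = ind.blocked_kfold(M, K=4, seed=r)
            if np.isnan(out.loc["t", "held_out_A"]):
                continue
            diffs_a.append(tab.loc["t", "A"] - out.loc["t", "held_out_A"])
            diffs_b.append(tab.loc["t", "B"] - out.loc["t", "held_out_B"])
        assert np.mean(diffs_a) > 0
        assert np.mean(diffs_b) > 0


class TestPresenceScore:
    def _matrix_with_counts(self, n_focal, n_total, n_sites_focal, n_other=120):
        """Construct a presence matrix realising the given presence counts:
        the focal group has n_sites_focal sites with n_focal presences; the
        remaining presences are diluted over a large second group so the
        focal group maximises the score."""
        sites = [(f"B{i}", "FOC") for i in range(n_sites_focal)]
        sites += [(f"B{100 + i}", "OTH") for i in range(max(n_other, n_total - n_focal))]
        pres = [1] * n_focal + [0] * (n_sites_focal - n_focal)
        n_oth = len(sites) - n_sites_focal
        pres += [1] * (n_total - n_focal) + [0] * (n_oth - (n_total - n_focal))
        return make_matrix(sites, {"t": pres})

    @pytest.mark.parametrize(
        "n_focal,n_total,n_sites,a,b,score",
        [
            (15, 33, 16, 0.45, 0.94, 0.43),
            (12, 23, 15, 0.52, 0.80, 0.42),
            (4, 5, 16, 0.80, 0.25, 0.20),
            (14, 37, 16, 0.38, 0.88, 0.33),
            (15, 52, 15, 0.29, 1.00, 0.29),
        ],
    )
    def test_reference_score_rows(self, n_focal, n_total, n_sites, a, b, score):
        """Presence-count triples reproduce the published 2-dp A, B and A x B."""
        M = self._matrix_with_counts(n_focal, n_total, n_sites)
        row = ind.presence_score(M).loc["t"]
        assert row["group"] == "FOC"
        assert row["A_display"] == a
        assert row["B_display"] == b
        assert row["score_display"] == score

    def test_share_conservation_and_score_bound(self, small_archive):
        from myxindic import archive

        records, _ = small_archive
        frame = archive.aggregate_counts(records, taxon_col="genus")
        M = ind.build_sites(frame, taxon_col="genus")
        out = ind.presence_score(M)
        assert (out["score"] <= out[["A", "B"]].min(axis=1) + 1e-12).all()
        # focal presences never exceed the total, and A <= 1
        assert (out["n_focal"] <= out["n_total"]).all()
        assert (out["A"] <= 1.0 + 1e-12).all()


class TestPhScreening:
    def test_stratum_summary_reference_rows(self):
        """A stratum with 36 records / 25 species / 19 singletons gives
        coverage 0.47; 2 records of one species give 1.00."""
        rows = []
        # 36-record LIG mid stratum: 19 singletons + 6 species sharing 17
        sp = 0
        for _ in range(19):
            rows.append(("C1", "LIG", f"s{sp}", 6.0))
            sp += 1
        reps = [3, 3, 3, 3, 3, 2]
        for r in reps:
            for _ in range(r):
                rows.append(("C1", "LIG", f"s{sp}", 6.0))
            sp += 1
        # 2-record single-species FOL alkaline stratum
        rows += [("C1", "FOL", "sx", 8.0), ("C1", "FOL", "sx", 8.0)]
        records = pd.DataFrame(rows, columns=["country", "substrateCategory", "species", "pH"])
        out = ind.ph_screening(records, n_perm=9, n_boot=10)
        summary = out["stratum_summary"].set_index(["substrateCategory", "ph_band"])
        lig = summary.loc[("LIG", "5.01-7.00")]
        assert (lig["records"], lig["species"], lig["singletons"]) == (36, 25, 19)
        assert lig["coverage"] == 0.47
        fol = summary.loc[("FOL", ">=7.01")]
        assert (fol["records"], fol["species"], fol["singletons"]) == (2, 1, 0)
        assert fol["coverage"] == 1.00
        assert out["label"] == "screening"

    def test_empty_measured_subset(self):
        records = pd.DataFrame(
            {"country": ["A"], "substrateCategory": ["LIG"], "species": ["x"], "pH": [np.nan]}
        )
        out = ind.ph_screening(records)
        assert out["stratum_summary"].empty
        assert out["tables"] == {}

    def test_null_ph_few_discoveries(self, small_archive):
        """pH independent of taxa: BH-adjusted p-values yield few discoveries."""
        records, _ = small_archive
        out = ind.ph_screening(records, n_perm=199, n_boot=20, seed=3)
        if "species" in out["tables"]:
            tab = out["tables"]["species"]
            assert (tab["p_adjusted"] < 0.05).mean() <= 0.1
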
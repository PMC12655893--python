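"""Diversity, ordination, permutation tests, correlation and biomarkers.

Hand-built statistics (ACE, PCoA, ANOSIM, the Kruskal-Wallis screen) are
cross-checked against independent implementations: scikit-bio for
ACE/PCoA/ANOSIM and scipy.stats.kruskal for the vectorised screen.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import rhizojip as rj


class TestTotalSumScale:
    def test_normalization_and_idempotence(self, small_table):
        rel = rj.total_sum_scale(small_table)
        assert np.allclose(rel.row_sums(), 1.0)
        again = rj.total_sum_scale(rel)
        assert np.allclose(rel.values, again.values)

    def test_zero_row_names_sample(self, small_table):
        vals = small_table.values.copy()
        vals.loc["TN01"] = 0
        with pytest.raises(ValueError, match="TN01"):
            rj.total_sum_scale(rj.AbundanceTable(vals))


class TestACE:
    def test_hand_worked_breakdown(self):
        b = rj.ace_index([1, 1, 2, 15])
        assert (b.s_abund, b.s_rare, b.n_rare) == (1, 3, 4)
        assert b.c_ace == pytest.approx(0.5)
        assert b.gamma2 == pytest.approx(0.0)
        assert b.ace == pytest.approx(7.0)

    def test_no_rare_taxa_falls_back_to_s_obs(self):
        b = rj.ace_index([15, 20, 100])
        assert b.ace == 3 and b.fallback

    def test_zero_counts_are_ignored(self):
        a = rj.ace_index([1, 1, 2, 15])
        b = rj.ace_index([0, 1, 0, 1, 2, 15, 0])
        assert a.ace == b.ace

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            rj.ace_index([1.5, 2.0])

    def test_matches_scikit_bio_on_random_vectors(self):
        from skbio.diversity.alpha import ace as sk_ace

        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(300):
            v = rng.poisson(rng.uniform(0.5, 8.0), size=rng.integers(10, 60))
            v = v[v > 0]
            mine = rj.ace_index(v) if v.size else None
            if mine is None or mine.fallback:
                continue
            assert mine.ace == pytest.approx(float(sk_ace(v)), abs=1e-9)
            checked += 1
        assert checked > 150


class TestBrayCurtis:
    def test_formula_cases(self, small_table):
        x = rj.AbundanceTable(
            pd.DataFrame([[2.0, 2.0], [1.0, 3.0]], index=["a", "b"],
                         columns=["t1", "t2"])
        )
        d = rj.bray_curtis_matrix(x)
        assert d.loc["a", "b"] == pytest.approx(0.25)
        disjoint = rj.AbundanceTable(
            pd.DataFrame([[5.0, 0.0], [0.0, 7.0]], index=["a", "b"],
                         columns=["t1", "t2"])
        )
        assert rj.bray_curtis_matrix(disjoint).loc["a", "b"] == pytest.approx(1.0)

    @given(
        arrays(np.float64, (5, 8), elements=st.floats(0, 100, allow_nan=False))
    )
    @settings(derandomize=True, max_examples=60)
    def test_bounded_semimetric(self, x):
        x = x + 1e-6  # keep rows nonzero
        table = rj.AbundanceTable(
            pd.DataFrame(x, index=[f"s{i}" for i in range(5)],
                         columns=[f"t{j}" for j in range(8)])
        )
        d = rj.bray_curtis_matrix(table).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()

    def test_all_zero_sample_rejected(self):
        t = rj.AbundanceTable(
            pd.DataFrame([[0.0, 0.0], [1.0, 2.0]], index=["a", "b"],
                         columns=["t1", "t2"])
        )
        with pytest.raises(ValueError, match="all-zero"):
            rj.bray_curtis_matrix(t)


class TestPCoA:
    def test_collinear_points_load_on_one_axis(self):
        # 1-D configuration at mutual distances 1, 1, 2
        d = pd.DataFrame(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], index=list("abc"),
            columns=list("abc"), dtype=float,
        )
        res = rj.pcoa(d)
        assert res.variance_explained[0] == pytest.approx(100.0)

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(2)
        for n in (5, 9, 12):
            pts = rng.normal(size=(n, 3))
            d = pd.DataFrame(squareform(pdist(pts)))
            res = rj.pcoa(d)
            rec = squareform(pdist(res.coordinates.to_numpy()))
            assert np.abs(rec - d.to_numpy()).max() < 1e-9
            assert np.abs(res.coordinates.mean(axis=0)).max() < 1e-9

    def test_degenerate_all_zero_distances(self):
        d = pd.DataFrame(np.zeros((4, 4)))
        res = rj.pcoa(d)
        assert res.eigenvalues.size == 0

    def test_asymmetric_rejected(self):
        d = pd.DataFrame([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            rj.pcoa(d)

    def test_matches_scikit_bio_eigenvalues(self, design6):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa as sk_pcoa

        table = rj.simulate_abundance(rj.CommunityParams(seed=8), design6)
        dm = rj.bray_curtis_matrix(rj.total_sum_scale(table))
        mine = rj.pcoa(dm)
        ref = sk_pcoa(DistanceMatrix(dm.to_numpy(), ids=dm.index))
        k = mine.eigenvalues.size
        assert np.allclose(mine.eigenvalues, ref.eigvals.to_numpy()[:k], atol=1e-9)


class TestAnosim:
    def _separated(self):
        d = np.array(
            [[0.0, 0.10, 0.90, 0.80],
             [0.10, 0.0, 0.85, 0.95],
             [0.90, 0.85, 0.0, 0.12],
             [0.80, 0.95, 0.12, 0.0]]
        )
        return pd.DataFrame(d, index=list("abcd"), columns=list("abcd"))

    def test_perfect_separation_gives_r_one_and_exhaustive_third(self):
        res = rj.anosim(self._separated(), ["g1", "g1", "g2", "g2"])
        assert res.r == pytest.approx(1.0)
        assert res.method == "exhaustive" and res.n_permutations == 6
        # observed labeling and its mirror are the only ones reaching R = 1
        assert res.p == pytest.approx(1 / 3)

    def test_r_matches_scikit_bio(self, design6):
        from skbio.stats.distance import DistanceMatrix, anosim as sk_anosim

        table = rj.simulate_abundance(
            rj.CommunityParams(markers=(rj.PlantedMarker(10, "TA", 2.0),), seed=7),
            design6,
        )
        dm = rj.bray_curtis_matrix(rj.total_sum_scale(table))
        mine = rj.anosim(dm, design6["group"], n_permutations=99, seed=0)
        ref = sk_anosim(
            DistanceMatrix(dm.to_numpy(), ids=dm.index),
            grouping=list(design6["group"]), permutations=99,
        )
        assert mine.r == pytest.approx(float(ref["test statistic"]), abs=1e-12)
        assert mine.method == "montecarlo"

    def test_exhaustive_and_montecarlo_agree(self):
        # n = 6 in two groups of 3: 20 distinct labelings -> exhaustive
        rng = np.random.default_rng(4)
        for _ in range(6):
            pts = rng.normal(size=(6, 2))
            pts[3:] += rng.uniform(0, 1.5)
            d = pd.DataFrame(squareform(pdist(pts)))
            labels = ["a"] * 3 + ["b"] * 3
            ex = rj.anosim(d, labels)
            assert ex.method == "exhaustive"
            big = 4999
            mc_count = 0
            rng2 = np.random.default_rng(0)
            # Monte-Carlo estimate with the add-one rule, many draws
            iu, ju = np.triu_indices(6, k=1)
            ranks = stats.rankdata(d.to_numpy()[iu, ju])
            lab = np.asarray(labels)
            from rhizojip.community import _anosim_r

            r_obs = _anosim_r(ranks, lab[iu] == lab[ju])
            for _ in range(big):
                perm = rng2.permutation(lab)
                if _anosim_r(ranks, perm[iu] == perm[ju]) >= r_obs - 1e-12:
                    mc_count += 1
            p_mc = (1 + mc_count) / (1 + big)
            se = np.sqrt(ex.p * (1 - ex.p) / big)
            assert abs(p_mc - ex.p) <= 2 * se + 1 / big

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2 members"):
            rj.anosim(self._separated(), ["g1", "g1", "g1", "g2"])

    def test_type_one_error_calibrated(self):
        # exchangeable distances, random groups: rejection rate ~ alpha
        rng = np.random.default_rng(42)
        labels = np.repeat(list("abcd"), 3)
        rej = 0
        n_sim = 150
        for _ in range(n_sim):
            pts = rng.normal(size=(12, 5))
            d = pd.DataFrame(squareform(pdist(pts)))
            res = rj.anosim(d, labels, n_permutations=499,
                            seed=int(rng.integers(2**31)))
            rej += res.p <= 0.05
        rate = rej / n_sim
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n_sim)


class TestCoreTaxa:
    def test_identical_groups_share_everything(self, design2):
        counts = pd.DataFrame(
            np.tile([5, 3, 2], (8, 1)),
            index=design2["sample_id"], columns=["t1", "t2", "t3"],
        )
        res = rj.core_taxa(rj.AbundanceTable(counts), design2)
        assert res.n_core == res.n_union == 3
        assert res.core_pct == pytest.approx(100.0)

    def test_disjoint_groups_share_nothing(self, design2):
        counts = pd.DataFrame(0.0, index=design2["sample_id"],
                              columns=[f"t{i}" for i in range(4)])
        for i, g in enumerate(["TN", "TA", "SN", "SA"]):
            sel = design2["sample_id"][design2["group"] == g]
            counts.loc[sel, f"t{i}"] = 3
        res = rj.core_taxa(rj.AbundanceTable(counts), design2)
        assert res.n_core == 0

    def test_planted_shared_fraction(self, design2):
        # 10 taxa, 7 in every group, 3 in one group only -> 70%
        counts = pd.DataFrame(1.0, index=design2["sample_id"],
                              columns=[f"t{i}" for i in range(10)])
        outside_ta = design2.loc[design2["group"] != "TA", "sample_id"]
        counts.loc[outside_ta, ["t7", "t8", "t9"]] = 0
        res = rj.core_taxa(rj.AbundanceTable(counts), design2)
        assert res.core_pct == pytest.approx(70.0)


class TestTopN:
    def test_clamps_and_breaks_ties_lexicographically(self, small_table):
        top = rj.top_n_taxa(small_table, n=50, rank="genus")
        assert len(top) == 3
        tied = rj.AbundanceTable(
            pd.DataFrame(
                [[5.0, 5.0]], index=["s1"],
                columns=["k__B;g__Zeta;s__x", "k__B;g__Alpha;s__y"],
            )
        )
        assert rj.top_n_taxa(tied, n=2, rank="genus") == ["Alpha", "Zeta"]

    def test_sample_order_invariance(self, small_table):
        a = rj.top_n_taxa(small_table, n=2, rank="genus")
        shuffled = rj.AbundanceTable(small_table.values.iloc[::-1])
        assert a == rj.top_n_taxa(shuffled, n=2, rank="genus")

    def test_missing_rank_rejected(self):
        t = rj.AbundanceTable(pd.DataFrame([[1.0]], index=["s"], columns=["taxon"]))
        with pytest.raises(ValueError, match="rank"):
            rj.top_n_taxa(t, rank="genus")


class TestCorrelation:
    def test_monotone_transform_gives_rho_one(self, design6):
        table = rj.simulate_abundance(rj.CommunityParams(seed=1), design6)
        rel = table.values.div(table.row_sums(), axis=0)
        phys = pd.DataFrame(
            {"sample_id": table.samples, "indicator": "SPAD",
             "value": np.exp(rel[table.taxa[5]])}
        )
        res = rj.correlate_taxa_physiology(table, phys, design6)
        assert res.rho.loc[table.taxa[5], "SPAD"] == pytest.approx(1.0)

    def test_reverse_ranks_give_minus_one(self):
        # t1 relative abundance is 0.1, 0.2, 0.3, 0.4 after scaling
        x = np.array([[1.0, 9.0], [2.0, 8.0], [3.0, 7.0], [4.0, 6.0]])
        taxa = rj.AbundanceTable(
            pd.DataFrame(x, index=list("abcd"), columns=["t1", "t2"])
        )
        design = pd.DataFrame(
            {"sample_id": list("abcd"), "variety": "T", "soil": "N", "group": "TN"}
        )
        phys = pd.DataFrame(
            {"sample_id": list("abcd"), "indicator": "MDA",
             "value": [4.0, 3.0, 2.0, 1.0]}
        )
        res = rj.correlate_taxa_physiology(taxa, phys, design)
        assert res.rho.loc["t1", "MDA"] == pytest.approx(-1.0)

    def test_matches_scipy_spearman(self, design6):
        table = rj.simulate_abundance(rj.CommunityParams(n_taxa=20, seed=3), design6)
        rng = np.random.default_rng(0)
        phys = pd.DataFrame(
            [{"sample_id": s, "indicator": ind, "value": rng.normal()}
             for ind in ("MDA", "SOD") for s in table.samples]
        )
        res = rj.correlate_taxa_physiology(table, phys, design6)
        rel = rj.total_sum_scale(table)
        wide = phys.pivot(index="sample_id", columns="indicator", values="value")
        wide = wide.loc[rel.samples]
        for taxon in table.taxa[:5]:
            for ind in ("MDA", "SOD"):
                rho, p = stats.spearmanr(rel.values[taxon], wide[ind])
                assert res.rho.loc[taxon, ind] == pytest.approx(rho, abs=1e-12)
                assert res.p.loc[taxon, ind] == pytest.approx(p, abs=1e-12)

    def test_constant_vector_reported_missing(self, design6):
        table = rj.simulate_abundance(rj.CommunityParams(n_taxa=10, seed=3), design6)
        phys = pd.DataFrame(
            {"sample_id": table.samples, "indicator": "flat", "value": 1.0}
        )
        res = rj.correlate_taxa_physiology(table, phys, design6)
        assert res.rho["flat"].isna().all()

    def test_bh_q_dominates_p_and_is_monotone(self, design6):
        table = rj.simulate_abundance(rj.CommunityParams(n_taxa=30, seed=5), design6)
        rng = np.random.default_rng(1)
        phys = pd.DataFrame(
            [{"sample_id": s, "indicator": ind, "value": rng.normal()}
             for ind in ("a", "b", "c") for s in table.samples]
        )
        res = rj.correlate_taxa_physiology(table, phys, design6)
        p = res.p.to_numpy().ravel()
        q = res.q.to_numpy().ravel()
        ok = ~np.isnan(p)
        assert (q[ok] >= p[ok] - 1e-12).all()
        order = np.argsort(p[ok])
        assert (np.diff(q[ok][order]) >= -1e-12).all()


class TestKruskalScreen:
    def test_hand_worked_two_group_example(self, design6):
        t = rj.AbundanceTable(
            pd.DataFrame({"t1": [1.0, 2, 3, 10, 11, 12]},
                         index=[f"s{i}" for i in range(6)])
        )
        screen = rj.kruskal_wallis_screen(t, ["a"] * 3 + ["b"] * 3)
        assert screen["H"].iloc[0] == pytest.approx(3.857, abs=1e-3)
        assert screen["p"].iloc[0] == pytest.approx(0.0495, abs=1e-3)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 5, size=(12, 15)).astype(float)
        t = rj.AbundanceTable(
            pd.DataFrame(x, index=[f"s{i}" for i in range(12)],
                         columns=[f"t{j}" for j in range(15)])
        )
        labels = np.repeat(["a", "b", "c"], 4)
        screen = rj.kruskal_wallis_screen(t, labels)
        for j in range(15):
            col = x[:, j]
            if np.ptp(col) == 0:
                assert screen["p"].iloc[j] == 1.0
                continue
            h, p = stats.kruskal(col[:4], col[4:8], col[8:])
            assert screen["H"].iloc[j] == pytest.approx(h, abs=1e-10)
            assert screen["p"].iloc[j] == pytest.approx(p, abs=1e-10)

    def test_all_tied_taxon_never_passes(self):
        t = rj.AbundanceTable(
            pd.DataFrame({"t1": [2.0] * 6}, index=[f"s{i}" for i in range(6)])
        )
        screen = rj.kruskal_wallis_screen(t, ["a"] * 3 + ["b"] * 3)
        assert screen["p"].iloc[0] == 1.0 and not screen["passed"].iloc[0]


class TestBiomarkers:
    def _ta_sa(self, params, design):
        table = rj.simulate_abundance(params, design)
        keep = [s for s in table.samples if s[:2] in ("TA", "SA")]
        sub = table.subset_samples(keep)
        return sub, [s[:2] for s in keep]

    def test_flat_feature_fails_stage_one(self, design6):
        sub, grouping = self._ta_sa(rj.CommunityParams(seed=2), design6)
        vals = sub.values.copy()
        vals[vals.columns[0]] = 100.0
        res = rj.lda_effect_size(rj.AbundanceTable(vals), grouping, seed=0)
        assert not res[0].passes and np.isnan(res[0].lda_score)

    def test_planted_marker_detected_with_correct_group(self, design6):
        params = rj.CommunityParams(
            markers=(rj.PlantedMarker(37, "TA", 3.0),), seed=5
        )
        sub, grouping = self._ta_sa(params, design6)
        res = rj.lda_effect_size(sub, grouping, seed=1)
        marker = res[37]
        assert marker.passes and marker.enriched_group == "TA"
        assert marker.lda_score > 2.0

    def test_power_increases_with_effect_size(self, design6):
        scores = []
        for effect in (0.5, 1.5, 3.0):
            hits = 0
            for seed in range(8):
                params = rj.CommunityParams(
                    markers=(rj.PlantedMarker(37, "TA", effect),), seed=100 + seed
                )
                sub, grouping = self._ta_sa(params, design6)
                res = rj.lda_effect_size(sub, grouping, seed=seed)
                hits += res[37].passes
            scores.append(hits)
        assert scores[0] <= scores[1] <= scores[2] and scores[2] >= 7

    def test_permuted_labels_control_false_positives(self, design6):
        rng = np.random.default_rng(3)
        total_pass = total_taxa = 0
        for seed in range(6):
            sub, grouping = self._ta_sa(rj.CommunityParams(seed=seed), design6)
            perm = rng.permutation(grouping)
            res = rj.lda_effect_size(sub, perm, seed=seed)
            total_pass += sum(r.passes for r in res)
            total_taxa += len(res)
        assert total_pass <= 0.05 * total_taxa + 3 * np.sqrt(0.05 * total_taxa)

    def test_requires_two_groups_and_min_n(self, small_table):
        with pytest.raises(ValueError, match="two groups"):
            rj.lda_effect_size(small_table, ["a", "a", "b", "c"])
        with pytest.raises(ValueError, match=">= 3"):
            rj.lda_effect_size(small_table, ["a", "a", "b", "b"])
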
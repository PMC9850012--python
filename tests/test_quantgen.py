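"""Trait preparation filters against brute-force predicates, the h2 and QST
ratios and their invariances, trend tests, family-effect PCA ordering and the
label-shuffling permutation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qstfst.lmm import VarianceComponents
from qstfst.quantgen import (
    cv_per_ring,
    family_effect_matrix,
    family_effect_pca,
    filter_families,
    heritability,
    normalize_traits,
    per_ring_battery,
    prepare_rings,
    qst,
    qst_per_trait,
    shuffle_variance_test,
    trend_test,
)
from qstfst.simdata import TRAITS

from conftest import flat_config


def vc(F=None, B=None, A=None, resid=1.0):
    terms = {}
    if F is not None:
        terms["family"] = F
    if B is not None:
        terms["site:block"] = B
    if A is not None:
        terms["cluster"] = A
    return VarianceComponents(by_term=terms, resid=resid)


# ---------------------------------------------------------------------------
# Preparation
# ---------------------------------------------------------------------------

class TestPrepareRings:
    def _table(self, rings, year=2000):
        return pd.DataFrame({
            "tree_id": "t1", "ring": rings, "year": year,
            "dbh": 1.0,
        })

    def test_rings_one_to_fifteen_keep_eleven(self):
        out, rep = prepare_rings(self._table(list(range(1, 16))))
        assert sorted(out["ring"]) == list(range(3, 14))
        assert rep["removed_innermost"] == 2
        assert rep["removed_beyond_max_ring"] == 2

    def test_already_prepared_table_unchanged(self):
        out, rep = prepare_rings(self._table(list(range(3, 14))))
        assert len(out) == 11
        assert rep["rows_in"] == rep["rows_out"]

    def test_calendar_year_cutoff(self):
        tab = self._table([5, 6, 7], year=2007)
        tab.loc[2, "year"] = 2009
        out, rep = prepare_rings(tab)
        assert rep["removed_after_cutoff_year"] == 1
        assert 7 not in out["ring"].values

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame({
            "tree_id": rng.integers(0, 20, 500),
            "ring": rng.integers(1, 20, 500),
            "year": rng.integers(2000, 2012, 500),
            "dbh": 1.0,
        })
        out, _ = prepare_rings(tab)
        expect = tab[(tab.ring > 2) & (tab.ring <= 13) & (tab.year <= 2008)]
        assert len(out) == len(expect)
        assert np.array_equal(
            out[["ring", "year"]].to_numpy(), expect[["ring", "year"]].to_numpy()
        )

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            prepare_rings(self._table([1, 2]))


class TestFilterFamilies:
    def _table(self, fam_sizes):
        rows = []
        for fam, (na, nb) in fam_sizes.items():
            for i in range(na):
                rows.append({"tree_id": f"{fam}_A{i}", "family": fam, "site": "A"})
            for i in range(nb):
                rows.append({"tree_id": f"{fam}_B{i}", "family": fam, "site": "B"})
        return pd.DataFrame(rows)

    def test_family_below_threshold_at_one_site_removed(self):
        tab = self._table({"f1": (4, 3), "f2": (4, 4)})
        out, rep = filter_families(tab)
        assert set(out["family"]) == {"f2"}
        assert rep["families_removed_offspring"] == 1

    def test_compliant_families_unchanged(self):
        tab = self._table({"f1": (4, 5), "f2": (6, 4)})
        out, _ = filter_families(tab)
        assert len(out) == len(tab)

    def test_matches_brute_force_group_count(self):
        rng = np.random.default_rng(2)
        tab = pd.DataFrame({
            "tree_id": np.arange(800),
            "family": rng.integers(0, 40, 800).astype(str),
            "site": rng.choice(["A", "B"], 800),
        })
        out, _ = filter_families(tab, min_offspring_per_site=4)
        keep = set()
        for fam in tab["family"].unique():
            sub = tab[tab.family == fam]
            counts = [len(sub[sub.site == s]) for s in ("A", "B")]
            if all(c >= 4 for c in counts):
                keep.add(fam)
        assert set(out["family"]) == keep

    def test_stand_filter_applied_when_present(self):
        tab = self._table({"f1": (4, 4), "f2": (4, 4), "f3": (4, 4)})
        tab["stand"] = np.where(tab["family"] == "f3", "s2", "s1")
        out, rep = filter_families(tab, min_families_per_stand=2)
        assert set(out["family"]) == {"f1", "f2"}
        assert rep["families_removed_stand"] == 1


class TestNormalize:
    def test_constant_trait_normalises_to_one(self):
        tab = pd.DataFrame({t: 7.0 for t in TRAITS} | {"abh": 5.0}, index=range(10))
        out = normalize_traits(tab)
        for t in TRAITS:
            assert np.allclose(out[t], 1.0)
        assert np.allclose(out["abh"], 5.0)  # ABH stays in years

    def test_grand_means_exactly_one(self, small_sim_table):
        out = normalize_traits(small_sim_table)
        for t in TRAITS:
            assert out[t].mean() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, small_sim_table):
        a = normalize_traits(small_sim_table)
        doubled = small_sim_table.copy()
        for t in TRAITS:
            doubled[t] *= 2.0
        b = normalize_traits(doubled)
        for t in TRAITS:
            assert np.allclose(a[t], b[t])

    def test_zero_mean_rejected(self):
        tab = pd.DataFrame({t: 0.0 for t in TRAITS}, index=range(3))
        with pytest.raises(ValueError):
            normalize_traits(tab)


# ---------------------------------------------------------------------------
# h2 and QST
# ---------------------------------------------------------------------------

class TestRatios:
    def test_heritability_formula(self):
        assert heritability(vc(F=0.05, B=0.0, resid=0.45)) == pytest.approx(0.40)
        assert heritability(vc(F=0.0, B=0.1, resid=0.9)) == 0.0

    def test_heritability_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            heritability(vc(F=0.0, B=0.0, resid=0.0))

    def test_qst_formula(self):
        assert qst(vc(F=0.2, A=0.1)) == pytest.approx(0.2)
        assert qst(vc(F=0.5, A=0.0)) == 0.0
        assert qst(vc(F=0.0, A=0.3)) == 1.0

    def test_qst_spitze_denominator_option(self):
        assert qst(vc(F=0.1, A=0.1), family_var_scale=8.0) == pytest.approx(1 / 9)

    def test_qst_undefined_when_both_zero(self):
        with pytest.raises(ValueError):
            qst(vc(F=0.0, A=0.0))

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        v1 = vc(F=0.03, B=0.04, A=0.02, resid=0.2)
        v2 = vc(F=0.03 * c, B=0.04 * c, A=0.02 * c, resid=0.2 * c)
        assert heritability(v1) == pytest.approx(heritability(v2), rel=1e-9)
        assert qst(v1) == pytest.approx(qst(v2), rel=1e-9)

    @given(st.floats(0.0, 1.0), st.floats(0.001, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_qst_monotone_in_cluster_variance(self, a, f):
        assert qst(vc(F=f, A=a + 0.1)) > qst(vc(F=f, A=a))


# ---------------------------------------------------------------------------
# Battery, trends, PCA, permutation
# ---------------------------------------------------------------------------

class TestBattery:
    def test_cluster_signal_detected_only_where_present(self):
        # cluster effects injected into DBH only
        cfg = flat_config(
            families_per_cluster=10, offspring_per_family_per_site=4,
            blocks_per_site=(4, 4), ring_range=(3, 6),
            var_cluster=0.0, var_family=0.05, var_block=0.02, var_resid=0.2,
            seed=21,
        )
        from qstfst.simdata import simulate_phenotypes

        tab = simulate_phenotypes(cfg)
        shift = {c: d for c, d in zip(
            sorted(tab["cluster"].unique()), np.linspace(-0.3, 0.3, 6)
        )}
        tab["dbh"] = tab["dbh"] + tab["cluster"].map(shift)
        _, summary = per_ring_battery(tab, model_id=2)
        cl = summary[summary.term == "cluster"]
        sig = cl.groupby("trait")["bonferroni_significant"].any()
        assert sig["dbh"]
        assert not sig.drop("dbh").any()

    def test_battery_row_order_invariance(self, small_sim_table):
        t1 = small_sim_table
        t2 = t1.sample(frac=1.0, random_state=3)
        _, s1 = per_ring_battery(t1, model_id=1, traits=("dbh",))
        _, s2 = per_ring_battery(t2, model_id=1, traits=("dbh",))
        m1 = s1.set_index(["trait", "ring", "term"])["chisq"].sort_index()
        m2 = s2.set_index(["trait", "ring", "term"])["chisq"].sort_index()
        assert np.allclose(m1.to_numpy(), m2.to_numpy(), rtol=1e-6)

    def test_qst_per_trait_returns_all_rings(self, small_sim_table):
        res = qst_per_trait(normalize_traits(small_sim_table), traits=("dbh",))
        r = res["dbh"]
        assert list(r.per_ring_qst.index) == [3, 4, 5, 6]
        assert 0 <= r.mean_qst <= 1
        assert r.mean_qst == pytest.approx(r.per_ring_qst.mean())


class TestTrendTest:
    def test_linear_series_detected(self):
        res = trend_test(pd.Series(np.arange(3, 14) * 0.5, index=range(3, 14)))
        assert res["slope"] == pytest.approx(0.5)
        assert res["p"] < 1e-10

    def test_reverse_flips_slope_sign(self):
        s = pd.Series([1.0, 2.0, 2.5, 4.0, 4.2], index=range(5))
        a = trend_test(s)
        b = trend_test(pd.Series(s.to_numpy()[::-1], index=range(5)))
        assert a["slope"] == pytest.approx(-b["slope"])
        assert a["t"] == pytest.approx(-b["t"])

    def test_constant_series_reported_undefined(self):
        res = trend_test(pd.Series([1.0] * 5, index=range(5)))
        assert np.isnan(res["t"])

    def test_type_one_error_calibrated_on_noise(self):
        rng = np.random.default_rng(17)
        hits = sum(
            trend_test(pd.Series(rng.normal(0, 1, 11), index=range(3, 14)))["p"] < 0.05
            for _ in range(1000)
        )
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(hits / 1000 - 0.05) < 3 * se

    def test_too_few_ages_rejected(self):
        with pytest.raises(ValueError):
            trend_test(pd.Series([1.0, 2.0]))


class TestFamilyEffectPca:
    def test_latitudinal_ordering_recovered(self):
        rng = np.random.default_rng(23)
        clusters = [f"C{i}" for i in range(6)]
        lat_means = np.linspace(-1, 1, 6)
        rows, fam_cluster = {}, {}
        for i, c in enumerate(clusters):
            for j in range(15):
                fam = f"{c}_f{j}"
                rows[fam] = lat_means[i] + rng.normal(0, 0.05, len(TRAITS))
                fam_cluster[fam] = i
        eff = pd.DataFrame.from_dict(rows, orient="index", columns=TRAITS)
        scores, pve = family_effect_pca(eff)
        cent = scores.groupby(pd.Series(fam_cluster))["PC1"].mean()
        rho = pd.Series(cent).corr(pd.Series(range(6), index=cent.index),
                                   method="spearman")
        assert abs(rho) == pytest.approx(1.0)
        assert pve.sum() <= 100.0 + 1e-9

    def test_zero_effects_rejected(self):
        eff = pd.DataFrame(0.0, index=[f"f{i}" for i in range(10)], columns=TRAITS)
        with pytest.raises(ValueError):
            family_effect_pca(eff)

    def test_fewer_families_than_traits_warns(self):
        rng = np.random.default_rng(24)
        eff = pd.DataFrame(rng.normal(0, 1, (3, 6)), columns=TRAITS)
        with pytest.warns(UserWarning, match="fewer families"):
            scores, _ = family_effect_pca(eff)
        assert scores.shape[0] == 3

    def test_blups_from_battery_feed_pca(self, small_sim_table):
        fits, _ = per_ring_battery(
            normalize_traits(small_sim_table), model_id=1,
            traits=("dbh", "wd"),
        )
        eff = family_effect_matrix(fits, traits=("dbh", "wd"))
        assert eff.shape[1] == 2
        scores, pve = family_effect_pca(eff)
        assert len(scores) == eff.shape[0]


class TestShuffleVariance:
    def _noise_table(self, seed, n_fam=20, n_per=6):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "y": rng.normal(0, 1, n_fam * n_per),
            "family": np.repeat([f"f{i}" for i in range(n_fam)], n_per),
        })

    def test_null_pvalues_average_half(self):
        ps = [
            shuffle_variance_test(self._noise_table(s), "y", "family",
                                  n_perm=150, seed=s)["p"]
            for s in range(20)
        ]
        assert 0.3 < np.mean(ps) < 0.7

    def test_strong_family_structure_hits_minimum_p(self):
        rng = np.random.default_rng(31)
        n_fam, n_per = 25, 8
        tab = pd.DataFrame({
            "y": np.repeat(rng.normal(0, 3, n_fam), n_per)
            + rng.normal(0, 0.05, n_fam * n_per),
            "family": np.repeat([f"f{i}" for i in range(n_fam)], n_per),
        })
        res = shuffle_variance_test(tab, "y", "family", n_perm=200, seed=1)
        assert res["p"] == pytest.approx(1 / 201)

    def test_shuffling_inflates_within_group_variance(self):
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            n_fam, n_per = 30, 6
            tab = pd.DataFrame({
                "y": np.repeat(rng.normal(0, 1, n_fam), n_per)
                + rng.normal(0, 1, n_fam * n_per),
                "family": np.repeat([f"f{i}" for i in range(n_fam)], n_per),
            })
            res = shuffle_variance_test(tab, "y", "family", n_perm=100, seed=s)
            assert res["perm_mean"] > res["observed"]

    def test_minimum_permutation_count_enforced(self):
        with pytest.raises(ValueError):
            shuffle_variance_test(self._noise_table(1), "y", "family", n_perm=10)


def test_cv_per_ring_matches_direct_computation(small_sim_table):
    cv = cv_per_ring(small_sim_table, "dbh")
    ring4 = small_sim_table.query("ring == 4")["dbh"]
    assert cv.loc[4] == pytest.approx(ring4.std(ddof=1) / ring4.mean())
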
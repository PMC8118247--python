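"""Bray-Curtis, covariate screen, PERMANOVA, forward selection, PERMDISP, CAP."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dietkit as dk
from dietkit.multivariate import gower_center


@pytest.fixture(scope="module")
def composition(rng):
    x = rng.dirichlet(np.ones(5) * 0.8, size=40) * 100
    return pd.DataFrame(x, index=[f"s{i}" for i in range(40)], columns=list("ABCDE"))


@pytest.fixture(scope="module")
def grouped_meta(composition, rng):
    return pd.DataFrame(
        {
            "g": ["a"] * 20 + ["b"] * 20,
            "z": rng.normal(size=40),
        },
        index=composition.index,
    )


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        comp = pd.DataFrame([[50.0, 50.0], [50.0, 50.0]])
        assert dk.bray_curtis(comp).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_rows_one(self):
        comp = pd.DataFrame([[100.0, 0.0], [0.0, 100.0]])
        assert dk.bray_curtis(comp).values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        comp = pd.DataFrame([[75.0, 25.0], [25.0, 75.0]])
        assert dk.bray_curtis(comp).values[0, 1] == pytest.approx(0.5)  # (50+50)/200

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            dk.bray_curtis(pd.DataFrame([[0.0, 0.0], [1.0, 1.0]]))

    def test_entries_in_unit_interval(self, composition):
        d = dk.bray_curtis(composition).values
        assert d.min() >= 0 and d.max() <= 1 and np.allclose(d, d.T)


class TestCovariateScreen:
    def test_duplicate_covariate_dropped(self, rng):
        x = rng.normal(size=60)
        meta = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=60)})
        retained, report = dk.covariate_screen(meta)
        assert retained == ["a", "c"]
        assert (report.loc[(report.var_a == "a") & (report.var_b == "b"), "flagged"]).all()

    def test_independent_covariates_usually_retained(self, rng):
        drops = 0
        for _ in range(50):
            meta = pd.DataFrame(rng.normal(size=(100, 2)), columns=["a", "b"])
            retained, _ = dk.covariate_screen(meta)
            drops += len(retained) < 2
        # r > 0.65 at n = 100 is far beyond chance for independent normals
        assert drops == 0

    def test_constant_covariate_dropped_with_warning(self):
        meta = pd.DataFrame({"a": [1.0] * 10, "b": np.arange(10.0), "c": np.arange(10.0) ** 2})
        with pytest.warns(UserWarning, match="constant"):
            retained, _ = dk.covariate_screen(meta)
        assert "a" not in retained


class TestPermanova:
    def test_euclidean_one_factor_equals_anova_f(self, rng):
        """With Euclidean distance on 1-D data, pseudo-F is the classical ANOVA F."""
        y = rng.normal(size=12)
        y[6:] += 1.0
        g = np.array(["a"] * 6 + ["b"] * 6)
        df = pd.DataFrame({"y": y}, index=[str(i) for i in range(12)])
        meta = pd.DataFrame({"g": g}, index=df.index)
        tab = dk.permanova(dk.euclidean_distance(df), meta, ["g"], permutations=9, seed=0)
        f_classical = stats.f_oneway(y[:6], y[6:]).statistic
        assert tab.table.loc["g", "F"] == pytest.approx(f_classical, abs=1e-9)

    def test_exact_p_matches_brute_force_enumeration(self, rng):
        """n = 6: permutation p must equal the fraction over all 720 orderings,
        recomputed by an independent classical-ANOVA oracle."""
        y = rng.normal(size=6)
        g = np.array(["a"] * 3 + ["b"] * 3)
        df = pd.DataFrame({"y": y}, index=[str(i) for i in range(6)])
        meta = pd.DataFrame({"g": g}, index=df.index)
        tab = dk.permanova(dk.euclidean_distance(df), meta, ["g"], permutations="exact")
        f_obs = stats.f_oneway(y[g == "a"], y[g == "b"]).statistic
        fs = [
            stats.f_oneway(y[list(p)][:3], y[list(p)][3:]).statistic
            for p in itertools.permutations(range(6))
        ]
        p_brute = np.mean(np.asarray(fs) >= f_obs - 1e-12)
        assert tab.table.loc["g", "p"] == pytest.approx(p_brute, abs=1e-12)

    def test_matches_skbio_one_way(self, composition, grouped_meta):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        d = dk.bray_curtis(composition)
        ours = dk.permanova(d, grouped_meta, ["g"], permutations=99, seed=0)
        sk = sk_permanova(SkDM(d.values, ids=d.ids), grouped_meta["g"].values, permutations=99)
        assert ours.table.loc["g", "F"] == pytest.approx(sk["test statistic"], abs=1e-9)

    def test_r2_and_df_partition(self, composition, grouped_meta):
        d = dk.bray_curtis(composition)
        tab = dk.permanova(d, grouped_meta, ["g", "z"], permutations=49, seed=1).table
        terms = tab.drop(index="Total")
        assert terms["r2"].sum() == pytest.approx(1.0, abs=1e-9)
        assert terms["df"].sum() == len(composition) - 1
        assert tab.loc[["g", "z"], "p"].between(1 / 50, 1.0).all()

    def test_factor_relabel_invariance(self, composition, grouped_meta):
        d = dk.bray_curtis(composition)
        relabeled = grouped_meta.assign(g=grouped_meta["g"].map({"a": "zzz", "b": "aaa"}))
        a = dk.permanova(d, grouped_meta, ["g"], permutations=99, seed=2).table
        b = dk.permanova(d, relabeled, ["g"], permutations=99, seed=2).table
        assert a.loc["g", "F"] == pytest.approx(b.loc["g", "F"], abs=1e-9)
        assert a.loc["g", "p"] == b.loc["g", "p"]

    def test_seed_reproducibility_and_p_floor(self, composition, grouped_meta):
        d = dk.bray_curtis(composition)
        a = dk.permanova(d, grouped_meta, ["g"], permutations=99, seed=3).table
        b = dk.permanova(d, grouped_meta, ["g"], permutations=99, seed=3).table
        assert a.equals(b)
        assert a.loc["g", "p"] >= 1 / 100

    def test_aliased_term_rejected(self, composition, grouped_meta):
        meta = grouped_meta.assign(g2=grouped_meta["g"])
        with pytest.raises(ValueError, match="aliased"):
            dk.permanova(dk.bray_curtis(composition), meta, ["g", "g2"], permutations=9, seed=0)


class TestForwardSelect:
    def test_planted_factor_selected_first(self, rng):
        cfg = dk.scenario("planted_location_effect")
        ds = dk.apply_exclusions(dk.simulate_diet_dataset(cfg, n_per_stratum=30, seed=4))
        comp = dk.per_stomach_proportions(ds, "number")
        meta = ds.metadata_frame(full_only=True).loc[comp.index]
        meta["noise"] = rng.normal(size=len(meta))
        res = dk.forward_select(
            dk.bray_curtis(comp), meta, ["location", "noise"], permutations=99, seed=5
        )
        assert res.order and res.order[0] == "location"
        assert res.table.index[0] == "location"  # re-ranked by F

    def test_no_signal_usually_empty(self, rng):
        hits = 0
        for i in range(20):
            comp = pd.DataFrame(rng.dirichlet(np.ones(4), size=24) * 100)
            comp.index = comp.index.astype(str)
            meta = pd.DataFrame({"noise": rng.normal(size=24)}, index=comp.index)
            res = dk.forward_select(dk.bray_curtis(comp), meta, ["noise"], permutations=99, seed=i)
            hits += bool(res.order)
        # one candidate at entry α = 0.05: inclusions should be rare
        assert hits <= 4

    def test_duplicate_candidate_never_added(self, composition, grouped_meta):
        meta = grouped_meta.assign(g_copy=grouped_meta["g"])
        res = dk.forward_select(
            dk.bray_curtis(composition), meta, ["g", "g_copy"], permutations=99, seed=6
        )
        assert "g_copy" not in res.order  # aliased → zero marginal SS


class TestPermdisp:
    def test_matches_skbio_centroid_statistic(self, rng):
        # Euclidean input: no negative eigenvalues, so the embedding convention
        # cannot differ and the statistics must agree exactly
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permdisp as sk_permdisp

        pts = pd.DataFrame(rng.normal(size=(24, 3)), index=[str(i) for i in range(24)])
        pts.iloc[12:] *= 2.0
        g = pd.Series(["a"] * 12 + ["b"] * 12, index=pts.index)
        d = dk.euclidean_distance(pts)
        ours = dk.permdisp(d, g, permutations=99, seed=0)
        sk = sk_permdisp(SkDM(d.values, ids=d.ids), g.values, permutations=99, test="centroid")
        assert ours.f == pytest.approx(sk["test statistic"], abs=1e-9)

    def test_degenerate_group_zero_dispersion(self, rng):
        pts = np.vstack([np.tile([1.0, 2.0], (6, 1)), rng.normal(size=(6, 2)) * 3])
        df = pd.DataFrame(pts, index=[str(i) for i in range(12)])
        res = dk.permdisp(
            dk.euclidean_distance(df),
            pd.Series(["dup"] * 6 + ["spread"] * 6, index=df.index),
            permutations=99,
            seed=0,
        )
        assert res.group_dispersion["dup"] == pytest.approx(0.0, abs=1e-9)
        assert res.f > 10

    def test_euclidean_embedding_matches_direct_geometry(self, rng):
        """2-D Euclidean input: distances to centroid in PCoA space equal the
        directly computed plane geometry (no embedding distortion)."""
        pts = rng.normal(size=(15, 2))
        groups = pd.Series(["a"] * 7 + ["b"] * 8)
        df = pd.DataFrame(pts, index=[str(i) for i in range(15)])
        res = dk.permdisp(dk.euclidean_distance(df), groups.set_axis(df.index),
                          permutations=49, seed=0)
        direct = {}
        for lv in ("a", "b"):
            sub = pts[(groups == lv).values]
            direct[lv] = float(np.linalg.norm(sub - sub.mean(axis=0), axis=1).mean())
        assert res.group_dispersion["a"] == pytest.approx(direct["a"], abs=1e-9)
        assert res.group_dispersion["b"] == pytest.approx(direct["b"], abs=1e-9)

    def test_single_member_group_excluded(self, composition, grouped_meta):
        g = grouped_meta["g"].copy()
        g.iloc[0] = "solo"
        with pytest.warns(UserWarning, match="size 1"):
            dk.permdisp(dk.bray_curtis(composition), g, permutations=49, seed=0)


class TestCap:
    def test_overall_f_equals_permanova_on_euclidean(self, rng):
        y = pd.DataFrame(rng.normal(size=(20, 3)), index=[str(i) for i in range(20)])
        meta = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 10}, index=y.index)
        d = dk.euclidean_distance(y)
        c = dk.cap(d, meta, ["g"], permutations=49, seed=1)
        p = dk.permanova(d, meta, ["g"], permutations=49, seed=1)
        assert c.overall_f == pytest.approx(p.table.loc["g", "F"], abs=1e-9)

    def test_two_group_discriminant_direction(self, rng):
        """One binary factor, Euclidean distance: the single canonical axis is
        the projection onto the group-mean difference direction."""
        pts = rng.normal(size=(30, 2))
        pts[15:] += [2.0, 1.0]
        df = pd.DataFrame(pts, index=[str(i) for i in range(30)])
        meta = pd.DataFrame({"g": ["a"] * 15 + ["b"] * 15}, index=df.index)
        c = dk.cap(dk.euclidean_distance(df), meta, ["g"], permutations=49, seed=1)
        assert len(c.eigenvalues) == 1
        direction = pts[15:].mean(0) - pts[:15].mean(0)
        direction /= np.linalg.norm(direction)
        proj = (pts - pts.mean(0)) @ direction
        corr = np.corrcoef(c.site_scores.iloc[:, 0], proj)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-9)

    def test_internal_consistency(self, composition, grouped_meta):
        c = dk.cap(
            dk.bray_curtis(composition),
            grouped_meta,
            ["g", "z"],
            permutations=49,
            seed=2,
            composition=composition,
        )
        assert (np.diff(c.eigenvalues) <= 1e-12).all()
        assert c.pct_variance.sum() == pytest.approx(c.explained_pct, abs=1e-9)
        assert c.species_scores is not None and c.species_scores.shape[0] == 5
        assert {"g=a", "g=b", "z"} <= set(c.variable_scores.index)

    def test_overdetermined_design_rejected(self, rng):
        y = pd.DataFrame(rng.normal(size=(4, 2)), index=[str(i) for i in range(4)])
        meta = pd.DataFrame(
            rng.normal(size=(4, 5)), columns=list("abcde"), index=y.index
        )
        with pytest.raises(ValueError):
            dk.cap(dk.euclidean_distance(y), meta, list("abcde"), permutations=9, seed=0)
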
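"""Random-structure selection, LRT backward elimination, contrasts,
correlations."""

import numpy as np
import pandas as pd
import pytest

from opsinchoice.association import (AssociationModel, droppable_terms,
                                     expand_terms, interaction_comparison,
                                     preference_expression_correlation,
                                     terms_to_formula)


class TestTermAlgebra:
    def test_star_expansion(self):
        terms = expand_terms("a*b*c")
        assert len(terms) == 7
        assert frozenset(["a", "b", "c"]) in terms
        assert terms[0] == frozenset(["a"])  # mains first

    def test_plus_and_colon(self):
        terms = expand_terms("a + b + a:b")
        assert terms == [frozenset(["a"]), frozenset(["b"]),
                         frozenset(["a", "b"])]

    def test_droppable_respects_marginality(self):
        terms = expand_terms("a*b + c")
        d = droppable_terms(terms)
        assert frozenset(["a", "b"]) in d and frozenset(["c"]) in d
        assert frozenset(["a"]) not in d  # main inside interaction

    def test_formula_build(self):
        f = terms_to_formula("y", expand_terms("a + b"), ("age",))
        assert f == "y ~ a + b + age"


def _sim_grouped(seed, n_groups=12, per_group=6, group_sd=1.0, resid_sd=0.5,
                 effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, group_sd)
        for i in range(per_group):
            light = "deep" if (g * per_group + i) % 2 else "shallow"
            y = u + (effect if light == "deep" else 0.0) \
                + rng.normal(0, resid_sd)
            rows.append({"y": y, "dam_id": f"D{g}", "sire_id": f"S{g % 4}",
                         "light": light})
    return pd.DataFrame(rows)


class TestRandomStructure:
    def test_single_candidate_kept(self):
        df = _sim_grouped(0)
        m = AssociationModel(df, "y", "light", random_candidates=("dam_id",))
        rand, cov, table = m.select_random_structure()
        assert set(table["random"]) == {"(none)", "dam_id"}
        assert rand in ((), ("dam_id",))

    def test_strong_maternal_effect_selected(self):
        """Maternal sd twice the residual sd: the dam intercept should be
        selected in nearly every replicate."""
        hits = 0
        for seed in range(20):
            df = _sim_grouped(seed, group_sd=1.0, resid_sd=0.5)
            m = AssociationModel(df, "y", "light",
                                 random_candidates=("dam_id", "sire_id"))
            rand, _, _ = m.select_random_structure()
            hits += "dam_id" in rand
        assert hits >= 18

    def test_no_grouping_signal_prefers_simplicity(self):
        hits = 0
        for seed in range(12):
            df = _sim_grouped(seed, group_sd=0.0, resid_sd=1.0)
            m = AssociationModel(df, "y", "light",
                                 random_candidates=("dam_id",))
            rand, _, _ = m.select_random_structure()
            hits += rand == ()
        assert hits >= 6  # intercept-only wins most often


class TestFixedEffects:
    def test_absent_term_refused(self):
        df = _sim_grouped(0)
        m = AssociationModel(df, "y", "light")
        res = m.fit(select_random=False, backward=False)
        with pytest.raises(ValueError):
            res.term_pvalue("species")

    def test_unknown_factor_refused(self):
        df = _sim_grouped(0)
        with pytest.raises(ValueError):
            AssociationModel(df, "y", "light*ghost")

    def test_planted_effect_retained_in_mam(self):
        """A rearing-light shift of 0.04 against residual sd 0.03 at
        n = 80 keeps the light term in the MAM in most replicates."""
        hits = 0
        for seed in range(15):
            rng = np.random.default_rng(seed)
            light = np.resize(["shallow", "deep"], 80)
            y = np.where(light == "deep", 0.04, 0.0) + rng.normal(0, 0.03, 80)
            df = pd.DataFrame({"y": y, "light": light})
            res = AssociationModel(df, "y", "light").fit()
            hits += frozenset(["light"]) in res.mam_terms
        assert hits >= 12

    def test_marginality_invariant(self):
        """No MAM contains an interaction without its main effects."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 72
            df = pd.DataFrame({
                "a": np.resize(["x", "y"], n),
                "b": np.resize(["u", "v", "w"], n),
                "y": rng.normal(size=n)})
            res = AssociationModel(df, "y", "a*b").fit()
            for t in res.mam_terms:
                if len(t) > 1:
                    for f in t:
                        assert frozenset([f]) in res.mam_terms

    def test_backward_elimination_deterministic(self):
        df = _sim_grouped(3, effect=0.5)
        r1 = AssociationModel(df, "y", "light",
                              random_candidates=("dam_id",)).fit()
        r2 = AssociationModel(df, "y", "light",
                              random_candidates=("dam_id",)).fit()
        assert r1.mam_formula == r2.mam_formula
        assert np.allclose(r1.lrt_table["p"], r2.lrt_table["p"],
                           equal_nan=True)


class TestContrasts:
    def _fit_three_level(self, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        n = 90
        sp = np.resize(["blue", "red", "hybrid"], n)
        y = np.where(sp == "red", shift, 0.0) + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "species": sp})
        return AssociationModel(df, "y", "species").fit(backward=False)

    def test_two_levels_no_adjustment(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"y": rng.normal(size=40),
                           "light": np.resize(["shallow", "deep"], 40)})
        res = AssociationModel(df, "y", "light").fit(backward=False)
        tab = res.contrasts("light")
        assert len(tab) == 1
        assert tab.loc[0, "p_adj"] == pytest.approx(tab.loc[0, "p_raw"])

    def test_adjusted_at_least_raw(self):
        tab = self._fit_three_level(2, shift=1.0).contrasts("species")
        assert len(tab) == 3
        assert (tab["p_adj"] >= tab["p_raw"] - 1e-12).all()
        assert (tab["p_adj"] <= 1.0).all()

    def test_strong_shift_detected(self):
        tab = self._fit_three_level(3, shift=2.0).contrasts("species")
        red = tab[(tab["level_1"] == "red") | (tab["level_2"] == "red")]
        assert (red["p_adj"] < 0.01).all()

    def test_within_condition_families(self):
        rng = np.random.default_rng(4)
        n = 240
        geno = np.resize(["HH", "PP", "HET"], n)
        light = np.resize(["shallow", "shallow", "shallow", "deep", "deep",
                           "deep"], n)
        shift = np.where((geno == "HH") & (light == "shallow"), 1.5,
                         np.where((geno == "PP") & (light == "shallow"),
                                  -1.5, 0.0))
        df = pd.DataFrame({"y": shift + rng.normal(0, 1, n),
                           "genotype": geno, "test_light": light})
        res = AssociationModel(df, "y", "genotype*test_light").fit(
            backward=False)
        tab = res.contrasts("genotype", by="test_light")
        sh = tab[(tab["by"] == "shallow") & (tab["level_1"] == "HH")
                 & (tab["level_2"] == "PP")]
        dp = tab[(tab["by"] == "deep") & (tab["level_1"] == "HH")
                 & (tab["level_2"] == "PP")]
        assert sh["p_adj"].iloc[0] < 0.001
        assert dp["p_adj"].iloc[0] > 0.05

    def test_factor_not_in_mam_refused(self):
        res = self._fit_three_level(5)
        with pytest.raises(ValueError):
            res.contrasts("light")


class TestCorrelation:
    def _tables(self, x, y):
        means = pd.DataFrame({"female_id": [f"F{i}" for i in range(len(x))],
                              "mean_pref_Q": y})
        profiles = pd.DataFrame({"sample": [f"F{i}" for i in range(len(x))],
                                 "prop_LWS": x})
        return means, profiles

    def test_perfect_linear(self):
        x = np.linspace(0.1, 0.4, 10)
        means, profiles = self._tables(x, 2 * x - 0.1)
        tab = preference_expression_correlation(means, profiles,
                                                genes=("LWS",))
        assert tab.loc[0, "r"] == pytest.approx(1.0)
        assert tab.loc[0, "df"] == 8

    def test_anti_linear(self):
        x = np.linspace(0.1, 0.4, 10)
        means, profiles = self._tables(x, -x)
        tab = preference_expression_correlation(means, profiles,
                                                genes=("LWS",))
        assert tab.loc[0, "r"] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        means, profiles = self._tables(np.full(8, 0.3), np.arange(8.0))
        tab = preference_expression_correlation(means, profiles,
                                                genes=("LWS",))
        assert tab.loc[0, "flag"] == "zero_variance"

    def test_moderate_correlation_recovered(self):
        """True rho = 0.35 at n = 25 (the study's pairing size) is
        recovered on average across replicates."""
        rho, n = 0.35, 25
        rng = np.random.default_rng(99)
        rs = []
        for _ in range(300):
            x = rng.normal(size=n)
            y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
            means, profiles = self._tables(x, y)
            tab = preference_expression_correlation(means, profiles,
                                                    genes=("LWS",))
            rs.append(tab.loc[0, "r"])
        assert abs(np.mean(rs) - rho) < 0.03


class TestInteractionComparison:
    def test_confounded_refused(self):
        df = pd.DataFrame({
            "pref_LD": np.random.default_rng(0).normal(size=40),
            "genotype": np.resize(["HH", "PP"], 40),
            "species": np.resize(["red", "blue"], 40),
            "test_light": np.resize(["shallow", "shallow", "deep", "deep"],
                                    40),
            "female_id": [f"F{i % 10}" for i in range(40)]})
        with pytest.raises(ValueError, match="confounded"):
            interaction_comparison(df)

    def test_reports_both_interactions(self):
        rng = np.random.default_rng(1)
        females = []
        for i in range(30):
            geno = ["HH", "PP", "HET"][i % 3]
            species = {"HH": "red", "PP": "blue",
                       "HET": ["red", "hybrid"][i % 2]}[geno]
            females.append((f"F{i:02d}", geno, species))
        rows = []
        for fid, geno, species in females:
            for j in range(4):
                rows.append({"pref_LD": rng.normal(), "genotype": geno,
                             "species": species,
                             "test_light": ["shallow", "deep"][j % 2],
                             "female_id": fid})
        df = pd.DataFrame(rows)
        tab = interaction_comparison(df)
        assert list(tab["interaction"]) == ["genotype:test_light",
                                            "species:test_light"]
        assert tab["p"].between(0, 1).all()
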
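"""Matched-resampling null, branch deviations, empirical p and q values."""

import numpy as np
import pandas as pd
import pytest

from riskdrift import (
    DiseasePanel,
    PopulationTree,
    RiskDifferentiationModel,
    SimulationConfig,
    branch_empirical_p,
    branch_qvalues,
    cohort_risks,
    draw_null_panel,
    observed_branch_deviations,
    simulate_cohort,
)
from riskdrift.differentiation import _null_pvalues

from conftest import make_genotypes, make_panel_snp


# ----------------------------------------------------------------------
# observed deviations
# ----------------------------------------------------------------------

class TestObservedDeviations:
    def test_two_leaf_contrast(self):
        tree = PopulationTree.from_newick("(A,B);")
        risks = pd.DataFrame(
            {"individual": ["a1", "a2", "b1", "b2"],
             "population": ["A", "A", "B", "B"],
             "risk": [1.0, 1.0, 0.0, 0.0]}
        )
        obs = observed_branch_deviations(tree, risks)
        assert obs["B"] == pytest.approx(1.0)  # ancestral (A) minus descendant (B)

    def test_equal_risks_give_zero_everywhere(self):
        tree = PopulationTree.from_newick("((A,B),(C,D));")
        risks = pd.DataFrame(
            {"individual": [f"i{k}" for k in range(8)],
             "population": list("AABBCCDD"),
             "risk": [0.7] * 8}
        )
        obs = observed_branch_deviations(tree, risks)
        assert (obs.abs() < 1e-12).all()

    def test_hand_computed_four_leaf_fixture(self):
        """12 individuals with hand-set risks; individual-weighted means."""
        tree = PopulationTree.from_newick("((A,B),(C,D));")
        risks = pd.DataFrame(
            {
                "individual": [f"i{k}" for k in range(12)],
                "population": list("AAABBBCCCDDD"),
                "risk": [1, 2, 3, 4, 4, 4, 0, 0, 3, 1, 1, 1],
            }
        )
        obs = observed_branch_deviations(tree, risks)
        # branch above A: ancestral = B,C,D mean 2, descendant = A mean 2
        assert obs["A"] == pytest.approx(2.0 - 2.0)
        # branch above C: ancestral = A,B,D mean 21/9, descendant = C mean 1
        assert obs["C"] == pytest.approx(21 / 9 - 1.0)
        # root child A|B: ancestral = C,D mean 1, descendant mean 3
        assert obs["A|B"] == pytest.approx(1.0 - 3.0)


# ----------------------------------------------------------------------
# empirical p-values
# ----------------------------------------------------------------------

class TestEmpiricalP:
    def test_fifteen_in_hundred_thousand(self):
        row = np.concatenate([np.full(15, 2.0), np.zeros(99_985)])
        p, direction = branch_empirical_p(1.0, row)
        assert p == pytest.approx(1.5e-4)
        assert direction == "decreased"

    def test_zero_exceedances_floor_at_one_over_k(self):
        row = np.zeros(100_000)
        p, _ = branch_empirical_p(1.0, row)
        assert p == pytest.approx(1.0e-5)

    def test_observed_at_null_median_is_central(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=10_001)
        p, _ = branch_empirical_p(float(np.median(row)), row)
        assert 0.45 < p < 0.55

    def test_negative_observed_uses_lower_tail(self):
        row = np.concatenate([np.full(10, -2.0), np.zeros(990)])
        p, direction = branch_empirical_p(-1.0, row)
        assert p == pytest.approx(0.01)
        assert direction == "increased"

    def test_two_sided_doubles_smaller_tail(self):
        row = np.concatenate([np.full(10, 2.0), np.zeros(990)])
        p1, _ = branch_empirical_p(1.0, row, alternative="one-sided")
        p2, _ = branch_empirical_p(1.0, row, alternative="two-sided")
        assert p2 == pytest.approx(min(1.0, 2 * p1))

    def test_floor_is_exactly_one_over_k(self):
        for k in (50, 1000):
            p, _ = branch_empirical_p(10.0, np.zeros(k))
            assert p == 1.0 / k


# ----------------------------------------------------------------------
# q-values
# ----------------------------------------------------------------------

class TestQValues:
    def test_all_p_one_caps_at_one(self):
        null = np.random.default_rng(0).normal(size=(3, 200))
        null_p = _null_pvalues(null, "one-sided")
        q = branch_qvalues(np.ones(3), null_p)
        assert (q == 1.0).all()

    def test_brute_force_expected_count_on_small_matrix(self):
        """q equals a literal loop over stored null rows at K=100."""
        rng = np.random.default_rng(5)
        null = rng.normal(size=(2, 100))
        null_p = _null_pvalues(null, "one-sided")
        observed_p = np.array([0.03, 0.5])
        q = branch_qvalues(observed_p, null_p)
        for i, alpha in enumerate(observed_p):
            n_obs = int((observed_p <= alpha).sum())
            e_null = np.mean([(null_p[:, k] <= alpha).sum() for k in range(100)])
            assert q[i] == pytest.approx(min(1.0, e_null / n_obs))

    def test_null_p_respects_floor_and_self_count(self):
        null = np.random.default_rng(1).normal(size=(1, 50))
        null_p = _null_pvalues(null, "one-sided")
        assert (null_p >= 1 / 50).all()
        assert (null_p <= 1.0).all()

    def test_q_monotone_in_alpha_at_fixed_counts(self):
        """Smaller alpha cannot raise q while N stays constant."""
        rng = np.random.default_rng(2)
        null_p = _null_pvalues(rng.normal(size=(1, 500)), "one-sided")
        alphas = np.array([0.01, 0.05, 0.2])
        qs = [branch_qvalues(np.array([a]), null_p)[0] for a in alphas]
        assert qs[0] <= qs[1] <= qs[2]


# ----------------------------------------------------------------------
# matched pools and null draws
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_model(small_cohort):
    c = small_cohort
    return RiskDifferentiationModel(c.genotypes, c.panel, c.tree, c.annotations)


class TestMatchedPool:
    def test_candidates_share_bin_category_and_exclude_self(self, small_model,
                                                            small_cohort):
        ann = small_cohort.annotations.set_index("snp_id")
        for snp in small_cohort.panel:
            cands = small_model.matched_pool(snp.snp_id)
            assert snp.snp_id not in cands
            cat = ann.loc[snp.snp_id, "functional_category"]
            b = int((1 - ann.loc[snp.snp_id, "global_maf"]) / 0.02 + 1e-9)
            for cand in cands:
                assert ann.loc[cand, "functional_category"] == cat
                assert int((1 - ann.loc[cand, "global_maf"]) / 0.02 + 1e-9) == b

    def test_counts_match_direct_enumeration(self, small_model, small_cohort):
        ann = small_cohort.annotations.set_index("snp_id")
        snp = small_cohort.panel.snps[0]
        cands = small_model.matched_pool(snp.snp_id)
        maf = ann.loc[snp.snp_id, "global_maf"]
        cat = ann.loc[snp.snp_id, "functional_category"]
        brute = ann[
            (ann["functional_category"] == cat)
            & (((1 - ann["global_maf"]) / 0.02 + 1e-9).astype(int)
               == int((1 - maf) / 0.02 + 1e-9))
        ].index.difference([snp.snp_id])
        assert sorted(cands) == sorted(brute)

    def test_category_stripped_from_pool_errors(self, small_cohort):
        c = small_cohort
        snp = c.panel.snps[0]
        cat = snp.annotation.functional_category
        stripped = c.annotations[
            (c.annotations["functional_category"] != cat)
            | (c.annotations["snp_id"] == snp.snp_id)
        ]
        model = RiskDifferentiationModel(c.genotypes, c.panel, c.tree, stripped)
        with pytest.raises(ValueError, match=snp.snp_id):
            model.matched_pool(snp.snp_id)


class TestDrawNullPanel:
    def test_singleton_pools_are_deterministic(self, small_cohort):
        pools = {s: [f"only_{s}"] for s in small_cohort.panel.snp_ids}
        rng = np.random.default_rng(0)
        drawn = draw_null_panel(small_cohort.panel, pools, rng)
        assert drawn == [f"only_{s}" for s in small_cohort.panel.snp_ids]

    def test_same_seed_same_panel(self, small_model, small_cohort):
        pools = {s.snp_id: small_model.matched_pool(s.snp_id)
                 for s in small_cohort.panel}
        d1 = draw_null_panel(small_cohort.panel, pools,
                             np.random.default_rng(9))
        d2 = draw_null_panel(small_cohort.panel, pools,
                             np.random.default_rng(9))
        assert d1 == d2

    def test_draws_are_uniform_over_candidates(self, small_model, small_cohort):
        snp = small_cohort.panel.snps[0]
        pool = small_model.matched_pool(snp.snp_id)
        rng = np.random.default_rng(3)
        counts = {c: 0 for c in pool}
        n = 10_000
        for _ in range(n):
            counts[pool[int(rng.integers(len(pool)))]] += 1
        expected = n / len(pool)
        # 5 sigma band per candidate
        band = 5 * np.sqrt(expected * (1 - 1 / len(pool)))
        assert all(abs(v - expected) < band for v in counts.values())


# ----------------------------------------------------------------------
# the null matrix against an independent reimplementation
# ----------------------------------------------------------------------

def _score_replaced_panel(cohort, replacement_ids):
    """From-scratch risk scoring of a replaced panel, pure pandas/python.

    Replacements inherit the original SNP's L; the risk allele maps to the
    counted (minor) allele when the original's risk allele was counted,
    otherwise to the other allele.
    """
    gm = cohort.genotypes
    rows = []
    for i, ind in enumerate(gm.individuals):
        r = 0.0
        for orig, rep in zip(cohort.panel, replacement_ids):
            call = gm.calls[i, gm.snp_ids.index(rep)]
            if call == -1:
                continue
            risk_counted = orig.risk_allele == gm.counted_allele[orig.snp_id]
            dosage = call if risk_counted else 2 - call
            r += np.log(orig.effect.L[int(dosage)])
        rows.append({"individual": ind, "population": gm.populations[i],
                     "risk": r})
    return pd.DataFrame(rows)


class TestNullMatrix:
    def test_columns_equal_observed_deviations_of_drawn_panels(self, small_cohort):
        """Each stored draw recomputes, from scratch, to its null column."""
        c = small_cohort
        model = RiskDifferentiationModel(c.genotypes, c.panel, c.tree,
                                         c.annotations)
        null = model.build_null_matrix(draws=3, seed=21)
        for k in range(3):
            risks = _score_replaced_panel(c, null.draw_snp_ids[k])
            obs = observed_branch_deviations(c.tree, risks)
            expected = obs.reindex(null.branch_ids).to_numpy()
            assert np.allclose(expected, null.values[:, k], atol=1e-12)

    def test_rows_are_correlated_across_branches(self, small_cohort):
        """Shared draws induce correlation between nested branches."""
        c = small_cohort
        model = RiskDifferentiationModel(c.genotypes, c.panel, c.tree,
                                         c.annotations)
        null = model.build_null_matrix(draws=400, seed=8)
        ids = null.branch_ids
        # pick a parent and one of its children among tested branches
        by_id = {b.id: b for b in c.tree.tested_branches()}
        pair = None
        for b in by_id.values():
            if b.parent in by_id:
                pair = (b.id, b.parent)
                break
        assert pair is not None
        r = np.corrcoef(null.values[ids.index(pair[0])],
                        null.values[ids.index(pair[1])])[0, 1]
        assert r > 0.2

    def test_same_seed_gives_identical_fit(self, small_cohort):
        c = small_cohort
        model = RiskDifferentiationModel(c.genotypes, c.panel, c.tree,
                                         c.annotations)
        r1 = model.fit(draws=200, seed=4)
        r2 = model.fit(draws=200, seed=4)
        pd.testing.assert_frame_equal(r1.branch_table, r2.branch_table)
        assert (r1.null_matrix.values == r2.null_matrix.values).all()
        r3 = model.fit(draws=200, seed=5)
        assert not (r1.null_matrix.values == r3.null_matrix.values).all()


# ----------------------------------------------------------------------
# population-vs-rest and fit options
# ----------------------------------------------------------------------

class TestPopulationVsRest:
    def test_population_identical_to_rest_is_central(self):
        """With zero drift every population matches the rest of the world."""
        cohort = simulate_cohort(
            SimulationConfig(n_populations=4, n_individuals_per_pop=25,
                             n_pool_snps=400, panel_size=6, drift_f=0.0,
                             seed=13)
        )
        model = RiskDifferentiationModel(cohort.genotypes, cohort.panel,
                                         cohort.tree, cohort.annotations,
                                         maf_bin_width=0.2)
        res = model.fit_population(cohort.tree.leaves[0], draws=400, seed=1)
        row = res.branch_table.iloc[0]
        assert abs(row["observed"]) < 0.2
        assert row["p_value"] > 0.05

    def test_injected_leaf_event_detected_with_direction(self, balanced_tree8):
        cfg = SimulationConfig(seed=31, tree=balanced_tree8,
                               injected_events=(("POP05", 0.15),))
        c = simulate_cohort(cfg)
        model = RiskDifferentiationModel(c.genotypes, c.panel, c.tree,
                                         c.annotations)
        res = model.fit_population("POP05", draws=1000, seed=2)
        row = res.branch_table.iloc[0]
        assert row["direction"] == "increased"
        assert row["p_value"] < 0.05
        assert res.population_risks["POP05"] > res.population_risks.drop("POP05").mean()


class TestFitOptions:
    def test_remove_outliers_excludes_planted_individual(self, small_cohort):
        c = small_cohort
        gm = c.genotypes
        # plant an extreme outlier: all homozygous risk in one individual
        calls = gm.calls.copy()
        cols = [gm.snp_ids.index(s) for s in c.panel.snp_ids]
        risk_counted = [
            s.risk_allele == gm.counted_allele[s.snp_id] for s in c.panel
        ]
        calls[0, cols] = [2 if rc else 0 for rc in risk_counted]
        from riskdrift import GenotypeMatrix

        gm2 = GenotypeMatrix(list(gm.individuals), list(gm.populations),
                             list(gm.snp_ids), calls,
                             dict(gm.counted_allele))
        model = RiskDifferentiationModel(gm2, c.panel, c.tree, c.annotations)
        res = model.fit(draws=100, seed=0, remove_outliers=True)
        assert gm.individuals[0] in res.removed_outliers

    def test_fully_flagged_pool_matches_unrestricted_run(self, small_cohort):
        c = small_cohort
        flagged = c.annotations.copy()
        flagged["phenotype_associated"] = True
        m_all = RiskDifferentiationModel(c.genotypes, c.panel, c.tree, flagged)
        r_all = m_all.fit(draws=150, seed=6, pool="all")
        r_flag = m_all.fit(draws=150, seed=6, pool="phenotype-associated")
        pd.testing.assert_frame_equal(r_all.branch_table, r_flag.branch_table)

    def test_unflagged_pool_errors(self, small_cohort):
        c = small_cohort
        unflagged = c.annotations.copy()
        unflagged["phenotype_associated"] = False
        model = RiskDifferentiationModel(c.genotypes, c.panel, c.tree,
                                         unflagged)
        with pytest.raises(ValueError, match="phenotype-associated"):
            model.fit(draws=10, seed=0, pool="phenotype-associated")

    def test_shuffling_columns_leaves_p_unchanged(self, small_cohort):
        """Draws are exchangeable: p depends only on the set of deviations."""
        c = small_cohort
        model = RiskDifferentiationModel(c.genotypes, c.panel, c.tree,
                                         c.annotations)
        res = model.fit(draws=300, seed=12)
        rng = np.random.default_rng(0)
        perm = rng.permutation(300)
        for i in range(len(res.branch_table)):
            o = res.branch_table["observed"].iloc[i]
            p1, _ = branch_empirical_p(o, res.null_matrix.values[i])
            p2, _ = branch_empirical_p(o, res.null_matrix.values[i][perm])
            assert p1 == p2
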
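import itertools

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_cohort
from morbnet.association import (EdgeRecord, PairwiseAssociation, all_pairs,
                                 benjamini_hochberg, filter_edges,
                                 fit_age_adjusted_logistic, irls_logistic)
from morbnet.codebook import CODES, Cohort
from morbnet.synthetic import pair_logistic_cohort


def two_by_two_cohort(a, b, c, d, ages=None):
    """Cohort realizing exposure/outcome cell counts a=(1,1), b=(1,0),
    c=(0,1), d=(0,0)."""
    rows = ([(1, 1)] * a + [(1, 0)] * b + [(0, 1)] * c + [(0, 0)] * d)
    ind = np.zeros((len(rows), 16), int)
    for i, (e, o) in enumerate(rows):
        ind[i, CODES.index("HYP")] = e
        ind[i, CODES.index("DM")] = o
    return make_cohort(ind, ages=ages)


class TestSingleFit:
    def test_balanced_null_design_gives_or_one(self):
        cohort = two_by_two_cohort(10, 10, 10, 10)
        assoc = fit_age_adjusted_logistic(cohort, "DM", "HYP")
        assert assoc.or_adj == pytest.approx(1.0, abs=1e-8)

    def test_constant_age_matches_cross_product_ratio(self):
        # a=20, b=10, c=5, d=10 -> OR = ad/bc = 4; constant age makes the
        # adjustment vacuous
        assoc = fit_age_adjusted_logistic(two_by_two_cohort(20, 10, 5, 10),
                                          "DM", "HYP")
        assert assoc.converged
        assert assoc.or_adj == pytest.approx(4.0, rel=1e-6)

    def test_random_tables_match_cross_product(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a, b, c, d = rng.integers(3, 60, size=4)
            assoc = fit_age_adjusted_logistic(
                two_by_two_cohort(int(a), int(b), int(c), int(d)), "DM", "HYP")
            assert assoc.or_adj == pytest.approx(a * d / (b * c), rel=1e-6)

    def test_matches_statsmodels_on_random_cohorts(self):
        """IRLS coefficients and Wald SEs equal an independent optimizer
        (statsmodels GLM) to 1e-6 on 50 random small cohorts."""
        rng = np.random.default_rng(1)
        for trial in range(50):
            n = int(rng.integers(60, 200))
            x = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(float)
            age = rng.uniform(45, 90, n)
            logit = rng.normal(0, 0.5) + rng.normal(0, 0.7) * x \
                + rng.normal(0, 0.02) * (age - 60)
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
            if y.min() == y.max() or x.min() == x.max():
                continue
            w = rng.lognormal(0, 0.4, n)
            X = np.column_stack([np.ones(n), x, age - 60])
            beta, se, conv, _ = irls_logistic(X, y, weights=w)
            ref = sm.GLM(y, X, family=sm.families.Binomial(),
                         freq_weights=w).fit(tol=1e-12)
            if not conv or np.abs(beta).max() > 10:
                continue
            np.testing.assert_allclose(beta, ref.params, atol=1e-6)
            np.testing.assert_allclose(se, ref.bse, atol=1e-6, rtol=1e-6)

    def test_recovers_known_adjusted_or(self):
        cohort = pair_logistic_cohort(50_000, p_exposure=0.3, beta0=-0.85,
                                      beta_exp=np.log(2), beta_age=0.03, seed=5)
        assoc = fit_age_adjusted_logistic(cohort, "DM", "HYP")
        assert 1.9 <= assoc.or_adj <= 2.1

    def test_unweighted_flag_ignores_weights(self):
        cohort = two_by_two_cohort(20, 10, 5, 10)
        cohort.df["weight"] = np.linspace(0.5, 2.0, len(cohort.df))
        weighted = fit_age_adjusted_logistic(cohort, "DM", "HYP", use_weights=True)
        unweighted = fit_age_adjusted_logistic(cohort, "DM", "HYP", use_weights=False)
        assert unweighted.or_adj == pytest.approx(4.0, rel=1e-6)
        assert weighted.or_adj != pytest.approx(4.0, rel=1e-4)

    def test_robust_se_matches_statsmodels_sandwich(self):
        rng = np.random.default_rng(2)
        n = 400
        x = (rng.random(n) < 0.4).astype(float)
        age = rng.uniform(45, 80, n)
        y = (rng.random(n) < 0.35).astype(float)
        X = np.column_stack([np.ones(n), x, age - 60])
        _, se, conv, _ = irls_logistic(X, y, robust=True)
        assert conv
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit(cov_type="HC0")
        np.testing.assert_allclose(se, ref.bse, rtol=1e-5)

    def test_perfect_separation_flagged(self):
        assoc = fit_age_adjusted_logistic(two_by_two_cohort(20, 0, 0, 20),
                                          "DM", "HYP")
        assert not assoc.converged
        assert np.isnan(assoc.or_adj)

    def test_degenerate_exposure_raises(self):
        cohort = two_by_two_cohort(10, 10, 0, 0)  # HYP all 1
        with pytest.raises(ValueError, match="degenerate"):
            fit_age_adjusted_logistic(cohort, "DM", "HYP")

    def test_same_disease_raises(self, tiny_cohort):
        with pytest.raises(ValueError):
            fit_age_adjusted_logistic(tiny_cohort, "HYP", "HYP")


@pytest.fixture(scope="module")
def random_cohort():
    rng = np.random.default_rng(17)
    ind = (rng.random((600, 16)) < 0.35).astype(int)
    return make_cohort(ind, ages=rng.uniform(45, 90, 600),
                       weights=rng.lognormal(0, 0.3, 600))


class TestAllPairs:
    def test_one_record_per_unordered_pair(self, random_cohort):
        assocs = all_pairs(random_cohort)
        assert len(assocs) == 120
        pairs = [(a.outcome, a.exposure) for a in assocs]
        assert pairs == list(itertools.combinations(CODES, 2))

    def test_all_zero_disease_flags_its_pairs(self, random_cohort):
        df = random_cohort.df.copy()
        df["CA"] = 0
        assocs = all_pairs(Cohort(df))
        bad = [a for a in assocs if "CA" in (a.outcome, a.exposure)]
        good = [a for a in assocs if "CA" not in (a.outcome, a.exposure)]
        assert len(bad) == 15 and not any(a.converged for a in bad)
        assert len(good) == 105 and all(a.converged for a in good)

    def test_record_shuffle_invariance(self, random_cohort):
        shuffled = Cohort(random_cohort.df.sample(frac=1, random_state=3)
                          .reset_index(drop=True))
        for a, b in zip(all_pairs(random_cohort), all_pairs(shuffled)):
            assert a.or_adj == pytest.approx(b.or_adj, rel=1e-9)
            assert a.p_value == pytest.approx(b.p_value, rel=1e-9)

    def test_geomean_symmetrization(self, random_cohort):
        assocs = {(a.outcome, a.exposure): a for a in all_pairs(random_cohort)}
        one = fit_age_adjusted_logistic(random_cohort, "DM", "HYP")
        other = fit_age_adjusted_logistic(random_cohort, "HYP", "DM")
        sym = assocs[("DM", "HYP")]
        assert sym.or_adj == pytest.approx(np.sqrt(one.or_adj * other.or_adj))
        assert sym.p_value == pytest.approx(max(one.p_value, other.p_value))

    def test_first_orientation_matches_single_fit(self, random_cohort):
        assocs = all_pairs(random_cohort, orientation="first")
        single = fit_age_adjusted_logistic(random_cohort, "CA", "AS")
        first = next(a for a in assocs if {a.outcome, a.exposure} == {"AS", "CA"})
        assert first.or_adj == pytest.approx(single.or_adj)


class TestFilterEdges:
    def _assoc(self, or_adj, p, converged=True):
        return PairwiseAssociation("AS", "CA", or_adj, 0.1, p, converged)

    @pytest.mark.parametrize("or_adj, p, included", [
        (1.2, 0.04, True),    # OR boundary is inclusive
        (0.8, 0.001, False),  # negative association excluded
        (3.0, 0.06, False),   # non-significant excluded
        (3.0, 0.05, False),   # p boundary is exclusive
        (1.1999, 0.001, False),
    ])
    def test_boundary_semantics(self, or_adj, p, included):
        (edge,) = filter_edges([self._assoc(or_adj, p)])
        assert edge.included is included

    def test_nonconverged_never_included(self):
        (edge,) = filter_edges([self._assoc(np.nan, np.nan, converged=False)])
        assert not edge.included

    @given(st.floats(1.0, 3.0), st.floats(0.001, 0.2))
    def test_monotone_in_thresholds(self, or_min, alpha):
        rng = np.random.default_rng(5)
        assocs = [self._assoc(float(o), float(p))
                  for o, p in zip(rng.uniform(0.5, 4, 40), rng.uniform(0, 0.2, 40))]
        base = {i for i, e in enumerate(filter_edges(assocs, 1.2, 0.05)) if e.included}
        tighter = {i for i, e in enumerate(
            filter_edges(assocs, max(1.2, or_min), min(0.05, alpha))) if e.included}
        assert tighter <= base

    def test_bh_is_more_conservative(self):
        rng = np.random.default_rng(6)
        assocs = [self._assoc(2.0, float(p)) for p in rng.uniform(0, 0.1, 30)]
        raw = sum(e.included for e in filter_edges(assocs))
        bh = sum(e.included for e in filter_edges(assocs, bh=True))
        assert bh <= raw

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, 50)
        ours = benjamini_hochberg(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(ours, ref, atol=1e-12)
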
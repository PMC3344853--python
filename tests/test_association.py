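"""Growth summaries, allele-count regression, permutation P, BH-FDR,
unrelated sampling and mitochondrial haplotypes."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pooldiff.association import (
    allele_count_regression,
    bh_fdr,
    build_mt_haplotypes,
    cv,
    empirical_p,
    haplotype_association,
    sample_unrelated,
    sgr,
)
from pooldiff.types import DegenerateDesignError
from .conftest import make_genotypes, make_pedigree


class TestGrowthSummaries:
    def test_sgr_doubling(self):
        # 100 g -> 200 g over the 170 -> 218 d interval
        assert sgr(100, 200, 170, 218) == pytest.approx(100 * math.log(2) / 48)
        assert sgr(100, 200, 170, 218) == pytest.approx(1.444, abs=1e-3)

    def test_sgr_equal_weights_zero(self):
        assert sgr(150, 150, 170, 218) == 0.0

    @pytest.mark.parametrize("args", [(100, 200, 218, 218), (0, 200, 170, 218),
                                      (100, -1, 170, 218)])
    def test_sgr_invalid_inputs(self, args):
        with pytest.raises(ValueError):
            sgr(*args)

    def test_cv_definition(self):
        x = [75, 100, 125]
        assert cv(x) == pytest.approx(np.std(x, ddof=1) / 100)

    def test_cv_constant_zero(self):
        assert cv([5, 5, 5]) == 0.0

    @pytest.mark.parametrize("values", [[7], [1, -1]])
    def test_cv_invalid(self, values):
        with pytest.raises(ValueError):
            cv(values)


def ols_oracle(y, x):
    """Closed-form simple OLS: slope, t, two-sided P, R^2."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = len(y)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    b = sxy / sxx
    a = y.mean() - b * x.mean()
    resid = y - a - b * x
    sse = (resid**2).sum()
    df = n - 2
    se = math.sqrt(sse / df / sxx)
    t = b / se
    p = 2 * stats.t.sf(abs(t), df)
    r2 = 1 - sse / ((y - y.mean()) ** 2).sum()
    return b, t, p, r2


class TestRegression:
    Y = [10.0, 12.0, 13.5, 15.0, 18.0, 19.5]
    X = [0, 0, 1, 1, 2, 2]

    def test_matches_closed_form_oracle(self):
        res = allele_count_regression(self.Y, self.X)
        b, t, p, r2 = ols_oracle(self.Y, self.X)
        assert res.slope == pytest.approx(b, abs=1e-10)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.p_asymptotic == pytest.approx(p, abs=1e-10)
        assert res.r2 == pytest.approx(r2, abs=1e-10)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        fit = sm.OLS(self.Y, sm.add_constant(np.asarray(self.X, float))).fit()
        res = allele_count_regression(self.Y, self.X)
        assert res.slope == pytest.approx(fit.params[1], abs=1e-10)
        assert res.t == pytest.approx(fit.tvalues[1], abs=1e-8)
        assert res.p_asymptotic == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_r2_internal_identity(self, rng):
        """R^2 = t^2 / (t^2 + df) for simple regression."""
        for _ in range(20):
            y = rng.normal(size=12)
            x = rng.integers(0, 3, size=12).astype(float)
            if np.ptp(x) == 0:
                continue
            res = allele_count_regression(y, x)
            df = res.n - 2
            assert res.r2 == pytest.approx(res.t**2 / (res.t**2 + df), abs=1e-10)

    def test_constant_phenotype(self):
        res = allele_count_regression([5.0] * 6, self.X)
        assert (res.slope, res.t, res.p_asymptotic) == (0.0, 0.0, 1.0)

    def test_constant_dosage_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            allele_count_regression(self.Y, [1] * 6)

    def test_perfect_collinearity_flagged(self):
        y = [2.0 * x + 1.0 for x in self.X]
        res = allele_count_regression(y, self.X)
        assert res.r2 == pytest.approx(1.0)
        assert res.degenerate_se

    def test_missing_pairs_dropped_listwise(self):
        y = self.Y + [99.0]
        x = self.X + [np.nan]
        res = allele_count_regression(y, x)
        assert res.n == 6
        assert res.slope == pytest.approx(ols_oracle(self.Y, self.X)[0])

    def test_slope_sign_flips_under_allele_relabel(self):
        res = allele_count_regression(self.Y, self.X)
        flipped = allele_count_regression(self.Y, [2 - x for x in self.X])
        assert flipped.slope == pytest.approx(-res.slope)
        assert flipped.p_asymptotic == pytest.approx(res.p_asymptotic)

    def test_covariate_adjustment_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 40
        x = rng.integers(0, 3, size=n).astype(float)
        z = rng.normal(size=n)
        y = 0.8 * x + 1.5 * z + rng.normal(size=n)
        res = allele_count_regression(y, x, covariates=z)
        X = sm.add_constant(np.column_stack([x, z]))
        fit = sm.OLS(y, X).fit()
        assert res.slope == pytest.approx(fit.params[1], abs=1e-10)
        assert res.t == pytest.approx(fit.tvalues[1], abs=1e-8)


class TestEmpiricalP:
    def test_constant_phenotype_p_one(self):
        p, _ = empirical_p([5.0] * 8, [0, 1, 2, 0, 1, 2, 0, 1], k=99, seed=1)
        assert p == 1.0

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=30)
        x = rng.integers(0, 3, size=30).astype(float)
        p1, _ = empirical_p(y, x, k=999, seed=7)
        p2, _ = empirical_p(y, x, k=999, seed=7)
        assert p1 == p2

    def test_bounds(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=30)
        x = rng.integers(0, 3, size=30).astype(float)
        k = 499
        p, res = empirical_p(y, x, k=k, seed=3)
        assert 1 / (k + 1) <= p <= 1.0
        assert res.n_permutations == k

    def test_agrees_with_asymptotic_for_normal_y(self):
        rng = np.random.default_rng(6)
        n, k = 200, 20_000
        x = rng.integers(0, 3, size=n).astype(float)
        y = 0.12 * x + rng.normal(size=n)
        p_emp, res = empirical_p(y, x, k=k, seed=11)
        se = math.sqrt(res.p_asymptotic * (1 - res.p_asymptotic) / k)
        assert abs(p_emp - res.p_asymptotic) < 3 * se + 1 / (k + 1)

    def test_within_family_scheme_permutes_within_families(self):
        ped = make_pedigree({"famA": ["a1", "a2", "a3"], "famB": ["b1", "b2", "b3"]})
        samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        # dosage separates families perfectly; within-family shuffles
        # cannot break that separation, so the family signal is null-proof
        y = [1.0, 2.0, 3.0, 11.0, 12.0, 13.0]
        x = [0, 0, 0, 2, 2, 2]
        p, _ = empirical_p(y, x, k=199, scheme="within_family",
                           sample_ids=samples, ped=ped, seed=13)
        assert p == 1.0  # every within-family permutation gives |t| >= observed

    def test_family_scheme_without_pedigree_is_error(self):
        with pytest.raises(ValueError, match="pedigree"):
            empirical_p([1.0, 2.0, 3.0], [0, 1, 2], k=9, scheme="within_family")

    def test_null_uniformity(self, rng):
        """Under the null the empirical P is uniform (KS over 300 datasets)."""
        k, n = 199, 25
        ps = []
        for i in range(300):
            y = rng.normal(size=n)
            x = rng.integers(0, 3, size=n).astype(float)
            if np.ptp(x) == 0:
                continue
            p, _ = empirical_p(y, x, k=k, seed=1000 + i)
            ps.append(p)
        stat = stats.kstest(ps, "uniform").pvalue
        assert stat > 0.01


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37]) == pytest.approx([0.37])

    def test_equal_ps_unchanged(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_matches_statsmodels(self, rng):
        multipletests = pytest.importorskip(
            "statsmodels.stats.multitest"
        ).multipletests
        p = rng.uniform(size=50)
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_fdr(p) == pytest.approx(expected, abs=1e-12)

    def test_bounded_between_input_and_one(self, rng):
        p = rng.uniform(size=30)
        adj = bh_fdr(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)

    def test_monotone_in_order_statistics(self, rng):
        p = rng.uniform(size=30)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestSampleUnrelated:
    def test_study_design_40_families_3_sets(self):
        fams = {f"fam{i}": [f"fam{i}_kid{j}" for j in range(17)] for i in range(40)}
        ped = make_pedigree(fams)
        genotyped = [k for kids in fams.values() for k in kids]
        sets = sample_unrelated(ped, genotyped, n_sets=3, seed=1)
        assert len(sets) == 3
        fam_of = {s: e.family for s, e in ped.entries.items()}
        for subset in sets:
            assert len(subset) == 40
            assert len({fam_of[s] for s in subset}) == 40

    def test_sets_differ_across_draws(self):
        fams = {f"fam{i}": [f"fam{i}_kid{j}" for j in range(17)] for i in range(40)}
        ped = make_pedigree(fams)
        genotyped = [k for kids in fams.values() for k in kids]
        sets = sample_unrelated(ped, genotyped, n_sets=3, seed=1)
        assert sets[0] != sets[1]

    def test_deterministic_for_seed(self):
        fams = {f"fam{i}": [f"fam{i}_kid{j}" for j in range(5)] for i in range(10)}
        ped = make_pedigree(fams)
        genotyped = [k for kids in fams.values() for k in kids]
        assert sample_unrelated(ped, genotyped, seed=2) == sample_unrelated(
            ped, genotyped, seed=2
        )

    def test_family_without_genotyped_offspring_is_error(self):
        ped = make_pedigree({"famA": ["a1"], "famB": ["b1"]})
        with pytest.raises(ValueError, match="no genotyped"):
            sample_unrelated(ped, ["a1"], seed=1)


def mito_gm(strings: dict, markers=None):
    """strings: {sample: allele string over mito markers (None = missing)}."""
    n_mark = len(next(iter(strings.values())))
    ids = [f"mt{i + 1}" for i in range(n_mark)]
    markers = markers or {m: ("A", "G", "mito") for m in ids}
    calls = {}
    for sample, chars in strings.items():
        row = {}
        for m, ch in zip(ids, chars):
            a1, a2, _ = markers[m]
            row[m] = None if ch is None else (0.0 if ch == a1 else 2.0)
        calls[sample] = row
    return make_genotypes(calls, markers), ids


class TestMtHaplotypes:
    def test_single_haplotype(self):
        gm, ids = mito_gm({f"s{i}": "AAGA" for i in range(5)})
        table = build_mt_haplotypes(gm, ids)
        assert table.haplotypes == ["AAGA"]
        assert table.frequencies == [1.0]

    def test_two_haplotypes_differing_at_two_sites(self):
        gm, ids = mito_gm({"s1": "AAAA", "s2": "AAAA", "s3": "AGAG", "s4": "AGAG"})
        table = build_mt_haplotypes(gm, ids)
        assert sorted(table.haplotypes) == ["AAAA", "AGAG"]
        assert table.frequencies == [0.5, 0.5]

    def test_near_identical_haplotypes_stay_distinct(self):
        # three haplotypes where two share every position except two
        # designated markers (positions 2 and 4 of 6)
        strings = (["GAAAAA"] * 5) + (["GGAGAA"] * 3) + (["GAAGAA"] * 2)
        gm, ids = mito_gm({f"s{i}": s for i, s in enumerate(strings)})
        table = build_mt_haplotypes(gm, ids)
        assert len(table.haplotypes) == 3
        freq = dict(zip(table.haplotypes, table.frequencies))
        assert freq["GAAAAA"] == pytest.approx(0.5)
        assert freq["GGAGAA"] == pytest.approx(0.3)
        assert freq["GAAGAA"] == pytest.approx(0.2)

    def test_partial_string_assigned_when_unique(self):
        strings = {"s1": "AAAA", "s2": "AGGG", "s3": ["A", None, "G", "G"]}
        gm, ids = mito_gm(strings)
        table = build_mt_haplotypes(gm, ids)
        assert table.assignments["s3"] == "AGGG"

    def test_ambiguous_partial_string_unassigned(self):
        strings = {"s1": "AAAA", "s2": "AGAA", "s3": [None, None, "A", "A"]}
        gm, ids = mito_gm(strings)
        table = build_mt_haplotypes(gm, ids)
        assert table.assignments["s3"] is None

    def test_too_many_missing_unassigned(self):
        strings = {"s1": "AAAA", "s2": ["A", None, None, None]}
        gm, ids = mito_gm(strings)
        table = build_mt_haplotypes(gm, ids, max_missing=2)
        assert table.assignments["s2"] is None

    def test_nuclear_marker_rejected(self):
        gm, ids = mito_gm({"s1": "AA"})
        gm.markers[ids[0]].genome = "nuclear"
        with pytest.raises(ValueError, match="not mitochondrial"):
            build_mt_haplotypes(gm, ids)


class TestHaplotypeAssociation:
    def test_universal_carriage_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            haplotype_association([1.0, 2.0, 3.0], [1, 1, 1], k=9, seed=1)

    def test_recovers_carrier_shift(self, rng):
        n = 120
        slopes = []
        ses = []
        for rep in range(20):
            carrier = rng.integers(0, 2, size=n)
            y = 5.0 + 2.5 * carrier + rng.normal(0, 1.0, size=n)
            res = allele_count_regression(y, carrier)
            slopes.append(res.slope)
            ses.append(abs(res.slope / res.t))
        mean_slope = float(np.mean(slopes))
        assert abs(mean_slope - 2.5) < 2 * float(np.mean(ses)) / math.sqrt(20)

    def test_zero_effect_p_not_extreme(self, rng):
        n = 100
        carrier = rng.integers(0, 2, size=n)
        y = rng.normal(size=n)
        res = haplotype_association(y, carrier, k=999, seed=5)
        assert res.p_empirical > 1 / 1000
        assert res.n_permutations == 999
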
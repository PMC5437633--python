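"""Frequency datasets, canonical ordination, PERMANOVA and the
correlation/regression analyses."""

import itertools

import numpy as np
import pytest

from ssrevol.detect import MicrosatelliteLocus
from ssrevol.imperfection import (build_datasets, canonical_ordination,
                                  pairwise_length_correlations, permanova,
                                  regress_mismatch_on_length)
from ssrevol.motifs import complete_standardize


def _locus(length, mm, motif="AG", chrom="c"):
    return MicrosatelliteLocus(
        chromosome=chrom, start=0, end=length, motif=motif,
        standardized_motif=complete_standardize(motif).motif_class,
        repeat_length=length, mismatch_count=mm, score=length - 6 * mm)


class TestBuildDatasets:
    def test_single_locus_lands_in_one_cell(self):
        ds1, ds2 = build_datasets({"g": [_locus(22, 1)]})
        assert ds1.loc["g", (22, 1)] == 1
        assert ds1.to_numpy().sum() == 1
        assert ds2.to_numpy().sum() == 0

    def test_short_locus_excluded_everywhere(self):
        ds1, ds2 = build_datasets({"g": [_locus(19, 0)]})
        assert ds1.to_numpy().sum() == 0 and ds2.to_numpy().sum() == 0

    def test_dataset_windows(self):
        loci = [_locus(20, 0), _locus(24, 1), _locus(25, 1), _locus(29, 2),
                _locus(25, 0), _locus(30, 1)]
        ds1, ds2 = build_datasets({"g": loci})
        assert ds1.to_numpy().sum() == 2   # (20,0) and (24,1)
        assert ds2.to_numpy().sum() == 2   # (25,1) and (29,2)

    def test_counts_match_planted_composition(self, small_sim):
        from ssrevol.detect import scan_genome
        loci = scan_genome(small_sim.sequences)
        ds1, _ = build_datasets({"sim": loci})
        expect = sum(1 for p in small_sim.truth
                     if 20 <= p.true_repeat_length <= 24
                     and p.true_mismatch_count in (0, 1))
        assert ds1.to_numpy().sum() == expect


class TestCanonicalOrdination:
    def test_identical_blocks_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        A = rng.poisson(20, size=(10, 6)).astype(float)
        res, _, _ = canonical_ordination(A, A.copy(), n_permutations=99,
                                         seed=1)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value >= 1 / 100

    def test_scaling_invariance(self):
        rng = np.random.default_rng(1)
        A = rng.poisson(20, size=(12, 5)).astype(float)
        B = rng.poisson(10, size=(12, 5)).astype(float)
        r1, _, _ = canonical_ordination(A, B, n_permutations=0, seed=0)
        r2, _, _ = canonical_ordination(A, B * 7.5, n_permutations=0, seed=0)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            canonical_ordination(np.ones((2, 3)), np.ones((2, 3)))
        with pytest.raises(ValueError):
            canonical_ordination(np.ones((5, 3)), np.zeros((5, 3)) + 2.0)

    def test_null_rejection_rate_is_calibrated(self):
        """Independent random blocks: p ~ Uniform, so the rejection rate at
        alpha=0.05 over 200 replicates stays within [0.02, 0.09]."""
        rng = np.random.default_rng(2023)
        rejections = 0
        reps = 200
        for _ in range(reps):
            A = rng.poisson(15, size=(13, 5)).astype(float)
            B = rng.poisson(15, size=(13, 5)).astype(float)
            res, _, _ = canonical_ordination(
                A, B, n_permutations=99, seed=int(rng.integers(2 ** 31)))
            if res.p_value <= 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.09

    def test_permutation_p_reproducible_and_positive(self):
        rng = np.random.default_rng(3)
        A = rng.poisson(15, size=(8, 4)).astype(float)
        B = rng.poisson(15, size=(8, 4)).astype(float)
        r1, _, _ = canonical_ordination(A, B, n_permutations=199, seed=7)
        r2, _, _ = canonical_ordination(A, B, n_permutations=199, seed=7)
        assert r1.p_value == r2.p_value > 0


def _brute_force_one_way_F(X, labels):
    """Pseudo-F via explicit group centroids (Euclidean case)."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    groups = {g: X[np.asarray(labels) == g] for g in set(labels)}
    a = len(groups)
    grand = X.mean(axis=0)
    ss_total = ((X - grand) ** 2).sum()
    ss_within = sum(((G - G.mean(axis=0)) ** 2).sum()
                    for G in groups.values())
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_degenerate_identical_rows_flagged(self):
        X = np.ones((6, 4))
        res = permanova(X, {"f": ["a", "a", "a", "b", "b", "b"]},
                        n_permutations=19, seed=0)
        assert res["f"].degenerate
        assert np.isnan(res["f"].statistic)

    def test_single_level_factor_errors(self):
        with pytest.raises(ValueError):
            permanova(np.random.default_rng(0).normal(size=(6, 3)),
                      {"f": ["a"] * 6})

    def test_pseudo_f_equals_centroid_brute_force(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5))
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        res = permanova(X, {"f": labels}, n_permutations=9, seed=0)
        assert res["f"].statistic == pytest.approx(
            _brute_force_one_way_F(X, labels), rel=1e-10)

    def test_pseudo_f_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        from scipy.spatial.distance import pdist, squareform
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 4))
        labels = ["a"] * 5 + ["b"] * 5
        dm = skbio.DistanceMatrix(squareform(pdist(X)))
        expected = skbio.stats.distance.permanova(
            dm, grouping=labels, permutations=9)["test statistic"]
        res = permanova(X, {"f": labels}, n_permutations=9, seed=0)
        assert res["f"].statistic == pytest.approx(expected, rel=1e-10)

    def test_exhaustive_p_equals_relabeling_enumeration(self):
        """On 6 rows in two groups of 3 the permutation p must equal the
        exact enumeration over all C(6,3)=20 distinct relabelings."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(6, 3))
        X[3:] += 1.5
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(X, {"f": labels}, n_permutations="exhaustive")
        f_obs = _brute_force_one_way_F(X, labels)
        count = 0
        for combo in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(combo)] = "a"
            if _brute_force_one_way_F(X, lab) >= f_obs - 1e-12:
                count += 1
        assert res["f"].p_value == pytest.approx(count / 20)
        assert res["f"].statistic == pytest.approx(f_obs, rel=1e-10)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(16, 4))
        X[8:] += 10.0
        labels = ["a"] * 8 + ["b"] * 8
        res = permanova(X, {"f": labels}, n_permutations=999, seed=1)
        assert res["f"].p_value <= 0.01

    def test_sequential_terms_partition_variance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(24, 3))
        lens = np.repeat([30, 40, 50, 60], 6)
        mms = np.tile([1, 1, 2, 2, 3, 3], 4)
        res = permanova(X, {"length": lens, "mismatch": mms},
                        n_permutations=99, seed=0)
        assert set(res) == {"length", "mismatch"}
        assert all(r.p_value > 0 for r in res.values())


class TestCorrelationsAndRegression:
    def test_self_and_negated_vectors(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=13)
        from scipy.stats import pearsonr
        assert pearsonr(x, x)[0] == pytest.approx(1.0)
        assert pearsonr(x, -x)[0] == pytest.approx(-1.0)
        # through the public API: genomes whose mismatch-2 counts equal
        # their mismatch-1 counts correlate perfectly
        loci = {}
        for i in range(5):
            per = []
            for _ in range(i + 1):
                per.append(_locus(31, 1))
                per.append(_locus(31, 2))
            loci[f"g{i}"] = per
        tab = pairwise_length_correlations(loci, lengths=(30,))
        row = tab[(tab.mismatch_a == 1) & (tab.mismatch_b == 2)].iloc[0]
        assert row.r == pytest.approx(1.0)

    def test_constant_vector_flagged(self):
        loci = {f"g{i}": [_locus(31, 1)] for i in range(4)}
        tab = pairwise_length_correlations(loci, lengths=(30,))
        assert not tab.defined.any()

    def test_needs_three_genomes(self):
        with pytest.raises(ValueError):
            pairwise_length_correlations({"a": [], "b": []})

    def test_known_correlation_recovered(self):
        """Bivariate normal with rho=0.8, n=13: mean sample r over many
        replicates within +-0.05 of 0.8."""
        rng = np.random.default_rng(10)
        from scipy.stats import pearsonr
        rs = []
        cov = [[1, 0.8], [0.8, 1]]
        for _ in range(500):
            xy = rng.multivariate_normal([0, 0], cov, size=13)
            rs.append(pearsonr(xy[:, 0], xy[:, 1])[0])
        assert abs(np.mean(rs) - 0.8) <= 0.05

    def test_regression_exact_line(self):
        loci = []
        for i, motif in enumerate(["AC", "AG", "AT", "CG"]):
            length = 20 + 10 * i
            mm = round(0.1 * length - 1, 10)
            # two identical loci per class so the class mean is exact
            for _ in range(2):
                loci.append(_locus(length, mm, motif=motif))
        fit = regress_mismatch_on_length(loci)
        assert fit.slope == pytest.approx(0.1)
        assert fit.intercept == pytest.approx(-1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_regression_flat_when_mismatch_constant(self):
        loci = [_locus(20 + 5 * i, 1, motif=m)
                for i, m in enumerate(["AC", "AG", "AT"])]
        fit = regress_mismatch_on_length(loci)
        assert fit.slope == 0.0 and fit.r_squared == 0.0

    def test_regression_requires_three_classes(self):
        with pytest.raises(ValueError):
            regress_mismatch_on_length([_locus(20, 0), _locus(25, 1)])

    def test_planted_linear_trend_recovered(self):
        """Mismatch counts growing linearly with class length: the fitted
        slope is within 10% of the planted slope."""
        rng = np.random.default_rng(11)
        slope = 0.05
        loci = []
        from ssrevol.motifs import enumerate_classes
        classes = sorted(c.motif_class for k in (2, 3, 4)
                         for c in enumerate_classes(k))[:12]
        for i, motif in enumerate(classes):
            length = 20 + 4 * i
            mean_mm = slope * length
            for _ in range(40):
                mm = max(0, rng.poisson(mean_mm))
                loci.append(_locus(length, mm, motif=motif))
        fit = regress_mismatch_on_length(loci)
        assert fit.slope == pytest.approx(slope, rel=0.10)
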
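import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirnasv.core_model import GenomicInterval, SequenceRecord, SmallRNASpecies
from pirnasv.smallrna_quant import (
    FeatureAbundance,
    Library,
    calibrate_oxidized,
    expression_variance,
    feature_abundance,
    normalize_to_mirna,
    shannon_diversity,
    strand_bias,
    wf_complexity,
)


def lib_of(species, mirna_total=1e6, label="L"):
    return Library(label, species, mirna_total)


def uspecies(seq, count, chrom="chr1", pos=100, strand="+"):
    return SmallRNASpecies(seq, count, [(chrom, pos, strand)])


class TestNormalize:
    def test_linear_scaling(self):
        lib = lib_of([uspecies("A" * 26, 10.0)], mirna_total=2e6)
        (out,) = normalize_to_mirna([lib], scale=1e6)
        assert out.species[0].count == pytest.approx(5.0)
        assert out.mirna_total == 1e6

    def test_idempotent_at_factor_one(self):
        lib = lib_of([uspecies("A" * 26, 7.0)], mirna_total=1e6)
        (out,) = normalize_to_mirna([lib], scale=1e6)
        assert out.species[0].count == pytest.approx(7.0)

    def test_ratio_identity_between_libraries(self):
        seq = "ACGT" * 7
        l1 = lib_of([uspecies(seq, 30.0)], mirna_total=3e6)
        l2 = lib_of([uspecies(seq, 10.0)], mirna_total=5e5)
        n1, n2 = normalize_to_mirna([l1, l2], scale=1e6)
        expected = (30.0 / 10.0) * (5e5 / 3e6)
        assert n1.species[0].count / n2.species[0].count == pytest.approx(expected)

    def test_zero_mirna_total_names_library(self):
        lib = lib_of([uspecies("A" * 26, 1.0)], mirna_total=0.0, label="bad")
        with pytest.raises(ValueError, match="bad"):
            normalize_to_mirna([lib])


class TestCalibrateOxidized:
    def test_factor_from_shared_sums(self):
        seq = "ACGTACGTACGTACGTACGTACGTAC"
        total = lib_of([uspecies(seq, 200.0)])
        ox = lib_of([uspecies(seq, 100.0), uspecies("G" * 26, 50.0)])
        out = calibrate_oxidized(ox, total)
        by_seq = {s.sequence: s.count for s in out.species}
        assert by_seq[seq] == pytest.approx(200.0)  # f = 2
        assert by_seq["G" * 26] == pytest.approx(100.0)

    def test_identity_on_identical_libraries(self):
        seq = "ACGTACGTACGTACGTACGTACGTAC"
        a = lib_of([uspecies(seq, 42.0)])
        out = calibrate_oxidized(a, a)
        assert out.species[0].count == pytest.approx(42.0)

    def test_disjoint_species_error(self):
        a = lib_of([uspecies("A" * 26, 1.0)])
        b = lib_of([uspecies("C" * 26, 1.0)])
        with pytest.raises(ValueError):
            calibrate_oxidized(a, b)

    def test_idempotent_second_pass(self):
        seq = "ACGTACGTACGTACGTACGTACGTAC"
        total = lib_of([uspecies(seq, 300.0)])
        ox = lib_of([uspecies(seq, 100.0)])
        once = calibrate_oxidized(ox, total)
        twice = calibrate_oxidized(once, total)
        assert twice.species[0].count == pytest.approx(once.species[0].count)

    def test_short_species_not_shared(self):
        # 22-nt species must not contribute to the calibration factor
        shared = "ACGTACGTACGTACGTACGTACGTAC"
        short = "ACGTACGTACGTACGTACGTAC"  # 22 nt
        total = lib_of([uspecies(shared, 100.0), uspecies(short, 999.0)])
        ox = lib_of([uspecies(shared, 50.0), uspecies(short, 1.0)])
        out = calibrate_oxidized(ox, total)
        by_seq = {s.sequence: s.count for s in out.species}
        assert by_seq[shared] == pytest.approx(100.0)


class TestFeatureAbundance:
    def test_ppm_rpkm_with_pseudocount(self):
        feature = GenomicInterval("chr1", 0, 1000)
        # one unique 26-nt species, count 10, inside; library total 1e6 reads
        filler = uspecies("A" * 26, 1e6 - 10, chrom="chr2", pos=5)
        sp = uspecies("C" * 26, 10.0, pos=500)
        lib = lib_of([sp, filler])
        (fa,) = feature_abundance(lib, [feature])
        assert fa.ppm == pytest.approx(10.001)
        assert fa.rpkm == pytest.approx(10.001)

    def test_short_species_excluded(self):
        feature = GenomicInterval("chr1", 0, 1000)
        lib = lib_of([uspecies("A" * 22, 50.0, pos=10)])
        (fa,) = feature_abundance(lib, [feature])
        assert fa.total_count == 0

    def test_multimapper_fractional(self):
        feature = GenomicInterval("chr1", 0, 1000)
        sp = SmallRNASpecies("A" * 26, 10.0,
                             [("chr1", 100, "+"), ("chr2", 100, "+")])
        lib = lib_of([sp])
        (fa,) = feature_abundance(lib, [feature])
        assert fa.total_count == pytest.approx(5.0)

    def test_five_prime_assignment(self):
        # 5' base at 999 is in; at 1000 is out (half-open)
        feature = GenomicInterval("chr1", 0, 1000)
        inside = uspecies("A" * 26, 1.0, pos=999)
        outside = uspecies("C" * 26, 1.0, pos=1000)
        lib = lib_of([inside, outside])
        (fa,) = feature_abundance(lib, [feature])
        assert fa.total_count == pytest.approx(1.0)

    def test_count_conservation(self):
        # fractional apportionment never creates or destroys counts
        rng = np.random.default_rng(7)
        features = [GenomicInterval("chr1", i * 1000, (i + 1) * 1000)
                    for i in range(10)]
        species = []
        for i in range(50):
            n_map = int(rng.integers(1, 4))
            maps = [("chr1", int(rng.integers(0, 10_000)), "+")
                    for _ in range(n_map)]
            species.append(SmallRNASpecies("ACGT" * 7, float(rng.integers(1, 9)),
                                           maps))
        lib = lib_of(species)
        total_assigned = sum(fa.total_count
                             for fa in feature_abundance(lib, features))
        total_counts = sum(s.count for s in species)
        assert total_assigned <= total_counts + 1e-9

    def test_empty_features(self):
        assert feature_abundance(lib_of([uspecies("A" * 26, 1.0)]), []) == []


class TestShannon:
    def test_single_species_zero(self):
        assert shannon_diversity({"a": 5.0}) == pytest.approx(0.0)

    def test_uniform_four(self):
        h = shannon_diversity({"a": 1, "b": 1, "c": 1, "d": 1})
        assert h == pytest.approx(math.log(4), abs=1e-12)

    def test_three_one_split(self):
        h = shannon_diversity({"a": 3, "b": 1})
        expected = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        assert h == pytest.approx(expected, abs=1e-12)

    def test_zero_counts_ignored(self):
        assert shannon_diversity({"a": 2, "b": 0}) == pytest.approx(0.0)

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            shannon_diversity({"a": 0.0})


class TestStrandBias:
    @pytest.mark.parametrize("w,c,expected", [
        (10, 0, 1.0), (5, 5, 0.5), (30, 10, 0.75)])
    def test_values(self, w, c, expected):
        fa = FeatureAbundance(GenomicInterval("chr1", 0, 100), 0, 0, w, c)
        assert strand_bias(fa) == pytest.approx(expected)

    def test_empty_is_missing(self):
        fa = FeatureAbundance(GenomicInterval("chr1", 0, 100), 0, 0, 0, 0)
        assert strand_bias(fa) is None


class TestExpressionVariance:
    def test_identical_individuals_zero_cv(self):
        m = np.tile(np.linspace(1, 100, 20)[:, None], (1, 4))
        records = expression_variance(m)
        assert all(r.cv == pytest.approx(0.0) for r in records)
        assert all(abs(r.residual) < 1e-9 for r in records)

    def test_decorrelation(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(11)
        n = 1000
        medians = 10 ** rng.uniform(0, 4, size=n)
        # mean-variance trend: CV shrinks with expression
        cv_true = 1.0 / np.sqrt(medians) * 5 + 0.1
        m = medians[:, None] * (
            1 + cv_true[:, None] * rng.standard_normal((n, 8)))
        m = np.abs(m)
        records = expression_variance(m, loess_span=0.4)
        rho = spearmanr([r.residual for r in records],
                        [r.median_expr for r in records]).statistic
        assert abs(rho) < 0.1

    def test_planted_high_variance_recovered(self):
        rng = np.random.default_rng(3)
        n = 200
        medians = 10 ** rng.uniform(1, 3, size=n)
        cv = np.full(n, 0.2)
        cv[:20] = 0.4  # planted high-variance subset
        m = np.abs(medians[:, None] *
                   (1 + cv[:, None] * rng.standard_normal((n, 10))))
        records = expression_variance(m, loess_span=0.5)
        res = np.array([r.residual for r in records])
        assert res[:20].mean() > res[20:].mean()

    def test_zero_mean_dropped_with_warning(self):
        m = np.abs(np.random.default_rng(0).standard_normal((12, 4))) + 0.5
        m[3] = 0.0
        with pytest.warns(UserWarning):
            records = expression_variance(m)
        assert len(records) == 11

    def test_minimum_shape(self):
        with pytest.raises(ValueError):
            expression_variance(np.ones((5, 4)))
        with pytest.raises(ValueError):
            expression_variance(np.ones((20, 2)))


class TestWfComplexity:
    def test_homopolymer_zero(self):
        assert wf_complexity("AAAA") == pytest.approx(0.0, abs=1e-12)

    def test_acgt(self):
        assert wf_complexity("ACGT") == pytest.approx(
            math.log(24) / (4 * math.log(4)), abs=1e-12)

    def test_aacc(self):
        assert wf_complexity("AACC") == pytest.approx(
            math.log(6) / (4 * math.log(4)), abs=1e-12)

    def test_sequence_record_input(self):
        assert wf_complexity(SequenceRecord("ACGT")) == wf_complexity("ACGT")

    def test_ambiguity_rejected(self):
        with pytest.raises(ValueError):
            wf_complexity("ACGN")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60),
           st.randoms(use_true_random=False))
    @settings(max_examples=60, deadline=None)
    def test_permutation_invariant(self, seq, rnd):
        shuffled = list(seq)
        rnd.shuffle(shuffled)
        assert wf_complexity(seq) == pytest.approx(
            wf_complexity("".join(shuffled)), abs=1e-12)

    @given(st.integers(1, 30))
    @settings(max_examples=30, deadline=None)
    def test_balanced_is_maximal(self, k):
        balanced = "ACGT" * k
        skewed = "A" * (4 * k)
        assert wf_complexity(balanced) >= wf_complexity(skewed)

    def test_long_sequence_no_overflow(self):
        value = wf_complexity("ACGT" * 100_000)
        assert 0.99 < value <= 1.0
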
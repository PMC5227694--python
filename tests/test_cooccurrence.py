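"""Overlap proportions and plain / abundance-matched resampling nulls."""

import numpy as np
import pytest

from metophos.cooccurrence import (abundance_matched_null, cooccurrence_test,
                                   null_overlap, overlap_proportion,
                                   quartile_strata)
from metophos.ptm_tables import ProteinRecord, ProteinSet
from metophos.stats_core import ks_two_sample


def _proteome(n, abundances=None, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        ab = abundances[i] if abundances is not None else float(
            rng.lognormal(9.0, 2.0))
        records.append(ProteinRecord(f"A{i:04d}", "MKSAY", abundance=ab))
    return ProteinSet(records)


class TestOverlapProportion:
    def test_printed_count_arithmetic(self):
        target = {f"T{i}" for i in range(774)}
        other = {f"T{i}" for i in range(758)} | {"X1", "X2"}
        assert overlap_proportion(target, other) == pytest.approx(758 / 774)

    def test_subset_and_disjoint(self):
        assert overlap_proportion({"a", "b"}, {"a", "b", "c"}) == 1.0
        assert overlap_proportion({"a"}, {"b"}) == 0.0

    def test_empty_target(self):
        with pytest.raises(ValueError):
            overlap_proportion(set(), {"a"})


class TestNullOverlap:
    def test_other_is_whole_proteome(self):
        proteome = _proteome(30)
        null = null_overlap(proteome, proteome.accessions(), 10, 200, seed=1)
        assert (null.values == 1.0).all()

    def test_null_mean_matches_population_fraction(self):
        proteome = _proteome(500)
        other = proteome.accessions()[:200]  # f = 0.4
        null = null_overlap(proteome, other, 100, 4000, seed=2)
        # hypergeometric sd of one sample's proportion, then SE of the mean
        sd_one = np.sqrt(0.4 * 0.6 / 100 * (400 / 499))
        se_mean = sd_one / np.sqrt(4000)
        assert abs(null.values.mean() - 0.4) < 3 * se_mean
        assert ((null.values >= 0) & (null.values <= 1)).all()

    def test_seed_reproducibility_and_size_guard(self):
        proteome = _proteome(30)
        a = null_overlap(proteome, ["A0001"], 10, 100, seed=7)
        b = null_overlap(proteome, ["A0001"], 10, 100, seed=7)
        assert np.array_equal(a.values, b.values)
        with pytest.raises(ValueError):
            null_overlap(proteome, [], 31, 10)

    def test_exact_and_counting_paths_agree_in_distribution(self):
        proteome = _proteome(120)
        other = proteome.accessions()[:50]
        exact = null_overlap(proteome, other, 40, 3000, seed=3, method="exact")
        count = null_overlap(proteome, other, 40, 3000, seed=4, method="count")
        assert ks_two_sample(exact.values, count.values).p > 0.01


class TestQuartileStrata:
    def test_sizes_sum_to_target_when_not_divisible(self):
        target = np.linspace(1, 100, 533)  # 533 % 4 == 1
        _, sizes, _ = quartile_strata(target, target)
        assert sizes.sum() == 533
        assert sizes.tolist() == [134, 133, 133, 133]  # remainder to stratum 1

    def test_boundary_value_goes_to_lower_stratum(self):
        target = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        q1 = float(np.quantile(target, 0.25))
        _, _, candidates = quartile_strata(target, np.array([q1]))
        assert len(candidates[0]) == 1 and len(candidates[1]) == 0


class TestAbundanceMatchedNull:
    def test_sampling_from_target_itself_matches(self):
        ab = np.random.default_rng(0).lognormal(9, 2, 97).tolist()
        proteome = _proteome(97, abundances=ab)
        target = proteome.accessions()
        null, diag = abundance_matched_null(proteome, target, target[:50],
                                            n_samples=200, seed=1)
        assert sum(diag.strata_sizes) == len(target)
        assert diag.ks_statistic.mean() < 0.2
        assert np.abs(diag.mean_log10_abundance - diag.target_mean_log10).mean() < 0.2

    def test_median_ks_p_high_on_adequate_pools(self):
        rng = np.random.default_rng(5)
        ab = rng.lognormal(9, 2, 800).tolist()
        proteome = _proteome(800, abundances=ab)
        target = list(rng.choice(proteome.accessions(), 120, replace=False))
        null, diag = abundance_matched_null(proteome, target, target[:30],
                                            n_samples=300, seed=6)
        assert np.median(diag.ks_p) > 0.05

    def test_insufficient_stratum_errors(self):
        # degenerate target quartiles (all internal boundaries equal): the
        # middle strata have no candidates at all, yet still need one each
        ab = [1.0, 1.0, 1.0, 1.0, 5.0, 500.0, 600.0, 700.0]
        proteome = _proteome(8, abundances=ab)
        target = proteome.accessions()[:5]
        with pytest.raises(ValueError, match="stratum"):
            abundance_matched_null(proteome, target, target[:2],
                                   n_samples=10, seed=0)

    def test_matching_shifts_null_toward_planted_correlation(self):
        # membership in `other` grows with abundance; the target sits in the
        # upper abundance range, so the matched null must concentrate on
        # higher overlap values than the uniform null.
        rng = np.random.default_rng(11)
        ab = np.sort(rng.lognormal(9, 2, 600))
        proteome = _proteome(600, abundances=ab.tolist())
        accs = proteome.accessions()  # sorted by abundance by construction
        other = [a for i, a in enumerate(accs) if rng.random() < i / 600]
        target = list(rng.choice(accs[360:], 80, replace=False))
        matched, _ = abundance_matched_null(proteome, target, other,
                                            n_samples=400, seed=12)
        uniform = null_overlap(proteome, other, len(target), 400, seed=13)
        assert matched.values.mean() > uniform.values.mean() + 0.05

    def test_target_without_abundance_rejected(self):
        records = [ProteinRecord("B1", "MKSAY"),
                   ProteinRecord("B2", "MKSAY", abundance=5.0)]
        proteome = ProteinSet(records)
        with pytest.raises(ValueError, match="abundance"):
            abundance_matched_null(proteome, ["B1"], ["B2"], 10, 0)


def test_cooccurrence_test_end_to_end():
    proteome = _proteome(200, seed=9)
    target = proteome.accessions()[:40]
    other = proteome.accessions()[:150]
    res = cooccurrence_test(proteome, target, other, n_samples=500, seed=3)
    assert res.observed_proportion == 1.0
    assert 0 < res.p <= 1
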
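"""Profiles, logarithmic binning, clustering, and the co-conservation tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coevoqtl.conservation_profiles import (
    BIN_SIZES,
    HIGH,
    LOW,
    BinnedProfile,
    ClusterModel,
    ConservationProfile,
    ContingencyTable2x2,
    average_pileup,
    bin_profile,
    chi_squared_yates,
    contingency_table,
    extract_profile,
    kmeans_cluster,
    ks_compare,
    label_centroids,
)
from coevoqtl.io_formats import ConservationTrack, GenomicInterval


def make_track(values, chrom="chr1", start=0):
    t = ConservationTrack()
    t.add_run(chrom, start, np.asarray(values, dtype=float))
    return t


def make_profile(scores):
    return ConservationProfile(GenomicInterval("chr1", 5000, 5001), scores)


class TestExtractProfile:
    def test_profile_has_2001_positions(self):
        track = make_track(np.zeros(12000))
        prof = extract_profile(track, GenomicInterval("chr1", 5000, 5001))
        assert prof.scores.size == 2001

    def test_constant_track_gives_constant_profile(self):
        track = make_track(np.full(12000, 3.25))
        prof = extract_profile(track, GenomicInterval("chr1", 5000, 5001))
        assert (prof.scores == 3.25).all()

    def test_minus_strand_profile_is_reversed_window(self, rng):
        values = rng.normal(size=12000)
        track = make_track(values)
        plus = extract_profile(track, GenomicInterval("chr1", 5000, 5001, "+"))
        minus = extract_profile(track, GenomicInterval("chr1", 5000, 5001, "-"))
        np.testing.assert_array_equal(minus.scores, plus.scores[::-1])

    def test_off_chromosome_positions_are_missing(self):
        track = make_track(np.ones(50))
        prof = extract_profile(track, GenomicInterval("chr1", 10, 11), flank=20)
        assert np.isnan(prof.scores[:10]).all()
        assert (prof.scores[10:31] == 1).all()

    def test_long_locus_rejected(self):
        track = make_track(np.zeros(100))
        with pytest.raises(ValueError, match="length 1"):
            extract_profile(track, GenomicInterval("chr1", 10, 12))


def reference_bin_layout():
    """Rebuild the bin sizes from their defining rule: center bin of 1,
    doubling outward (2, 4, ..., 256), terminal bin absorbing the rest of
    the 1000 flanking bases on each side."""
    side = [2**k for k in range(1, 9)]  # 2 .. 256
    side.append(1000 - sum(side))  # 490
    return tuple(reversed(side)) + (1,) + tuple(side)


class TestBinProfile:
    def test_layout_matches_defining_rule(self):
        assert BIN_SIZES == reference_bin_layout()
        assert sum(BIN_SIZES) == 2001
        assert BIN_SIZES[len(BIN_SIZES) // 2] == 1

    def test_profile_reduces_to_19_values(self, rng):
        binned = bin_profile(make_profile(rng.normal(size=2001)))
        assert binned.values.size == 19

    def test_constant_profile_bins_to_constant(self):
        binned = bin_profile(make_profile(np.full(2001, -1.5)))
        np.testing.assert_allclose(binned.values, -1.5)

    def test_ramp_profile_matches_bruteforce_bin_means(self):
        """Score = relative position; each bin mean must equal the plain
        average over that bin's positions, computed by explicit slicing."""
        ramp = np.arange(-1000, 1001, dtype=float)
        binned = bin_profile(make_profile(ramp))
        edges = np.concatenate([[0], np.cumsum(reference_bin_layout())])
        expected = [ramp[e0:e1].mean() for e0, e1 in zip(edges, edges[1:])]
        np.testing.assert_allclose(binned.values, expected)

    def test_missing_bases_excluded_from_bin_mean(self):
        scores = np.ones(2001)
        scores[0:100] = np.nan  # inside the first 490-bin
        binned = bin_profile(make_profile(scores))
        assert binned.values[0] == 1.0  # mean over the 390 non-missing
        scores[0:490] = np.nan
        assert np.isnan(bin_profile(make_profile(scores)).values[0])

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="2001"):
            bin_profile(make_profile(np.zeros(2003)))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_size_weighted_mean_recovers_full_mean(self, seed):
        scores = np.random.default_rng(seed).normal(size=2001)
        binned = bin_profile(make_profile(scores))
        weighted = np.dot(binned.values, BIN_SIZES) / sum(BIN_SIZES)
        assert weighted == pytest.approx(scores.mean(), abs=1e-12)

    def test_binwise_constant_profile_reconstructs_exactly(self, rng):
        edges = np.concatenate([[0], np.cumsum(BIN_SIZES)])
        levels = rng.normal(size=19)
        scores = np.concatenate(
            [np.full(s, v) for s, v in zip(BIN_SIZES, levels)]
        )
        np.testing.assert_allclose(
            bin_profile(make_profile(scores)).values, levels, atol=1e-12
        )


class TestAveragePileup:
    def test_single_profile_is_identity(self, rng):
        p = make_profile(rng.normal(size=2001))
        np.testing.assert_array_equal(average_pileup([p]), p.scores)

    def test_opposite_profiles_cancel(self, rng):
        scores = rng.normal(size=2001)
        mean = average_pileup([make_profile(scores), make_profile(-scores)])
        np.testing.assert_allclose(mean, 0, atol=1e-12)

    def test_zoom_returns_central_window(self, rng):
        p = make_profile(rng.normal(size=2001))
        zoom = average_pileup([p], half_width=100)
        np.testing.assert_array_equal(zoom, p.scores[900:1101])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            average_pileup([])


class TestKmeans:
    @staticmethod
    def two_groups(rng, n=60, sep=3.0):
        a = rng.normal(0, 0.3, size=(n, 19))
        b = rng.normal(sep, 0.3, size=(n, 19))
        profiles = [BinnedProfile(row) for row in np.vstack([a, b])]
        truth = np.array([0] * n + [1] * n)
        return profiles, truth

    def test_recovers_planted_partition(self, rng):
        profiles, truth = self.two_groups(rng)
        model = kmeans_cluster(profiles, seed=0)
        agree = (model.assignments == truth).mean()
        assert max(agree, 1 - agree) == 1.0

    def test_duplicated_dataset_same_centroids(self, rng):
        profiles, _ = self.two_groups(rng)
        m1 = kmeans_cluster(profiles, seed=0)
        m2 = kmeans_cluster(profiles + profiles, seed=0)
        c1 = np.sort(m1.centroids[:, 0])
        c2 = np.sort(m2.centroids[:, 0])
        np.testing.assert_allclose(c1, c2, atol=1e-8)

    def test_deterministic_given_seed(self, rng):
        profiles, _ = self.two_groups(rng)
        m1 = kmeans_cluster(profiles, seed=7, restarts=5)
        m2 = kmeans_cluster(profiles, seed=7, restarts=5)
        np.testing.assert_array_equal(m1.assignments, m2.assignments)
        np.testing.assert_array_equal(m1.centroids, m2.centroids)

    def test_fewer_profiles_than_k_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_cluster([BinnedProfile(rng.normal(size=19))], k=2)


class TestLabelCentroids:
    @staticmethod
    def model(c0, c1):
        return ClusterModel(
            centroids=np.vstack([c0, c1]),
            assignments=np.array([0, 1]),
            inertia=0.0,
            seed=0,
            restarts=1,
        )

    def test_larger_mean_is_high(self):
        m = label_centroids(self.model(np.full(19, 0.5), np.zeros(19)))
        assert m.labels == {0: HIGH, 1: LOW}

    def test_equal_means_tie_broken_by_center_bin(self):
        c0, c1 = np.zeros(19), np.zeros(19)
        c0[0], c1[9] = 1.0, 1.0  # same mean; c1 has the larger center bin
        m = label_centroids(self.model(c0, c1))
        assert m.labels == {1: HIGH, 0: LOW}

    def test_flank_bumped_centroid_is_high(self):
        """A centroid shaped like the conserved-flank pattern (positive
        flanks, negative center) outranks a flat near-zero centroid."""
        bumped = np.concatenate([np.full(9, 0.6), [-0.5], np.full(9, 0.6)])
        flat = np.random.default_rng(0).normal(0, 0.01, 19)
        m = label_centroids(self.model(bumped, flat))
        assert m.labels[0] == HIGH

    def test_k3_unsupported(self):
        m = ClusterModel(np.zeros((3, 19)), np.arange(3), 0.0, 0, 1)
        with pytest.raises(ValueError):
            label_centroids(m)


class TestContingency:
    @staticmethod
    def catalog_with_counts(a, b, c, d):
        """A catalog of unique loci reproducing the given cell counts."""
        rows, snp_labels, gene_labels = [], {}, {}
        idx = 0
        for count, s_lab, g_lab in [
            (a, "high", "high"),
            (b, "low", "high"),
            (c, "high", "low"),
            (d, "low", "low"),
        ]:
            for _ in range(count):
                snp, gene = f"rs{idx}", f"g{idx}"
                rows.append((snp, gene))
                snp_labels[snp] = s_lab
                gene_labels[gene] = g_lab
                idx += 1
        df = pd.DataFrame(rows, columns=["snp_id", "gene_id"])
        return df, snp_labels, gene_labels

    def test_published_style_counts_and_marginals(self):
        df, sl, gl = self.catalog_with_counts(428, 7544, 1775, 40975)
        table = contingency_table(df, sl, gl)
        assert (table.a, table.b, table.c, table.d) == (428, 7544, 1775, 40975)
        assert table.row_totals == (7972, 42750)
        assert table.col_totals == (2203, 48519)
        assert table.total == 50722

    def test_empty_catalog_gives_zero_table(self):
        df = pd.DataFrame(columns=["snp_id", "gene_id"])
        table = contingency_table(df, {}, {})
        assert table.total == 0

    def test_single_hc_hc_pair(self):
        df, sl, gl = self.catalog_with_counts(1, 0, 0, 0)
        table = contingency_table(df, sl, gl)
        assert (table.a, table.b, table.c, table.d) == (1, 0, 0, 0)

    def test_unlabeled_member_lists_offenders(self):
        df = pd.DataFrame({"snp_id": ["rsX"], "gene_id": ["gY"]})
        with pytest.raises(ValueError, match="rsX"):
            contingency_table(df, {}, {"gY": "high"})


class TestChiSquared:
    def test_yates_statistic_on_reference_table(self):
        """The corrected chi-squared for the (428, 7544, 1775, 40975) table
        is 23.651 with p about 1.155e-6."""
        res = chi_squared_yates(ContingencyTable2x2(428, 7544, 1775, 40975))
        assert res.statistic == pytest.approx(23.651, abs=5e-4)
        assert res.p_value == pytest.approx(1.155e-6, rel=1e-3)
        assert res.corrected

    def test_proportional_table_gives_zero(self):
        res = chi_squared_yates(ContingencyTable2x2(10, 20, 30, 60))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_uncorrected_matches_bruteforce_formula(self):
        """Without continuity correction the same table gives about 23.9 --
        the corrected form is what reproduces 23.651."""
        t = ContingencyTable2x2(428, 7544, 1775, 40975)
        res = chi_squared_yates(t, correction=False)
        obs = t.counts
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        brute = ((obs - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(brute, abs=1e-12)
        assert res.statistic == pytest.approx(23.94, abs=5e-3)

    @given(
        st.tuples(*[st.integers(1, 400)] * 4)
    )
    @settings(max_examples=50, deadline=None)
    def test_correction_never_increases_statistic(self, cells):
        t = ContingencyTable2x2(*cells)
        corrected = chi_squared_yates(t).statistic
        plain = chi_squared_yates(t, correction=False).statistic
        assert corrected <= plain + 1e-12

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_squared_yates(ContingencyTable2x2(0, 0, 5, 5))


def ecdf_sup(a, b):
    """Brute-force two-sample KS statistic via explicit ECDF evaluation."""
    grid = np.concatenate([a, b])
    fa = np.array([(a <= x).mean() for x in grid])
    fb = np.array([(b <= x).mean() for x in grid])
    return np.abs(fa - fb).max()


class TestKsCompare:
    def test_identical_samples(self):
        d, p = ks_compare([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_compare([0.0], [1.0])
        assert d == 1.0

    def test_matches_bruteforce_ecdf_on_uniform_samples(self, rng):
        a, b = rng.random(1000), rng.random(1000)
        d, _ = ks_compare(a, b)
        assert d == pytest.approx(ecdf_sup(a, b), abs=1e-8)

    def test_one_sided_directions(self, rng):
        small = rng.normal(0, 1, 800)
        large = rng.normal(1, 1, 800)
        _, p_less = ks_compare(small, large, "a_less")
        _, p_greater = ks_compare(small, large, "a_greater")
        assert p_less < 1e-10 < p_greater

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])
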
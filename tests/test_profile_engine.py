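"""Profile matrices, metaprofiles, row ordering and differential profiles."""

import numpy as np
import pytest

from bivalentscope.genomic_core import GenomicInterval, SignalTrack
from bivalentscope.profile_engine import (
    MetaProfile,
    ProfileMatrix,
    build_scaled_body_matrix,
    build_tss_matrix,
    compare_profiles,
    genebody_density,
    mean_profile,
    order_rows,
)
from conftest import make_gene


def delta_track(chrom, pos, value=1.0, sizes=None):
    return SignalTrack.from_intervals([(chrom, pos, pos + 1, value)], sizes)


class TestTssMatrix:
    def test_zero_track_gives_zero_matrix(self, empty_track):
        genes = [make_gene("g1"), make_gene("g2", start=20_000, end=25_000)]
        m = build_tss_matrix(empty_track, genes, flank=1000, bin_width=50)
        assert m.values.shape == (2, 40)
        assert np.all(m.values == 0)
        assert np.all(np.diff(m.axis) > 0)
        assert m.axis[0] == -m.axis[-1]  # symmetric about 0

    def test_unit_signal_at_tss_lands_in_first_downstream_bin(self):
        g = make_gene(start=1000, end=5000, strand="+")
        track = delta_track("chr1", 1000)
        m = build_tss_matrix(track, [g], flank=500, bin_width=50)
        nz = np.flatnonzero(m.values[0])
        assert list(nz) == [10]  # first bin right of 0
        assert m.axis[10] == 25.0

    def test_minus_strand_downstream_signal_maps_to_positive_axis(self):
        # gene on -, tss = 4999; 200 bp downstream along transcript = base 4799
        g = make_gene(start=1000, end=5000, strand="-")
        track = delta_track("chr1", 4799)
        m = build_tss_matrix(track, [g], flank=500, bin_width=50)
        nz = np.flatnonzero(m.values[0])
        assert list(nz) == [14]
        assert m.axis[14] == 225.0  # bin covering offset +200

    def test_conservation_at_single_bp_bins(self):
        rng = np.random.default_rng(0)
        runs = [("chr1", int(p), int(p) + 1, float(v))
                for p, v in zip(rng.choice(2000, 50, replace=False), rng.random(50))]
        track = SignalTrack.from_intervals(runs, {"chr1": 10_000})
        g = make_gene(start=1000, end=3000, strand="+")
        m = build_tss_matrix(track, [g], flank=1000, bin_width=1)
        window_total = track.integral("chr1", 0, 2000)
        assert m.values[0].sum() == pytest.approx(window_total, abs=1e-9)

    def test_mirror_genome_leaves_matrix_unchanged(self):
        L = 50_000
        rng = np.random.default_rng(1)
        pos = rng.choice(L - 1, 200, replace=False)
        vals = rng.random(200)
        fwd = SignalTrack.from_intervals(
            [("chr1", int(p), int(p) + 1, float(v)) for p, v in zip(pos, vals)],
            {"chr1": L},
        )
        rev = SignalTrack.from_intervals(
            [("chr1", L - 1 - int(p), L - int(p), float(v)) for p, v in zip(pos, vals)],
            {"chr1": L},
        )
        g_fwd = make_gene(start=20_000, end=30_000, strand="+")
        g_rev = make_gene(start=L - 30_000, end=L - 20_000, strand="-")
        m_fwd = build_tss_matrix(fwd, [g_fwd], flank=5000, bin_width=50)
        m_rev = build_tss_matrix(rev, [g_rev], flank=5000, bin_width=50)
        np.testing.assert_allclose(m_fwd.values, m_rev.values, atol=1e-12)

    def test_empty_gene_list_rejected(self, empty_track):
        with pytest.raises(ValueError):
            build_tss_matrix(empty_track, [], flank=1000, bin_width=50)


class TestScaledBodyMatrix:
    def test_uniform_coverage_fills_body_bins(self, uniform_track):
        for length in (3000, 7000):
            g = make_gene(start=30_000, end=30_000 + length, strand="+")
            m = build_scaled_body_matrix(uniform_track, [g], flank=2000,
                                         n_body_bins=100, bin_width=50)
            body = m.values[0][40:140]
            np.testing.assert_allclose(body, 2.0)

    def test_signal_in_first_half_of_gene(self):
        g = make_gene(start=10_000, end=14_000, strand="+")
        track = SignalTrack.from_intervals([("chr1", 10_000, 12_000, 1.0)])
        m = build_scaled_body_matrix(track, [g], flank=2000, n_body_bins=100,
                                     bin_width=50)
        body = m.values[0][40:140]
        np.testing.assert_allclose(body[:50], 1.0)
        np.testing.assert_allclose(body[50:], 0.0)

    def test_minus_strand_body_reads_5prime_to_3prime(self):
        # signal over the first transcribed half of a minus-strand gene
        g = make_gene(start=10_000, end=14_000, strand="-")
        track = SignalTrack.from_intervals([("chr1", 12_000, 14_000, 1.0)])
        m = build_scaled_body_matrix(track, [g], flank=2000, n_body_bins=100,
                                     bin_width=50)
        body = m.values[0][40:140]
        np.testing.assert_allclose(body[:50], 1.0)
        np.testing.assert_allclose(body[50:], 0.0)

    def test_empty_track_zero_matrix(self, empty_track):
        g = make_gene(start=10_000, end=14_000)
        m = build_scaled_body_matrix(empty_track, [g], flank=2000, n_body_bins=100)
        assert np.all(m.values == 0)

    def test_short_gene_flagged(self, uniform_track):
        g = make_gene("tiny", start=10_000, end=10_050)
        m = build_scaled_body_matrix(uniform_track, [g], flank=2000, n_body_bins=100)
        assert "tiny" in m.clipped
        np.testing.assert_allclose(m.values[0][40:140], 2.0)


class TestMeanProfile:
    def make_matrix(self, values):
        values = np.asarray(values, dtype=float)
        n, b = values.shape
        axis = np.arange(b) * 10.0
        return ProfileMatrix([f"g{i}" for i in range(n)], axis, values, "tss", b * 5, 10)

    def test_single_row_identity(self):
        m = self.make_matrix([[1.0, 2.0, 3.0]])
        mp = mean_profile(m)
        np.testing.assert_allclose(mp.values, [1, 2, 3])
        assert mp.n_genes == 1

    def test_two_rows_mean(self):
        m = self.make_matrix([[1.0, 2.0], [3.0, 6.0]])
        np.testing.assert_allclose(mean_profile(m).values, [2.0, 4.0])

    def test_matches_brute_force_column_mean(self):
        rng = np.random.default_rng(3)
        vals = rng.random((10, 7))
        m = self.make_matrix(vals)
        brute = np.array([sum(vals[i, j] for i in range(10)) / 10 for j in range(7)])
        np.testing.assert_allclose(mean_profile(m).values, brute, atol=1e-9)

    def test_empty_intersection_rejected(self):
        m = self.make_matrix([[1.0, 2.0]])
        with pytest.raises(ValueError):
            mean_profile(m, subset={"nope"})


class TestGenebodyDensity:
    def test_uniform_coverage(self, uniform_track):
        g = make_gene(start=1000, end=5000)
        assert genebody_density(uniform_track, g) == pytest.approx(2.0)

    def test_zero_track(self, empty_track):
        assert genebody_density(empty_track, make_gene()) == 0.0

    def test_three_run_toy_hand_sum(self):
        track = SignalTrack.from_intervals(
            [("chr1", 1000, 1100, 2.0), ("chr1", 2000, 2500, 1.0), ("chr1", 4900, 5000, 3.0)]
        )
        g = make_gene(start=1000, end=5000)
        expected = (2.0 * 100 + 1.0 * 500 + 3.0 * 100) / 4000
        assert genebody_density(track, g) == pytest.approx(expected)


class TestOrderRows:
    def make_matrix(self):
        vals = np.arange(10, dtype=float).reshape(5, 2)
        return ProfileMatrix([f"g{i}" for i in range(5)], np.array([0.0, 10.0]),
                             vals, "tss", 10, 10)

    def test_ordered_input_unchanged(self):
        m = self.make_matrix()
        key = {f"g{i}": 5 - i for i in range(5)}
        out = order_rows(m, key, descending=True)
        assert out.gene_ids == m.gene_ids
        np.testing.assert_array_equal(out.values, m.values)

    def test_reversed_key_reverses_rows(self):
        m = self.make_matrix()
        key = {f"g{i}": i for i in range(5)}
        out = order_rows(m, key, descending=True)
        assert out.gene_ids == [f"g{i}" for i in reversed(range(5))]

    def test_ties_break_by_gene_id(self):
        m = self.make_matrix()
        key = {"g0": 1.0, "g1": 1.0, "g2": 2.0, "g3": 1.0, "g4": 2.0}
        out = order_rows(m, key, descending=True)
        assert out.gene_ids == ["g2", "g4", "g0", "g1", "g3"]


class TestCompareProfiles:
    def make_pair(self, a_vals, b_vals):
        a_vals = np.asarray(a_vals, dtype=float)
        axis = np.arange(a_vals.shape[1]) * 10.0
        ids = [f"g{i}" for i in range(a_vals.shape[0])]
        ma = ProfileMatrix(ids, axis, a_vals, "tss", 10, 10)
        mb = ProfileMatrix(ids, axis, np.asarray(b_vals, dtype=float), "tss", 10, 10)
        return ma, mb

    def test_identical_conditions_are_null(self):
        rng = np.random.default_rng(4)
        vals = rng.random((20, 5))
        ma, mb = self.make_pair(vals, vals)
        cmp_ = compare_profiles(ma, mb, n_perm=199, seed=0)
        np.testing.assert_allclose(cmp_.diff, 0.0)
        np.testing.assert_allclose(cmp_.pvalues, 1.0)

    def test_constant_shift_recovered(self):
        rng = np.random.default_rng(5)
        vals = rng.random((20, 5))
        ma, mb = self.make_pair(vals, vals + 3.0)
        cmp_ = compare_profiles(ma, mb, n_perm=199, seed=0)
        np.testing.assert_allclose(cmp_.diff, -3.0)

    def test_axis_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        ma, _ = self.make_pair(rng.random((4, 5)), rng.random((4, 5)))
        mb = ProfileMatrix(ma.gene_ids, ma.axis + 1.0, ma.values, "tss", 10, 10)
        with pytest.raises(ValueError, match="axes"):
            compare_profiles(ma, mb)

    def test_planted_center_effect_vs_exhaustive_oracle(self):
        """A 2x reduction in center bins must be significant, flanks null, and
        MC p-values must track the exhaustive sign-flip null on a small case."""
        rng = np.random.default_rng(7)
        n, bins = 10, 12
        base = 1.0 + 0.1 * rng.random((n, bins))
        reduced = base.copy()
        center = slice(4, 8)
        reduced[:, center] *= 0.5
        noise_a = 0.02 * rng.standard_normal((n, bins))
        noise_b = 0.02 * rng.standard_normal((n, bins))
        ma, mb = self.make_pair(base + noise_a, reduced + noise_b)
        cmp_ = compare_profiles(ma, mb, n_perm=4000, seed=1)
        # exhaustive oracle: all 2^10 sign patterns
        delta = ma.values - mb.values
        obs = delta.mean(axis=0)
        signs = np.array(
            [[1 if (m >> i) & 1 else -1 for i in range(n)] for m in range(2**n)]
        )
        perm = signs @ delta / n
        exact_p = (np.abs(perm) >= np.abs(obs)[None, :] - 1e-12).mean(axis=0)
        assert np.all(exact_p[center] < 0.01)
        assert np.all(cmp_.pvalues[center] < 0.01)
        flank = [j for j in range(bins) if not (4 <= j < 8)]
        np.testing.assert_allclose(cmp_.pvalues[flank], exact_p[flank], atol=0.05)
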
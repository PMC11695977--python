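"""Binning, contact assignment, normalization, cis/trans and enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from triadmap import contacts as cm


@pytest.fixture
def genes():
    return pd.DataFrame(
        {
            "gene_id": ["gA", "gB"],
            "chrom": ["chr1", "chr2"],
            "start": [1_000_000, 50_000],
            "end": [1_010_000, 60_000],
            "strand": ["+", "-"],
            "biotype": ["lncRNA", "protein_coding"],
        }
    )


class TestMakeBins:
    def test_tiling_with_short_terminal_bin(self):
        bins = cm.make_bins({"chr1": 12_000}, cm.ContactConfig(bin_width=5000))
        assert bins.values.tolist() == [
            ["chr1", 0, 5000],
            ["chr1", 5000, 10_000],
            ["chr1", 10_000, 12_000],
        ]

    def test_width_larger_than_chromosome(self):
        bins = cm.make_bins({"chr1": 3000}, cm.ContactConfig(bin_width=5000))
        assert bins.values.tolist() == [["chr1", 0, 3000]]

    def test_bin_count_closed_form(self):
        sizes = {"chr1": 12_345, "chr2": 4999, "chr3": 50_000}
        cfg = cm.ContactConfig(bin_width=5000)
        bins = cm.make_bins(sizes, cfg)
        expected = sum(-(-s // 5000) for s in sizes.values())
        assert len(bins) == expected

    def test_zero_length_chromosome_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            bins = cm.make_bins({"chr1": 0, "chr2": 100}, cm.ContactConfig())
        assert set(bins.chrom) == {"chr2"}


def _parts_row(read_id, dna=("chr1", 7_000_100, True), rna=("chr1", 1_000_500, True),
               rna3=("chr1", 1_002_000, True)):
    return {
        "read_id": read_id, "dna_chrom": dna[0], "dna_pos": dna[1], "dna_unique": dna[2],
        "rna_chrom": rna[0], "rna_pos": rna[1], "rna_unique": rna[2],
        "rna3_chrom": rna3[0], "rna3_pos": rna3[1], "rna3_unique": rna3[2],
    }


class TestAssignContacts:
    sizes = {"chr1": 10_000_000, "chr2": 10_000_000}

    def test_single_valid_pair(self, genes):
        parts = pd.DataFrame([_parts_row("r1")])
        table, drops = cm.assign_contacts(parts, genes, self.sizes)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.rna_gene_id == "gA" and row.start == 7_000_000 and row.raw_count == 1
        assert sum(drops.values()) == 0

    def test_rna_mates_in_different_genes_dropped(self, genes):
        parts = pd.DataFrame([_parts_row("r1", rna3=("chr2", 55_000, True))])
        table, drops = cm.assign_contacts(parts, genes, self.sizes)
        assert len(table) == 0 and drops["rna_gene_mismatch"] == 1

    def test_non_unique_parts_dropped(self, genes):
        parts = pd.DataFrame(
            [
                _parts_row("r1", dna=("chr1", 7_000_100, False)),
                _parts_row("r2", rna=("chr1", 1_000_500, False)),
            ]
        )
        table, drops = cm.assign_contacts(parts, genes, self.sizes)
        assert len(table) == 0
        assert drops["dna_not_unique"] == 1 and drops["rna_not_unique"] == 1

    def test_rna_outside_any_gene_dropped(self, genes):
        parts = pd.DataFrame([_parts_row("r1", rna=("chr1", 5_000_000, True))])
        table, drops = cm.assign_contacts(parts, genes, self.sizes)
        assert len(table) == 0 and drops["rna_no_gene"] == 1

    def test_counts_aggregate_per_gene_bin(self, genes):
        parts = pd.DataFrame([_parts_row(f"r{i}") for i in range(5)])
        table, _ = cm.assign_contacts(parts, genes, self.sizes)
        assert len(table) == 1 and table.iloc[0].raw_count == 5


class TestNormalize:
    def test_single_contact_full_scale(self):
        table = pd.DataFrame(
            [("g", "chr1", 0, 5000, 1)],
            columns=["rna_gene_id", "chrom", "start", "end", "raw_count"],
        )
        out = cm.normalize(table)
        assert out.normalized_frequency.iloc[0] == 1e6

    def test_scale_invariance_under_depth_doubling(self):
        table = pd.DataFrame(
            [("g1", "chr1", 0, 5000, 3), ("g2", "chr1", 5000, 10_000, 7)],
            columns=["rna_gene_id", "chrom", "start", "end", "raw_count"],
        )
        a = cm.normalize(table)
        doubled = table.assign(raw_count=table.raw_count * 2)
        b = cm.normalize(doubled)
        assert np.allclose(a.normalized_frequency, b.normalized_frequency)

    def test_conservation(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            {
                "rna_gene_id": [f"g{i}" for i in range(50)],
                "chrom": "chr1",
                "start": np.arange(50) * 5000,
                "end": (np.arange(50) + 1) * 5000,
                "raw_count": rng.integers(1, 100, size=50),
            }
        )
        out = cm.normalize(table)
        assert np.isclose(out.normalized_frequency.sum(), 1e6)

    def test_empty_table(self):
        empty = pd.DataFrame(
            columns=["rna_gene_id", "chrom", "start", "end", "raw_count"]
        )
        out = cm.normalize(empty)
        assert len(out) == 0 and "normalized_frequency" in out


class TestClassifyCisTrans:
    def _table(self, chrom, start, end):
        return pd.DataFrame(
            [("gA", chrom, start, end, 1)],
            columns=["rna_gene_id", "chrom", "start", "end", "raw_count"],
        )

    def test_distal_same_chromosome_is_trans(self, genes):
        out = cm.classify_cis_trans(self._table("chr1", 7_000_000, 7_005_000), genes)
        assert out.rna_class.iloc[0] == "trans"  # gap 5,990,000

    def test_bin_inside_gene_is_cis(self, genes):
        out = cm.classify_cis_trans(self._table("chr1", 1_000_000, 1_005_000), genes)
        assert out.rna_class.iloc[0] == "cis"

    def test_exact_5mb_gap_is_cis(self, genes):
        # gene ends at 1,010,000; bin starting at 6,010,000 has gap exactly 5 Mb
        out = cm.classify_cis_trans(self._table("chr1", 6_010_000, 6_015_000), genes)
        assert out.rna_class.iloc[0] == "cis"
        out = cm.classify_cis_trans(self._table("chr1", 6_010_001, 6_015_001), genes)
        assert out.rna_class.iloc[0] == "trans"

    def test_other_chromosome_is_trans(self, genes):
        out = cm.classify_cis_trans(self._table("chr2", 0, 5000), genes)
        assert out.rna_class.iloc[0] == "trans"


class TestFrequencyDistribution:
    def _table(self, freqs):
        return pd.DataFrame({"normalized_frequency": freqs})

    def test_identical_tables_give_unit_fold_change(self):
        t = self._table([0.5, 1.5, 3.0, 7.0, 15.0, 30.0])
        out = cm.frequency_distribution(t, t)
        filled = out.dropna(subset=["fold_change"])
        assert (filled.fold_change == 1.0).all()

    def test_high_strata_enrichment(self):
        redc = self._table([0.5, 1.5, 15.0])
        redchip = self._table([0.5, 1.5, 15.0, 16.0, 18.0])
        out = cm.frequency_distribution(redc, redchip)
        high = out[(out.freq_lo == 10.0)].iloc[0]
        low = out[(out.freq_lo == 0.0)].iloc[0]
        assert high.fold_change == 3.0 and low.fold_change == 1.0

    def test_empty_stratum_is_nan_not_zero(self):
        redc = self._table([0.5])
        redchip = self._table([0.5, 15.0])
        out = cm.frequency_distribution(redc, redchip)
        assert np.isnan(out[out.freq_lo == 10.0].fold_change.iloc[0])

    def test_mismatched_scales_rejected(self):
        t = self._table([1.0])
        with pytest.raises(ValueError):
            cm.frequency_distribution(t, t, norm_scale_a=1e6, norm_scale_b=1e3)


def exact_signed_rank_p(diffs):
    """Two-sided exact signed-rank p by enumerating all 2^n sign vectors."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    ew = n * (n + 1) / 4
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        dist.append(sum(r for r, s in zip(ranks, signs) if s))
    dist = np.array(dist)
    p = np.mean(np.abs(dist - ew) >= abs(w_obs - ew) - 1e-12)
    return p


class TestSignedRank:
    def test_matches_exact_enumeration_small_vectors(self):
        rng = np.random.default_rng(8)
        for n in (5, 6, 8, 10):
            for _ in range(5):
                x = rng.normal(size=n)
                y = rng.normal(size=n)
                _, p = cm.signed_rank_test(x, y)
                assert np.isclose(p, exact_signed_rank_p(x - y), atol=1e-12)

    def test_six_pair_toy_vector(self):
        x = np.array([3.1, 2.0, 4.5, 1.2, 6.6, 0.3])
        y = np.array([1.0, 2.5, 3.0, 0.4, 2.2, 0.1])
        _, p = cm.signed_rank_test(x, y)
        assert np.isclose(p, exact_signed_rank_p(x - y), atol=1e-12)


class TestPeakOverlap:
    def _contacts(self):
        return pd.DataFrame(
            {
                "rna_gene_id": ["g1"] * 4 + ["g2"] * 4,
                "chrom": "chr1",
                "start": [0, 5000, 10_000, 15_000] * 2,
                "end": [5000, 10_000, 15_000, 20_000] * 2,
                "raw_count": 1,
                "normalized_frequency": [10.0, 1.0, 12.0, 2.0, 8.0, 0.5, 9.0, 1.5],
            }
        )

    def test_all_bins_covered_by_peaks(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [20_000]})
        out, _ = cm.peak_overlap_frequencies(self._contacts(), peaks)
        assert out.in_peak.all()

    def test_peak_equal_to_bin_marks_exactly_that_bin(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [5000], "end": [10_000]})
        out, _ = cm.peak_overlap_frequencies(self._contacts(), peaks)
        assert out.in_peak.tolist() == [False, True, False, False] * 2

    def test_planted_in_peak_enrichment_detected(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(30)]
        rows = []
        for g in genes:
            # two bins per gene: the peak bin carries higher frequency
            rows.append((g, "chr1", 0, 5000, 1, 10.0 + rng.normal(0, 1)))
            rows.append((g, "chr1", 5000, 10_000, 1, 2.0 + rng.normal(0, 1)))
        table = pd.DataFrame(
            rows,
            columns=["rna_gene_id", "chrom", "start", "end", "raw_count", "normalized_frequency"],
        )
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [5000]})
        _, res = cm.peak_overlap_frequencies(table, peaks)
        assert res["pvalue"] < 0.01 and res["n_pairs"] == 30


class TestShufflePeaks:
    def _peaks(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [100, 5000, 200],
                "end": [600, 5400, 900],
            }
        )

    def test_lengths_and_chromosomes_preserved(self):
        peaks = self._peaks()
        sizes = {"chr1": 100_000, "chr2": 100_000}
        out = cm.shuffle_peaks(peaks, sizes, seed=1)
        assert (out.end - out.start).tolist() == (peaks.end - peaks.start).tolist()
        assert out.chrom.tolist() == peaks.chrom.tolist()

    def test_per_chromosome_bp_conserved(self):
        peaks = self._peaks()
        sizes = {"chr1": 100_000, "chr2": 100_000}
        out = cm.shuffle_peaks(peaks, sizes, seed=2)
        for chrom in ("chr1", "chr2"):
            a = (peaks[peaks.chrom == chrom].end - peaks[peaks.chrom == chrom].start).sum()
            b = (out[out.chrom == chrom].end - out[out.chrom == chrom].start).sum()
            assert a == b

    def test_deterministic_under_seed(self):
        peaks = self._peaks()
        sizes = {"chr1": 100_000, "chr2": 100_000}
        assert cm.shuffle_peaks(peaks, sizes, seed=3).equals(
            cm.shuffle_peaks(peaks, sizes, seed=3)
        )

    def test_no_overlap_among_shuffled(self):
        rng = np.random.default_rng(0)
        starts = rng.choice(50_000, size=30, replace=False) * 2
        peaks = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 500})
        out = cm.shuffle_peaks(peaks, {"chr1": 200_000}, seed=4).sort_values("start")
        assert (out.start.to_numpy()[1:] >= out.end.to_numpy()[:-1]).all()

    def test_crowded_chromosome_raises(self):
        peaks = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [0, 400, 800], "end": [400, 800, 1200]}
        )
        with pytest.raises(ValueError):
            cm.shuffle_peaks(peaks, {"chr1": 1210}, seed=5, max_tries=50)
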
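"""Window scanning, labeling, and encoding rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histmark.dataset import (
    DEFAULT_MARKERS,
    OpennessTrack,
    build_batch,
    build_site_table,
    call_sites,
    center_region,
    encode_openness,
    encode_sequence,
    epigenome_passes_filter,
    load_dataset,
    save_dataset,
)
from histmark.formats_io import GenomicInterval, PaddedInterval, PeakRecord


def brute_force_call_sites(peaks, chrom_sizes, window_bp=200, step_bp=200,
                           min_overlap_bp=100):
    """Per-base oracle: mark union coverage, count per grid window."""
    out = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        covered = np.zeros(size, dtype=bool)
        for peak in peaks:
            if peak.interval.chrom == chrom:
                covered[max(0, peak.interval.start): min(size, peak.interval.end)] = True
        start = 0
        while start < size:
            if covered[start: start + window_bp].sum() >= min_overlap_bp:
                out.append(GenomicInterval(chrom, start, start + window_bp))
            start += step_bp
    return out


def random_peak_set(rng, size=10_000, max_peaks=12):
    peaks = []
    for _ in range(rng.integers(1, max_peaks + 1)):
        start = int(rng.integers(0, size - 1))
        length = int(rng.integers(1, 600))
        peaks.append(
            PeakRecord(GenomicInterval("chr1", start, min(start + length, size)))
        )
    return peaks


class TestCallSites:
    SIZES = {"chr1": 10_000}

    def test_full_containment_calls_both_windows(self):
        peaks = [PeakRecord(GenomicInterval("chr1", 0, 400))]
        assert call_sites(peaks, self.SIZES) == [
            GenomicInterval("chr1", 0, 200),
            GenomicInterval("chr1", 200, 400),
        ]

    def test_sub_threshold_overlaps_call_nothing(self):
        peaks = [PeakRecord(GenomicInterval("chr1", 150, 260))]
        assert call_sites(peaks, self.SIZES) == []

    def test_union_of_abutting_peaks_counts_jointly(self):
        peaks = [
            PeakRecord(GenomicInterval("chr1", 150, 200)),
            PeakRecord(GenomicInterval("chr1", 100, 150)),
        ]
        assert call_sites(peaks, self.SIZES) == [GenomicInterval("chr1", 0, 200)]

    def test_configuration_errors(self):
        peak = [PeakRecord(GenomicInterval("chr1", 0, 100))]
        with pytest.raises(ValueError):
            call_sites(peak, self.SIZES, window_bp=0)
        with pytest.raises(ValueError):
            call_sites(peak, self.SIZES, min_overlap_bp=300)
        with pytest.raises(KeyError):
            call_sites([PeakRecord(GenomicInterval("chrX", 0, 100))], self.SIZES)

    def test_matches_per_base_oracle_on_random_sets(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            peaks = random_peak_set(rng)
            assert call_sites(peaks, self.SIZES) == brute_force_call_sites(
                peaks, self.SIZES
            )

    def test_non_tiling_grid_also_matches_oracle(self):
        rng = np.random.default_rng(78)
        for _ in range(10):
            peaks = random_peak_set(rng)
            got = call_sites(peaks, self.SIZES, window_bp=200, step_bp=100)
            expected = brute_force_call_sites(peaks, self.SIZES, step_bp=100)
            assert got == expected


class TestSiteTable:
    W1 = GenomicInterval("chr1", 0, 200)

    def test_shared_site_is_multilabel(self):
        table = build_site_table(
            {DEFAULT_MARKERS[0]: [self.W1], DEFAULT_MARKERS[1]: [self.W1]}
        )
        assert len(table) == 1
        np.testing.assert_array_equal(table.labels[0], [1, 1, 0, 0, 0, 0, 0])

    def test_disjoint_sets_union(self):
        a = [GenomicInterval("chr1", i * 200, i * 200 + 200) for i in range(3)]
        b = [GenomicInterval("chr2", i * 200, i * 200 + 200) for i in range(2)]
        table = build_site_table({DEFAULT_MARKERS[0]: a, DEFAULT_MARKERS[1]: b})
        assert len(table) == 5
        assert (table.labels.sum(axis=1) == 1).all()

    def test_all_markers_share_one_window(self):
        table = build_site_table({m: [self.W1] for m in DEFAULT_MARKERS})
        assert table.labels.shape == (1, 7)
        assert table.labels.sum() == 7

    def test_unknown_marker_rejected(self):
        with pytest.raises(KeyError):
            build_site_table({"H3K119ub": [self.W1]})

    def test_label_matrix_conserves_per_marker_counts(self, rng):
        windows = [GenomicInterval("chr1", i * 200, i * 200 + 200) for i in range(40)]
        per_marker = {
            m: [w for w in windows if rng.random() < 0.4] for m in DEFAULT_MARKERS
        }
        per_marker[DEFAULT_MARKERS[0]] = windows  # keep every row non-empty
        table = build_site_table(per_marker)
        total_sites = sum(len(v) for v in per_marker.values())
        assert int(table.labels.sum()) == total_sites


class TestEpigenomeFilter:
    def test_threshold_is_strict_less_than(self):
        base = {m: 60_000 for m in DEFAULT_MARKERS}
        assert epigenome_passes_filter(base)
        low = dict(base, **{DEFAULT_MARKERS[3]: 49_999})
        assert not epigenome_passes_filter(low)
        edge = dict(base, **{DEFAULT_MARKERS[3]: 50_000})
        assert epigenome_passes_filter(edge)

    def test_missing_marker_is_an_error(self):
        counts = {m: 60_000 for m in DEFAULT_MARKERS[:-1]}
        with pytest.raises(KeyError):
            epigenome_passes_filter(counts)


class TestCenterRegion:
    def test_midpoint_preserved(self):
        region = center_region(GenomicInterval("chr1", 1000, 1200))
        assert (region.chrom, region.start, region.end) == ("chr1", 600, 1600)

    def test_negative_start_allowed(self):
        region = center_region(GenomicInterval("chr1", 0, 200))
        assert (region.start, region.end) == (-400, 600)

    def test_parity_violation_rejected(self):
        with pytest.raises(ValueError):
            center_region(GenomicInterval("chr1", 0, 200), region_bp=999)


class TestEncodeSequence:
    def test_acgt_is_identity(self):
        np.testing.assert_array_equal(encode_sequence("ACGT"), np.eye(4))

    def test_n_is_zero_column(self):
        np.testing.assert_array_equal(encode_sequence("N"), np.zeros((4, 1)))

    def test_invalid_symbol_named(self):
        with pytest.raises(ValueError, match="X"):
            encode_sequence("ACGX")

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_column_sums_binary_and_n_count(self, seq):
        onehot = encode_sequence(seq)
        sums = onehot.sum(axis=0)
        assert set(np.unique(sums)) <= {0.0, 1.0}
        assert int((sums == 0).sum()) == seq.count("N")


class TestEncodeOpenness:
    REGION = GenomicInterval("chr1", 0, 1000)

    def test_empty_track_is_zero(self):
        out = encode_openness(OpennessTrack([]), self.REGION, chrom_size=1000)
        assert out.shape == (1000,)
        assert (out == 0).all()

    def test_covering_peak_assigns_fold_enrichment(self):
        track = OpennessTrack(
            [PeakRecord(GenomicInterval("chr1", 0, 1000), signal_value=5.2)]
        )
        out = encode_openness(track, self.REGION, chrom_size=1000)
        assert (out == np.float32(5.2)).all()

    def test_overlap_resolves_by_maximum(self):
        track = OpennessTrack(
            [
                PeakRecord(GenomicInterval("chr1", 0, 500), signal_value=2.0),
                PeakRecord(GenomicInterval("chr1", 400, 1000), signal_value=7.0),
            ]
        )
        out = encode_openness(track, self.REGION, chrom_size=1000)
        assert out[450] == 7.0 and out[100] == 2.0

    def test_padded_positions_are_zero(self):
        track = OpennessTrack(
            [PeakRecord(GenomicInterval("chr1", 0, 50), signal_value=3.0)]
        )
        region = PaddedInterval("chr1", -100, 100)
        out = encode_openness(track, region, chrom_size=50)
        assert (out[:100] == 0).all() and (out[100:150] == 3.0).all()
        assert (out[150:] == 0).all()

    def test_adding_a_peak_is_monotone(self, rng):
        base = [
            PeakRecord(
                GenomicInterval("chr1", int(s), int(s) + int(l)),
                signal_value=float(v),
            )
            for s, l, v in zip(
                rng.integers(0, 900, 5), rng.integers(1, 100, 5), rng.random(5) * 9
            )
        ]
        extra = PeakRecord(GenomicInterval("chr1", 200, 600), signal_value=4.5)
        before = encode_openness(OpennessTrack(base), self.REGION, chrom_size=1000)
        after = encode_openness(OpennessTrack(base + [extra]), self.REGION, chrom_size=1000)
        assert (after >= before).all()


class TestBuildBatch:
    @pytest.fixture
    def world(self, rng):
        genome = {
            "chr1": "".join(rng.choice(list("ACGT"), size=3000))
        }
        windows = [GenomicInterval("chr1", 0, 200), GenomicInterval("chr1", 1000, 1200)]
        labels = np.zeros((2, 7), dtype=np.uint8)
        labels[:, 0] = 1
        from histmark.dataset import SiteTable

        table = SiteTable("E000", DEFAULT_MARKERS, windows, labels)
        track = OpennessTrack(
            [PeakRecord(GenomicInterval("chr1", 0, 3000), signal_value=2.0)]
        )
        return genome, track, table

    def test_shape_contract(self, world):
        genome, track, table = world
        batch = build_batch(genome, track, table, [0])
        assert batch.seq.shape == (1, 4, 1000)
        assert batch.openness.shape == (1, 1, 1000)
        assert batch.labels.shape == (1, 7)

    def test_duplicated_rows_are_identical(self, world):
        genome, track, table = world
        batch = build_batch(genome, track, table, [1, 1])
        np.testing.assert_array_equal(batch.seq[0], batch.seq[1])

    def test_chromosome_start_window_left_pads(self, world):
        genome, track, table = world
        batch = build_batch(genome, track, table, [0])
        # the 200-bp window at position 0 centres a 1000-bp region at -400
        assert (batch.seq[0, :, :400] == 0).all()
        assert batch.seq[0, :, 400:].sum() == 600
        assert (batch.openness[0, 0, :400] == 0).all()
        assert (batch.openness[0, 0, 400:] == 2.0).all()

    def test_dataset_directory_roundtrip(self, world, tmp_path):
        genome, track, table = world
        batch = build_batch(genome, track, table)
        save_dataset(tmp_path / "ds", table, batch)
        table2, batch2, manifest = load_dataset(tmp_path / "ds")
        assert table2.windows == table.windows
        np.testing.assert_array_equal(table2.labels, table.labels)
        np.testing.assert_array_equal(batch2.seq, batch.seq)
        np.testing.assert_allclose(batch2.openness, batch.openness)
        assert manifest["n_sites"] == 2
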
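"""Quantization, thresholding, chunk sizing, de-duplication and the
end-to-end compression pipeline."""

import os

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldmx import (
    CompressionParams,
    DataError,
    compress,
    open_container,
    query_range,
    read_chunk,
    RegionQuery,
    write_banded_window,
)
from ldmx.compress import (
    apply_threshold,
    chunk_start_of,
    dedupe_variants,
    infer_chunk_size,
    partition_chunks,
    quantize,
)

from conftest import make_window, transform_truth


def total_entries(manifest):
    return sum(read_chunk(manifest, cs).n_entries for cs, _ in manifest.chunk_index)


class TestQuantize:
    def test_fixed_points_and_plain_rounding(self):
        assert quantize(1.0, 4) == 1.0
        assert quantize(-0.123449, 4) == -0.1234
        assert quantize(0.12344, 4) == 0.1234

    def test_tie_at_fourth_place_rounds_to_even(self):
        # 0.00005 is a tie at 4 decimals: half-even keeps the even digit 0
        assert quantize(0.00005, 4) == 0.0
        assert quantize(-0.00005, 4) == 0.0

    def test_lossless_marker_is_identity(self):
        v = np.array([0.123456789, -0.5])
        assert quantize(v, None) is v

    @settings(derandomize=True, max_examples=200)
    @given(
        v=st.floats(min_value=-1.0, max_value=1.0),
        d=st.integers(min_value=0, max_value=9),
    )
    def test_rounding_properties(self, v, d):
        q = float(quantize(v, d))
        assert abs(q - v) <= 0.5 * 10**-d + 1e-12
        assert float(quantize(q, d)) == q  # idempotent
        assert q == np.rint(q * 10**d) / 10**d  # representable at d decimals


class TestThreshold:
    def test_below_threshold_dropped(self):
        assert apply_threshold(0.05, 0.06) == 0.0

    def test_boundary_value_kept(self):
        assert apply_threshold(-0.06, 0.06) == -0.06

    def test_zero_threshold_is_identity(self):
        assert apply_threshold(0.9, 0.0) == 0.9

    def test_array_form_preserves_survivors_exactly(self):
        v = np.array([0.05, -0.061, 0.12, 1.0, 0.0])
        out = apply_threshold(v, 0.06)
        assert np.array_equal(out, [0.0, -0.061, 0.12, 1.0, 0.0])

    @settings(derandomize=True, max_examples=100)
    @given(
        v=st.floats(min_value=-1.0, max_value=1.0),
        t1=st.floats(min_value=0.0, max_value=0.5),
        t2=st.floats(min_value=0.0, max_value=0.5),
    )
    def test_survivors_shrink_with_threshold(self, v, t1, t2):
        lo, hi = sorted([t1, t2])
        if apply_threshold(v, lo) == 0.0:
            assert apply_threshold(v, hi) == 0.0


class TestInferChunkSize:
    def test_ukbb_style_sliding_windows(self):
        # 3 Mb windows starting every 1 Mb -> 1 Mb chunks
        bounds = [
            (s, s + 3_000_000 - 1) for s in range(1, 20_000_000, 1_000_000)
        ]
        assert infer_chunk_size(bounds) == 1_000_000

    def test_single_window_uses_its_length(self):
        assert infer_chunk_size([(1, 2_000_000)]) == 2_000_000

    def test_modal_gap_of_half_megabase_starts(self):
        bounds = [(1, 10), (500_001, 10), (1_000_001, 10), (1_500_001, 10)]
        bounds = [(s, s + 1_499_999) for s, _ in bounds]
        assert infer_chunk_size(bounds) == 500_000

    def test_duplicate_windows_merged(self, caplog):
        bounds = [(1, 300_000), (1, 300_000), (100_001, 400_000)]
        with caplog.at_level("WARNING"):
            assert infer_chunk_size(bounds) == 100_000
        assert any("duplicate" in r.message for r in caplog.records)

    def test_empty_list_is_error(self):
        with pytest.raises(DataError):
            infer_chunk_size([])


class TestDedupeVariants:
    def test_exact_center_wins(self):
        bounds = [(1, 3_000_000), (1_000_000, 4_000_000)]
        pos = np.array([1_500_000])
        masks = dedupe_variants(bounds, [pos, pos])
        assert masks[0][0] and not masks[1][0]

    def test_nearest_center_wins_either_way(self):
        bounds = [(50, 150), (51, 151)]  # centers 100 and 101
        masks = dedupe_variants(bounds, [np.array([100]), np.array([100])])
        assert masks[0][0] and not masks[1][0]
        masks = dedupe_variants(bounds, [np.array([101]), np.array([101])])
        assert not masks[0][0] and masks[1][0]

    def test_equidistant_tie_goes_to_earlier_window(self):
        bounds = [(10, 110), (50, 150)]  # centers 60 and 100: tie at pos 80
        masks = dedupe_variants(bounds, [np.array([80]), np.array([80])])
        assert masks[0][0] and not masks[1][0]

    def test_triple_overlap_assignment_is_a_partition(self, small_fixture):
        """Brute-force check: every position owned exactly once, by the
        window with the nearest center."""
        paths, truth = small_fixture
        bounds = truth.window_bounds
        pos_lists = [
            truth.positions[
                (truth.positions >= s) & (truth.positions <= e)
            ]
            for s, e in bounds
        ]
        masks = dedupe_variants(bounds, pos_lists)
        owned = {}
        for k, (pos, mask) in enumerate(zip(pos_lists, masks)):
            for p in pos[mask]:
                assert p not in owned
                owned[int(p)] = k
        assert set(owned) == set(truth.positions.tolist())
        for p, k in owned.items():
            dists = [
                abs(p - (s + e) / 2)
                for (s, e), pl in zip(bounds, pos_lists)
                if s <= p <= e
            ]
            center = (bounds[k][0] + bounds[k][1]) / 2
            assert abs(p - center) == min(dists)


class TestPartitionChunks:
    def test_pair_is_owned_by_its_row_chunk(self):
        starts = partition_chunks(
            np.array([999_999]), np.array([1_000_050]), 1_000_000
        )
        assert starts.tolist() == [1]
        assert chunk_start_of(1_000_050, 1_000_000) == 1_000_001

    def test_random_pairs_repartition_brute_force(self):
        rng = np.random.default_rng(4)
        row = rng.integers(1, 5_000_000, size=1000)
        col = row + rng.integers(0, 100_000, size=1000)
        starts = partition_chunks(row, col, 250_000)
        for r, s in zip(row, starts):
            assert s <= r <= s + 250_000 - 1
            assert (s - 1) % 250_000 == 0
        # each pair in exactly one chunk: counts sum to the input size
        assert sum(np.bincount(starts // 250_000).tolist()) == 1000


class TestCompressPipeline:
    def test_empty_input_list_is_error(self, tmp_path):
        with pytest.raises(DataError, match="no input"):
            compress([], CompressionParams(), tmp_path / "c.h5")

    def test_mixed_chromosomes_is_error(self, tmp_path):
        w1 = make_window([10, 20], np.eye(2) + np.eye(2)[::-1] * 0.5, chrom="1")
        w2 = make_window([30, 40], np.eye(2) + np.eye(2)[::-1] * 0.5, chrom="2")
        p1 = write_banded_window(w1, tmp_path / "a.npz")
        p2 = write_banded_window(w2, tmp_path / "b.npz")
        with pytest.raises(DataError, match="chromosome"):
            compress([p1, p2], CompressionParams(), tmp_path / "c.h5")

    def test_conflicting_metadata_is_error(self, tmp_path):
        w1 = make_window([10, 20], np.eye(2))
        w2 = make_window([20, 30], np.eye(2))
        # same position 20, different vid ("v1" in w1, "v0" in w2)
        p1 = write_banded_window(w1, tmp_path / "a.npz")
        p2 = write_banded_window(w2, tmp_path / "b.npz")
        with pytest.raises(DataError, match="conflicting.*20"):
            compress([p1, p2], CompressionParams(), tmp_path / "c.h5")

    def test_lossy_parameters_keep_exactly_the_surviving_values(self, tmp_path):
        """decimals=4, threshold=0.06 on {0.05, 0.061, 0.12344}: only
        {0.061, 0.1234} survive."""
        vals = np.array(
            [
                [1.0, 0.05, 0.061, 0.12344],
                [0.05, 1.0, 0.0, 0.0],
                [0.061, 0.0, 1.0, 0.0],
                [0.12344, 0.0, 0.0, 1.0],
            ]
        )
        w = make_window([10, 20, 30, 40], vals)
        p = write_banded_window(w, tmp_path / "w.npz")
        m = compress(
            [p],
            CompressionParams(decimals=4, threshold=0.06),
            tmp_path / "c.h5",
        )
        chunk = read_chunk(m, m.chunk_index[0][0])
        assert sorted(chunk.vals.tolist()) == [0.061, 0.1234]

    def test_lossless_container_equals_input(self, small_fixture, small_lossless):
        _, truth = small_fixture
        res = query_range(small_lossless, RegionQuery(1, 10**9))
        assert np.array_equal(res.matrix, truth.matrix)

    @pytest.mark.parametrize("decimals,threshold", [(2, 0.1), (4, 0.06)])
    def test_lossy_fidelity(self, small_fixture, tmp_path, decimals, threshold):
        paths, truth = small_fixture
        m = compress(
            paths,
            CompressionParams(decimals=decimals, threshold=threshold),
            tmp_path / "c.h5",
        )
        res = query_range(m, RegionQuery(1, 10**9))
        assert np.array_equal(
            res.matrix, transform_truth(truth.matrix, decimals, threshold)
        )

    def test_entry_count_monotone_in_threshold(self, small_fixture, tmp_path):
        paths, _ = small_fixture
        counts = []
        for t in (0.06, 0.1):
            m = compress(
                paths,
                CompressionParams(decimals=4, threshold=t),
                tmp_path / f"t{t}.h5",
            )
            counts.append(total_entries(m))
        assert counts[1] <= counts[0]

    def test_idempotent_on_already_lossy_input(self, small_fixture, tmp_path):
        """Compressing the reconstruction of a lossy container with the
        same parameters stores an identical entry set."""
        from ldmx import reconstruct_original

        paths, truth = small_fixture
        params = CompressionParams(decimals=3, threshold=0.1)
        m1 = compress(paths, params, tmp_path / "c1.h5")
        outs = reconstruct_original(
            m1, truth.window_bounds, "plain", tmp_path / "rec"
        )
        m2 = compress(outs, params, tmp_path / "c2.h5")
        for (cs, _), (cs2, _) in zip(m1.chunk_index, m2.chunk_index):
            c1, c2 = read_chunk(m1, cs), read_chunk(m2, cs2)
            assert np.array_equal(c1.rows, c2.rows)
            assert np.array_equal(c1.cols, c2.cols)
            assert np.array_equal(c1.vals, c2.vals)

    def test_chunk_size_does_not_change_stored_content(
        self, small_fixture, tmp_path
    ):
        paths, _ = small_fixture
        params = lambda cs: CompressionParams(
            decimals=4, threshold=0.06, chunk_size_bp=cs
        )
        m1 = compress(paths, params(50_000), tmp_path / "a.h5")
        m2 = compress(paths, params(100_000), tmp_path / "b.h5")
        assert total_entries(m1) == total_entries(m2)

    def test_file_size_non_increasing_in_decimals(self, small_fixture, tmp_path):
        paths, _ = small_fixture
        sizes = []
        for d in (6, 4, 2):
            m = compress(
                paths, CompressionParams(decimals=d), tmp_path / f"d{d}.h5"
            )
            sizes.append(os.path.getsize(m.path))
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_inferred_chunk_size_recorded_in_manifest(self, small_lossless):
        assert small_lossless.chunk_size_bp == 100_000
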
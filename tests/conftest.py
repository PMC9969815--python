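"""Shared fixtures: synthetic window sets at two scales plus brute-force
oracle helpers used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from ldmx import (
    CompressionParams,
    HaploSimSpec,
    VariantRecord,
    BandedLDWindow,
    compress,
    generate_fixture,
)
from ldmx.compress import apply_threshold, quantize


# ---------------------------------------------------------------------------
# oracle helpers (independent brute force over the truth matrix)
# ---------------------------------------------------------------------------

def transform_truth(matrix: np.ndarray, decimals, threshold: float) -> np.ndarray:
    """Expected decoded content of a lossy container: quantize then
    threshold the truth matrix, diagonal pinned to 1."""
    out = apply_threshold(quantize(matrix.copy(), decimals), threshold)
    out = np.asarray(out, dtype=np.float64)
    np.fill_diagonal(out, 1.0)
    return out


def brute_submatrix(truth, selected_positions) -> np.ndarray:
    """Slice the full truth matrix down to the given positions."""
    idx = np.searchsorted(truth.positions, np.asarray(selected_positions))
    return truth.matrix[np.ix_(idx, idx)]


def make_window(positions, values, chrom="21", window_start=None,
                window_end=None, max_dist=10**9, maf=None) -> BandedLDWindow:
    """Small hand-built window for unit tests."""
    positions = list(positions)
    variants = [
        VariantRecord(
            chrom=chrom,
            pos=int(p),
            vid=f"v{k}",
            allele1="A",
            allele2="G",
            maf=None if maf is None else float(maf[k]),
        )
        for k, p in enumerate(positions)
    ]
    return BandedLDWindow(
        variants=variants,
        values=np.asarray(values, dtype=np.float64),
        window_start=window_start if window_start is not None else min(positions, default=1),
        window_end=window_end if window_end is not None else max(positions, default=1),
        max_dist=max_dist,
    )


# ---------------------------------------------------------------------------
# small fixture for unit tests (seconds)
# ---------------------------------------------------------------------------

SMALL_SPEC = dict(
    n_haplotypes=200, n_variants=300, span_bp=300_000, max_dist=100_000, seed=11
)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """(paths, truth) for a 300-variant, 3-window fixture."""
    out = tmp_path_factory.mktemp("small_windows")
    return generate_fixture(HaploSimSpec(**SMALL_SPEC), out)


@pytest.fixture(scope="session")
def small_lossless(small_fixture, tmp_path_factory):
    paths, _ = small_fixture
    out = tmp_path_factory.mktemp("small_lossless") / "c.h5"
    return compress(paths, CompressionParams(), out)


@pytest.fixture(scope="session")
def small_lossy(small_fixture, tmp_path_factory):
    """decimals=4, threshold=0.06 container over the small fixture."""
    paths, _ = small_fixture
    out = tmp_path_factory.mktemp("small_lossy") / "c.h5"
    return compress(paths, CompressionParams(decimals=4, threshold=0.06), out)


# ---------------------------------------------------------------------------
# full-scale fixture for the acceptance suite (default study conditions:
# 2,000 variants on 1,000 haplotypes, three overlapping 300 kb windows)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def accept_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("accept_windows")
    return generate_fixture(HaploSimSpec(seed=7), out)


@pytest.fixture(scope="session")
def accept_lossless(accept_fixture, tmp_path_factory):
    paths, _ = accept_fixture
    out = tmp_path_factory.mktemp("accept_lossless") / "c.h5"
    return compress(paths, CompressionParams(), out)


@pytest.fixture(scope="session")
def accept_lossy(accept_fixture, tmp_path_factory):
    paths, _ = accept_fixture
    out = tmp_path_factory.mktemp("accept_lossy") / "c.h5"
    return compress(paths, CompressionParams(decimals=4, threshold=0.06), out)
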
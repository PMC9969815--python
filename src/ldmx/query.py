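"""Queries against an LD container: region, loci-list and MAF-range
submatrix extraction, streamed output for large results, window
reconstruction, and heatmap plotting.

A stored pair lives in the chunk of its lower (row) position, so any query
whose selected positions are known can be answered completely from the
chunks containing those positions: for a selected pair (p, q), p <= q, the
row p is itself selected, hence its chunk is visited.

Results over more than ``STREAM_THRESHOLD_VARIANTS`` variants per side are
written to disk in row blocks rather than materialized (the in-memory and
streamed paths produce byte-identical files).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np

from .container import read_banded_window, read_chunk, write_banded_window
from .errors import CapabilityError, DataError, ParameterError
from .types import (
    BandedLDWindow,
    ContainerManifest,
    LociQuery,
    MafRange,
    QueryResult,
    RegionQuery,
    VariantRecord,
)

logger = logging.getLogger(__name__)

#: auto-stream when a result exceeds this many variants per side
STREAM_THRESHOLD_VARIANTS = 2000

PathLike = Union[str, Path]
Query = Union[RegionQuery, LociQuery, MafRange, tuple[MafRange, RegionQuery]]


# ---------------------------------------------------------------------------
# chunk location and position selection
# ---------------------------------------------------------------------------

def locate_chunks(
    manifest: ContainerManifest, query_span: tuple[int, int]
) -> list[int]:
    """Chunk starts whose [chunk_start, chunk_end] intersects the span."""
    start, end = query_span
    return [cs for cs, ce in manifest.chunk_index if cs <= end and ce >= start]


def _variants_of_chunks(
    manifest: ContainerManifest, chunk_starts: Sequence[int]
) -> tuple[np.ndarray, list[VariantRecord]]:
    """All variants of the given chunks, in position order."""
    positions: list[np.ndarray] = []
    records: list[VariantRecord] = []
    for cs in chunk_starts:  # chunk_index is sorted, chunks do not overlap
        chunk = read_chunk(manifest, cs)
        positions.append(chunk.positions)
        maf = chunk.maf
        for i in range(chunk.n_variants):
            records.append(
                VariantRecord(
                    chrom=manifest.chrom,
                    pos=int(chunk.positions[i]),
                    vid=str(chunk.vid[i]),
                    allele1=str(chunk.allele1[i]),
                    allele2=str(chunk.allele2[i]),
                    maf=float(maf[i]) if maf is not None else None,
                )
            )
    pos = (
        np.concatenate(positions) if positions else np.zeros(0, dtype=np.int64)
    )
    return pos, records


def _select_positions(manifest: ContainerManifest, query: Query) -> tuple[
    np.ndarray, list[VariantRecord], list[int]
]:
    """Resolve a query to (selected positions, their records, missing)."""
    if isinstance(query, RegionQuery):
        chunks = locate_chunks(manifest, (query.start, query.end))
        pos, recs = _variants_of_chunks(manifest, chunks)
        keep = (pos >= query.start) & (pos <= query.end)
        return pos[keep], [r for r, k in zip(recs, keep) if k], []
    if isinstance(query, LociQuery):
        wanted = np.asarray(query.positions, dtype=np.int64)
        if wanted.size == 0:
            return np.zeros(0, dtype=np.int64), [], []
        chunks = locate_chunks(manifest, (int(wanted[0]), int(wanted[-1])))
        pos, recs = _variants_of_chunks(manifest, chunks)
        keep = np.isin(pos, wanted)
        found = pos[keep]
        missing = sorted(set(wanted.tolist()) - set(found.tolist()))
        return found, [r for r, k in zip(recs, keep) if k], missing
    mrange, region = (
        query if isinstance(query, tuple) else (query, None)
    )
    if not isinstance(mrange, MafRange):
        raise ParameterError(f"unsupported query type: {type(query).__name__}")
    if not manifest.has_maf:
        raise CapabilityError("container has no MAF data")
    if region is not None:
        chunks = locate_chunks(manifest, (region.start, region.end))
    else:
        chunks = [cs for cs, _ in manifest.chunk_index]
    pos, recs = _variants_of_chunks(manifest, chunks)
    maf = np.asarray([r.maf for r in recs], dtype=np.float64)
    keep = (maf >= mrange.lo) & (maf <= mrange.hi)
    if region is not None:
        keep &= (pos >= region.start) & (pos <= region.end)
    return pos[keep], [r for r, k in zip(recs, keep) if k], []


def _fill_matrix(
    manifest: ContainerManifest, positions: np.ndarray
) -> np.ndarray:
    """Dense symmetric submatrix over the given sorted positions."""
    n = positions.size
    matrix = np.zeros((n, n), dtype=np.float64)
    np.fill_diagonal(matrix, 1.0)
    if n == 0:
        return matrix
    for cs in locate_chunks(manifest, (int(positions[0]), int(positions[-1]))):
        chunk = read_chunk(manifest, cs)
        if chunk.n_entries == 0:
            continue
        row_pos = chunk.positions[chunk.rows]
        i = np.searchsorted(positions, row_pos)
        j = np.searchsorted(positions, chunk.cols)
        ok = (
            (i < n)
            & (j < n)
            & (positions[np.minimum(i, n - 1)] == row_pos)
            & (positions[np.minimum(j, n - 1)] == chunk.cols)
        )
        matrix[i[ok], j[ok]] = chunk.vals[ok]
        matrix[j[ok], i[ok]] = chunk.vals[ok]
    return matrix


# ---------------------------------------------------------------------------
# public query operations
# ---------------------------------------------------------------------------

def query_range(manifest: ContainerManifest, region: RegionQuery) -> QueryResult:
    """All container variants with position in the region, as a labeled
    symmetric submatrix (zeros where no value is stored)."""
    pos, recs, _ = _select_positions(manifest, region)
    if pos.size == 0:
        logger.warning(
            "region %d-%d contains no variants", region.start, region.end
        )
    return QueryResult(variants=recs, matrix=_fill_matrix(manifest, pos))


def query_loci(manifest: ContainerManifest, loci: LociQuery) -> QueryResult:
    """Submatrix over the found loci; absent loci are reported in
    ``missing``, never an error."""
    pos, recs, missing = _select_positions(manifest, loci)
    return QueryResult(
        variants=recs, matrix=_fill_matrix(manifest, pos), missing=missing
    )


def query_maf(
    manifest: ContainerManifest,
    mrange: MafRange,
    region: Optional[RegionQuery] = None,
) -> QueryResult:
    """Submatrix over variants with MAF in the closed interval
    ``[lo, hi]``, optionally intersected with a region."""
    query: Query = (mrange, region) if region is not None else mrange
    pos, recs, _ = _select_positions(manifest, query)
    return QueryResult(variants=recs, matrix=_fill_matrix(manifest, pos))


# ---------------------------------------------------------------------------
# output writing (shared by in-memory and streamed paths)
# ---------------------------------------------------------------------------

def _iter_blocks_from_matrix(
    matrix: np.ndarray, block_rows: int
) -> Iterator[tuple[int, np.ndarray]]:
    for a in range(0, matrix.shape[0], block_rows):
        yield a, matrix[a : a + block_rows]


def _iter_blocks_from_chunks(
    manifest: ContainerManifest, positions: np.ndarray, block_rows: int
) -> Iterator[tuple[int, np.ndarray]]:
    """Assemble result rows blockwise straight from the chunk groups.

    Memory is bounded by one block plus one chunk's entry arrays; chunks
    are re-scanned per block.
    """
    n = positions.size
    chunk_starts = (
        locate_chunks(manifest, (int(positions[0]), int(positions[-1])))
        if n
        else []
    )
    for a in range(0, n, block_rows):
        b = min(a + block_rows, n)
        block = np.zeros((b - a, n), dtype=np.float64)
        for i in range(a, b):
            block[i - a, i] = 1.0
        for cs in chunk_starts:
            chunk = read_chunk(manifest, cs)
            if chunk.n_entries == 0:
                continue
            row_pos = chunk.positions[chunk.rows]
            i = np.searchsorted(positions, row_pos)
            j = np.searchsorted(positions, chunk.cols)
            ok = (
                (i < n)
                & (j < n)
                & (positions[np.minimum(i, n - 1)] == row_pos)
                & (positions[np.minimum(j, n - 1)] == chunk.cols)
            )
            i, j, v = i[ok], j[ok], chunk.vals[ok]
            sel = (i >= a) & (i < b)
            block[i[sel] - a, j[sel]] = v[sel]
            sel = (j >= a) & (j < b)
            block[j[sel] - a, i[sel]] = v[sel]
        yield a, block


def _write_dense_csv(
    sink, positions: np.ndarray, blocks: Iterator[tuple[int, np.ndarray]]
) -> None:
    labels = [str(int(p)) for p in positions]
    sink.write("pos," + ",".join(labels) + "\n")
    for a, block in blocks:
        for r in range(block.shape[0]):
            sink.write(
                labels[a + r]
                + ","
                + ",".join(repr(float(x)) for x in block[r])
                + "\n"
            )


def _write_long_tsv(
    sink, positions: np.ndarray, blocks: Iterator[tuple[int, np.ndarray]]
) -> None:
    """Upper-triangle (pos_i, pos_j, value) triplets; zeros omitted."""
    sink.write("pos_i\tpos_j\tvalue\n")
    for a, block in blocks:
        for r in range(block.shape[0]):
            i = a + r
            row = block[r]
            for j in np.flatnonzero(row):
                if j >= i:
                    sink.write(
                        f"{int(positions[i])}\t{int(positions[j])}\t"
                        f"{float(row[j])!r}\n"
                    )


def write_result(result: QueryResult, path: PathLike, fmt: str = "dense") -> Path:
    """Write an in-memory result to disk (same bytes as the streamed path)."""
    path = Path(path)
    blocks = _iter_blocks_from_matrix(result.matrix, result.matrix.shape[0] or 1)
    with open(path, "w") as sink:
        if fmt == "dense":
            _write_dense_csv(sink, result.positions, blocks)
        elif fmt == "long":
            _write_long_tsv(sink, result.positions, blocks)
        else:
            raise ParameterError(f"unknown output format {fmt!r}")
    return path


def stream_result(
    manifest: ContainerManifest,
    query: Query,
    sink: PathLike,
    block_rows: int = 512,
    fmt: str = "dense",
) -> QueryResult:
    """Answer a query writing the result to ``sink`` in row blocks.

    The concatenated sink content is byte-identical to
    :func:`write_result` applied to the in-memory result of the same
    query. The returned :class:`QueryResult` carries no matrix.
    """
    pos, recs, missing = _select_positions(manifest, query)
    blocks = _iter_blocks_from_chunks(manifest, pos, block_rows)
    sink = Path(sink)
    with open(sink, "w") as fh:
        if fmt == "dense":
            _write_dense_csv(fh, pos, blocks)
        elif fmt == "long":
            _write_long_tsv(fh, pos, blocks)
        else:
            raise ParameterError(f"unknown output format {fmt!r}")
    return QueryResult(
        variants=recs, matrix=None, missing=missing, streamed=True, path=str(sink)
    )


def execute(
    manifest: ContainerManifest,
    query: Query,
    out: Optional[PathLike] = None,
    fmt: str = "dense",
    stream: Optional[bool] = None,
    block_rows: int = 512,
) -> QueryResult:
    """Run a query, streaming automatically when the result is large.

    ``stream=None`` auto-selects: stream iff an output path is given and
    the result exceeds ``STREAM_THRESHOLD_VARIANTS`` variants per side.
    """
    pos, recs, missing = _select_positions(manifest, query)
    if stream is None:
        stream = out is not None and pos.size > STREAM_THRESHOLD_VARIANTS
    if stream:
        if out is None:
            raise ParameterError("streaming requires an output path")
        return stream_result(manifest, query, out, block_rows=block_rows, fmt=fmt)
    result = QueryResult(
        variants=recs, matrix=_fill_matrix(manifest, pos), missing=missing
    )
    if out is not None:
        result.path = str(write_result(result, out, fmt=fmt))
    return result


# ---------------------------------------------------------------------------
# reconstruction and plotting
# ---------------------------------------------------------------------------

def reconstruct_original(
    manifest: ContainerManifest,
    windows: Sequence[tuple[int, int]],
    dialect: str,
    out_dir: PathLike,
) -> list[Path]:
    """Rebuild per-window banded LD files from the container.

    For a lossless container the emitted matrices equal the original
    inputs exactly; for a lossy one they equal the quantized + thresholded
    originals. One file ``window_<start>_<end>.npz`` per requested window.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for start, end in windows:
        result = query_range(manifest, RegionQuery(start, end))
        window = BandedLDWindow(
            variants=result.variants,
            values=result.matrix,
            window_start=start,
            window_end=end,
            max_dist=manifest.max_dist,
        )
        path = out_dir / f"window_{start}_{end}.npz"
        write_banded_window(window, path, dialect)
        paths.append(path)
    return paths


def plot_submatrix(result: QueryResult, image_path: PathLike) -> Path:
    """Heatmap of a query result: diverging scale fixed to [-1, 1],
    position-labeled axes."""
    if result.n == 0 or result.matrix is None:
        raise DataError("nothing to plot: empty query result")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(
        result.matrix, cmap="RdBu_r", vmin=-1.0, vmax=1.0, interpolation="nearest"
    )
    pos = result.positions
    n_ticks = min(10, result.n)
    ticks = np.linspace(0, result.n - 1, n_ticks).astype(int)
    ax.set_xticks(ticks)
    ax.set_yticks(ticks)
    ax.set_xticklabels([str(int(pos[t])) for t in ticks], rotation=90, fontsize=7)
    ax.set_yticklabels([str(int(pos[t])) for t in ticks], fontsize=7)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("position (bp)")
    fig.colorbar(im, ax=ax, label="LD (r)")
    fig.tight_layout()
    fig.savefig(image_path, dpi=120)
    plt.close(fig)
    return Path(image_path)
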
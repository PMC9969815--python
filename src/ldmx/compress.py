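"""Compression pipeline: overlapping banded windows -> one HDF5 container.

The input windows overlap (UKBB-style sliding windows), so most variants and
pairs appear in several files. Each variant is assigned to exactly one
source window — the one whose center is nearest its position, which
maximizes the band available on both sides — and every stored pair takes its
value from the row (lower-position) variant's assigned window. Pairs are
quantized (round-half-to-even to ``decimals`` places), thresholded
(``|r| < threshold`` dropped, equality kept), and partitioned into
non-overlapping chunks of ``chunk_size_bp`` base pairs: a pair lives in the
chunk containing its row position, its column recorded by absolute position
so the stored entries form a trapezoid reaching into later chunks.

Windows are processed one at a time and chunks are flushed as soon as no
later window can touch them, so peak memory is bounded by one window plus
the open chunk buffers.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .container import ContainerWriter, open_container, read_banded_window, read_window_bounds
from .errors import DataError
from .types import LOSSLESS, CompressionParams, ContainerManifest

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def quantize(v, decimals: Optional[int]):
    """Round LD values to ``decimals`` places, ties to even.

    ``decimals=None`` (lossless) returns the input unchanged. Accepts
    scalars or arrays; the result is exactly representable by the
    scaled-integer codec at the same number of decimals.
    """
    if decimals is None or decimals == LOSSLESS:
        return v
    return np.round(v, int(decimals))


def apply_threshold(v, threshold: float):
    """Zero out values with ``|v|`` strictly below ``threshold``.

    Values exactly equal to the threshold are kept (it is the minimum
    retained magnitude). Diagonal values (1.0) always survive since
    ``threshold < 1``.
    """
    if threshold == 0.0:
        return v
    arr = np.asarray(v, dtype=np.float64)
    out = np.where(np.abs(arr) < threshold, 0.0, arr)
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


def infer_chunk_size(bounds: Sequence[tuple[int, int]]) -> int:
    """Chunk width inferred from window overlap: the modal gap between
    consecutive distinct window starts (the step of the sliding windows).

    A single window yields its own length. Duplicate window starts are
    merged first (with a warning).
    """
    if not bounds:
        raise DataError("cannot infer chunk size from an empty window list")
    starts = sorted({s for s, _ in bounds})
    if len(starts) < len(bounds):
        logger.warning("duplicate window starts merged before chunk-size inference")
    if len(starts) == 1:
        s = starts[0]
        e = max(end for b, end in bounds if b == s)
        return e - s + 1
    gaps = np.diff(starts)
    modal = Counter(int(g) for g in gaps).most_common()
    best = min(count_size[0] for count_size in modal if count_size[1] == modal[0][1])
    return best


def dedupe_variants(
    bounds: Sequence[tuple[int, int]],
    positions_per_window: Sequence[np.ndarray],
) -> list[np.ndarray]:
    """Assign each variant position to exactly one source window.

    The winner is the window (among those containing the position) whose
    center is nearest the position; ties go to the earlier window. Returns,
    per window, a boolean mask over that window's positions marking the
    variants it owns.
    """
    order = sorted(range(len(bounds)), key=lambda k: bounds[k])
    best: dict[int, tuple[float, int]] = {}  # pos -> (distance, window rank)
    for rank, k in enumerate(order):
        ws, we = bounds[k]
        center = (ws + we) / 2.0
        for p in positions_per_window[k]:
            p = int(p)
            d = abs(p - center)
            if p not in best or d < best[p][0]:
                best[p] = (d, rank)
    masks: list[np.ndarray] = [None] * len(bounds)  # type: ignore[list-item]
    for rank, k in enumerate(order):
        pos = positions_per_window[k]
        masks[k] = np.asarray([best[int(p)][1] == rank for p in pos], dtype=bool)
    return masks


def chunk_start_of(pos: int, chunk_size_bp: int) -> int:
    """1-based start of the chunk containing ``pos``."""
    return ((pos - 1) // chunk_size_bp) * chunk_size_bp + 1


def partition_chunks(
    row_pos: np.ndarray, col_pos: np.ndarray, chunk_size_bp: int
) -> np.ndarray:
    """Chunk start owning each pair: the chunk of the row (lower) position."""
    row_pos = np.asarray(row_pos, dtype=np.int64)
    return ((row_pos - 1) // chunk_size_bp) * chunk_size_bp + 1


class _ChunkBuffer:
    """Accumulates one chunk's variants and entries until flush."""

    __slots__ = ("meta", "row_pos", "col_pos", "vals")

    def __init__(self) -> None:
        self.meta: dict[int, tuple[str, str, str, Optional[float]]] = {}
        self.row_pos: list[np.ndarray] = []
        self.col_pos: list[np.ndarray] = []
        self.vals: list[np.ndarray] = []


def compress(
    input_paths: Sequence[PathLike],
    params: CompressionParams,
    output_path: PathLike,
    dialect: str = "plain",
    progress: bool = False,
) -> ContainerManifest:
    """Compress a set of overlapping window files into one container.

    All inputs must cover the same chromosome. Returns the manifest of the
    written container. ``progress=True`` wraps the window loop in a tqdm
    bar (useful from the CLI).
    """
    if not input_paths:
        raise DataError("no input files given")
    paths = [Path(p) for p in input_paths]

    # pre-scan: bounds + variant tables only (no matrices)
    scans = [read_window_bounds(p, dialect) for p in paths]
    order = sorted(range(len(paths)), key=lambda k: (scans[k]["window_start"], scans[k]["window_end"]))
    scans = [scans[k] for k in order]
    paths = [paths[k] for k in order]

    chroms = {s["chrom"] for s in scans if s["chrom"] is not None}
    if len(chroms) > 1:
        raise DataError(f"inputs mix chromosomes: {sorted(chroms)}")
    chrom = chroms.pop() if chroms else "NA"
    bounds = [(s["window_start"], s["window_end"]) for s in scans]
    max_dist = max(s["max_dist"] for s in scans)

    # cross-window metadata consistency, and global MAF availability
    seen: dict[int, tuple[str, str, str]] = {}
    has_maf = all("maf" in s["meta"].columns for s in scans)
    conflicts = []
    for s in scans:
        df = s["meta"]
        for pos, vid, a1, a2 in zip(
            df["position"], df["id"], df["allele1"], df["allele2"]
        ):
            key = (str(vid), str(a1), str(a2))
            prev = seen.setdefault(int(pos), key)
            if prev != key:
                conflicts.append(int(pos))
        # prune positions no later window can contain
        lo = s["window_start"]
        seen = {p: v for p, v in seen.items() if p >= lo}
    if conflicts:
        raise DataError(
            f"conflicting variant metadata across windows at positions "
            f"{sorted(set(conflicts))}"
        )

    chunk_size = params.chunk_size_bp or infer_chunk_size(bounds)
    masks = dedupe_variants(bounds, [s["positions"] for s in scans])

    all_pos = np.unique(np.concatenate([s["positions"] for s in scans]))
    if all_pos.size == 0:
        raise DataError("inputs contain no variants")
    first_chunk = chunk_start_of(int(all_pos[0]), chunk_size)
    last_chunk = chunk_start_of(int(all_pos[-1]), chunk_size)

    decimals = LOSSLESS if params.decimals is None else int(params.decimals)
    writer = ContainerWriter(
        output_path,
        chrom=chrom,
        chunk_size_bp=chunk_size,
        decimals=decimals,
        threshold=params.threshold,
        max_dist=max_dist,
        has_maf=has_maf,
    )

    buffers: dict[int, _ChunkBuffer] = defaultdict(_ChunkBuffer)
    n_entries_total = 0

    def flush(chunk_start: int) -> None:
        nonlocal n_entries_total
        buf = buffers.pop(chunk_start, _ChunkBuffer())
        pos = np.asarray(sorted(buf.meta), dtype=np.int64)
        local = {int(p): i for i, p in enumerate(pos)}
        meta = [buf.meta[int(p)] for p in pos]
        if buf.row_pos:
            rp = np.concatenate(buf.row_pos)
            cp = np.concatenate(buf.col_pos)
            vv = np.concatenate(buf.vals)
            srt = np.lexsort((cp, rp))
            rp, cp, vv = rp[srt], cp[srt], vv[srt]
            rows = np.asarray([local[int(p)] for p in rp], dtype=np.int32)
        else:
            rows = np.zeros(0, dtype=np.int32)
            cp = np.zeros(0, dtype=np.int64)
            vv = np.zeros(0, dtype=np.float64)
        nonlocal_maf = (
            np.asarray([m[3] for m in meta], dtype=np.float64) if has_maf else None
        )
        writer.write_chunk(
            chunk_start,
            chunk_start + chunk_size - 1,
            pos,
            np.asarray([m[0] for m in meta], dtype=object),
            np.asarray([m[1] for m in meta], dtype=object),
            np.asarray([m[2] for m in meta], dtype=object),
            nonlocal_maf,
            rows,
            cp,
            vv,
        )
        n_entries_total += len(cp)

    pending = list(range(first_chunk, last_chunk + 1, chunk_size))

    iterator = zip(paths, scans, masks)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc="windows", unit="window")

    try:
        for k, (path, scan, mask) in enumerate(iterator):
            window = read_banded_window(path, dialect)
            pos = window.positions
            vals = np.asarray(window.values, dtype=np.float64)
            vq = apply_threshold(quantize(vals, params.decimals), params.threshold)
            owned = np.flatnonzero(mask)
            for i in owned:
                p_i = int(pos[i])
                cols = np.flatnonzero(vq[i])
                cols = cols[pos[cols] > p_i]  # strict upper triangle, no diagonal
                cs = chunk_start_of(p_i, chunk_size)
                buf = buffers[cs]
                v = window.variants[i]
                buf.meta[p_i] = (v.vid, v.allele1, v.allele2, v.maf)
                if cols.size:
                    buf.row_pos.append(np.full(cols.size, p_i, dtype=np.int64))
                    buf.col_pos.append(pos[cols].astype(np.int64))
                    buf.vals.append(vq[i, cols])
            # flush chunks no later window can touch
            next_start = scan["window_end"] + 1
            if k + 1 < len(scans):
                next_start = scans[k + 1]["window_start"]
            while pending and pending[0] + chunk_size - 1 < next_start:
                flush(pending.pop(0))
        while pending:
            flush(pending.pop(0))
    finally:
        writer.close()

    logger.info(
        "wrote %s: %d chunks, %d stored entries", output_path,
        len(range(first_chunk, last_chunk + 1, chunk_size)), n_entries_total,
    )
    return open_container(output_path)
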
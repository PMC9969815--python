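"""On-disk formats: banded-window inputs and the chunked HDF5 container.

Two input dialects are supported for per-window LD files:

* ``plain`` — an NPZ archive holding the dense symmetric matrix plus window
  bounds, with an uncompressed TSV metadata table alongside.
* ``ukbb`` — an NPZ archive holding the upper triangle as a SciPy CSR sparse
  matrix (readable with :func:`scipy.sparse.load_npz`), with a gzipped TSV
  metadata table whose leading ``#key=value`` lines carry the window bounds.

The metadata table has header columns ``chromosome position id allele1
allele2`` and optionally ``maf``, one row per matrix row/column.

The container is a single HDF5 file: root attributes describe the
compression parameters, and one group per chunk (``chunk_<start>``) holds the
chunk's position table, string metadata, optional MAF array, and the sparse
upper-triangle entries. Lossy values are stored as scaled signed integers
(``round(v * 10**decimals)``) in the smallest sufficient width; lossless
values as 8-byte floats. All datasets use the shuffle + gzip(6) filters.

All writers are byte-deterministic: identical inputs produce identical
files, which makes outputs checksum-comparable across runs.
"""

from __future__ import annotations

import gzip
import io
import logging
import zipfile
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import FormatError, VersionError
from .types import (
    LOSSLESS,
    BandedLDWindow,
    ChunkRecord,
    ContainerManifest,
    VariantRecord,
)

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1
CREATOR = "ldmx 0.1.0"

DIALECTS = ("plain", "ukbb")

_META_COLS = ["chromosome", "position", "id", "allele1", "allele2"]

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# deterministic NPZ writing
# ---------------------------------------------------------------------------

def _write_npz(path: PathLike, arrays: dict[str, np.ndarray]) -> None:
    """Write an NPZ archive with fixed zip timestamps (byte-stable)."""
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.lib.format.write_array(
                buf, np.asanyarray(arr), allow_pickle=False
            )
            info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, buf.getvalue())


def _gzip_bytes(data: bytes) -> bytes:
    """Gzip without filename/mtime header fields (byte-stable)."""
    out = io.BytesIO()
    with gzip.GzipFile(fileobj=out, mode="wb", mtime=0) as gz:
        gz.write(data)
    return out.getvalue()


# ---------------------------------------------------------------------------
# banded-window files
# ---------------------------------------------------------------------------

def metadata_path(path: PathLike, dialect: str) -> Path:
    """Metadata table path paired with a matrix file path."""
    p = Path(path)
    stem = p.with_suffix("") if p.suffix == ".npz" else p
    return stem.with_name(stem.name + (".tsv" if dialect == "plain" else ".tsv.gz"))


def _check_dialect(dialect: str) -> None:
    if dialect not in DIALECTS:
        raise FormatError(f"unknown input dialect {dialect!r}; expected {DIALECTS}")


def _meta_to_frame(window: BandedLDWindow) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "chromosome": [v.chrom for v in window.variants],
            "position": [v.pos for v in window.variants],
            "id": [v.vid for v in window.variants],
            "allele1": [v.allele1 for v in window.variants],
            "allele2": [v.allele2 for v in window.variants],
        }
    )
    if window.has_maf:
        df["maf"] = [v.maf for v in window.variants]
    return df


def _frame_to_variants(df: pd.DataFrame) -> list[VariantRecord]:
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata table lacks required columns {missing}")
    has_maf = "maf" in df.columns
    return [
        VariantRecord(
            chrom=str(r.chromosome),
            pos=int(r.position),
            vid=str(r.id),
            allele1=str(r.allele1),
            allele2=str(r.allele2),
            maf=float(r.maf) if has_maf else None,
        )
        for r in df.itertuples(index=False)
    ]


def write_banded_window(
    window: BandedLDWindow, path: PathLike, dialect: str = "plain"
) -> Path:
    """Write one window in the chosen dialect; returns the matrix file path.

    Round-trip exact: :func:`read_banded_window` recovers the window
    value-for-value (float64 values are stored in binary, never as text).
    """
    _check_dialect(dialect)
    window.validate()
    path = Path(path)
    df = _meta_to_frame(window)
    bounds = {
        "window_start": np.int64(window.window_start),
        "window_end": np.int64(window.window_end),
        "max_dist": np.int64(window.max_dist),
    }
    if dialect == "plain":
        _write_npz(path, {"ld": np.asarray(window.values, dtype=np.float64), **bounds})
        df.to_csv(metadata_path(path, dialect), sep="\t", index=False)
    else:  # ukbb: upper triangle as scipy CSR, bounds in the gzipped TSV header
        upper = sp.csr_matrix(np.triu(np.asarray(window.values, dtype=np.float64)))
        _write_npz(
            path,
            {
                "data": upper.data,
                "indices": upper.indices,
                "indptr": upper.indptr,
                "shape": np.asarray(upper.shape, dtype=np.int64),
                "format": np.asarray(b"csr"),
            },
        )
        head = "".join(f"#{k}={int(v)}\n" for k, v in bounds.items())
        body = df.to_csv(sep="\t", index=False)
        metadata_path(path, dialect).write_bytes(
            _gzip_bytes((head + body).encode())
        )
    return path


def _read_metadata(path: PathLike, dialect: str) -> tuple[pd.DataFrame, dict]:
    mpath = metadata_path(path, dialect)
    if not mpath.exists():
        raise FormatError(f"metadata table not found: {mpath}")
    header: dict[str, int] = {}
    if dialect == "plain":
        df = pd.read_csv(
            mpath, sep="\t", dtype={"chromosome": str},
            float_precision="round_trip",
        )
    else:
        with gzip.open(mpath, "rt") as fh:
            lines = fh.readlines()
        n_head = 0
        for line in lines:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            header[k] = int(v)
            n_head += 1
        df = pd.read_csv(
            io.StringIO("".join(lines[n_head:])), sep="\t",
            dtype={"chromosome": str}, float_precision="round_trip",
        )
    return df, header


def read_banded_window(path: PathLike, dialect: str = "plain") -> BandedLDWindow:
    """Read a per-window LD file; symmetrizes the ``ukbb`` stored triangle.

    Raises :class:`FormatError` on dimension mismatch, non-monotone
    positions, asymmetry or out-of-range values beyond 1e-6.
    """
    _check_dialect(dialect)
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    df, header = _read_metadata(path, dialect)
    variants = _frame_to_variants(df)
    with np.load(path) as npz:
        if dialect == "plain":
            values = np.asarray(npz["ld"], dtype=np.float64)
            bounds = {
                k: int(npz[k]) for k in ("window_start", "window_end", "max_dist")
            }
        else:
            upper = sp.csr_matrix(
                (npz["data"], npz["indices"], npz["indptr"]),
                shape=tuple(npz["shape"]),
            )
            dense = upper.toarray()
            values = dense + dense.T
            np.fill_diagonal(values, np.diag(dense))
            bounds = header
            for k in ("window_start", "window_end", "max_dist"):
                if k not in bounds:
                    raise FormatError(f"metadata header lacks #{k}= line: {path}")
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise FormatError(f"LD matrix is not square: shape {values.shape}")
    if values.shape[0] != len(variants):
        raise FormatError(
            f"matrix dimension {values.shape[0]} does not match "
            f"metadata row count {len(variants)}"
        )
    window = BandedLDWindow(variants=variants, values=values, **bounds)
    window.validate()
    return window


def read_window_bounds(path: PathLike, dialect: str = "plain") -> dict:
    """Cheap pre-scan: window bounds, chromosome and positions — no matrix.

    Returns ``{"window_start", "window_end", "max_dist", "chrom",
    "positions", "meta"}`` where ``meta`` is the variant table.
    """
    _check_dialect(dialect)
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    df, header = _read_metadata(path, dialect)
    if dialect == "plain":
        with np.load(path) as npz:
            header = {
                k: int(npz[k]) for k in ("window_start", "window_end", "max_dist")
            }
    for k in ("window_start", "window_end", "max_dist"):
        if k not in header:
            raise FormatError(f"window bounds missing from {path}")
    chroms = set(df["chromosome"].astype(str)) if len(df) else set()
    if len(chroms) > 1:
        raise FormatError(f"multiple chromosomes in one window file: {sorted(chroms)}")
    return {
        **header,
        "chrom": chroms.pop() if chroms else None,
        "positions": df["position"].to_numpy(dtype=np.int64),
        "meta": df,
    }


# ---------------------------------------------------------------------------
# scaled-integer value codec
# ---------------------------------------------------------------------------

def _int_dtype(decimals: int) -> np.dtype:
    """Smallest signed integer dtype holding ``10**decimals`` (|r| <= 1)."""
    limit = 10 ** decimals
    for dt in (np.int8, np.int16, np.int32):
        if limit <= np.iinfo(dt).max:
            return np.dtype(dt)
    raise ValueError(f"decimals={decimals} out of supported range")


def encode_values(vals: np.ndarray, decimals: int) -> np.ndarray:
    """Encode already-quantized values for storage.

    Lossless (``decimals == LOSSLESS``): float64 pass-through. Lossy:
    ``round(v * 10**decimals)`` as the smallest sufficient signed integer.
    """
    vals = np.asarray(vals, dtype=np.float64)
    if decimals == LOSSLESS:
        return vals
    return np.rint(vals * 10 ** decimals).astype(_int_dtype(decimals))


def decode_values(stored: np.ndarray, decimals: int) -> np.ndarray:
    """Inverse of :func:`encode_values`; exact at the stored precision."""
    if decimals == LOSSLESS:
        return np.asarray(stored, dtype=np.float64)
    return np.asarray(stored, dtype=np.float64) / 10 ** decimals


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def chunk_group_name(chunk_start: int) -> str:
    return f"chunk_{chunk_start}"


_STR = h5py.string_dtype(encoding="utf-8")
_FILTERS = dict(compression="gzip", compression_opts=6, shuffle=True)


class ContainerWriter:
    """Incremental writer: one :meth:`write_chunk` call per chunk group."""

    def __init__(
        self,
        path: PathLike,
        *,
        chrom: str,
        chunk_size_bp: int,
        decimals: int,
        threshold: float,
        max_dist: int,
        has_maf: bool,
    ):
        self.path = Path(path)
        self._h5 = h5py.File(self.path, "w")
        self.decimals = decimals
        self.has_maf = has_maf
        attrs = self._h5.attrs
        attrs["format_version"] = np.int64(FORMAT_VERSION)
        attrs["chrom"] = str(chrom)
        attrs["chunk_size_bp"] = np.int64(chunk_size_bp)
        attrs["decimals"] = np.int64(decimals)
        attrs["threshold"] = float(threshold)
        attrs["max_dist"] = np.int64(max_dist)
        attrs["has_maf"] = np.int64(has_maf)
        attrs["creator"] = CREATOR

    def write_chunk(
        self,
        chunk_start: int,
        chunk_end: int,
        positions: np.ndarray,
        vid: np.ndarray,
        allele1: np.ndarray,
        allele2: np.ndarray,
        maf: Optional[np.ndarray],
        rows: np.ndarray,
        cols: np.ndarray,
        vals: np.ndarray,
    ) -> None:
        g = self._h5.create_group(chunk_group_name(chunk_start))
        g.attrs["chunk_start"] = np.int64(chunk_start)
        g.attrs["chunk_end"] = np.int64(chunk_end)
        g.attrs["n_variants"] = np.int64(len(positions))
        g.attrs["n_entries"] = np.int64(len(rows))

        def ds(name, data, dtype):
            g.create_dataset(name, data=np.asarray(data, dtype=dtype), **_FILTERS)

        ds("positions", positions, np.int64)
        ds("vid", vid, _STR)
        ds("allele1", allele1, _STR)
        ds("allele2", allele2, _STR)
        if self.has_maf:
            ds("maf", maf, np.float64)
        ds("rows", rows, np.int32)
        ds("cols", cols, np.int64)
        g.create_dataset(
            "vals", data=encode_values(np.asarray(vals), self.decimals), **_FILTERS
        )

    def close(self) -> None:
        self._h5.close()

    def __enter__(self) -> "ContainerWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def open_container(path: PathLike) -> ContainerManifest:
    """Read the root attributes and chunk index of an LD container."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"container not found: {path}")
    if not h5py.is_hdf5(path):
        raise FormatError(f"not an LD container (not an HDF5 file): {path}")
    with h5py.File(path, "r") as h5:
        attrs = dict(h5.attrs)
        if "format_version" not in attrs:
            raise FormatError(f"not an LD container (no format_version): {path}")
        version = int(attrs["format_version"])
        if version != FORMAT_VERSION:
            raise VersionError(
                f"unsupported container format version {version} "
                f"(this build reads version {FORMAT_VERSION})"
            )
        index = sorted(
            (int(g.attrs["chunk_start"]), int(g.attrs["chunk_end"]))
            for g in h5.values()
            if isinstance(g, h5py.Group)
        )
    return ContainerManifest(
        path=str(path),
        chrom=str(attrs["chrom"]),
        chunk_size_bp=int(attrs["chunk_size_bp"]),
        decimals=int(attrs["decimals"]),
        threshold=float(attrs["threshold"]),
        max_dist=int(attrs["max_dist"]),
        has_maf=bool(attrs["has_maf"]),
        chunk_index=index,
        format_version=version,
        creator=str(attrs.get("creator", "")),
    )


def read_chunk(manifest: ContainerManifest, chunk_start: int) -> ChunkRecord:
    """Load and decode one chunk group; values come back as float64."""
    name = chunk_group_name(chunk_start)
    with h5py.File(manifest.path, "r") as h5:
        if name not in h5:
            raise KeyError(f"no such chunk group: {name}")
        g = h5[name]
        maf = g["maf"][:] if "maf" in g else None
        return ChunkRecord(
            chunk_start=int(g.attrs["chunk_start"]),
            chunk_end=int(g.attrs["chunk_end"]),
            positions=g["positions"][:],
            vid=np.asarray(g["vid"].asstr()[:]),
            allele1=np.asarray(g["allele1"].asstr()[:]),
            allele2=np.asarray(g["allele2"].asstr()[:]),
            maf=maf,
            rows=g["rows"][:],
            cols=g["cols"][:],
            vals=decode_values(g["vals"][:], manifest.decimals),
        )
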
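"""Core domain types.

Coordinates are 1-based and inclusive throughout: a window ``[start, end]``
contains every variant whose position ``p`` satisfies ``start <= p <= end``.
LD values are the signed correlation ``r`` between 0/1 allele indicators and
therefore lie in ``[-1, 1]``; the diagonal is identically 1 and is never
stored on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import FormatError, ParameterError

#: tolerance for symmetry / range checks on floating-point input
FLOAT_TOL = 1e-6

#: marker for lossless value storage (no decimal truncation)
LOSSLESS = -1


@dataclass(frozen=True)
class VariantRecord:
    """One variant: the row/column label of every matrix in the package.

    Parameters
    ----------
    chrom : chromosome label (e.g. ``"21"``).
    pos : 1-based base-pair coordinate.
    vid : variant identifier (rsID or similar).
    allele1, allele2 : allele strings.
    maf : minor allele frequency in ``[0, 0.5]``, or ``None`` if unknown.
    """

    chrom: str
    pos: int
    vid: str
    allele1: str
    allele2: str
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"variant position must be >= 1, got {self.pos}")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise FormatError(
                f"MAF must lie in [0, 0.5], got {self.maf} at pos {self.pos}"
            )


@dataclass
class BandedLDWindow:
    """A square symmetric LD matrix over an ordered variant set, with values
    defined only within ``max_dist`` base pairs of the diagonal.

    ``values`` is dense ``(n, n)`` float64; entries beyond the band are zero.
    """

    variants: list[VariantRecord]
    values: np.ndarray
    window_start: int
    window_end: int
    max_dist: int

    @property
    def n(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([v.pos for v in self.variants], dtype=np.int64)

    @property
    def chrom(self) -> Optional[str]:
        return self.variants[0].chrom if self.variants else None

    @property
    def has_maf(self) -> bool:
        return bool(self.variants) and all(v.maf is not None for v in self.variants)

    def validate(self) -> None:
        """Raise :class:`FormatError` on any invariant violation."""
        n = self.n
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.shape != (n, n):
            raise FormatError(
                f"matrix dimension {vals.shape} does not match "
                f"metadata row count {n}"
            )
        if self.window_start > self.window_end:
            raise FormatError("window_start exceeds window_end")
        if n == 0:
            return
        pos = self.positions
        if np.any(np.diff(pos) <= 0):
            raise FormatError("variant positions are not strictly increasing")
        if pos[0] < self.window_start or pos[-1] > self.window_end:
            raise FormatError(
                f"variant positions [{pos[0]}, {pos[-1]}] outside window "
                f"[{self.window_start}, {self.window_end}]"
            )
        asym = np.max(np.abs(vals - vals.T)) if n else 0.0
        if asym > FLOAT_TOL:
            raise FormatError(f"matrix asymmetry {asym:.3g} exceeds {FLOAT_TOL}")
        if np.max(np.abs(vals)) > 1.0 + FLOAT_TOL:
            raise FormatError("LD values outside [-1, 1] beyond tolerance")
        if np.max(np.abs(np.diag(vals) - 1.0)) > FLOAT_TOL:
            raise FormatError("diagonal entries must equal 1")
        dist = np.abs(pos[:, None] - pos[None, :])
        off_band = (dist > self.max_dist) & (vals != 0.0)
        if np.any(off_band):
            i, j = np.argwhere(off_band)[0]
            raise FormatError(
                f"nonzero LD at positions {pos[i]},{pos[j]} beyond "
                f"max_dist={self.max_dist}"
            )

    def __eq__(self, other: object) -> bool:  # value-for-value equality
        if not isinstance(other, BandedLDWindow):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.window_start == other.window_start
            and self.window_end == other.window_end
            and self.max_dist == other.max_dist
            and self.values.shape == other.values.shape
            and bool(np.array_equal(self.values, other.values))
        )


@dataclass(frozen=True)
class CompressionParams:
    """Lossy-compression knobs.

    decimals : number of decimal places kept (0..9), or ``None`` for lossless.
    threshold : minimum retained ``|r|``; values strictly below are dropped.
    chunk_size_bp : chunk width in bp, or ``None`` to infer from the overlap
        of the input windows.
    """

    decimals: Optional[int] = None
    threshold: float = 0.0
    chunk_size_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.decimals is not None and not (0 <= int(self.decimals) <= 9):
            raise ParameterError(f"decimals must be in 0..9, got {self.decimals}")
        if not (0.0 <= self.threshold < 1.0):
            raise ParameterError(f"threshold must be in [0, 1), got {self.threshold}")
        if self.chunk_size_bp is not None and self.chunk_size_bp < 1:
            raise ParameterError(
                f"chunk_size_bp must be a positive integer, got {self.chunk_size_bp}"
            )


@dataclass
class ChunkRecord:
    """Decoded payload of one container chunk.

    ``rows`` are indices into ``positions`` (local to the chunk); ``cols``
    are absolute base-pair positions, which may point beyond ``chunk_end``
    into later chunks' territory (the trapezoid shape of banded storage).
    Only the upper triangle (``pos[row] <= col``) is stored and the diagonal
    is implicit.
    """

    chunk_start: int
    chunk_end: int
    positions: np.ndarray  # int64, sorted
    vid: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray
    maf: Optional[np.ndarray]
    rows: np.ndarray  # int32, local row indices
    cols: np.ndarray  # int64, absolute positions
    vals: np.ndarray  # float64, decoded

    @property
    def n_variants(self) -> int:
        return int(self.positions.size)

    @property
    def n_entries(self) -> int:
        return int(self.rows.size)


@dataclass
class ContainerManifest:
    """Root metadata of an LD container plus its chunk index."""

    path: str
    chrom: str
    chunk_size_bp: int
    decimals: int  # LOSSLESS (-1) for lossless storage
    threshold: float
    max_dist: int
    has_maf: bool
    chunk_index: list[tuple[int, int]]  # sorted (chunk_start, chunk_end)
    format_version: int
    creator: str = ""

    @property
    def lossless(self) -> bool:
        return self.decimals == LOSSLESS


@dataclass(frozen=True)
class RegionQuery:
    """Contiguous genomic span, 1-based inclusive."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParameterError(f"region start {self.start} > end {self.end}")


@dataclass(frozen=True)
class LociQuery:
    """Explicit list of positions; stored sorted and de-duplicated."""

    positions: tuple[int, ...]

    def __init__(self, positions: Sequence[int]):
        object.__setattr__(
            self, "positions", tuple(sorted(set(int(p) for p in positions)))
        )


@dataclass(frozen=True)
class MafRange:
    """Closed MAF interval ``[lo, hi]`` within ``[0, 0.5]``."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo <= self.hi <= 0.5):
            raise ParameterError(f"invalid MAF range [{self.lo}, {self.hi}]")


@dataclass
class QueryResult:
    """A labeled symmetric LD submatrix.

    ``missing`` lists requested positions absent from the container. A zero
    in ``matrix`` means "dropped by thresholding or never stored" — the
    container cannot distinguish the two. When ``streamed`` is true the
    matrix was written incrementally to ``path`` and ``matrix`` is ``None``.
    """

    variants: list[VariantRecord] = field(default_factory=list)
    matrix: Optional[np.ndarray] = None
    missing: list[int] = field(default_factory=list)
    streamed: bool = False
    path: Optional[str] = None

    @property
    def n(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([v.pos for v in self.variants], dtype=np.int64)
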
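"""Synthetic haplotype panels and the banded LD windows derived from them.

The generator emulates the structure of population-scale LD inputs:
haploblocks (runs of adjacent variants in high mutual LD, as produced by
recombination hotspots), a banded support (pairs beyond a maximum genomic
distance are never computed), per-variant MAF, and overlapping sliding
windows each holding the full matrix over its span.

Haplotypes are simulated by a copy-with-mutation chain: within a block each
variant's 0/1 column is the previous column with entries flipped at a small
rate, which yields a target adjacent-variant correlation and — because LD is
then measured on actual 0/1 data — guarantees every emitted matrix is a
mathematically valid correlation matrix with no post-hoc projection.

The module also returns the exact ground-truth banded matrix, which the
test suite uses as a brute-force oracle for compression and queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .container import write_banded_window
from .errors import DataError, ParameterError
from .types import BandedLDWindow, VariantRecord

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass
class HaploSimSpec:
    """Parameters of the simulated haplotype panel.

    Defaults give the standard fixture: 2,000 variants over 300 kb on 1,000
    haplotypes, ~10 kb haploblocks with 0.8 adjacent correlation, a 1% MAF
    floor, and a 100 kb band — which with the default window geometry
    (300 kb windows every 100 kb) yields three overlapping windows.
    """

    n_haplotypes: int = 1000
    n_variants: int = 2000
    positions: Optional[Sequence[int]] = None  # drawn over span_bp when None
    span_bp: int = 300_000
    block_length_bp: int = 10_000
    within_block_corr: float = 0.8
    maf_floor: float = 0.01
    max_dist: int = 100_000
    chrom: str = "21"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes < 2:
            raise ParameterError("need at least 2 haplotypes")
        if not (0.0 < self.within_block_corr < 1.0):
            raise ParameterError("within_block_corr must lie in (0, 1)")
        if not (0.0 < self.maf_floor < 0.5):
            raise ParameterError("maf_floor must lie in (0, 0.5)")
        if self.maf_floor < 1.0 / self.n_haplotypes:
            raise ParameterError(
                f"maf_floor={self.maf_floor} below the smallest nonzero "
                f"frequency 1/{self.n_haplotypes}"
            )

    def resolve_positions(self) -> np.ndarray:
        if self.positions is not None:
            pos = np.asarray(sorted(self.positions), dtype=np.int64)
            if len(np.unique(pos)) != len(pos):
                raise ParameterError("positions must be distinct")
            return pos
        rng = np.random.default_rng(self.seed)
        pos = rng.choice(
            np.arange(1, self.span_bp + 1), size=self.n_variants, replace=False
        )
        return np.sort(pos).astype(np.int64)


def _block_ids(positions: np.ndarray, mean_len_bp: int, rng) -> np.ndarray:
    """Assign variants to haploblocks with exponentially distributed lengths."""
    ids = np.zeros(positions.size, dtype=np.int64)
    if positions.size == 0:
        return ids
    block, start = 0, positions[0]
    limit = rng.exponential(mean_len_bp)
    for k, p in enumerate(positions):
        if p - start > limit:
            block += 1
            start = p
            limit = rng.exponential(mean_len_bp)
        ids[k] = block
    return ids


def simulate_haplotypes(spec: HaploSimSpec) -> np.ndarray:
    """Binary haplotype table, shape (n_haplotypes, n_variants).

    Deterministic given the spec's seed. Every column's minor-allele count
    is at least ``ceil(maf_floor * n_haplotypes)``.
    """
    rng = np.random.default_rng(spec.seed)
    positions = spec.resolve_positions()
    n, m = spec.n_haplotypes, positions.size
    blocks = _block_ids(positions, spec.block_length_bp, rng)
    mu = (1.0 - spec.within_block_corr) / 2.0  # flip rate for target corr
    min_minor = int(np.ceil(spec.maf_floor * n))
    haps = np.empty((n, m), dtype=np.uint8)

    def draw(k: int) -> np.ndarray:
        if k == 0 or blocks[k] != blocks[k - 1]:
            p = rng.uniform(spec.maf_floor, 1.0 - spec.maf_floor)
            return (rng.random(n) < p).astype(np.uint8)
        flips = rng.random(n) < mu
        return haps[:, k - 1] ^ flips

    for k in range(m):
        col = draw(k)
        for _ in range(200):  # resample rare-variant columns
            s = int(col.sum())
            if min(s, n - s) >= min_minor:
                break
            col = draw(k)
        else:
            # force the floor: flip majority-allele entries chosen at random
            s = int(col.sum())
            major = 1 if s > n - s else 0
            idx = np.flatnonzero(col == major)
            need = min_minor - min(s, n - s)
            col[rng.choice(idx, size=need, replace=False)] ^= 1
        haps[:, k] = col
    return haps


def ld_from_haplotypes(haps: np.ndarray, i: int, j: int) -> float:
    """Signed LD correlation r between variants i and j.

    r = (p_ij - p_i p_j) / sqrt(p_i (1 - p_i) p_j (1 - p_j)), where p_i is
    the allele-1 frequency of column i and p_ij the joint frequency.
    """
    x = np.asarray(haps[:, i], dtype=np.float64)
    y = np.asarray(haps[:, j], dtype=np.float64)
    p_i, p_j = x.mean(), y.mean()
    if p_i in (0.0, 1.0) or p_j in (0.0, 1.0):
        raise DataError(f"LD undefined: monomorphic column ({i}, {j})")
    p_ij = (x * y).mean()
    r = (p_ij - p_i * p_j) / np.sqrt(p_i * (1 - p_i) * p_j * (1 - p_j))
    return float(np.clip(r, -1.0, 1.0))


def _corr_matrix(haps: np.ndarray) -> np.ndarray:
    """Pairwise correlation of 0/1 columns; exact unit diagonal, symmetric."""
    m = np.corrcoef(np.asarray(haps, dtype=np.float64), rowvar=False)
    m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return m


def _band_mask(positions: np.ndarray, max_dist: int) -> np.ndarray:
    d = np.abs(positions[:, None] - positions[None, :])
    return d <= max_dist


@dataclass
class TruthBundle:
    """Ground truth behind a generated fixture: the full banded LD matrix
    and the variant table, for use as a brute-force oracle."""

    variants: list[VariantRecord]
    matrix: np.ndarray  # (n, n) banded, symmetric, unit diagonal
    window_bounds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([v.pos for v in self.variants], dtype=np.int64)

    @property
    def maf(self) -> np.ndarray:
        return np.asarray([v.maf for v in self.variants], dtype=np.float64)


_ALLELES = ("A", "C", "G", "T")


def _variant_table(
    positions: np.ndarray, haps: np.ndarray, chrom: str, meta_seed: int
) -> list[VariantRecord]:
    rng = np.random.default_rng(meta_seed)
    freq = haps.mean(axis=0)
    records = []
    for k, p in enumerate(positions):
        a1, a2 = rng.choice(4, size=2, replace=False)
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=int(p),
                vid=f"rs{k + 1:06d}",
                allele1=_ALLELES[a1],
                allele2=_ALLELES[a2],
                maf=float(min(freq[k], 1.0 - freq[k])),
            )
        )
    return records


def build_windows(
    haps: np.ndarray,
    positions: np.ndarray,
    window_bp: int,
    step_bp: int,
    max_dist: int,
    out_dir: PathLike,
    dialect: str = "plain",
    chrom: str = "21",
    meta_seed: int = 0,
    with_maf: bool = True,
) -> tuple[list[Path], TruthBundle]:
    """Write overlapping window files and return them with their truth.

    Windows start at 1 and every ``step_bp`` thereafter while variants
    remain, each spanning ``window_bp``; pairs beyond ``max_dist`` are
    zeroed inside every window (the banded support).
    """
    if window_bp < step_bp:
        raise ParameterError("window_bp must be >= step_bp")
    positions = np.asarray(positions, dtype=np.int64)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    variants = _variant_table(positions, haps, chrom, meta_seed)
    if not with_maf:
        variants = [
            VariantRecord(v.chrom, v.pos, v.vid, v.allele1, v.allele2, None)
            for v in variants
        ]

    truth_matrix = _corr_matrix(haps)
    truth_matrix[~_band_mask(positions, max_dist)] = 0.0

    paths: list[Path] = []
    bounds: list[tuple[int, int]] = []
    last = int(positions[-1]) if positions.size else 1
    start = 1
    while start <= last:
        end = start + window_bp - 1
        sel = np.flatnonzero((positions >= start) & (positions <= end))
        sub = truth_matrix[np.ix_(sel, sel)].copy()
        np.fill_diagonal(sub, 1.0)
        window = BandedLDWindow(
            variants=[variants[k] for k in sel],
            values=sub,
            window_start=start,
            window_end=end,
            max_dist=max_dist,
        )
        path = out_dir / f"ld_{chrom}_{start}_{end}.npz"
        write_banded_window(window, path, dialect)
        paths.append(path)
        bounds.append((start, end))
        start += step_bp
    return paths, TruthBundle(
        variants=variants, matrix=truth_matrix, window_bounds=bounds
    )


def generate_fixture(
    spec: HaploSimSpec,
    out_dir: PathLike,
    dialect: str = "plain",
    window_bp: Optional[int] = None,
    step_bp: Optional[int] = None,
    with_maf: bool = True,
) -> tuple[list[Path], TruthBundle]:
    """One-call fixture: simulate haplotypes and emit UKBB-style sliding
    windows (default geometry: window = 3 x step, step = ``max_dist``, so
    every banded pair is covered by some window)."""
    step = step_bp if step_bp is not None else spec.max_dist
    window = window_bp if window_bp is not None else 3 * step
    haps = simulate_haplotypes(spec)
    positions = spec.resolve_positions()
    return build_windows(
        haps,
        positions,
        window,
        step,
        spec.max_dist,
        out_dir,
        dialect=dialect,
        chrom=spec.chrom,
        meta_seed=spec.seed + 1,
        with_maf=with_maf,
    )
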
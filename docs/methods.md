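# Methods

## The data model

A linkage-disequilibrium (LD) matrix over an ordered set of variants holds
the signed correlation r between 0/1 allele indicators for every variant
pair within a maximum genomic distance (`max_dist`); outside that band the
value is never computed. The matrix is symmetric with unit diagonal and all
entries lie in [−1, 1]. Inputs arrive as overlapping sliding-window files
(each window holds the full matrix over its span), plus a per-variant
metadata table (chromosome, 1-based position, identifier, two alleles,
optional minor-allele frequency). All coordinates in this package are
1-based and inclusive.

## Compression

**De-duplication.** Because windows overlap, a variant (and most pairs)
appears in several files. Each variant position is assigned to exactly one
source window: the one whose center is nearest the position, which
maximizes the band available on both sides; exact ties go to the earlier
window. Every stored pair takes its value from the row (lower-position)
variant's assigned window. Conflicting metadata for the same position
across windows (different id or alleles) is a hard error.

**Lossy transform.** Values are first rounded to `decimals` places
(round-half-to-even, via numpy's scaled rounding), then entries with
|r| strictly below `threshold` are dropped; a value exactly equal to the
threshold survives — the threshold is the minimum retained magnitude.
Fixing quantize-before-threshold makes the pipeline's fidelity exactly
testable: the decoded container equals `threshold(quantize(input))`
elementwise, and re-compressing its own reconstruction with the same
parameters is a no-op. Values that round to exactly zero are never stored,
even at threshold 0, since an absent entry already decodes to zero. One
consequence worth noting: at a fixed nonzero threshold the stored-entry
count is not independent of `decimals` — coarser rounding can move values
just below the threshold up onto it (never past it downward when the
threshold is representable at every precision compared), so the count is
non-increasing as `decimals` grows.

**Chunking.** The container is tiled by non-overlapping chunks of
`chunk_size_bp` base pairs with boundaries at k·chunk_size+1; the tiling
runs from the chunk containing the first variant to the chunk containing
the last, including empty chunks in between. A pair belongs to the chunk
containing its row position; the column is stored as an absolute position,
so a chunk's entries form a trapezoid whose columns may reach up to
`max_dist` beyond its end without cross-chunk pointers. When no explicit
size is given, the chunk size is the modal gap between consecutive
distinct window starts — the step of the sliding windows — or the window
length if there is a single window.

**Encoding.** Lossy values are stored as scaled signed integers
`round(v·10^d)` in the smallest integer width that can hold 10^d (int8 up
to d=2, int16 up to d=4, int32 beyond); lossless values as float64. All
datasets use the HDF5 shuffle + gzip(6) filters. Integer scaling is what
makes 4-decimal data compress far better than floats: the codec is exact
(`decode(encode(v)) == round(v, d)` bit-for-bit), so lossy fidelity is
testable with equality, not tolerance. Every writer in the package (NPZ,
gzipped TSV, HDF5) is byte-deterministic — fixed zip timestamps, no gzip
filename/mtime header, no HDF5 creation times that vary — so identical
inputs yield checksum-identical files, and the CLI and library produce
byte-identical artifacts.

**Memory.** Windows are processed one at a time in genomic order; a chunk
is flushed to the container as soon as the next window's start lies beyond
it. Peak memory is one dense window plus the open chunk buffers (the
variant metadata tables, which are small relative to the matrices, are
pre-scanned to compute the assignment).

## Queries

A stored pair lives in the chunk of its row position, and for any selected
pair both endpoints are selected; therefore scanning exactly the chunks
that contain selected positions yields complete results. Range queries
select all variants in a span; loci queries select an explicit position
list, reporting absent positions in `missing` rather than failing; MAF
queries select variants whose MAF lies in a closed interval, optionally
intersected with a region. Range and loci queries never consult MAF. A
zero in a returned matrix means "dropped by thresholding or never stored"
— the container cannot distinguish the two.

Results above 2,000 variants per side (~4·10⁶ cells) are streamed: rows
are assembled block-by-block straight from the chunk groups and written
incrementally, bounding memory by one block plus one chunk's entries (at
the cost of re-scanning the touched chunks once per block). The streamed
and in-memory writers share the same formatting code, so their outputs are
byte-identical. Two output formats: dense CSV with positions as row/column
labels, and long-format TSV triplets (pos_i, pos_j, value) that omit
zeros. Floats are written with Python's shortest round-trip repr.

Reconstruction emits one banded-window file per requested span in either
input dialect; from a lossless container the rebuilt windows equal the
originals value-for-value, from a lossy one they equal the
quantized-and-thresholded originals.

## Input dialects

* `plain`: NPZ with the dense matrix and window bounds, plus a TSV
  metadata table.
* `ukbb`: NPZ holding the upper triangle as a SciPy CSR matrix (loadable
  with `scipy.sparse.load_npz`), plus a gzipped TSV whose leading
  `#key=value` lines carry the window bounds.

Metadata floats are parsed with round-trip precision so a written MAF
reads back as the identical double.

## Synthetic data

The generator emulates the structural features the compressor and query
engine depend on: haploblocks, banded support, per-variant MAF, and
overlapping window files — not population-genetic realism (no recombination
maps, demography, or coalescent genealogies; adjacent-variant correlation
is a single tunable constant rather than a decaying function of distance).
Passing tests therefore certify the storage and query machinery on validly
structured LD data, not inference on real cohorts.

Haplotypes are binary tables simulated by a copy-with-mutation chain:
block boundaries are drawn with exponentially distributed lengths (mean
`block_length_bp`, default 10 kb); the first variant of a block is
Bernoulli with a uniform frequency; each subsequent column copies its
neighbour with entries flipped at rate (1−ρ)/2, giving adjacent
correlation ≈ ρ (`within_block_corr`, default 0.8). Columns whose MAF
falls below `maf_floor` (default 0.01; must be ≥ 1/n_haplotypes to be
meaningful) are resampled, with a forced repair after 200 draws. Because
LD is then measured on actual 0/1 data, every emitted matrix is a
mathematically valid correlation matrix with no post-hoc projection, and
the metadata MAF equals the column's minor-allele frequency exactly. The
LD measure is the signed correlation r; r² is out of scope.

Default fixture geometry: 2,000 variants drawn uniformly over 300 kb on
1,000 haplotypes, `max_dist` = 100 kb, windows of 3×step sliding every
step = `max_dist` — three overlapping windows. With window = 3·step and
step = `max_dist`, every variant's assigned window covers its full forward
band, so the de-duplicated union of the windows reproduces the complete
banded truth matrix; the generator returns that matrix as the brute-force
oracle for the test suite. This scale keeps the whole suite and the
acceptance script in the tens of seconds on one CPU while exercising
multi-chunk, multi-window behaviour.

## Numerical and design choices

* Round-half-to-even at the scaled value (numpy semantics): `0.00005`
  rounds to `0.0` at 4 decimals. Ties are resolved on the double produced
  by `v·10^d`, which for decimal literals matches arbitrary-precision
  decimal rounding of the literal.
* Threshold comparison uses the decoded (post-rounding) value, so the
  stored set satisfies |v| ≥ t exactly.
* The streaming size threshold (2,000 variants per side) and the
  chunk-group dataset/attribute names are this package's own conventions.
* Diagonal entries are never stored; every position in a chunk's table
  implies r = 1 with itself.
* MAF absent from any input window disables MAF storage for the whole
  container (`has_maf=false`), and MAF queries against such a container
  raise a capability error.
* Manual chunk sizes need not divide the window step; content is invariant
  to chunking (only the grouping changes).
* Limitations: one chromosome per container; queries are position-based
  (no rsID lookup); third-party LD formats (e.g. LDStore2 `.bcor`, Hail
  block matrices) are not read; the per-block chunk re-scan makes streamed
  queries O(blocks × entries) in the touched region.
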
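# ldmx

Queryable compression for large linkage-disequilibrium (LD) matrices.

LD matrices derived from biobank-scale cohorts — pairwise signed
correlations *r* ∈ [−1, 1] between the 0/1 allele indicators of nearby
variants — are enormous (tens to hundreds of GB per chromosome) even though
values are only computed for variant pairs within a few megabases of each
other. They are typically shipped as many overlapping per-window array
files, which makes extracting a small submatrix awkward and memory-hungry.

`ldmx` compresses a set of overlapping banded window files into a **single
chunked HDF5 container** and answers submatrix queries against it directly:

* **lossless** mode stores exact float64 values; **lossy** mode rounds
  values to *d* decimal places (round-half-to-even) and drops entries with
  |r| strictly below a minimum-LD threshold *t*, storing the survivors as
  scaled integers `round(r·10^d)` in the smallest sufficient width;
* the container is partitioned into non-overlapping genomic **chunks**
  (HDF5 groups `chunk_<start>`, width inferred from the input window
  overlap or set explicitly); each chunk owns every stored pair whose
  lower-position variant falls inside it, with columns recorded by absolute
  position — the "trapezoid" of banded storage;
* queries by **genomic range**, **loci list**, or **MAF range** return a
  labeled symmetric submatrix; large results stream to disk in row blocks;
  the original per-window files can be rebuilt from the container.

A synthetic-data module simulates haplotype panels with haploblock
structure (copy-with-mutation chains), so the full pipeline is testable
without any external download.

## Worked example

```
$ ldmx synth -o windows --seed 5 \
    --spec <(echo '{"n_haplotypes":100,"n_variants":120,"span_bp":300000}')
wrote 3 windows (120 variants) to windows

$ ldmx compress -i "windows/*.npz" -o ld.h5 --decimals 4 --min-ld 0.06
wrote ld.h5: 3 chunks, chunk size 100000 bp

$ ldmx inspect ld.h5
container:   ld.h5
chromosome:  21
chunk size:  100000 bp (3 chunks)
decimals:    4
threshold:   0.06
max dist:    100000 bp
has MAF:     yes
variants:    120
entries:     2264
per chunk:   min 467  median 630  max 1167
```

The three 300 kb windows slide every 100 kb, so the chunk size is inferred
as 100 kb. Of all upper-triangle pairs within the 100 kb band, 2,264 values
survive rounding to 4 decimals and the 0.06 threshold; everything else is
an implicit zero. Querying returns a position-labeled CSV (here a 21-variant
submatrix):

```
$ ldmx query ld.h5 --range 1-50000 --out q.csv
wrote q.csv (21 variants)
$ ldmx query ld.h5 --maf 0.3-0.5 --format long --out common.tsv
$ ldmx reconstruct ld.h5 --windows spans.txt -o rebuilt/
```

The same operations are available as library functions
(`ldmx.compress`, `ldmx.query_range`, `ldmx.query_loci`, `ldmx.query_maf`,
`ldmx.reconstruct_original`, ...).

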
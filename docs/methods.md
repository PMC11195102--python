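# Methods

This note documents the data model, the conversion procedure, the
numerical conventions, and the choices made where the design was genuinely
open. It states no empirical result that the test suite does not itself
compute.

## Data model

Every VCF field maps to one Zarr array. FORMAT fields are
`call_<KEY>` with leading dimensions `(variants, samples)`; INFO fields are
`variant_<KEY>` with leading dimension `(variants,)`; the fixed columns use
reserved names, and GT expands to `call_genotype` (allele indexes),
`call_genotype_phased` (per-call phase flag) and `call_genotype_mask`
(true wherever the genotype entry is negative). Header structure is also
stored: `contig_id`/`contig_length`, `filter_id` and `sample_id` arrays,
plus the verbatim source header text and the full storage schema in the
root attributes. The on-disk layout is Zarr v2 (`.zarray`/`.zattrs` JSON,
row-major chunks keyed `i.j.k`), written either as a directory hierarchy or
as an uncompressed Zip archive of that hierarchy; both are readable by the
query layer.

### Shapes

The trailing dimension of an array comes from the field's `Number`
declaration: fixed `k`, `A` (alternate alleles, extent `max_alleles - 1`),
`R` (alleles, extent `max_alleles`), `G` (unordered genotypes, extent
`C(max_alleles + ploidy - 1, ploidy)`), or `.` (extent = maximum observed
length, floored at 1 so no array is zero-extent). All extents are global
maxima over the dataset — this is what makes the arrays rectangular and
chunkable, and also why highly multi-allelic datasets need the
local-allele encoding (below). Records shorter than the extent are padded
with the fill sentinel.

### Sentinels

Two in-band values distinguish *missing* (absent in the source: `.`) from
*fill* (padding beyond a record's own length):

| dtype   | missing                  | fill                     |
|---------|--------------------------|--------------------------|
| integer | -1                       | -2                       |
| float32 | quiet NaN, payload 0x1 (bits `0x7FC00001`) | quiet NaN, payload 0x2 (bits `0x7FC00002`) |
| string  | `"."`                    | `""`                     |

Because -1/-2 are reserved, an integer field whose genuine values include
them is rejected at conversion with the advice to use a float field. The
float sentinels are fixed bit patterns so that a storage round trip is
bit-exact and testable; other implementations are only required to use
*some* non-signalling NaN, so bit-exact interchange of missing floats with
other writers is not guaranteed. A related storage subtlety: the Zarr fill
value for float arrays is 0.0, not NaN, because a NaN fill value would let
the writer elide all-NaN chunks and erase the payload bits; every chunk is
written explicitly during encoding, so the fill value is never observed.

A FORMAT vector given as `.` is stored as one missing value plus fill
padding (the BCF convention), not as an all-missing vector. Rendering
strips trailing fill and prints a remaining all-missing vector as `.`, so
the distinction is invisible in round-tripped text.

Two corner cases are non-invertible by design: a field that is present but
entirely missing cannot be distinguished from an absent field, and FILTER
`.` cannot be distinguished from an empty filter set (both give an
all-false row of the boolean `variant_filter` matrix).

### Dtypes and codecs

Integer fields use the narrowest signed width whose range covers the
observed min/max *and* the sentinels; floats are stored as float32 (VCF
`Float` is 32-bit); flags as booleans; strings as variable-length UTF-8.
The default compressor is Blosc zstd at level 7 for every array (the level
is this package's documented default; only the codec choice itself is
externally prescribed). Bit shuffle is enabled exactly for `call_genotype`
and boolean arrays: genotype bytes and booleans have almost all high bits
zero, so grouping equal-significance bits compresses dramatically better,
while on noisy count-like fields shuffling can hurt. Byte shuffle is never
a default. All defaults can be overridden by editing the JSON schema
(`mkschema` → edit → `encode --schema`).

Default chunks are 10,000 variants × 1,000 samples (capped at the array
extents); trailing dimensions are never split.

## Two-phase conversion

**Explode.** Array extents and integer widths are global properties, so a
full pass is needed before any array can be written. The explode phase
streams records (via pysam/htslib) and appends each field's values to a
sequence of compressed chunks (pickled value lists, zstd level 3 — the
intermediate format is internal, so decode speed beats ratio), cutting a
chunk when the accumulated raw-size estimate reaches 1 MiB (cut *after*
the threshold, so a chunk may overshoot by one record; memory stays
bounded and the policy is trivially resumable). Exact per-field summaries
(min, max, longest value list) and per-partition record counts are kept
alongside; cumulative offsets let any record range be read back
decompressing only the chunks that overlap it.

Indexed inputs can be split into region partitions planned from the header
contig list and lengths; a partition's records are fetched through the
Tabix/CSI index, and a record belongs to the partition containing its POS
(duplicates surfaced by index-block overlap are dropped by position
comparison). Files lacking an index or contig lengths fall back to a
single whole-file partition with a warning. Every partition commits its
output by atomic directory rename, and finalise refuses to run while any
partition is incomplete, naming the pending indexes — the same model the
`dexplode-*`/`dencode-*` commands expose for batch execution on one
machine. Encode partitions are contiguous ranges of whole variant chunks,
so concurrent workers never touch the same stored chunk.

**Encode.** For each array, a buffer holding one full variant chunk is
filled from ICF values — short records padded with fill, missing entries
set to the missing sentinel — and flushed with the array's codec
configuration. Memory is bounded by one chunk per field regardless of
dataset size, and the result is element-wise identical for any variant
chunk size (a tested invariant).

## Local alleles

Fields indexed by allele (`Number=R`) or genotype (`Number=G`) grow with
the dataset-wide maximum allele count — quadratically for `G` — while any
one diploid call references at most two alleles. With `local_alleles`
enabled, the schema replaces such FORMAT fields with local counterparts:

- `call_LA[v, s]` — the sorted distinct allele indexes observed in the
  call's genotype, padded to ploidy with fill. A fully missing genotype
  observes no alleles, so its row is all fill. Listing observed alleles
  directly (rather than alternate-allele indexes as in VCF 4.5's LAA)
  means missing data never has to be disambiguated against the genotypes.
- `call_L<KEY>` for `Number=R`: `LAD[j] = AD[LA[j]]`.
- `call_L<KEY>` for `Number=G` (diploid only; other ploidies are rejected
  with a clear message): the value for local pair `(a, b)` is the global
  entry at the canonical unordered-pair index `k(k+1)/2 + j`.

Values at alleles a call never references are discarded — the transform is
lossy in general, and exact whenever every allele a call uses appears in
its `LA` row (always true here, since `LA` is derived from the genotype;
the tested reconstruction property). If a record's source list is shorter
than the index demanded (truncated source data), the local entry is
missing rather than an error.

## Precision filters

Per-array lossy float truncation before compression: `quantize(d)` rounds
to `d` decimal digits (`round(v·10^d)/10^d`); `bit_round(b)` keeps `b`
explicit mantissa bits with round-half-to-even on the dropped bits. Both
are implemented directly on the buffer (the arithmetic agrees with
numcodecs' BitRound exactly and with its Quantize to within the kept
digit, tested), because the filters must skip the sentinel NaNs
bit-unchanged — a codec-level filter would round them away.

## Region index and queries

At finalise an integer `region_index` array is built with one row per
contig run per variant chunk: `(chunk_index, contig_id, start_position,
end_position, num_records)`. The record end is `POS + len(REF) - 1`,
extended to `INFO/END` when present, so interval queries are correct for
deletions and symbolic alleles. A range query intersects the (tiny,
in-memory) index to find candidate chunks, then masks records by exact
interval overlap within only those chunks; results are identical to a
linear scan and independent of chunk size (tested). Unsorted positions
within a contig make the store unsuitable for region queries and fail the
index build. The column layout is this package's own contract.

Region strings use the bcftools dialect: `contig`, `contig:start`,
`contig:start-`, `contig:start-end`, 1-based inclusive.

## VCF text reconstruction

`view` emits the stored verbatim header (sample columns adjusted for
subsetting; synthesised declarations appended for arrays with no header
line, e.g. the local-allele fields), then rebuilds records field by field:
missing sentinels render as `.`, trailing fill is dropped, FILTER comes
from the boolean matrix, GT from `call_genotype` plus the phase flags.
Floats render as the shortest decimal string that round-trips at 32-bit
precision — semantically faithful, but byte-identical output against other
writers is not promised. A FORMAT field whose values are missing for every
emitted sample of a record is omitted from that record's FORMAT column.

Filter expressions support `INFO/K` and `FORMAT/K` (alias `FMT/K`) terms,
the six comparison operators, numeric literals, `&`, `|` and parentheses.
Missing values compare false. FORMAT terms evaluate per call, and a
*record* passes if any sample satisfies the whole conjunction (bcftools'
site-level `-i` behaviour); a per-call mask (the `-I` analogue) is
available separately and leaves values intact. Fields with a trailing
dimension are reduced with any-element-satisfies before combination.
String-valued fields are rejected in expressions with a clear message.

## Statistics kernels

All kernels traverse `call_genotype` one variant chunk at a time and are
exactly invariant to traversal order and chunk size (tested against
single-pass brute-force implementations).

- `allele_counts`: per-variant counts of each allele index over
  non-negative entries; conservation (total = called slots) is a tested
  invariant.
- `af_dist`: per variant, `q` = alternate slots / called slots, computed
  from the genotypes rather than `INFO/AF` — subsetting invalidates stored
  AF tags, and recomputing keeps the kernel self-contained. Every call
  with two non-missing slots and no extra genuine slots is collapsed to
  hom-ref/het/hom-alt (any allele index > 0 counts as alternate — the
  simplest documented extension of the biallelic reference computation to
  multi-allelic sites) and binned at `floor(p·n_bins)`, clamped so `p = 1`
  lands in the last bin. Incomplete and non-diploid calls are excluded and
  tallied. The table reports observed per-bin counts plus the analytic
  uniform reference mass (total/n_bins) — the package's own definition of
  the "expected" column.
- `qc_variant_mask`: evaluates a filter expression per variant and
  persists it as a named boolean array; no other array is touched (the
  chunk bytes of every existing array are unchanged, tested). Requires a
  directory store, as Zip archives are read-only.

## Synthetic data

The built-in generator emits sorted, well-formed VCFs — multi-allelic
sites (allele count uniform in [2, max_alleles]), indel-style REFs, mixed
ploidy (20% haploid calls when enabled), configurable missingness and
phasing rates, and a field menu covering scalar/vector integer fields,
`Number=A` floats, flags, strings, and a variable-length `Number=.` field.
Alternate-allele frequencies follow a Beta(0.5, 0.5) spectrum so every
af-dist bin receives mass; PL vectors follow the canonical genotype
ordering with the called genotype set to 0. Output is byte-deterministic
under (config, seed), and bgzip + Tabix companions can be written for
partition tests.

What it does not emulate: linkage disequilibrium or any population-genetic
structure, realistic QC-field error modes (depth/quality correlations),
structural/symbolic alleles, or multi-contig sort anomalies. Passing tests
therefore demonstrate correctness of the *encoding and query machinery*
over the VCF feature space, not robustness to the pathologies of
real-world pipelines.

Test problem sizes are deliberately small (tens of variants, a handful of
samples, dozens of configurations) — every tested property (round trips,
oracle equivalences, chunk invariances) is size-independent, so small
fixtures check the same logic the defaults (10,000 × 1,000 chunks) exercise
at scale.

## Known limitations

- BCF binary input is not parsed; inputs are VCF text and bgzip VCF.
- `localize_G_field` is diploid-only.
- The expression grammar is the subset above, not bcftools' full language.
- ICF is internal and unstable; it is not an interchange format.
- Mixed-ploidy `G` fields and the interaction of `INFO/END` with
  multi-contig stores follow the conventions stated here, which are this
  package's own contracts where the underlying formats are silent.
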
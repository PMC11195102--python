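# vczarr

Lossless conversion of VCF into chunked, compressed, analysis-ready Zarr
stores — with a bcftools-style read path and chunkwise statistics kernels.

## The problem

VCF encodes the variants × samples genotype matrix and its QC annotations
row by row: all information for one variant sits together in one
(compressed) line. That layout is excellent for interchange and streaming,
but hopeless for the access patterns of large-cohort analysis — reading a
single field (say, every variant's position, or one sample's depths) means
decompressing the entire dataset. `vczarr` decouples the VCF *data model*
from its row-oriented file layout: every field becomes a separately stored,
chunked, compressed n-dimensional Zarr array, so an analysis reads and
decompresses exactly the arrays and chunks it needs, in either the variant
or the sample dimension.

The mapping is systematic:

- FORMAT fields become `call_<KEY>` arrays with shape
  `(variants, samples, ...)`; INFO fields become `variant_<KEY>` arrays with
  shape `(variants, ...)`. The fixed columns map to reserved names
  (`variant_position`, `variant_contig`, `variant_allele`,
  `variant_quality`, `variant_filter`, `variant_id`), and GT expands to the
  triple `call_genotype` / `call_genotype_phased` / `call_genotype_mask`.
- The VCF `Number` declaration fixes the trailing dimension: `A` → one per
  alternate allele, `R` → one per allele, `G` → one per unordered genotype
  (`C(n + p - 1, p)`, i.e. `n(n+1)/2` for diploids), `.` → the maximum
  observed length. Extents are **global maxima** over all records; shorter
  records are padded with a *fill* sentinel.
- Missing data and padding are in-band sentinels: `-1` (missing) and `-2`
  (fill) for integers, two distinct quiet-NaN payloads for floats, `.`/`""`
  for strings. Integer widths are the narrowest that hold the observed
  range plus the sentinels.
- Arrays are compressed with Blosc zstd; bit shuffle is enabled exactly for
  `call_genotype` and boolean arrays, where grouping equal-significance
  bits pays off.

Conversion is two-phase, because array extents are global properties:
**explode** streams the VCF (optionally split into index-derived partitions
run in parallel or resumed after failure) into an intermediate columnar
format (ICF) holding per-field compressed chunk sequences and exact
min/max/dimension summaries; **encode** then materialises the Zarr arrays
one variant-chunk buffer at a time. For highly multi-allelic data the
*local-allele* encoding (`call_LA`, `call_LAD`, `call_LPL`) bounds
allele-indexed fields by ploidy instead of the worst-case allele count,
keeping only the values each call's genotype references.

## Worked example

The repository's canonical 3-variant × 2-sample example, end to end:

```bash
$ python -c "from vczarr.fixtures import TOY_VCF; open('toy.vcf','w').write(TOY_VCF)"
$ vczarr explode toy.vcf toy.icf
wrote ICF with 3 records to toy.icf
$ vczarr encode toy.icf toy.vcz
wrote Zarr store to toy.vcz
$ vczarr query toy.vcz -f '%CHROM:%POS %REF>%ALT\n'
chr1:100 A>T
chr1:200 G>A,C
chr1:300 T>G
$ vczarr stats af-dist toy.vcz
prob_start	prob_end	count
0	0.1	0
0.1	0.2	0
0.2	0.3	0
0.3	0.4	1
0.4	0.5	1
0.5	0.6	2
0.6	0.7	0
0.7	0.8	0
0.8	0.9	0
0.9	1	0
# excluded calls: 2
```

The af-dist table counts genotype calls by their Hardy–Weinberg
probability: per variant, the alternate allele frequency `q` is computed
from the genotypes, each complete diploid call is collapsed to
hom-ref/het/hom-alt with probability `(1-q)²`, `2q(1-q)` or `q²`, and the
probability is binned on `[0, 1]`. Here four calls are classified (one
record has a fully missing call and one a haploid call, both excluded) —
e.g. at `chr1:100` the called slots are `0|1` and `1/1`, so `q = 3/4`; the
het has probability `2·(3/4)·(1/4) = 0.375` (fourth bin) and the hom-alt
`(3/4)² = 0.5625` (sixth bin). `vczarr view toy.vcz` reconstructs the original VCF text
record for record, and `vczarr inspect toy.vcz` reports per-array storage
and compression.

The same pipeline is available as a library (`vczarr.explode`,
`vczarr.encode`, `vczarr.view`, `vczarr.query`, `vczarr.af_dist`, ...); the
scripts in `examples/` each demonstrate one capability — conversion and
schema defaults, region/sample/expression subsetting, af-dist, the
local-allele encoding, and the Quantize/BitRound precision filters.

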
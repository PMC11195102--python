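"""Second conversion phase: materialise ICF fields into a Zarr store.

The encoder consumes a finalised :class:`~vczarr.icf.IcfStore` and a
:class:`~vczarr.model.StoreSchema` (generated from the ICF summaries by
:func:`schema_from_icf`, optionally edited as JSON in between) and writes a
Zarr v2 group: one chunked, compressed array per field, the genotype triple,
optionally the local-allele fields, header-derived arrays (contig/filter/
sample ids) and a region index supporting interval queries.

Encoding works one variant-chunk at a time per field: a buffer holding a
full chunk of the array is filled from ICF values (short records padded
with the fill sentinel, missing entries set to the missing sentinel) and
flushed to storage, so memory use is bounded by the chunk size regardless
of dataset size.
"""

from __future__ import annotations

import json
import os
import zipfile

import numcodecs
import numpy as np
import zarr

from . import model
from .icf import GT_FIELD, IcfStore
from .model import (
    ArraySpec,
    Category,
    CodecConfig,
    FLOAT_FILL,
    FLOAT_MISSING,
    INT_FILL,
    INT_MISSING,
    StoreSchema,
    default_codec_config,
    genotype_dim_size,
    map_field_name,
    map_number_to_dims,
    select_integer_dtype,
)

#: Column order of the region_index array.
REGION_INDEX_COLUMNS = (
    "chunk_index", "contig_id", "start_position", "end_position", "num_records"
)


class EncodeError(Exception):
    pass


# ---------------------------------------------------------------------------
# Schema generation (mkschema)
# ---------------------------------------------------------------------------


def _field_dtype(descriptor, summary):
    t = descriptor.vcf_type
    if t == "Integer":
        lo = int(summary.observed_min) if summary.observed_min is not None else 0
        hi = int(summary.observed_max) if summary.observed_max is not None else 0
        return select_integer_dtype(lo, hi)
    if t == "Float":
        return "float32"
    if t == "Flag":
        return "bool"
    return "str"  # String / Character


def _chunks_for(dims, shape, variant_chunk, sample_chunk):
    chunks = []
    for dim, extent in zip(dims, shape):
        if dim == "variants":
            chunks.append(min(variant_chunk, extent) if extent else variant_chunk)
        elif dim == "samples":
            chunks.append(min(sample_chunk, extent) if extent else sample_chunk)
        else:
            chunks.append(max(1, extent))
    return chunks


def schema_from_icf(
    icf: IcfStore,
    variant_chunk: int = model.DEFAULT_VARIANT_CHUNK,
    sample_chunk: int = model.DEFAULT_SAMPLE_CHUNK,
    local_alleles: bool = False,
) -> StoreSchema:
    """Generate the default storage schema from ICF summaries.

    Integer widths are the narrowest representing the observed min/max with
    sentinels reserved; trailing extents are the observed maxima; chunks
    default to 10,000 variants x 1,000 samples.  With ``local_alleles`` set,
    FORMAT fields of Number=R/G are replaced by their local-allele
    counterparts (call_LA plus call_L<KEY>).
    """
    meta = icf.metadata
    n_variants = meta.num_records
    n_samples = len(meta.samples)
    s = meta.summaries
    max_alleles = max(1, s["ALLELES"].max_dimension)
    ploidy = max(1, s[GT_FIELD].max_dimension) if meta.has_gt else 1

    def make(name, dims, shape, dtype, source=None, number=None, vcf_type=None,
             description=""):
        spec = ArraySpec(
            name=name,
            dims=list(dims),
            shape=[int(x) for x in shape],
            dtype=dtype,
            chunks=_chunks_for(dims, shape, variant_chunk, sample_chunk),
            codec_config=CodecConfig(),
            description=description,
            source_field=source,
            vcf_number=number,
            vcf_type=vcf_type,
        )
        spec.codec_config = default_codec_config(spec)
        return spec

    fields = [
        make("variant_contig", ["variants"], [n_variants],
             select_integer_dtype(0, max(0, len(meta.contigs) - 1)),
             source="fixed/CHROM"),
        make("variant_position", ["variants"], [n_variants],
             select_integer_dtype(
                 int(s["POS"].observed_min or 0), int(s["POS"].observed_max or 0)
             ),
             source="fixed/POS"),
        make("variant_id", ["variants"], [n_variants], "str", source="fixed/ID"),
        make("variant_allele", ["variants", "alleles"],
             [n_variants, max_alleles], "str", source="fixed/ALLELES"),
        make("variant_quality", ["variants"], [n_variants], "float32",
             source="fixed/QUAL"),
        make("variant_filter", ["variants", "filters"],
             [n_variants, len(meta.filters)], "bool", source="fixed/FILTERS"),
    ]
    if meta.has_gt:
        fields += [
            make("call_genotype", ["variants", "samples", "ploidy"],
                 [n_variants, n_samples, ploidy],
                 select_integer_dtype(0, max(0, max_alleles - 1)),
                 source="fixed/GT"),
            make("call_genotype_phased", ["variants", "samples"],
                 [n_variants, n_samples], "bool", source="fixed/GT"),
            make("call_genotype_mask", ["variants", "samples", "ploidy"],
                 [n_variants, n_samples, ploidy], "bool", source="fixed/GT"),
        ]
    for d in meta.info_fields:
        summary = s[f"INFO/{d.key}"]
        trailing = map_number_to_dims(d, max_alleles, ploidy, summary.max_dimension)
        dims = ["variants"] + [t[0] for t in trailing]
        shape = [n_variants] + [t[1] for t in trailing]
        fields.append(
            make(map_field_name(Category.INFO, d.key), dims, shape,
                 _field_dtype(d, summary), source=f"INFO/{d.key}",
                 number=d.vcf_number, vcf_type=d.vcf_type,
                 description=d.description)
        )
    localised = []
    for d in meta.format_fields:
        summary = s[f"FORMAT/{d.key}"]
        if local_alleles and d.vcf_number in ("R", "G") and meta.has_gt:
            localised.append(d)
            continue
        trailing = map_number_to_dims(d, max_alleles, ploidy, summary.max_dimension)
        dims = ["variants", "samples"] + [t[0] for t in trailing]
        shape = [n_variants, n_samples] + [t[1] for t in trailing]
        fields.append(
            make(map_field_name(Category.FORMAT, d.key), dims, shape,
                 _field_dtype(d, summary), source=f"FORMAT/{d.key}",
                 number=d.vcf_number, vcf_type=d.vcf_type,
                 description=d.description)
        )
    if localised:
        fields.append(
            make("call_LA", ["variants", "samples", "local_alleles"],
                 [n_variants, n_samples, ploidy],
                 select_integer_dtype(0, max(0, max_alleles - 1)),
                 source="fixed/GT",
                 description="Sorted unique allele indexes observed in each "
                             "call's genotype, as indexes into variant_allele"),
        )
        for d in localised:
            summary = s[f"FORMAT/{d.key}"]
            if d.vcf_number == "R":
                dims = ["variants", "samples", "local_alleles"]
                shape = [n_variants, n_samples, ploidy]
            else:  # G
                if ploidy != 2:
                    raise EncodeError(
                        "local-allele encoding of Number=G fields is only "
                        f"supported for diploid data (ploidy is {ploidy})"
                    )
                dims = ["variants", "samples", "local_genotypes"]
                shape = [n_variants, n_samples, genotype_dim_size(ploidy, ploidy)]
            fields.append(
                make("call_L" + d.key, dims, shape, _field_dtype(d, summary),
                     source=f"FORMAT/{d.key}", number=d.vcf_number,
                     vcf_type=d.vcf_type, description=d.description)
            )
    return StoreSchema(
        format_version=model.FORMAT_VERSION,
        samples=list(meta.samples),
        contigs=[tuple(c) for c in meta.contigs],
        filters=list(meta.filters),
        fields=fields,
        ploidy=ploidy,
        max_alleles=max_alleles,
        local_alleles=bool(localised),
        vcf_header=meta.header_text,
    )


# ---------------------------------------------------------------------------
# Per-call transforms
# ---------------------------------------------------------------------------


def encode_genotypes(gt_values, ploidy: int, max_alleles: int):
    """Encode per-call (allele-tuple, phased) pairs for one record.

    Returns (genotype, phased, mask) numpy rows for a single variant:
    "." becomes the missing sentinel, absent trailing alleles of a
    lower-ploidy call become fill, and the mask is true wherever the
    genotype is negative.
    """
    n = len(gt_values)
    genotype = np.full((n, ploidy), INT_FILL, dtype=np.int64)
    phased = np.zeros(n, dtype=bool)
    for i, (alleles, ph) in enumerate(gt_values):
        if len(alleles) > ploidy:
            raise EncodeError(f"call ploidy {len(alleles)} exceeds {ploidy}")
        for j, a in enumerate(alleles):
            if a is None:
                genotype[i, j] = INT_MISSING
            else:
                if a >= max_alleles:
                    raise EncodeError(
                        f"allele index {a} out of range (max {max_alleles - 1})"
                    )
                genotype[i, j] = a
        phased[i] = ph
    return genotype, phased, genotype < 0


def compute_local_alleles(genotype_row: np.ndarray, ploidy: int) -> np.ndarray:
    """Sorted distinct allele indexes of one call, padded with fill.

    A fully missing genotype observes no alleles, so its row is all fill
    (and localised fields become all fill as a consequence).
    """
    observed = sorted({int(a) for a in genotype_row if a >= 0})
    out = np.full(ploidy, INT_FILL, dtype=np.int64)
    out[: len(observed)] = observed[:ploidy]
    return out


def localize_R_field(values, la: np.ndarray, missing, fill):
    """Restrict a Number=R value list to the call's local alleles."""
    out = [fill] * len(la)
    for i, a in enumerate(la):
        if a < 0:
            continue
        out[i] = values[a] if a < len(values) else missing
    return out


def localize_G_field(values, la: np.ndarray, missing, fill):
    """Restrict a diploid Number=G likelihood list to local genotype pairs.

    VCF orders the unordered pair (j, k), j <= k, at index k(k+1)/2 + j.
    Entries involving fill alleles are fill; global indexes beyond the
    record's value list are treated as missing.
    """
    if len(la) != 2:
        raise EncodeError("localize_G_field supports diploid data only")
    out = [fill] * genotype_dim_size(len(la), len(la))
    pos = 0
    for b in range(len(la)):
        for a in range(b + 1):
            ga, gb = la[a], la[b]
            if ga < 0 or gb < 0:
                out[pos] = fill
            else:
                j, k = int(min(ga, gb)), int(max(ga, gb))
                idx = k * (k + 1) // 2 + j
                out[pos] = values[idx] if idx < len(values) else missing
            pos += 1
    return out


def apply_precision_filter(values: np.ndarray, precision_filter) -> np.ndarray:
    """Lossy float truncation: quantize(d digits) or bit_round(b bits).

    NaN entries (which carry the missing/fill sentinel payloads) pass
    through bit-unchanged; the filter applies to finite values only.
    """
    kind, arg = precision_filter
    if arg < 0:
        raise ValueError("precision filter parameter must be >= 0")
    values = np.asarray(values, dtype=np.float32)
    out = values.copy()
    ok = np.isfinite(values)
    if kind == "quantize":
        scale = np.float64(10.0 ** arg)
        out[ok] = np.asarray(
            np.round(values[ok].astype(np.float64) * scale) / scale, np.float32
        )
    elif kind == "bit_round":
        if arg > 23:
            raise ValueError("bit_round keepbits must be <= 23 for float32")
        # Round half to even on the mantissa, keeping `arg` explicit bits.
        drop = 23 - arg
        if drop > 0:
            bits = out[ok].view(np.uint32)
            mask = np.uint32((0xFFFFFFFF >> drop) << drop)
            half_minus_one = np.uint32((1 << (drop - 1)) - 1)
            lsb = (bits >> np.uint32(drop)) & np.uint32(1)
            bits = (bits + lsb + half_minus_one) & mask
            out[ok] = bits.view(np.float32)
    else:
        raise ValueError(f"unknown precision filter {kind!r}")
    return out


# ---------------------------------------------------------------------------
# Buffer filling
# ---------------------------------------------------------------------------


def _sentinels_for(dtype: str):
    if dtype == "float32":
        return FLOAT_MISSING, FLOAT_FILL
    if dtype == "str":
        return model.STR_MISSING, model.STR_FILL
    if dtype == "bool":
        return False, False
    return INT_MISSING, INT_FILL


def _as_list(value):
    if value is None:
        return None
    if isinstance(value, tuple):
        return list(value)
    return [value]


def _fill_trailing(buf, row, values, missing, fill, name):
    """Write one record's value list into buf[row], padding with fill."""
    k = buf.shape[-1]
    if values is None:
        buf[row] = missing
        return
    if len(values) > k:
        raise EncodeError(
            f"record {row}: {name} has {len(values)} values, exceeding the "
            f"schema extent {k}"
        )
    for j, v in enumerate(values):
        buf[row][..., j] = missing if v is None else v
    buf[row][..., len(values):] = fill


def encode_field(icf: IcfStore, spec: ArraySpec, start: int, stop: int) -> np.ndarray:
    """Materialise records [start, stop) of one array as a numpy buffer."""
    n = stop - start
    missing, fill = _sentinels_for(spec.dtype)
    dtype = np.float32 if spec.dtype == "float32" else (
        object if spec.dtype == "str" else np.dtype(spec.dtype)
    )
    shape = (n,) + tuple(spec.shape[1:])
    source = spec.source_field

    if source == "fixed/CHROM":
        return np.array(icf.read_field_slice("CHROM", start, stop), dtype=dtype)
    if source == "fixed/POS":
        return np.array(icf.read_field_slice("POS", start, stop), dtype=dtype)
    if source == "fixed/ID":
        vals = icf.read_field_slice("ID", start, stop)
        return np.array([model.STR_MISSING if v is None else v for v in vals],
                        dtype=object)
    if source == "fixed/QUAL":
        vals = icf.read_field_slice("QUAL", start, stop)
        buf = np.empty(n, dtype=np.float32)
        for i, v in enumerate(vals):
            buf[i] = FLOAT_MISSING if v is None else v
        return buf
    if source == "fixed/ALLELES":
        vals = icf.read_field_slice("ALLELES", start, stop)
        buf = np.full(shape, model.STR_FILL, dtype=object)
        for i, alleles in enumerate(vals):
            if len(alleles) > buf.shape[1]:
                raise EncodeError(
                    f"record {start + i}: {len(alleles)} alleles exceed the "
                    f"schema extent {buf.shape[1]}"
                )
            buf[i, : len(alleles)] = alleles
        return buf
    if source == "fixed/FILTERS":
        filters = {f: j for j, f in enumerate(icf.metadata.filters)}
        vals = icf.read_field_slice("FILTERS", start, stop)
        buf = np.zeros(shape, dtype=bool)
        for i, fl in enumerate(vals):
            for f in fl:
                buf[i, filters[f]] = True
        return buf

    if spec.name.startswith(("variant_", "call_")) and source and (
        source.startswith("INFO/") or source.startswith("FORMAT/")
    ):
        vals = icf.read_field_slice(source, start, stop)
        if spec.dtype == "bool" and spec.vcf_type == "Flag":
            return np.array([bool(v) for v in vals], dtype=bool)
        buf = np.full(shape, fill, dtype=dtype)
        is_format = source.startswith("FORMAT/")
        scalar = len(spec.shape) == (2 if is_format else 1)
        for i, v in enumerate(vals):
            if is_format:
                for si, sv in enumerate(v):
                    if scalar:
                        buf[i, si] = missing if sv is None else (
                            sv[0] if isinstance(sv, tuple) else sv
                        )
                    else:
                        _fill_trailing(
                            buf[i], si, _as_list(sv), missing, fill, spec.name
                        )
            else:
                if scalar:
                    buf[i] = missing if v is None else (
                        v[0] if isinstance(v, tuple) else v
                    )
                else:
                    _fill_trailing(buf, i, _as_list(v), missing, fill, spec.name)
        if spec.codec_config.precision_filter is not None:
            buf = apply_precision_filter(buf, spec.codec_config.precision_filter)
        return buf
    raise EncodeError(f"cannot encode array {spec.name!r} (source {source!r})")


def _encode_genotype_chunk(icf, schema, start, stop):
    gt_vals = icf.read_field_slice(GT_FIELD, start, stop)
    n = stop - start
    ns = len(schema.samples)
    p = schema.ploidy
    genotype = np.full((n, ns, p), INT_FILL, dtype=np.int64)
    phased = np.zeros((n, ns), dtype=bool)
    for i, row in enumerate(gt_vals):
        g, ph, _ = encode_genotypes(row, p, schema.max_alleles)
        genotype[i], phased[i] = g, ph
    return genotype, phased


# ---------------------------------------------------------------------------
# Store writing
# ---------------------------------------------------------------------------


def _zarr_compressor(cc: CodecConfig):
    if cc.codec == "none":
        return None
    shuffle = {
        "none": numcodecs.Blosc.NOSHUFFLE,
        "bit": numcodecs.Blosc.BITSHUFFLE,
        "byte": numcodecs.Blosc.SHUFFLE,
    }[cc.shuffle]
    return numcodecs.Blosc(cname=cc.codec, clevel=cc.level, shuffle=shuffle)


def _create_array(root, spec: ArraySpec, n_variants: int):
    shape = tuple(spec.shape)
    chunks = tuple(max(1, c) for c in spec.chunks)
    if spec.dtype == "str":
        dtype = str
        fill = ""
    elif spec.dtype == "bool":
        dtype = "bool"
        fill = False
    elif spec.dtype == "float32":
        dtype = "float32"
        # Not NaN: a NaN fill value would let Zarr elide all-NaN chunks,
        # erasing the sentinel payload bits that distinguish missing from
        # fill.  Every chunk is written explicitly during encoding.
        fill = 0.0
    else:
        dtype = spec.dtype
        fill = INT_FILL
    arr = root.create_array(
        spec.name,
        shape=shape,
        chunks=chunks,
        dtype=dtype,
        compressors=_zarr_compressor(spec.codec_config),
        fill_value=fill,
    )
    arr.attrs["_ARRAY_DIMENSIONS"] = list(spec.dims)
    if spec.description:
        arr.attrs["description"] = spec.description
    if spec.source_field:
        arr.attrs["source_field"] = spec.source_field
    return arr


def _record_ends(icf, start, stop):
    """1-based inclusive end coordinate of each record.

    end = POS + len(REF) - 1, extended to INFO/END when present (covering
    symbolic alleles), so indel-aware interval queries are correct.
    """
    pos = np.array(icf.read_field_slice("POS", start, stop), dtype=np.int64)
    alleles = icf.read_field_slice("ALLELES", start, stop)
    rlen = np.array([len(a[0]) for a in alleles], dtype=np.int64)
    ends = pos + rlen - 1
    if any(d.key == "END" for d in icf.metadata.info_fields):
        info_end = icf.read_field_slice("INFO/END", start, stop)
        for i, e in enumerate(info_end):
            if e is not None:
                ends[i] = max(ends[i], int(e))
    return ends


def build_region_index(variant_contig, variant_position, record_end,
                       chunk_size: int) -> np.ndarray:
    """Region index rows: one per contig run per variant chunk.

    Columns are (chunk_index, contig_id, start_position, end_position,
    num_records).  Positions within each contig run must be sorted.
    """
    contig = np.asarray(variant_contig, dtype=np.int64)
    pos = np.asarray(variant_position, dtype=np.int64)
    end = np.asarray(record_end, dtype=np.int64)
    n = len(pos)
    rows = []
    for ci in range(0, max(1, -(-n // chunk_size))):
        lo, hi = ci * chunk_size, min((ci + 1) * chunk_size, n)
        if lo >= hi:
            continue
        run_start = lo
        for i in range(lo + 1, hi + 1):
            if i == hi or contig[i] != contig[run_start]:
                c = contig[run_start]
                p = pos[run_start:i]
                if np.any(np.diff(p) < 0):
                    raise EncodeError(
                        "positions are not sorted within a contig; the store "
                        "cannot support region queries"
                    )
                rows.append(
                    (ci, int(c), int(p[0]), int(end[run_start:i].max()), i - run_start)
                )
                run_start = i
    return np.array(rows, dtype=np.int64).reshape(-1, 5)


def _wip_dir(store_path):
    return os.path.join(str(store_path), ".encode_wip")


def encode_init(
    icf,
    store_path: str,
    schema: StoreSchema = None,
    variant_chunk: int = None,
    local_alleles: bool = False,
    target_partitions: int = 1,
) -> StoreSchema:
    """Create the store skeleton (arrays + metadata) and the partition plan.

    Each partition is a contiguous range of whole variant chunks, so
    partitions can be encoded independently (and concurrently) without two
    workers ever touching the same stored chunk.
    """
    if isinstance(icf, (str, os.PathLike)):
        icf = IcfStore(icf)
    if schema is None:
        kwargs = {}
        if variant_chunk is not None:
            kwargs["variant_chunk"] = variant_chunk
        schema = schema_from_icf(icf, local_alleles=local_alleles, **kwargs)
    n_variants = icf.metadata.num_records
    root = zarr.open_group(str(store_path), mode="w", zarr_format=2)
    root.attrs.update(
        {
            "format_version": schema.format_version,
            "vcf_header": schema.vcf_header,
            "contigs": [list(c) for c in schema.contigs],
            "filters": list(schema.filters),
            "samples": list(schema.samples),
            "ploidy": schema.ploidy,
            "max_alleles": schema.max_alleles,
            "local_alleles": schema.local_alleles,
            "sentinels": {
                "int_missing": INT_MISSING,
                "int_fill": INT_FILL,
                "float_missing_bits": model.FLOAT_MISSING_BITS,
                "float_fill_bits": model.FLOAT_FILL_BITS,
                "string_missing": model.STR_MISSING,
                "string_fill": model.STR_FILL,
            },
            "schema": schema.asdict(),
        }
    )
    # Header-structure arrays.
    contig_ids = np.array([c[0] for c in schema.contigs], dtype=object)
    sample_ids = np.array(schema.samples, dtype=object)
    filter_ids = np.array(schema.filters, dtype=object)
    for name, data in (
        ("contig_id", contig_ids), ("sample_id", sample_ids),
        ("filter_id", filter_ids),
    ):
        if len(data):
            a = root.create_array(
                name, shape=data.shape, chunks=data.shape, dtype=str,
                compressors=_zarr_compressor(CodecConfig()),
            )
            a[:] = data
    lengths = [c[1] for c in schema.contigs]
    if lengths and all(x is not None for x in lengths):
        a = root.create_array(
            "contig_length", shape=(len(lengths),), chunks=(len(lengths),),
            dtype="int64", compressors=_zarr_compressor(CodecConfig()),
        )
        a[:] = np.array(lengths, dtype=np.int64)

    specs = {f.name: f for f in schema.fields}
    for spec in specs.values():
        _create_array(root, spec, n_variants)

    vchunk = specs["variant_position"].chunks[0]
    n_chunks = max(1, -(-n_variants // vchunk)) if n_variants else 0
    target_partitions = max(1, min(target_partitions, max(1, n_chunks)))
    per_part = -(-n_chunks // target_partitions) if n_chunks else 0
    partitions = []
    for pi in range(target_partitions):
        lo = pi * per_part * vchunk
        hi = min((pi + 1) * per_part * vchunk, n_variants)
        if lo < hi or (n_variants == 0 and pi == 0):
            partitions.append([lo, hi])
    wip = _wip_dir(store_path)
    os.makedirs(wip, exist_ok=True)
    with open(os.path.join(wip, "manifest.json"), "w") as f:
        json.dump({"icf_path": icf.path, "partitions": partitions}, f)
    return schema


def encode_partition_states(store_path):
    """Map encode-partition index -> 'done' or 'pending'."""
    wip = _wip_dir(store_path)
    with open(os.path.join(wip, "manifest.json")) as f:
        manifest = json.load(f)
    return {
        i: "done" if os.path.exists(os.path.join(wip, f"p{i}.done")) else "pending"
        for i in range(len(manifest["partitions"]))
    }


def encode_partition(store_path, index: int, icf=None):
    """Encode one contiguous range of variant chunks into the store."""
    wip = _wip_dir(store_path)
    with open(os.path.join(wip, "manifest.json")) as f:
        manifest = json.load(f)
    if icf is None:
        icf = IcfStore(manifest["icf_path"])
    start, stop = manifest["partitions"][index]
    root = zarr.open_group(str(store_path), mode="r+")
    schema = StoreSchema.fromdict(dict(root.attrs)["schema"])
    specs = {f.name: f for f in schema.fields}
    arrays = {name: root[name] for name in specs}
    meta = icf.metadata

    gt_triple = {"call_genotype", "call_genotype_phased", "call_genotype_mask"}
    local_names = [n for n in specs if n == "call_LA" or
                   (n.startswith("call_L") and specs[n].source_field and
                    specs[n].source_field.startswith("FORMAT/"))]
    vchunk = specs["variant_position"].chunks[0]

    for lo in range(start, max(stop, start + 1), vchunk):
        if stop == start:
            break
        hi = min(lo + vchunk, stop)
        genotype = None
        if meta.has_gt and (gt_triple & set(specs) or local_names):
            genotype, phased = _encode_genotype_chunk(icf, schema, lo, hi)
            if "call_genotype" in arrays:
                arrays["call_genotype"][lo:hi] = genotype
                arrays["call_genotype_phased"][lo:hi] = phased
                arrays["call_genotype_mask"][lo:hi] = genotype < 0
        la = None
        if local_names:
            n, ns, p = genotype.shape
            la = np.empty((n, ns, p), dtype=np.int64)
            for i in range(n):
                for s in range(ns):
                    la[i, s] = compute_local_alleles(genotype[i, s], p)
            if "call_LA" in arrays:
                arrays["call_LA"][lo:hi] = la
        for name, spec in specs.items():
            if name in gt_triple or name == "call_LA":
                continue
            if name in local_names:
                arrays[name][lo:hi] = _encode_localised(icf, spec, la, lo, hi)
                continue
            arrays[name][lo:hi] = encode_field(icf, spec, lo, hi)
    # Atomic completion marker.
    marker = os.path.join(wip, f"p{index}.done")
    with open(marker + ".tmp", "w") as f:
        f.write("done")
    os.replace(marker + ".tmp", marker)


def encode_finalise(store_path) -> "zarr.Group":
    """Validate partitions, build the region index and clear the wip state."""
    import shutil

    states = encode_partition_states(store_path)
    missing = sorted(i for i, s in states.items() if s != "done")
    if missing:
        raise EncodeError(f"encode partitions not completed: {missing}")
    root = zarr.open_group(str(store_path), mode="r+")
    n_variants = root["variant_position"].shape[0]
    vchunk = root["variant_position"].chunks[0]
    contig_arr = root["variant_contig"][:]
    pos_arr = root["variant_position"][:].astype(np.int64)
    ref = root["variant_allele"][:, 0] if n_variants else np.array([], dtype=object)
    ends = pos_arr + np.array([len(r) for r in ref], dtype=np.int64) - 1
    if "variant_END" in root:
        info_end = root["variant_END"][:].astype(np.int64)
        ends = np.where(info_end > INT_MISSING, np.maximum(ends, info_end), ends)
    region_index = build_region_index(contig_arr, pos_arr, ends, vchunk)
    ri = root.create_array(
        "region_index", shape=region_index.shape,
        chunks=(max(1, region_index.shape[0]), 5), dtype="int64",
        compressors=_zarr_compressor(CodecConfig()), overwrite=True,
    )
    if region_index.size:
        ri[:] = region_index
    ri.attrs["columns"] = list(REGION_INDEX_COLUMNS)
    shutil.rmtree(_wip_dir(store_path), ignore_errors=True)
    return root


def encode(
    icf,
    store_path: str,
    schema: StoreSchema = None,
    variant_chunk: int = None,
    local_alleles: bool = False,
) -> "zarr.Group":
    """Encode a finalised ICF into a VCF Zarr directory store (one shot)."""
    if isinstance(icf, (str, os.PathLike)):
        icf = IcfStore(icf)
    encode_init(icf, store_path, schema=schema, variant_chunk=variant_chunk,
                local_alleles=local_alleles, target_partitions=1)
    encode_partition(store_path, 0, icf=icf)
    return encode_finalise(store_path)


def _encode_localised(icf, spec, la, start, stop):
    """Encode a call_L<KEY> array chunk from its global-allele ICF field."""
    missing, fill = _sentinels_for(spec.dtype)
    dtype = np.float32 if spec.dtype == "float32" else np.dtype(spec.dtype)
    vals = icf.read_field_slice(spec.source_field, start, stop)
    n, ns, p = la.shape
    k = spec.shape[-1]
    buf = np.full((n, ns, k), fill, dtype=dtype)
    localize = localize_R_field if spec.vcf_number == "R" else localize_G_field
    for i in range(n):
        for s in range(ns):
            sv = vals[i][s]
            if sv is None or (isinstance(sv, tuple) and all(x is None for x in sv)):
                # Source field absent for this call: slots for observed
                # alleles are missing, padding slots stay fill.
                if spec.vcf_number == "R":
                    buf[i, s] = [missing if a >= 0 else fill for a in la[i, s]]
                else:
                    row = localize_G_field(
                        [], la[i, s], missing, fill
                    ) if np.any(la[i, s] >= 0) else [fill] * k
                    buf[i, s] = [missing if v is None else v for v in row]
                continue
            sv = _as_list(sv)
            row = localize(sv, la[i, s], missing, fill)
            buf[i, s] = [missing if v is None else v for v in row]
    return buf


# ---------------------------------------------------------------------------
# Zip archive stores
# ---------------------------------------------------------------------------


def zip_store(directory: str, zip_path: str = None) -> str:
    """Archive a Zarr directory store as an uncompressed Zip file.

    The archive is simply the standard directory hierarchy; chunk data is
    already compressed, so entries are stored without recompression.
    """
    directory = str(directory)
    if zip_path is None:
        zip_path = directory.rstrip("/\\") + ".zip"
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_STORED) as z:
        for dirpath, _dirnames, filenames in os.walk(directory):
            for fn in sorted(filenames):
                full = os.path.join(dirpath, fn)
                z.write(full, os.path.relpath(full, directory))
    return zip_path


def open_store(path: str):
    """Open a VCF Zarr store from a directory or a .zip archive."""
    path = str(path)
    if path.endswith(".zip") or zipfile.is_zipfile(path):
        store = zarr.storage.ZipStore(path, mode="r")
        return zarr.open_group(store, mode="r")
    return zarr.open_group(path, mode="r")


def vcf_to_zarr(vcf_path, store_path, icf_path=None, local_alleles=False,
                variant_chunk=None, target_partitions=1):
    """Convenience two-phase conversion: VCF -> ICF -> Zarr."""
    import tempfile

    from .icf import explode

    if icf_path is None:
        tmp = tempfile.TemporaryDirectory()
        icf_path = os.path.join(tmp.name, "icf")
    icf = explode(vcf_path, icf_path, target_partitions=target_partitions)
    return encode(icf, store_path, local_alleles=local_alleles,
                  variant_chunk=variant_chunk)
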
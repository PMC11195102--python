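"""Intermediate columnar format (ICF): the first conversion phase.

Converting VCF to Zarr needs a full pass over the data before any array can
be written, because array extents (maximum alleles, maximum length of
Number=. fields) and integer widths are global properties.  The *explode*
phase performs that pass: it streams VCF records and stores each field
independently as a sequence of approximately fixed-size compressed chunks,
together with per-partition record counts and per-field min/max/dimension
summaries.  The second phase (:mod:`vczarr.encode`) then materialises the
Zarr arrays from the ICF with known global dimensions.

Large indexed files can be split into region partitions that are exploded
independently (in parallel or resumably); partitions commit their output by
atomic directory rename, so a failed run can be retried partition by
partition.  ICF is internal to this package and not a stable interchange
format.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import os
import pickle
import shutil
import warnings
from typing import Optional

import numcodecs
import pysam

from .model import Category, FieldDescriptor

#: Default raw-value bytes accumulated per field before a chunk is cut.
DEFAULT_CHUNK_TARGET_BYTES = 1 << 20

_ICF_CODEC = numcodecs.Zstd(level=3)

#: Pseudo-field names for the fixed VCF columns as stored in ICF.
FIXED_FIELDS = ("CHROM", "POS", "ID", "ALLELES", "QUAL", "FILTERS")
GT_FIELD = "GT"


class IcfError(Exception):
    pass


# ---------------------------------------------------------------------------
# Partition planning
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PartitionSpec:
    """A contiguous slice of the input: a whole file or indexed regions."""

    source_path: str
    index: int
    # None means the whole file; otherwise an ordered list of
    # (contig, start, end) 1-based inclusive regions.
    regions: Optional[list] = None

    def asdict(self):
        return {
            "source_path": self.source_path,
            "index": self.index,
            "regions": self.regions,
        }

    @classmethod
    def fromdict(cls, d):
        regions = d["regions"]
        if regions is not None:
            regions = [tuple(r) for r in regions]
        return cls(d["source_path"], d["index"], regions)


def _has_index(path: str) -> bool:
    return os.path.exists(path + ".tbi") or os.path.exists(path + ".csi")


def _split_contigs(contigs, k: int):
    """Split an ordered list of (name, length) contigs into k region groups."""
    total = sum(length for _, length in contigs)
    if len(contigs) >= k:
        # Group consecutive contigs into k balanced-by-length groups.
        groups = [[] for _ in range(k)]
        target = total / k
        gi, acc = 0, 0
        for name, length in contigs:
            if groups[gi] and acc + length > target * (gi + 1) and gi < k - 1:
                gi += 1
            groups[gi].append((name, 1, length))
            acc += length
        return [g for g in groups if g]
    # More partitions than contigs: subdivide contigs proportionally.
    counts = {name: 1 for name, _ in contigs}
    remaining = k - len(contigs)
    # Largest-remainder allocation of the extra splits by contig length.
    quotas = sorted(
        contigs, key=lambda c: -(c[1] / total)
    )
    while remaining > 0:
        for name, length in quotas:
            if remaining == 0:
                break
            counts[name] += 1
            remaining -= 1
    groups = []
    for name, length in contigs:
        n = counts[name]
        bounds = [1 + (length * i) // n for i in range(n)] + [length + 1]
        for i in range(n):
            start, end = bounds[i], bounds[i + 1] - 1
            if end >= start:
                groups.append([(name, start, end)])
    return groups


def plan_partitions(paths, target_partitions: int = 1):
    """Plan non-overlapping partitions covering every record exactly once.

    With more target partitions than files, indexed files are split into
    genomic region partitions; an unindexed file falls back to a single
    whole-file partition with a warning.
    """
    paths = [str(p) for p in paths]
    if target_partitions < 1:
        raise ValueError("target_partitions must be >= 1")
    per_file = max(1, target_partitions // len(paths))
    specs = []
    for path in paths:
        if per_file == 1 or not _has_index(path):
            if per_file > 1:
                warnings.warn(
                    f"{path}: no Tabix/CSI index found; using a single "
                    "whole-file partition",
                    stacklevel=2,
                )
            specs.append(PartitionSpec(path, len(specs), None))
            continue
        with pysam.VariantFile(path) as vf:
            contigs = [
                (name, vf.header.contigs[name].length)
                for name in vf.header.contigs
            ]
        if any(length is None for _, length in contigs):
            warnings.warn(
                f"{path}: contig lengths missing from header; using a "
                "single whole-file partition",
                stacklevel=2,
            )
            specs.append(PartitionSpec(path, len(specs), None))
            continue
        for regions in _split_contigs(contigs, per_file):
            specs.append(PartitionSpec(path, len(specs), list(regions)))
    return specs


# ---------------------------------------------------------------------------
# Header model
# ---------------------------------------------------------------------------


def _read_raw_header(path: str) -> str:
    """Verbatim ## header lines from a plain or bgzip/gzip compressed VCF."""
    opener = gzip.open if str(path).endswith((".gz", ".bgz")) else open
    lines = []
    with opener(path, "rt") as f:
        for line in f:
            if line.startswith("##"):
                lines.append(line)
            elif line.startswith("#"):
                break
            else:  # pragma: no cover - malformed input
                break
    return "".join(lines)


def _header_fields(header: pysam.VariantHeader):
    """FieldDescriptors for every INFO and FORMAT declaration (GT special)."""
    info, fmt = [], []
    for key, meta in header.info.items():
        info.append(
            FieldDescriptor(Category.INFO, key, str(meta.number), meta.type,
                            meta.description or "")
        )
    has_gt = False
    for key, meta in header.formats.items():
        if key == "GT":
            has_gt = True
            continue
        fmt.append(
            FieldDescriptor(Category.FORMAT, key, str(meta.number), meta.type,
                            meta.description or "")
        )
    return info, fmt, has_gt


# ---------------------------------------------------------------------------
# Summaries and metadata
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FieldSummary:
    """Exact single-pass summary of one field over a set of records."""

    field_name: str
    num_records: int = 0
    observed_min: Optional[float] = None
    observed_max: Optional[float] = None
    max_dimension: int = 0
    num_chunks: int = 0

    def update_value(self, value):
        if value is None:
            return
        if self.observed_min is None or value < self.observed_min:
            self.observed_min = value
        if self.observed_max is None or value > self.observed_max:
            self.observed_max = value

    def merge(self, other: "FieldSummary") -> "FieldSummary":
        out = FieldSummary(self.field_name)
        out.num_records = self.num_records + other.num_records
        out.max_dimension = max(self.max_dimension, other.max_dimension)
        out.num_chunks = self.num_chunks + other.num_chunks
        for v in (self.observed_min, other.observed_min):
            if v is not None and (out.observed_min is None or v < out.observed_min):
                out.observed_min = v
        for v in (self.observed_max, other.observed_max):
            if v is not None and (out.observed_max is None or v > out.observed_max):
                out.observed_max = v
        return out

    def asdict(self):
        return dataclasses.asdict(self)

    @classmethod
    def fromdict(cls, d):
        return cls(**d)


@dataclasses.dataclass
class IcfMetadata:
    samples: list
    contigs: list  # [(id, length-or-None)]
    filters: list
    header_text: str
    info_fields: list  # FieldDescriptor
    format_fields: list  # FieldDescriptor (GT excluded)
    has_gt: bool
    partition_record_counts: list
    summaries: dict  # field name -> FieldSummary

    @property
    def num_records(self) -> int:
        return sum(self.partition_record_counts)

    @property
    def record_offsets(self) -> list:
        """Cumulative record offset of each partition."""
        offsets, acc = [], 0
        for n in self.partition_record_counts:
            offsets.append(acc)
            acc += n
        return offsets

    def asdict(self):
        def desc(d):
            return {
                "category": d.category.value,
                "key": d.key,
                "vcf_number": d.vcf_number,
                "vcf_type": d.vcf_type,
                "description": d.description,
            }

        return {
            "samples": self.samples,
            "contigs": self.contigs,
            "filters": self.filters,
            "header_text": self.header_text,
            "info_fields": [desc(d) for d in self.info_fields],
            "format_fields": [desc(d) for d in self.format_fields],
            "has_gt": self.has_gt,
            "partition_record_counts": self.partition_record_counts,
            "summaries": {k: v.asdict() for k, v in self.summaries.items()},
        }

    @classmethod
    def fromdict(cls, d):
        def desc(x):
            return FieldDescriptor(
                Category(x["category"]), x["key"], x["vcf_number"],
                x["vcf_type"], x["description"]
            )

        return cls(
            samples=list(d["samples"]),
            contigs=[tuple(c) for c in d["contigs"]],
            filters=list(d["filters"]),
            header_text=d["header_text"],
            info_fields=[desc(x) for x in d["info_fields"]],
            format_fields=[desc(x) for x in d["format_fields"]],
            has_gt=d["has_gt"],
            partition_record_counts=list(d["partition_record_counts"]),
            summaries={k: FieldSummary.fromdict(v) for k, v in d["summaries"].items()},
        )

    def field_names(self):
        names = list(FIXED_FIELDS)
        if self.has_gt:
            names.append(GT_FIELD)
        names += [f"INFO/{d.key}" for d in self.info_fields]
        names += [f"FORMAT/{d.key}" for d in self.format_fields]
        return names


# ---------------------------------------------------------------------------
# Value extraction
# ---------------------------------------------------------------------------


def _approx_size(value) -> int:
    """Cheap raw-size estimate of one record value, for chunk cutting."""
    if value is None or isinstance(value, bool):
        return 1
    if isinstance(value, (int, float)):
        return 8
    if isinstance(value, str):
        return len(value) + 1
    if isinstance(value, (list, tuple)):
        return 2 + sum(_approx_size(v) for v in value)
    return 8


def _record_values(rec, contig_index, info_fields, format_fields, has_gt):
    """Extract one VCF record into a dict of per-field Python values."""
    values = {
        "CHROM": contig_index[rec.chrom],
        "POS": rec.pos,
        "ID": rec.id,
        "ALLELES": tuple(rec.alleles),
        "QUAL": rec.qual,
        "FILTERS": list(rec.filter),
    }
    info = rec.info
    for d in info_fields:
        key = d.key
        if key in info:
            try:
                values[f"INFO/{key}"] = info[key]
            except (ValueError, TypeError) as e:
                raise IcfError(
                    f"INFO field {key!r} at {rec.chrom}:{rec.pos} does not "
                    f"match its header declaration: {e}"
                ) from e
        else:
            values[f"INFO/{key}"] = False if d.vcf_type == "Flag" else None
    samples = rec.samples
    if has_gt:
        gts = []
        for s in samples.itervalues():
            alleles = s.allele_indices if "GT" in s else (None,)
            gts.append((tuple(alleles), bool(s.phased)))
        values[GT_FIELD] = gts
    for d in format_fields:
        key = d.key
        vals = []
        for s in samples.itervalues():
            if key in s:
                try:
                    vals.append(s[key])
                except (ValueError, TypeError) as e:
                    raise IcfError(
                        f"FORMAT field {key!r} at {rec.chrom}:{rec.pos} does "
                        f"not match its header declaration: {e}"
                    ) from e
            else:
                vals.append(None)
        values[f"FORMAT/{key}"] = vals
    return values


def _update_summary(summary: FieldSummary, name: str, value):
    summary.num_records += 1
    if name == "GT":
        dim = 0
        for alleles, _phased in value:
            dim = max(dim, len(alleles))
            for a in alleles:
                if a is not None:
                    summary.update_value(a)
        summary.max_dimension = max(summary.max_dimension, dim)
        return
    if name in ("ALLELES", "FILTERS"):
        summary.max_dimension = max(summary.max_dimension, len(value))
        return
    if name.startswith("FORMAT/"):
        dim = 0
        for v in value:
            if isinstance(v, tuple):
                dim = max(dim, len(v))
                for x in v:
                    if isinstance(x, (int, float)):
                        summary.update_value(x)
            else:
                dim = max(dim, 0 if v is None else 1)
                if isinstance(v, (int, float)) and not isinstance(v, bool):
                    summary.update_value(v)
        summary.max_dimension = max(summary.max_dimension, dim)
        return
    if isinstance(value, tuple):
        summary.max_dimension = max(summary.max_dimension, len(value))
        for x in value:
            if isinstance(x, (int, float)):
                summary.update_value(x)
    else:
        summary.max_dimension = max(summary.max_dimension, 0 if value is None else 1)
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            summary.update_value(value)


# ---------------------------------------------------------------------------
# Explode
# ---------------------------------------------------------------------------


class _FieldWriter:
    """Accumulates one field's values, cutting compressed pickle chunks."""

    def __init__(self, directory, target_bytes):
        self.directory = directory
        self.target_bytes = target_bytes
        self.buffer = []
        self.buffered_bytes = 0
        self.chunk_counts = []
        os.makedirs(directory, exist_ok=True)

    def append(self, value):
        self.buffer.append(value)
        self.buffered_bytes += _approx_size(value)
        if self.buffered_bytes >= self.target_bytes:
            self.flush()

    def flush(self):
        if not self.buffer:
            return
        data = _ICF_CODEC.encode(pickle.dumps(self.buffer))
        path = os.path.join(self.directory, str(len(self.chunk_counts)))
        with open(path, "wb") as f:
            f.write(data)
        self.chunk_counts.append(len(self.buffer))
        self.buffer = []
        self.buffered_bytes = 0


def _iter_partition_records(partition: PartitionSpec):
    with pysam.VariantFile(partition.source_path) as vf:
        if partition.regions is None:
            yield vf.header, iter(vf)
        else:
            def gen():
                for contig, start, end in partition.regions:
                    if contig not in vf.header.contigs:
                        continue
                    for rec in vf.fetch(contig, start - 1, end):
                        # fetch returns overlapping records; a record belongs
                        # to the partition containing its POS.
                        if rec.pos < start or rec.pos > end:
                            continue
                        yield rec

            yield vf.header, gen()


def explode_partition(
    out_path: str,
    partition: PartitionSpec,
    chunk_target_bytes: int = DEFAULT_CHUNK_TARGET_BYTES,
):
    """Explode one partition, committing its output by atomic rename."""
    out_path = str(out_path)
    pdir = os.path.join(out_path, "partitions", f"p{partition.index}")
    tmp = pdir + ".tmp"
    shutil.rmtree(tmp, ignore_errors=True)
    os.makedirs(tmp)
    for header, records in _iter_partition_records(partition):
        info_fields, format_fields, has_gt = _header_fields(header)
        contig_index = {name: i for i, name in enumerate(header.contigs)}
        names = list(FIXED_FIELDS) + (
            [GT_FIELD] if has_gt else []
        ) + [f"INFO/{d.key}" for d in info_fields] + [
            f"FORMAT/{d.key}" for d in format_fields
        ]
        writers = {
            name: _FieldWriter(
                os.path.join(tmp, "fields", name.replace("/", "__")),
                chunk_target_bytes,
            )
            for name in names
        }
        summaries = {name: FieldSummary(name) for name in names}
        num_records = 0
        for rec in records:
            try:
                values = _record_values(
                    rec, contig_index, info_fields, format_fields, has_gt
                )
            except IcfError:
                raise
            except Exception as e:
                raise IcfError(
                    f"malformed VCF record number {num_records} in partition "
                    f"{partition.index}: {e}"
                ) from e
            for name in names:
                writers[name].append(values[name])
                _update_summary(summaries[name], name, values[name])
            num_records += 1
        chunk_counts = {}
        for name, w in writers.items():
            w.flush()
            summaries[name].num_chunks = len(w.chunk_counts)
            chunk_counts[name] = w.chunk_counts
    summary_doc = {
        "index": partition.index,
        "num_records": num_records,
        "summaries": {k: v.asdict() for k, v in summaries.items()},
        "chunk_counts": chunk_counts,
    }
    with open(os.path.join(tmp, "summary.json"), "w") as f:
        json.dump(summary_doc, f)
    shutil.rmtree(pdir, ignore_errors=True)
    os.rename(tmp, pdir)


def explode_init(
    out_path: str,
    paths,
    target_partitions: int = 1,
    chunk_target_bytes: int = DEFAULT_CHUNK_TARGET_BYTES,
):
    """Create the ICF skeleton and the partition plan; returns the plan."""
    out_path = str(out_path)
    paths = [str(p) for p in paths]
    specs = plan_partitions(paths, target_partitions)
    os.makedirs(os.path.join(out_path, "partitions"), exist_ok=True)
    headers = []
    for p in paths:
        with pysam.VariantFile(p) as vf:
            headers.append(vf.header)
    first = headers[0]
    samples = list(first.samples)
    for h, p in zip(headers[1:], paths[1:]):
        if list(h.samples) != samples:
            raise IcfError(f"sample list of {p} differs from {paths[0]}")
    manifest = {
        "paths": paths,
        "chunk_target_bytes": chunk_target_bytes,
        "partitions": [s.asdict() for s in specs],
        "header_text": _read_raw_header(paths[0]),
    }
    with open(os.path.join(out_path, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2)
    return specs


def _load_manifest(out_path):
    with open(os.path.join(out_path, "manifest.json")) as f:
        return json.load(f)


def partition_states(out_path: str):
    """Map partition index -> 'done' or 'pending'."""
    manifest = _load_manifest(out_path)
    states = {}
    for d in manifest["partitions"]:
        i = d["index"]
        done = os.path.exists(
            os.path.join(out_path, "partitions", f"p{i}", "summary.json")
        )
        states[i] = "done" if done else "pending"
    return states


def finalise_explode(out_path: str) -> IcfMetadata:
    """Merge partition summaries into the final ICF metadata document.

    Fails, listing the offending indexes, if any partition has not
    completed, so that failed partitions can be retried.
    """
    out_path = str(out_path)
    manifest = _load_manifest(out_path)
    missing = sorted(i for i, s in partition_states(out_path).items() if s != "done")
    if missing:
        raise IcfError(f"partitions not completed: {missing}")
    partitions = manifest["partitions"]
    per_part = []
    for d in partitions:
        with open(
            os.path.join(out_path, "partitions", f"p{d['index']}", "summary.json")
        ) as f:
            per_part.append(json.load(f))
    with pysam.VariantFile(manifest["paths"][0]) as vf:
        info_fields, format_fields, has_gt = _header_fields(vf.header)
        contigs = [
            (name, vf.header.contigs[name].length) for name in vf.header.contigs
        ]
        filters = list(vf.header.filters)
        samples = list(vf.header.samples)
    merged = {}
    for doc in per_part:
        for name, sd in doc["summaries"].items():
            s = FieldSummary.fromdict(sd)
            merged[name] = merged[name].merge(s) if name in merged else s
    meta = IcfMetadata(
        samples=samples,
        contigs=contigs,
        filters=filters,
        header_text=manifest["header_text"],
        info_fields=info_fields,
        format_fields=format_fields,
        has_gt=has_gt,
        partition_record_counts=[doc["num_records"] for doc in per_part],
        summaries=merged,
    )
    with open(os.path.join(out_path, "metadata.json"), "w") as f:
        json.dump(meta.asdict(), f)
    return meta


def explode(
    paths,
    out_path: str,
    target_partitions: int = 1,
    chunk_target_bytes: int = DEFAULT_CHUNK_TARGET_BYTES,
) -> "IcfStore":
    """One-shot explode: init, run every partition, finalise."""
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    specs = explode_init(out_path, paths, target_partitions, chunk_target_bytes)
    for spec in specs:
        explode_partition(out_path, spec, chunk_target_bytes)
    finalise_explode(out_path)
    return IcfStore(out_path)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


class IcfStore:
    """Read access to a finalised ICF directory."""

    def __init__(self, path: str):
        self.path = str(path)
        meta_path = os.path.join(self.path, "metadata.json")
        if not os.path.exists(meta_path):
            raise IcfError(f"{path} is not a finalised ICF store")
        with open(meta_path) as f:
            self.metadata = IcfMetadata.fromdict(json.load(f))
        self._chunk_counts = {}
        for i in range(len(self.metadata.partition_record_counts)):
            with open(
                os.path.join(self.path, "partitions", f"p{i}", "summary.json")
            ) as f:
                self._chunk_counts[i] = json.load(f)["chunk_counts"]
        self._cache_key = None
        self._cache_values = None

    @property
    def num_records(self) -> int:
        return self.metadata.num_records

    def _read_chunk(self, partition: int, field: str, chunk: int):
        key = (partition, field, chunk)
        if self._cache_key == key:
            return self._cache_values
        path = os.path.join(
            self.path, "partitions", f"p{partition}", "fields",
            field.replace("/", "__"), str(chunk)
        )
        with open(path, "rb") as f:
            values = pickle.loads(_ICF_CODEC.decode(f.read()))
        self._cache_key, self._cache_values = key, values
        return values

    def read_field_slice(self, field: str, start: int, stop: int):
        """Values of ``field`` for records [start, stop), in record order.

        Only chunks overlapping the slice are decompressed.
        """
        if field not in self.metadata.field_names():
            raise KeyError(f"unknown ICF field {field!r}")
        n = self.num_records
        if not (0 <= start <= stop <= n):
            raise IndexError(f"slice [{start}, {stop}) out of range [0, {n}]")
        out = []
        offset = 0
        for pi, count in enumerate(self.metadata.partition_record_counts):
            if offset >= stop:
                break
            if offset + count > start:
                lo = max(start - offset, 0)
                hi = min(stop - offset, count)
                out.extend(self._read_partition_slice(pi, field, lo, hi))
            offset += count
        return out

    def _read_partition_slice(self, partition, field, lo, hi):
        counts = self._chunk_counts[partition].get(field, [])
        out = []
        coff = 0
        for ci, cn in enumerate(counts):
            if coff >= hi:
                break
            if coff + cn > lo:
                values = self._read_chunk(partition, field, ci)
                out.extend(values[max(lo - coff, 0):min(hi - coff, cn)])
            coff += cn
        return out

    def iter_field(self, field: str, batch: int = 10_000):
        """Stream a field in record order in batches of ``batch`` records."""
        n = self.num_records
        for start in range(0, n, batch):
            yield from self.read_field_slice(field, start, min(start + batch, n))
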
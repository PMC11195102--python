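"""Logical data model for the VCF Zarr encoding.

VCF is a row-wise interchange format: each record interleaves per-variant
metadata (the fixed columns and INFO fields) with per-call matrices (the
FORMAT fields).  The VCF Zarr encoding decouples this data model from the
row-oriented file layout, mapping every field to a separately stored,
chunked, compressed n-dimensional array.  This module defines that mapping:

* field naming — FORMAT fields become ``call_<KEY>`` arrays, INFO fields
  ``variant_<KEY>``, and the fixed columns map to reserved names;
* shape — the VCF ``Number`` declaration maps to trailing dimensions whose
  extents are *global* maxima over all records;
* dtype — the narrowest integer width that can represent the observed data
  (with the sentinel values reserved), 32-bit floats, booleans for flags,
  variable-length strings otherwise;
* sentinels — in-band values distinguishing *missing* data (a value that is
  absent in the source) from *fill* (padding beyond a record's true length);
* chunking and codec defaults.

Everything here is pure arithmetic and bookkeeping; actual I/O lives in
:mod:`vczarr.icf` and :mod:`vczarr.encode`.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
import struct
from typing import Optional

import numpy as np

FORMAT_VERSION = "0.1"

#: Names of the seven fixed per-variant columns plus the genotype field.
FIXED_FIELD_KEYS = ("CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "GT")

#: Reserved array names for the fixed columns.
RESERVED_NAMES = {
    "POS": "variant_position",
    "CHROM": "variant_contig",
    "ID": "variant_id",
    "QUAL": "variant_quality",
    "FILTER": "variant_filter",
}

#: The genotype column expands to this triple of arrays.
GENOTYPE_ARRAYS = ("call_genotype", "call_genotype_phased", "call_genotype_mask")


class Category(str, enum.Enum):
    FIXED = "fixed"
    INFO = "INFO"
    FORMAT = "FORMAT"


# ---------------------------------------------------------------------------
# Sentinels
# ---------------------------------------------------------------------------

#: Integer sentinel for a value that is missing in the source ("." in VCF).
INT_MISSING = -1
#: Integer sentinel padding a record out to the global maximum dimension.
INT_FILL = -2

STR_MISSING = "."
STR_FILL = ""


def _f32_from_bits(bits: int) -> np.float32:
    return np.frombuffer(struct.pack("<I", bits), dtype="<f4")[0]


# Quiet NaNs with distinct low-bit payloads so that missing and fill remain
# distinguishable after a bit-exact storage round trip.  Both are
# non-signalling (quiet bit set).
FLOAT_MISSING_BITS = 0x7FC00001
FLOAT_FILL_BITS = 0x7FC00002
FLOAT_MISSING = _f32_from_bits(FLOAT_MISSING_BITS)
FLOAT_FILL = _f32_from_bits(FLOAT_FILL_BITS)


def float_bits(values: np.ndarray) -> np.ndarray:
    """Bit patterns of a float32 array, for sentinel-aware comparisons."""
    return np.asarray(values, dtype=np.float32).view(np.uint32)


def is_float_missing(values: np.ndarray) -> np.ndarray:
    return float_bits(values) == FLOAT_MISSING_BITS


def is_float_fill(values: np.ndarray) -> np.ndarray:
    return float_bits(values) == FLOAT_FILL_BITS


# ---------------------------------------------------------------------------
# Descriptors and schema objects
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class FieldDescriptor:
    """One VCF header declaration (fixed column, INFO or FORMAT line)."""

    category: Category
    key: str
    vcf_number: str  # "0","1","2",... or "A","R","G","."
    vcf_type: str  # Integer, Float, String, Character, Flag
    description: str = ""

    def __post_init__(self):
        if self.category == Category.FIXED and self.key not in FIXED_FIELD_KEYS:
            raise ValueError(f"not a fixed VCF column: {self.key!r}")
        if self.vcf_type == "Flag" and self.category != Category.INFO:
            raise ValueError("Flag type is only valid for INFO fields")

    @property
    def name(self) -> str:
        return map_field_name(self.category, self.key)


@dataclasses.dataclass
class CodecConfig:
    """Compressor settings for one array (Blosc-style codec + shuffle)."""

    codec: str = "zstd"  # zstd | lz4 | none
    level: int = 7
    shuffle: str = "none"  # none | bit | byte
    precision_filter: Optional[tuple] = None  # ("quantize", d) | ("bit_round", b)

    def __post_init__(self):
        if self.codec not in ("zstd", "lz4", "none"):
            raise ValueError(f"unknown codec {self.codec!r}")
        if self.shuffle not in ("none", "bit", "byte"):
            raise ValueError(f"unknown shuffle {self.shuffle!r}")
        if self.precision_filter is not None:
            kind, arg = self.precision_filter
            if kind not in ("quantize", "bit_round"):
                raise ValueError(f"unknown precision filter {kind!r}")
            if arg < 0:
                raise ValueError("precision filter parameter must be >= 0")


@dataclasses.dataclass
class ArraySpec:
    """The logical and physical layout of one array in the store."""

    name: str
    dims: list  # dimension names; first is always "variants"
    shape: list  # per-dimension extents
    dtype: str  # int8|int16|int32|int64|float32|bool|str
    chunks: list
    codec_config: CodecConfig = dataclasses.field(default_factory=CodecConfig)
    description: str = ""
    # Provenance needed to reconstruct VCF text; None for synthesised arrays.
    source_field: Optional[str] = None  # "INFO/DP", "FORMAT/AD", "fixed/POS"
    vcf_number: Optional[str] = None
    vcf_type: Optional[str] = None

    def __post_init__(self):
        if len(self.dims) != len(self.shape):
            raise ValueError("dims and shape must have equal length")
        if self.dims and self.dims[0] != "variants":
            raise ValueError("first dimension must be 'variants'")
        if self.codec_config.precision_filter is not None and self.dtype != "float32":
            raise ValueError("precision filters only apply to float arrays")
        for extent, chunk in zip(self.shape, self.chunks):
            if extent > 0 and chunk > extent:
                raise ValueError(
                    f"chunk extent {chunk} exceeds shape extent {extent} in {self.name}"
                )

    @property
    def np_dtype(self) -> np.dtype:
        if self.dtype == "str":
            return np.dtype(object)
        return np.dtype(self.dtype)


@dataclasses.dataclass
class StoreSchema:
    """Full description of a VCF Zarr store, serialisable to editable JSON."""

    format_version: str
    samples: list
    contigs: list  # [(id, length-or-None), ...] in header declaration order
    filters: list  # filter ids in header order
    fields: list  # ArraySpec
    ploidy: int
    max_alleles: int
    local_alleles: bool = False
    vcf_header: str = ""

    def __post_init__(self):
        names = [f.name for f in self.fields]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate array names in schema: {dupes}")

    def field(self, name: str) -> ArraySpec:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def field_names(self) -> list:
        return [f.name for f in self.fields]

    # -- JSON round trip (the `mkschema` -> edit -> `encode --schema` path) --

    def asdict(self) -> dict:
        d = dataclasses.asdict(self)
        for f in d["fields"]:
            pf = f["codec_config"]["precision_filter"]
            if pf is not None:
                f["codec_config"]["precision_filter"] = list(pf)
        return d

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.asdict(), indent=indent)

    @classmethod
    def fromdict(cls, d: dict) -> "StoreSchema":
        fields = []
        for f in d["fields"]:
            cc = dict(f["codec_config"])
            if cc.get("precision_filter") is not None:
                cc["precision_filter"] = tuple(cc["precision_filter"])
            fields.append(
                ArraySpec(**{**f, "codec_config": CodecConfig(**cc)})
            )
        contigs = [tuple(c) for c in d["contigs"]]
        return cls(
            format_version=d["format_version"],
            samples=list(d["samples"]),
            contigs=contigs,
            filters=list(d["filters"]),
            fields=fields,
            ploidy=d["ploidy"],
            max_alleles=d["max_alleles"],
            local_alleles=d.get("local_alleles", False),
            vcf_header=d.get("vcf_header", ""),
        )

    @classmethod
    def from_json(cls, text: str) -> "StoreSchema":
        return cls.fromdict(json.loads(text))


# ---------------------------------------------------------------------------
# Name / shape / dtype mapping
# ---------------------------------------------------------------------------


def map_field_name(category: Category, key: str):
    """Map a VCF field to its array name(s).

    FORMAT fields get a ``call_`` prefix, INFO fields a ``variant_`` prefix,
    and the fixed columns map to reserved names.  GT is special: it expands
    to the triple (call_genotype, call_genotype_phased, call_genotype_mask).
    """
    category = Category(category)
    if category == Category.FIXED:
        if key == "GT":
            return GENOTYPE_ARRAYS
        if key in ("REF", "ALT"):
            return "variant_allele"
        try:
            return RESERVED_NAMES[key]
        except KeyError:
            raise ValueError(f"unknown fixed field {key!r}") from None
    prefix = "call_" if category == Category.FORMAT else "variant_"
    name = prefix + key
    reserved = set(RESERVED_NAMES.values()) | set(GENOTYPE_ARRAYS) | {"variant_allele"}
    if name in reserved:
        raise ValueError(
            f"{category.value} field {key!r} collides with the reserved array "
            f"name {name!r}; rename the field before conversion"
        )
    return name


def genotype_dim_size(n_alleles: int, ploidy: int) -> int:
    """Number of unordered genotypes: C(n_alleles + ploidy - 1, ploidy).

    This is the length of Number=G fields; for diploids it reduces to
    n(n+1)/2, the familiar quadratic dependency on the allele count.
    """
    if n_alleles < 1 or ploidy < 1:
        raise ValueError("n_alleles and ploidy must be >= 1")
    return math.comb(n_alleles + ploidy - 1, ploidy)


def map_number_to_dims(
    descriptor: FieldDescriptor,
    max_alleles: int,
    ploidy: int,
    max_dot_length: int = 1,
):
    """Map a field's Number declaration to trailing (dim-name, extent) pairs.

    Leading dimensions are implied by the category: FORMAT arrays are
    ``(variants, samples, ...)``, INFO arrays ``(variants, ...)``.  Returned
    here are the *trailing* dimensions only.
    """
    number = str(descriptor.vcf_number)
    key = descriptor.key
    if descriptor.vcf_type == "Flag":
        if number != "0":
            raise ValueError(f"Flag field {key!r} must have Number=0")
        return []
    if number == "1":
        return []
    if number == "A":
        return [("alt_alleles", max_alleles - 1)]
    if number == "R":
        return [("alleles", max_alleles)]
    if number == "G":
        return [("genotypes", genotype_dim_size(max_alleles, ploidy))]
    if number == ".":
        # Variable-length field: extent is the maximum observed length,
        # never zero so that the array stays well-formed.
        return [(f"{key}_dim", max(1, max_dot_length))]
    k = int(number)
    if k < 1:
        raise ValueError(f"invalid Number={number!r} for field {key!r}")
    return [(f"{key}_dim", k)]


_INT_DTYPES = ("int8", "int16", "int32", "int64")


def select_integer_dtype(observed_min: int, observed_max: int) -> str:
    """Narrowest signed integer dtype holding the data plus the sentinels.

    The sentinel values -1 (missing) and -2 (fill) are always reserved, so a
    field whose genuine values include them cannot be stored as an integer.
    """
    if observed_min in (INT_MISSING, INT_FILL) or observed_max in (INT_MISSING, INT_FILL):
        raise ValueError(
            "integer field contains -1 or -2, which are reserved as the "
            "missing/fill sentinels; store this field as a float instead"
        )
    lo = min(observed_min, INT_FILL)
    hi = max(observed_max, INT_MISSING)
    for dtype in _INT_DTYPES:
        info = np.iinfo(dtype)
        if info.min <= lo and hi <= info.max:
            return dtype
    raise ValueError(f"range [{observed_min}, {observed_max}] exceeds int64")


def uncompressed_size(shape, dtype: str) -> int:
    """Uncompressed byte count of an array: product of extents x item size."""
    itemsize = 1 if dtype == "bool" else np.dtype(dtype).itemsize
    return int(np.prod([int(s) for s in shape], dtype=object)) * itemsize


_BINARY_UNITS = ["B", "KiB", "MiB", "GiB", "TiB", "PiB"]


def format_bytes(n: int, digits: int = 2) -> str:
    """Human-readable binary-unit rendering (KiB/MiB/GiB/TiB)."""
    x = float(n)
    for unit in _BINARY_UNITS:
        if x < 1024 or unit == _BINARY_UNITS[-1]:
            if unit == "B":
                return f"{int(x)} B"
            return f"{x:.{digits}f} {unit}"
        x /= 1024.0
    raise AssertionError


def chunk_grid_count(shape, chunks) -> int:
    """Number of chunks in the grid: prod over dims of ceil(extent/chunk)."""
    total = 1
    for extent, chunk in zip(shape, chunks):
        if chunk <= 0:
            raise ValueError("chunk extents must be positive")
        total *= max(1, -(-int(extent) // int(chunk)))
    return total


#: Default chunk extents along the variants and samples dimensions.
DEFAULT_VARIANT_CHUNK = 10_000
DEFAULT_SAMPLE_CHUNK = 1_000
DEFAULT_ZSTD_LEVEL = 7


def default_codec_config(spec: ArraySpec) -> CodecConfig:
    """Default compressor: zstd everywhere; bit shuffle only where it pays.

    Bit shuffle groups equal-significance bits across values before
    compression, which helps enormously for low-entropy int8 genotypes and
    for booleans stored as bytes (top bits all zero), but tends to hurt
    noisy count-like fields, so it is enabled exactly for call_genotype and
    boolean arrays.
    """
    shuffle = "bit" if (spec.name == "call_genotype" or spec.dtype == "bool") else "none"
    return CodecConfig(codec="zstd", level=DEFAULT_ZSTD_LEVEL, shuffle=shuffle)
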
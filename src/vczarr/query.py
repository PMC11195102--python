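"""Read path for VCF Zarr stores: region/sample subsetting, VCF text
reconstruction (``view``) and format-string extraction (``query``).

The view operation is the inverse of conversion: it emits the stored
verbatim header followed by records rebuilt field by field from the
arrays — missing sentinels become ``.``, trailing fill values are dropped,
GT is reassembled from call_genotype and the phased flags, FILTER from the
boolean filter matrix.  Two corner cases are not invertible by design:
a field that is present but entirely missing is indistinguishable from an
absent field, and integer fields whose genuine values include -1/-2 are
rejected at conversion time.

Region queries go through the region index: only chunks whose position
range intersects the query are read, then records are masked by exact
interval overlap (POS..END vs query start..end, 1-based inclusive).
"""

from __future__ import annotations

import dataclasses
import re
from typing import Optional

import numpy as np

from . import expr as expr_mod
from .encode import open_store
from .model import (
    INT_FILL,
    INT_MISSING,
    STR_FILL,
    STR_MISSING,
    is_float_fill,
    is_float_missing,
)


class QueryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Store wrapper
# ---------------------------------------------------------------------------


class VczStore:
    """A VCF Zarr store opened for reading, with an array access log.

    The access log (`accessed`) records which arrays have been touched,
    which lets tests assert that ``query`` reads only the arrays its
    template references.
    """

    def __init__(self, path_or_group):
        if isinstance(path_or_group, (str,)) or hasattr(path_or_group, "__fspath__"):
            self.root = open_store(path_or_group)
        else:
            self.root = path_or_group
        attrs = dict(self.root.attrs)
        self.contigs = [tuple(c) for c in attrs.get("contigs", [])]
        self.contig_ids = [c[0] for c in self.contigs]
        self.filters = list(attrs.get("filters", []))
        self.samples = list(attrs.get("samples", []))
        self.header_text = attrs.get("vcf_header", "")
        self.attrs = attrs
        self.accessed = set()

    def __contains__(self, name):
        return name in self.root

    def array(self, name):
        if name not in self.root:
            raise QueryError(f"store has no array {name!r}")
        self.accessed.add(name)
        return self.root[name]

    def array_names(self):
        return sorted(self.root.array_keys())

    @property
    def num_variants(self):
        return self.array("variant_position").shape[0]

    @property
    def variant_chunk_size(self):
        return self.array("variant_position").chunks[0]

    def record_ends(self, start, stop):
        """1-based inclusive end coordinate of records [start, stop)."""
        pos = self.array("variant_position")[start:stop].astype(np.int64)
        ref = self.array("variant_allele")[start:stop, 0]
        ends = pos + np.array([len(r) for r in ref], dtype=np.int64) - 1
        if "variant_END" in self.root:
            info_end = self.array("variant_END")[start:stop].astype(np.int64)
            genuine = info_end > INT_MISSING
            ends = np.where(genuine, np.maximum(ends, info_end), ends)
        return ends


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RegionQuery:
    """1-based inclusive genomic interval; end=None means contig end."""

    contig: str
    start: int = 1
    end: Optional[int] = None

    def __post_init__(self):
        if self.start < 1:
            raise QueryError("region start must be >= 1")
        if self.end is not None and self.end < self.start:
            raise QueryError("region end must be >= start")


_REGION_RE = re.compile(r"^([^:]+)(?::(\d+)(?:(-)(\d+)?)?)?$")


def parse_region(text: str) -> RegionQuery:
    """Parse "contig", "contig:start", "contig:start-", "contig:start-end"."""
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise QueryError(f"malformed region {text!r}")
    contig, start, dash, end = m.groups()
    if start is None:
        return RegionQuery(contig)
    start = int(start)
    if dash is None:
        return RegionQuery(contig, start, start)
    return RegionQuery(contig, start, int(end) if end else None)


def parse_regions(text_or_list):
    if isinstance(text_or_list, str):
        parts = [p for p in text_or_list.split(",") if p]
    else:
        parts = list(text_or_list)
    return [parse_region(p) if isinstance(p, str) else p for p in parts]


def resolve_regions(store: VczStore, queries):
    """Map region queries to (chunk_index, intra-chunk record mask) pairs.

    Candidate chunks come from the region index; the per-record mask is
    computed by exact interval-overlap comparison within those chunks only.
    Results are in genome (record) order and deduplicated across queries.
    """
    index = store.array("region_index")[:]
    chunk_size = store.variant_chunk_size
    n = store.num_variants
    masks = {}
    for q in queries:
        if q.contig not in store.contig_ids:
            raise QueryError(
                f"unknown contig {q.contig!r}; known contigs: "
                f"{', '.join(store.contig_ids)}"
            )
        cid = store.contig_ids.index(q.contig)
        qstart = q.start
        qend = q.end if q.end is not None else np.iinfo(np.int64).max
        rows = index[
            (index[:, 1] == cid)
            & (index[:, 2] <= qend)
            & (index[:, 3] >= qstart)
        ]
        for ci in np.unique(rows[:, 0]):
            lo = int(ci) * chunk_size
            hi = min(lo + chunk_size, n)
            contig = store.array("variant_contig")[lo:hi]
            pos = store.array("variant_position")[lo:hi].astype(np.int64)
            ends = store.record_ends(lo, hi)
            mask = (contig == cid) & (pos <= qend) & (ends >= qstart)
            if int(ci) in masks:
                masks[int(ci)] |= mask
            else:
                masks[int(ci)] = mask
    return [(ci, masks[ci]) for ci in sorted(masks) if masks[ci].any()]


# ---------------------------------------------------------------------------
# Value rendering
# ---------------------------------------------------------------------------


def _render_float(v) -> str:
    if is_float_missing(np.float32(v)) or (np.isnan(v) and not is_float_fill(np.float32(v))):
        return STR_MISSING
    f = np.float32(v)
    if f == np.floor(f) and abs(f) < 1e15:
        return str(int(f))
    # Shortest decimal string that round-trips at 32-bit precision.
    return np.format_float_positional(f, unique=True, trim="0")


def _render_scalar(v, dtype_kind) -> str:
    if dtype_kind == "f":
        return _render_float(v)
    if dtype_kind in "iu":
        return STR_MISSING if v == INT_MISSING else str(int(v))
    # strings
    if v is None or v == STR_FILL or v == STR_MISSING:
        return STR_MISSING
    return str(v)


def _strip_fill(values, dtype_kind):
    """Drop trailing fill entries of one record's vector."""
    values = list(values)
    while values:
        v = values[-1]
        if dtype_kind == "f":
            if is_float_fill(np.float32(v)):
                values.pop()
                continue
        elif dtype_kind in "iu":
            if v == INT_FILL:
                values.pop()
                continue
        else:
            if v == STR_FILL:
                values.pop()
                continue
        break
    return values


def _render_vector(values, dtype_kind) -> Optional[str]:
    """Render one record's value list; None means "omit the field"."""
    vals = _strip_fill(values, dtype_kind)
    if not vals:
        return None
    rendered = [_render_scalar(v, dtype_kind) for v in vals]
    if all(r == STR_MISSING for r in rendered):
        return None
    return ",".join(rendered)


def _render_gt(genotype_row, phased) -> str:
    alleles = _strip_fill(genotype_row, "i")
    if not alleles:
        return STR_MISSING
    sep = "|" if phased else "/"
    return sep.join(STR_MISSING if a == INT_MISSING else str(int(a)) for a in alleles)


# ---------------------------------------------------------------------------
# view
# ---------------------------------------------------------------------------


def _resolve_samples(store, samples, exclude=False):
    if samples is None:
        return list(range(len(store.samples)))
    if isinstance(samples, str):
        if samples.startswith("^"):
            exclude = True
            samples = samples[1:]
        samples = [s for s in samples.split(",") if s]
    unknown = [s for s in samples if s not in store.samples]
    if unknown:
        raise QueryError(f"samples not in store: {', '.join(unknown)}")
    if exclude:
        return [i for i, s in enumerate(store.samples) if s not in set(samples)]
    index = {s: i for i, s in enumerate(store.samples)}
    return [index[s] for s in samples]


def _info_field_arrays(store):
    """INFO-derived arrays, as (key, name) pairs.

    Only arrays recorded as originating from an INFO field are rendered;
    user-added arrays (e.g. QC masks) are left out of reconstructed text.
    """
    out = []
    for name in store.array_names():
        if not name.startswith("variant_"):
            continue
        source = store.root[name].attrs.get("source_field", "")
        if source.startswith("INFO/"):
            out.append((name[len("variant_"):], name))
    return out


def _format_field_arrays(store):
    """FORMAT-derived arrays (including local-allele fields)."""
    out = []
    for name in store.array_names():
        if not name.startswith("call_") or name.startswith("call_genotype"):
            continue
        source = store.root[name].attrs.get("source_field", "")
        if source.startswith("FORMAT/") or name == "call_LA":
            out.append((name[len("call_"):], name))
    return out


def _synthesised_header_lines(store, info_fields, format_fields, declared):
    """Header lines for arrays with no declaration in the stored header."""
    lines = []
    for key, name in info_fields:
        if f"##INFO=<ID={key}," in declared or f"##INFO=<ID={key}>" in declared:
            continue
        lines.append(
            f'##INFO=<ID={key},Number=.,Type={_vcf_type(store, name)},'
            f'Description="Restored from {name}">'
        )
    for key, name in format_fields:
        if f"##FORMAT=<ID={key}," in declared:
            continue
        lines.append(
            f'##FORMAT=<ID={key},Number=.,Type={_vcf_type(store, name)},'
            f'Description="Restored from {name}">'
        )
    return lines


def _vcf_type(store, name):
    kind = store.array(name).dtype.kind
    return {"i": "Integer", "u": "Integer", "f": "Float", "b": "Flag"}.get(
        kind, "String"
    )


def view(
    store,
    regions=None,
    samples=None,
    exclude_samples: bool = False,
    include: Optional[str] = None,
    drop_genotypes: bool = False,
    batch: int = 1000,
):
    """Generate VCF text lines reconstructing the store's content.

    Yields strings (without trailing newline).  ``regions`` is a region
    string/list, ``samples`` a list or comma string (prefix ^ to exclude),
    ``include`` a filter expression; ``drop_genotypes`` emits a site-only
    VCF.
    """
    if not isinstance(store, VczStore):
        store = VczStore(store)
    sample_idx = _resolve_samples(store, samples, exclude_samples)
    if drop_genotypes:
        sample_idx = []
    has_gt = "call_genotype" in store and not drop_genotypes
    info_fields = _info_field_arrays(store)
    format_fields = [] if drop_genotypes else _format_field_arrays(store)

    header = store.header_text.rstrip("\n")
    declared = header
    lines = header.split("\n") if header else ["##fileformat=VCFv4.2"]
    lines += _synthesised_header_lines(store, info_fields, format_fields, declared)
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if sample_idx:
        cols += ["FORMAT"] + [store.samples[i] for i in sample_idx]
    yield from lines
    yield "\t".join(cols)

    include_node = expr_mod.parse_expression(include) if include else None

    for start, stop, mask in _selected_ranges(store, regions, batch):
        yield from _render_records(
            store, start, stop, mask, sample_idx, has_gt,
            info_fields, format_fields, include_node,
        )


def _selected_ranges(store, regions, batch):
    """Yield (start, stop, mask-or-None) record ranges to render."""
    n = store.num_variants
    if regions is None:
        for start in range(0, n, batch):
            yield start, min(start + batch, n), None
        return
    queries = parse_regions(regions)
    chunk_size = store.variant_chunk_size
    for ci, mask in resolve_regions(store, queries):
        start = ci * chunk_size
        yield start, min(start + chunk_size, n), mask


def _load_chunk(store, names, start, stop):
    return {name: store.array(name)[start:stop] for name in names}


def _render_records(store, start, stop, mask, sample_idx, has_gt,
                    info_fields, format_fields, include_node):
    n = stop - start
    names = [
        "variant_contig", "variant_position", "variant_id",
        "variant_allele", "variant_quality", "variant_filter",
    ]
    names += [name for _, name in info_fields]
    if has_gt:
        names += ["call_genotype", "call_genotype_phased"]
    names += [name for _, name in format_fields]
    data = _load_chunk(store, names, start, stop)

    keep = np.ones(n, dtype=bool) if mask is None else mask.copy()
    if include_node is not None:
        def resolve(field):
            kind, key = field
            name = ("call_" if kind == "FORMAT" else "variant_") + key
            if name not in data:
                data[name] = store.array(name)[start:stop]
            arr = data[name]
            if kind == "FORMAT" and arr.ndim >= 2:
                arr = arr[:, sample_idx]
            return arr

        keep &= expr_mod.evaluate(include_node, resolve)

    contigs = store.contig_ids
    filters = store.filters
    for i in np.nonzero(keep)[0]:
        yield _render_one(
            data, int(i), contigs, filters, sample_idx, has_gt,
            info_fields, format_fields,
        )


def _render_one(data, i, contigs, filters, sample_idx, has_gt,
                info_fields, format_fields):
    chrom = contigs[int(data["variant_contig"][i])]
    pos = str(int(data["variant_position"][i]))
    vid = _render_scalar(data["variant_id"][i], "O")
    alleles = _strip_fill(list(data["variant_allele"][i]), "O")
    ref = alleles[0] if alleles else "N"
    alt = ",".join(alleles[1:]) if len(alleles) > 1 else STR_MISSING
    qual = _render_float(data["variant_quality"][i])
    frow = data["variant_filter"][i]
    active = [filters[j] for j in np.nonzero(frow)[0]]
    filt = ";".join(active) if active else STR_MISSING

    info_parts = []
    for key, name in info_fields:
        arr = data[name]
        kind = arr.dtype.kind
        if kind == "b":
            if arr[i]:
                info_parts.append(key)
            continue
        if arr.ndim == 1:
            r = _render_scalar(arr[i], "O" if kind == "O" else kind)
            if r != STR_MISSING:
                info_parts.append(f"{key}={r}")
        else:
            r = _render_vector(list(arr[i]), "O" if kind == "O" else kind)
            if r is not None:
                info_parts.append(f"{key}={r}")
    info = ";".join(info_parts) if info_parts else STR_MISSING

    cols = [chrom, pos, vid, ref, alt, qual, filt, info]
    if not sample_idx:
        return "\t".join(cols)

    keys = []
    renders = []
    if has_gt:
        keys.append("GT")
        gt = data["call_genotype"][i]
        ph = data["call_genotype_phased"][i]
        renders.append([_render_gt(gt[s], ph[s]) for s in sample_idx])
    for key, name in format_fields:
        arr = data[name]
        kind = arr.dtype.kind
        if arr.ndim == 2:
            vals = [_render_scalar(arr[i, s], "O" if kind == "O" else kind)
                    for s in sample_idx]
        else:
            vals = []
            for s in sample_idx:
                r = _render_vector(list(arr[i, s]), "O" if kind == "O" else kind)
                vals.append(r if r is not None else STR_MISSING)
        if all(v == STR_MISSING for v in vals):
            continue  # field absent for this record
        keys.append(key)
        renders.append(vals)
    if not keys:
        return "\t".join(cols)
    cols.append(":".join(keys))
    for si in range(len(sample_idx)):
        cols.append(":".join(r[si] for r in renders))
    return "\t".join(cols)


# ---------------------------------------------------------------------------
# query (format-string extraction)
# ---------------------------------------------------------------------------

_TOKEN_SPLIT = re.compile(
    r"(%CHROM|%POS0?|%ID|%REF|%ALT|%QUAL|%FILTER|%INFO/[A-Za-z_][A-Za-z0-9_.]*"
    r"|\\n|\\t)"
)

_FIXED_TOKEN_ARRAYS = {
    "%CHROM": ["variant_contig"],
    "%POS": ["variant_position"],
    "%ID": ["variant_id"],
    "%REF": ["variant_allele"],
    "%ALT": ["variant_allele"],
    "%QUAL": ["variant_quality"],
    "%FILTER": ["variant_filter"],
}


def parse_template(template: str):
    """Split a bcftools-style format template into tokens."""
    tokens = []
    for part in _TOKEN_SPLIT.split(template):
        if not part:
            continue
        if part == "\\n":
            tokens.append(("literal", "\n"))
        elif part == "\\t":
            tokens.append(("literal", "\t"))
        elif part.startswith("%"):
            tokens.append(("field", part))
        else:
            if "%" in part:
                bad = part[part.index("%"):]
                raise QueryError(f"unknown format token {bad.split()[0]!r}")
            tokens.append(("literal", part))
    return tokens


def query(store, template: str, regions=None, batch: int = 1000):
    """Render a format template once per selected record (bcftools query).

    Only the arrays named in the template are read from variant-chunk
    storage (plus the region index machinery when ``regions`` is given).
    """
    if not isinstance(store, VczStore):
        store = VczStore(store)
    tokens = parse_template(template)
    needed = set()
    for kind, tok in tokens:
        if kind != "field":
            continue
        if tok.startswith("%INFO/"):
            name = "variant_" + tok[len("%INFO/"):]
            if name not in store:
                raise QueryError(f"unknown token {tok!r}: no array {name!r}")
            needed.add(name)
        elif tok in _FIXED_TOKEN_ARRAYS:
            needed.update(_FIXED_TOKEN_ARRAYS[tok])
        else:
            raise QueryError(f"unknown format token {tok!r}")

    contigs = store.contig_ids
    filters = store.filters
    out = []
    for start, stop, mask in _selected_ranges(store, regions, batch):
        data = {name: store.array(name)[start:stop] for name in needed}
        n = stop - start
        rows = np.nonzero(mask)[0] if mask is not None else range(n)
        for i in rows:
            parts = []
            for kind, tok in tokens:
                if kind == "literal":
                    parts.append(tok)
                    continue
                parts.append(_render_token(tok, data, int(i), contigs, filters))
            out.append("".join(parts))
    return "".join(out)


def _render_token(tok, data, i, contigs, filters):
    if tok == "%CHROM":
        return contigs[int(data["variant_contig"][i])]
    if tok == "%POS":
        return str(int(data["variant_position"][i]))
    if tok == "%ID":
        return _render_scalar(data["variant_id"][i], "O")
    if tok == "%REF":
        return str(data["variant_allele"][i, 0])
    if tok == "%ALT":
        alts = _strip_fill(list(data["variant_allele"][i])[1:], "O")
        return ",".join(alts) if alts else STR_MISSING
    if tok == "%QUAL":
        return _render_float(data["variant_quality"][i])
    if tok == "%FILTER":
        active = [filters[j] for j in np.nonzero(data["variant_filter"][i])[0]]
        return ";".join(active) if active else STR_MISSING
    # %INFO/KEY
    name = "variant_" + tok[len("%INFO/"):]
    arr = data[name]
    kind = arr.dtype.kind
    if kind == "b":
        return "1" if arr[i] else STR_MISSING
    if arr.ndim == 1:
        return _render_scalar(arr[i], "O" if kind == "O" else kind)
    r = _render_vector(list(arr[i]), "O" if kind == "O" else kind)
    return r if r is not None else STR_MISSING


def evaluate_include_expression(store, expression: str, start=0, stop=None,
                                per_call: bool = False):
    """Evaluate a filter expression over records [start, stop).

    Returns a per-record boolean mask (any-sample semantics for FORMAT
    terms), or a (records, samples) per-call mask with ``per_call``.
    """
    if not isinstance(store, VczStore):
        store = VczStore(store)
    if stop is None:
        stop = store.num_variants
    node = expr_mod.parse_expression(expression)

    def resolve(field):
        kind, key = field
        name = ("call_" if kind == "FORMAT" else "variant_") + key
        return store.array(name)[start:stop]

    if per_call:
        return expr_mod.evaluate_per_call(node, resolve)
    return expr_mod.evaluate(node, resolve)
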
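"""Shared oracles and comparators for the test suite.

The round-trip comparator parses VCF text with pysam and normalises both
sides to the semantic content of each record, collapsing the two
documented non-invertible representations: a field that is present but
entirely missing equals an absent field, and float values compare at
32-bit precision.
"""

import numpy as np
import pysam

from vczarr.model import INT_FILL, INT_MISSING, is_float_fill, is_float_missing


def _norm_value(v):
    if isinstance(v, float):
        return np.float32(v)
    if isinstance(v, tuple):
        out = tuple(None if x is None else _norm_value(x) for x in v)
        if all(x is None for x in out):
            return None
        return out
    return v


def norm_records(path_or_lines):
    """Parse a VCF into a list of normalised record tuples."""
    if isinstance(path_or_lines, (list, tuple)):
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".vcf", delete=False) as f:
            f.write("\n".join(path_or_lines) + "\n")
            path = f.name
    else:
        path = str(path_or_lines)
    records = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            info = {}
            for k, v in rec.info.items():
                v = _norm_value(v)
                if v is not None and v is not False:
                    info[k] = v
            samples = []
            for s in rec.samples.values():
                call = {}
                for k, v in s.items():
                    v = _norm_value(v)
                    if k == "GT":
                        if v is not None and any(a is not None for a in v):
                            call["GT"] = v
                            call["phased"] = s.phased
                    elif v is not None:
                        call[k] = v
                samples.append(call)
            records.append(
                (
                    rec.chrom,
                    rec.pos,
                    rec.id,
                    tuple(rec.alleles),
                    None if rec.qual is None else np.float32(rec.qual),
                    tuple(rec.filter),
                    info,
                    samples,
                )
            )
    return records


def assert_same_records(a, b):
    assert len(a) == len(b), f"record counts differ: {len(a)} vs {len(b)}"
    for i, (ra, rb) in enumerate(zip(a, b)):
        assert ra == rb, f"record {i} differs:\n  {ra}\n  {rb}"


def genuine_int(values):
    """Mask of genuine (non-sentinel) entries in an integer array."""
    v = np.asarray(values)
    return v > INT_MISSING


def genuine_float(values):
    v = np.asarray(values, dtype=np.float32)
    return ~(is_float_missing(v) | is_float_fill(v) | np.isnan(v))


# ---------------------------------------------------------------------------
# Brute-force af-dist oracle (direct loops, no chunking)
# ---------------------------------------------------------------------------


def brute_af_dist(genotypes, n_bins=10):
    """Per-call af-dist computed with plain Python loops."""
    g = np.asarray(genotypes)
    counts = np.zeros(n_bins, dtype=np.int64)
    excluded = 0
    for i in range(g.shape[0]):
        called = [a for s in range(g.shape[1]) for a in g[i, s] if a >= 0]
        q = (sum(1 for a in called if a > 0) / len(called)) if called else 0.0
        for s in range(g.shape[1]):
            call = list(g[i, s])
            if len(call) < 2 or call[0] < 0 or call[1] < 0 or any(
                a != INT_FILL for a in call[2:]
            ):
                excluded += 1
                continue
            n_alt = sum(1 for a in call[:2] if a > 0)
            if n_alt == 0:
                p = (1 - q) ** 2
            elif n_alt == 1:
                p = 2 * q * (1 - q)
            else:
                p = q**2
            counts[min(int(p * n_bins), n_bins - 1)] += 1
    return counts, excluded


def brute_allele_counts(genotypes, n_alleles):
    g = np.asarray(genotypes)
    out = np.zeros((g.shape[0], n_alleles), dtype=np.int64)
    for i in range(g.shape[0]):
        for s in range(g.shape[1]):
            for a in g[i, s]:
                if a >= 0:
                    out[i, int(a)] += 1
    return out


def brute_region_scan(contig, pos, ends, cid, start, end):
    """Indexes of records overlapping [start, end] on contig ``cid``."""
    return [
        i
        for i in range(len(pos))
        if contig[i] == cid and pos[i] <= end and ends[i] >= start
    ]
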
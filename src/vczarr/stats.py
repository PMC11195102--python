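"""Chunkwise statistics kernels over the genotype matrix.

These kernels process the call_genotype array one variant chunk at a time,
so memory stays bounded and the work parallelises naturally over chunks.
All results are exactly invariant to the chunk traversal order and chunk
size.

The af-dist diagnostic tabulates observed genotype calls against their
Hardy-Weinberg expectations: for each variant the alternate allele
frequency q is computed from the genotypes themselves, every complete
diploid call is collapsed to hom-ref / het / hom-alt (any non-reference
allele counts as alternate), assigned its Hardy-Weinberg probability
((1-q)^2, 2q(1-q) or q^2) and counted into equal-width probability bins on
[0, 1].  Computing q from the genotypes rather than INFO/AF keeps the
kernel self-contained (pipelines that rely on INFO/AF must recompute it
after subsetting anyway).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import zarr

from .query import VczStore, evaluate_include_expression


class StatsError(ValueError):
    pass


def allele_counts(genotypes: np.ndarray, n_alleles: int) -> np.ndarray:
    """Per-variant counts of each allele index over non-negative entries.

    ``genotypes`` is a (variants, samples, ploidy) chunk; missing (-1) and
    fill (-2) entries are excluded.  Returns (variants, n_alleles) counts.
    """
    g = np.asarray(genotypes)
    n = g.shape[0]
    counts = np.zeros((n, n_alleles), dtype=np.int64)
    flat = g.reshape(n, -1)
    for a in range(n_alleles):
        counts[:, a] = (flat == a).sum(axis=1)
    return counts


def store_allele_counts(store) -> np.ndarray:
    """Allele counts at each site, accumulated chunk by chunk."""
    if not isinstance(store, VczStore):
        store = VczStore(store)
    if "call_genotype" not in store:
        raise StatsError("store has no call_genotype array")
    gt = store.array("call_genotype")
    n_alleles = store.array("variant_allele").shape[1]
    out = np.zeros((gt.shape[0], n_alleles), dtype=np.int64)
    step = gt.chunks[0]
    for start in range(0, gt.shape[0], step):
        stop = min(start + step, gt.shape[0])
        out[start:stop] = allele_counts(gt[start:stop], n_alleles)
    return out


@dataclasses.dataclass
class AfDistTable:
    """Binned counts of Hardy-Weinberg genotype probabilities."""

    bin_edges: np.ndarray  # n_bins + 1 equally spaced values on [0, 1]
    observed_counts: np.ndarray  # per-bin count of classified calls
    n_excluded: int = 0  # incomplete / non-diploid calls left unclassified

    @property
    def n_bins(self) -> int:
        return len(self.observed_counts)

    @property
    def total_classified(self) -> int:
        return int(self.observed_counts.sum())

    @property
    def expected_uniform(self) -> np.ndarray:
        """Reference mass if probabilities were uniform on [0, 1]."""
        return np.full(self.n_bins, self.total_classified / self.n_bins)

    def __add__(self, other: "AfDistTable") -> "AfDistTable":
        if not np.array_equal(self.bin_edges, other.bin_edges):
            raise StatsError("cannot add tables with different bin edges")
        return AfDistTable(
            self.bin_edges,
            self.observed_counts + other.observed_counts,
            self.n_excluded + other.n_excluded,
        )

    def to_rows(self):
        for b in range(self.n_bins):
            yield (
                float(self.bin_edges[b]),
                float(self.bin_edges[b + 1]),
                int(self.observed_counts[b]),
            )


def classify_genotype_probabilities(
    genotypes: np.ndarray, alt_freq: np.ndarray, n_bins: int = 10
):
    """Bin the Hardy-Weinberg probability of every complete diploid call.

    Each call with two non-missing allele slots is collapsed to hom-ref,
    het or hom-alt (any allele index > 0 is "alt"); its probability under
    Hardy-Weinberg equilibrium at frequency q is (1-q)^2, 2q(1-q) or q^2,
    and falls in bin floor(p * n_bins), clamped so p = 1 lands in the last
    bin.  Returns (per-bin counts, number of excluded calls).
    """
    g = np.asarray(genotypes)
    if g.ndim != 3:
        raise StatsError("genotypes must be (variants, samples, ploidy)")
    q = np.asarray(alt_freq, dtype=np.float64)
    counts = np.zeros(n_bins, dtype=np.int64)
    ploidy = g.shape[2]
    if ploidy < 2:
        return counts, int(np.prod(g.shape[:2]))
    valid = (g[:, :, :2] >= 0).all(axis=2)
    if ploidy > 2:
        # slots beyond the second must all be fill for a diploid call
        valid &= (g[:, :, 2:] == -2).all(axis=2)
    n_alt = (g[:, :, :2] > 0).sum(axis=2)
    hom_ref = (1 - q[:, None]) ** 2
    het = 2 * q[:, None] * (1 - q[:, None])
    hom_alt = q[:, None] ** 2
    prob = np.where(n_alt == 0, hom_ref, np.where(n_alt == 1, het, hom_alt))
    bins = np.minimum((prob * n_bins).astype(np.int64), n_bins - 1)
    for b, c in zip(*np.unique(bins[valid], return_counts=True)):
        counts[b] = c
    n_excluded = int((~valid).sum())
    return counts, n_excluded


def alt_allele_frequency(genotypes: np.ndarray) -> np.ndarray:
    """Per-variant alternate allele frequency from the genotypes.

    q = (allele slots holding an index > 0) / (non-missing allele slots);
    variants with no called slots get q = 0.
    """
    g = np.asarray(genotypes)
    flat = g.reshape(g.shape[0], -1)
    called = (flat >= 0).sum(axis=1)
    alt = (flat > 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(called > 0, alt / np.maximum(called, 1), 0.0)
    return q


def af_dist(store, n_bins: int = 10) -> AfDistTable:
    """The af-dist diagnostic over a whole store, one chunk at a time."""
    if not isinstance(store, VczStore):
        store = VczStore(store)
    if "call_genotype" not in store:
        raise StatsError("store has no call_genotype array")
    gt = store.array("call_genotype")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    table = AfDistTable(edges, np.zeros(n_bins, dtype=np.int64), 0)
    step = gt.chunks[0]
    for start in range(0, gt.shape[0], step):
        chunk = gt[start:min(start + step, gt.shape[0])]
        q = alt_allele_frequency(chunk)
        counts, excluded = classify_genotype_probabilities(chunk, q, n_bins)
        table = table + AfDistTable(edges, counts, excluded)
    return table


def qc_variant_mask(store_path, expression: str, name: str) -> np.ndarray:
    """Evaluate a filter expression and persist it as a boolean array.

    The mask is written as a new array named ``name`` in the store root;
    no other array is modified.  Requires a directory store (Zip archives
    are read-only).
    """
    store = VczStore(store_path)
    mask = evaluate_include_expression(store, expression)
    root = zarr.open_group(str(store_path), mode="a", zarr_format=2)
    chunk = store.variant_chunk_size
    arr = root.create_array(
        name, shape=mask.shape, chunks=(min(chunk, max(1, len(mask))),),
        dtype="bool", overwrite=True,
    )
    arr[:] = mask
    arr.attrs["filter_expression"] = expression
    return mask
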
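"""Deterministic synthetic VCF generation for tests and examples.

Every capability of the converter is exercised with VCFs built by
:func:`generate_vcf`: multi-allelic sites, mixed ploidy, Number=A/R/G/. and
Flag fields, missing data at configurable rates, and bgzip + Tabix output
for partition-planning tests.  The generator makes no attempt at
population-genetic realism (it is not a coalescent simulator); it aims for
coverage of the VCF data model.  Alternate-allele frequencies are drawn
from a Beta(0.5, 0.5) spectrum so that both common and rare variants occur
and Hardy-Weinberg probability bins across [0, 1] are all populated.

:func:`toy_store` is the canonical 3-variant x 2-sample worked example with
hand-checkable expected array contents, used throughout the test suite.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Optional

import numpy as np
import pysam

from .model import INT_FILL, INT_MISSING

#: Field menu understood by the generator.
ALL_FIELDS = ("GT", "DP", "GQ", "AD", "PL", "AF", "AA", "DB", "CLV")


@dataclasses.dataclass
class FixtureConfig:
    """Parameters of one synthetic VCF; identical config+seed means
    byte-identical output."""

    n_variants: int = 20
    n_samples: int = 3
    ploidy: int = 2
    max_alleles: int = 2
    contigs: tuple = (("chr1", 100_000), ("chr2", 80_000))
    fields: tuple = ALL_FIELDS
    missing_rate: float = 0.1
    phased_rate: float = 0.3
    mixed_ploidy: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.ploidy < 1 or self.max_alleles < 2:
            raise ValueError("ploidy >= 1 and max_alleles >= 2 required")
        total = sum(length for _, length in self.contigs)
        if self.n_variants > total:
            raise ValueError("contigs too short for requested variant count")


_BASES = "ACGT"

_HEADER_LINES = {
    "DP": '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    "GQ": '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    "AD": '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    "PL": '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled likelihoods">',
    "AF": '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">',
    "AA": '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
    "DB": '##INFO=<ID=DB,Number=0,Type=Flag,Description="In a database">',
    "CLV": '##INFO=<ID=CLV,Number=.,Type=Integer,Description="Variable-length list">',
}


def _genotype_index(j: int, k: int) -> int:
    """VCF canonical index of the unordered diploid pair (j, k), j <= k."""
    return k * (k + 1) // 2 + j


def generate_vcf(
    config: FixtureConfig,
    path: Optional[str] = None,
    bgzip: bool = False,
    tabix: bool = False,
) -> str:
    """Render a sorted, well-formed VCF from ``config``; returns the text.

    If ``path`` is given the text is written there; with ``bgzip=True`` a
    bgzip-compressed copy ``path + '.gz'`` is written too, and with
    ``tabix=True`` a Tabix index for it.
    """
    rng = np.random.RandomState(config.seed)
    fields = set(config.fields)
    samples = [f"S{i}" for i in range(config.n_samples)]

    lines = ["##fileformat=VCFv4.2", "##source=vczarr-fixture"]
    for name, length in config.contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FILTER=<ID=PASS,Description="All filters passed">')
    lines.append('##FILTER=<ID=q10,Description="Quality below 10">')
    lines.append('##FILTER=<ID=lowdp,Description="Low depth">')
    for key in ("AF", "AA", "DB", "CLV", "GT", "DP", "GQ", "AD", "PL"):
        if key == "GT":
            if "GT" in fields:
                lines.append(
                    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
                )
        elif key in fields:
            lines.append(_HEADER_LINES[key])
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if fields & {"GT", "DP", "GQ", "AD", "PL"}:
        header_cols += ["FORMAT"] + samples
    lines.append("\t".join(header_cols))

    # Spread variants over contigs proportionally to length.
    total_len = sum(length for _, length in config.contigs)
    counts = [
        int(round(config.n_variants * length / total_len))
        for _, length in config.contigs
    ]
    while sum(counts) > config.n_variants:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < config.n_variants:
        counts[int(np.argmin(counts))] += 1

    vid = 0
    for (contig, length), n_here in zip(config.contigs, counts):
        if n_here == 0:
            continue
        positions = np.sort(
            rng.choice(np.arange(1, length + 1), size=n_here, replace=False)
        )
        for pos in positions:
            lines.append(
                _render_record(rng, config, fields, contig, int(pos), vid)
            )
            vid += 1

    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as f:
            f.write(text)
        if bgzip or tabix:
            pysam.tabix_compress(path, path + ".gz", force=True)
            if tabix:
                pysam.tabix_index(path + ".gz", preset="vcf", force=True)
    return text


def _render_record(rng, config, fields, contig, pos, vid):
    n_alleles = int(rng.randint(2, config.max_alleles + 1))
    ref = _BASES[rng.randint(4)]
    # Occasionally emit an indel-style REF so record ends vary.
    if rng.random_sample() < 0.15:
        ref = ref + "".join(_BASES[i] for i in rng.randint(0, 4, size=rng.randint(1, 4)))
    alts = []
    while len(alts) < n_alleles - 1:
        a = _BASES[rng.randint(4)]
        if a != ref[0] and a not in alts:
            alts.append(a)

    qual = "." if rng.random_sample() < 0.1 else f"{rng.random_sample() * 100:.1f}"
    r = rng.random_sample()
    if r < 0.5:
        filt = "PASS"
    elif r < 0.7:
        filt = "q10" if rng.random_sample() < 0.7 else "q10;lowdp"
    else:
        filt = "."
    rsid = f"rs{vid}" if rng.random_sample() < 0.5 else "."

    # Allele frequency spectrum shaped to exercise all af-dist bins.
    q = float(rng.beta(0.5, 0.5))

    info_parts = []
    if "AF" in fields and rng.random_sample() > config.missing_rate:
        afs = rng.random_sample(n_alleles - 1)
        afs = afs / max(1.0, afs.sum())
        info_parts.append("AF=" + ",".join(f"{a:.3g}" for a in afs))
    if "AA" in fields and rng.random_sample() > config.missing_rate:
        info_parts.append(f"AA={ref[0]}")
    if "DB" in fields and rng.random_sample() < 0.4:
        info_parts.append("DB")
    if "CLV" in fields and rng.random_sample() > config.missing_rate:
        k = rng.randint(1, 4)
        info_parts.append("CLV=" + ",".join(str(int(x)) for x in rng.randint(0, 50, k)))
    info = ";".join(info_parts) if info_parts else "."

    cols = [contig, str(pos), rsid, ref, ",".join(alts), qual, filt, info]

    fmt_keys = [k for k in ("GT", "DP", "GQ", "AD", "PL") if k in fields]
    if fmt_keys:
        cols.append(":".join(fmt_keys))
        for _ in range(config.n_samples):
            cols.append(
                _render_call(rng, config, fmt_keys, n_alleles, q)
            )
    return "\t".join(cols)


def _render_call(rng, config, fmt_keys, n_alleles, q):
    ploidy = config.ploidy
    if config.mixed_ploidy and ploidy > 1 and rng.random_sample() < 0.2:
        ploidy = int(rng.randint(1, config.ploidy))
    parts = []
    alleles = None
    for key in fmt_keys:
        if key == "GT":
            sep = "|" if rng.random_sample() < config.phased_rate else "/"
            if rng.random_sample() < config.missing_rate:
                parts.append(sep.join(["."] * ploidy))
            else:
                # Biased towards ref/first alt by the site frequency q.
                alleles = [
                    (1 if rng.random_sample() < q else 0)
                    if n_alleles == 2 or rng.random_sample() < 0.8
                    else int(rng.randint(0, n_alleles))
                    for _ in range(ploidy)
                ]
                parts.append(sep.join(str(a) for a in alleles))
        elif key == "DP":
            parts.append(
                "." if rng.random_sample() < config.missing_rate
                else str(int(rng.randint(0, 60)))
            )
        elif key == "GQ":
            parts.append(
                "." if rng.random_sample() < config.missing_rate
                else str(int(rng.randint(0, 100)))
            )
        elif key == "AD":
            if rng.random_sample() < config.missing_rate:
                parts.append(".")
            else:
                depths = rng.randint(0, 40, n_alleles)
                vals = [
                    "." if rng.random_sample() < config.missing_rate / 2 else str(int(d))
                    for d in depths
                ]
                parts.append(",".join(vals))
        elif key == "PL":
            if rng.random_sample() < config.missing_rate:
                parts.append(".")
            else:
                n_gt = _genotype_index(n_alleles - 1, n_alleles - 1) + 1
                pls = rng.randint(0, 200, n_gt)
                # Make the called genotype's likelihood 0 when we know it.
                if alleles is not None and len(alleles) == 2:
                    j, k = sorted(alleles)
                    pls[_genotype_index(j, k)] = 0
                parts.append(",".join(str(int(p)) for p in pls))
    return ":".join(parts)


# ---------------------------------------------------------------------------
# The canonical worked example
# ---------------------------------------------------------------------------

TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000>
##FILTER=<ID=PASS,Description="All filters passed">
##FILTER=<ID=q10,Description="Quality below 10">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled likelihoods">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tS0\tS1
""".replace("S0\tS1", "FORMAT\tS0\tS1") + """\
chr1\t100\trs1\tA\tT\t30\tPASS\tDP=20;AF=0.5\tGT:DP:AD:PL\t0|1:12:10,2:40,0,30\t1/1:8:0,8:90,10,0
chr1\t200\t.\tG\tA,C\t.\tq10\tDP=11\tGT:DP:AD:PL\t0/2:7:5,0,2:10,20,30,0,40,50\t./.:.:.:.
chr1\t300\trs3\tT\tG\t9.5\t.\tAF=0.25\tGT:DP:AD:PL\t1:9:1,8:50,0\t0/1:15:7,7:60,0,70
"""


def toy_store():
    """The 3-variant x 2-sample worked example and its expected arrays.

    Record 2 is multi-allelic (triallelic, so PL has six entries), sample 2
    at record 2 is fully missing, and sample 1 at record 3 is haploid, so
    the expected arrays exercise both the missing (-1) and fill (-2)
    sentinels.
    """
    m, f = INT_MISSING, INT_FILL
    expected = {
        "variant_position": np.array([100, 200, 300]),
        "variant_contig": np.array([0, 0, 0]),
        "variant_id": np.array(["rs1", ".", "rs3"], dtype=object),
        "variant_allele": np.array(
            [["A", "T", ""], ["G", "A", "C"], ["T", "G", ""]], dtype=object
        ),
        "variant_filter": np.array(
            [[True, False], [False, True], [False, False]]
        ),
        "variant_DP": np.array([20, 11, m]),
        "call_genotype": np.array(
            [[[0, 1], [1, 1]], [[0, 2], [m, m]], [[1, f], [0, 1]]], dtype=np.int8
        ),
        "call_genotype_phased": np.array(
            [[True, False], [False, False], [True, False]]
        ),
        "call_genotype_mask": np.array(
            [
                [[False, False], [False, False]],
                [[False, False], [True, True]],
                [[False, True], [False, False]],
            ]
        ),
        "call_DP": np.array([[12, 8], [7, m], [9, 15]]),
        "call_AD": np.array(
            [
                [[10, 2, f], [0, 8, f]],
                [[5, 0, 2], [m, f, f]],
                [[1, 8, f], [7, 7, f]],
            ]
        ),
        "call_PL": np.array(
            [
                [[40, 0, 30, f, f, f], [90, 10, 0, f, f, f]],
                [[10, 20, 30, 0, 40, 50], [m, f, f, f, f, f]],
                [[50, 0, f, f, f, f], [60, 0, 70, f, f, f]],
            ]
        ),
    }
    return TOY_VCF, expected


def write_fixture(
    config: FixtureConfig, directory, name: str = "fixture",
    bgzip: bool = False, tabix: bool = False,
) -> str:
    """Write a generated VCF under ``directory``; returns the .vcf path."""
    os.makedirs(str(directory), exist_ok=True)
    path = os.path.join(str(directory), name + ".vcf")
    generate_vcf(config, path=path, bgzip=bgzip, tabix=tabix)
    return path
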
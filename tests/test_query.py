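"""Tests for the read path: view round trips, regions, templates,
include expressions."""

import os

import numpy as np
import pytest

import vczarr
from vczarr.fixtures import FixtureConfig, generate_vcf
from vczarr.query import QueryError, VczStore, parse_region

from helpers import (
    assert_same_records,
    brute_region_scan,
    norm_records,
)


def _view_to_file(store, tmp_path, name="view.vcf", **kwargs):
    out = os.path.join(tmp_path, name)
    with open(out, "w") as f:
        for line in vczarr.view(store, **kwargs):
            f.write(line + "\n")
    return out


class TestViewRoundTrip:
    def test_toy_full_round_trip(self, toy_paths, tmp_path):
        out = _view_to_file(toy_paths["store"], tmp_path)
        assert_same_records(norm_records(toy_paths["vcf"]), norm_records(out))

    def test_medium_full_round_trip(self, medium_paths, tmp_path):
        out = _view_to_file(medium_paths["store"], tmp_path)
        assert_same_records(norm_records(medium_paths["vcf"]), norm_records(out))

    def test_site_only_view(self, toy_paths):
        lines = list(vczarr.view(toy_paths["store"], drop_genotypes=True))
        header = [l for l in lines if l.startswith("#CHROM")][0]
        assert header.split("\t") == [
            "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"
        ]
        body = [l for l in lines if not l.startswith("#")]
        assert len(body) == 3
        assert all(len(l.split("\t")) == 8 for l in body)

    def test_sample_subset(self, toy_paths, tmp_path):
        out = _view_to_file(toy_paths["store"], tmp_path, samples=["S1"])
        recs = norm_records(out)
        assert len(recs) == 3
        full = norm_records(toy_paths["vcf"])
        for r_sub, r_full in zip(recs, full):
            assert r_sub[7] == [r_full[7][1]]  # only S1's calls

    def test_sample_exclusion(self, toy_paths):
        lines = list(vczarr.view(toy_paths["store"], samples="^S0"))
        header = [l for l in lines if l.startswith("#CHROM")][0]
        assert header.split("\t")[-1] == "S1" and "S0" not in header.split("\t")

    def test_unknown_sample_rejected(self, toy_paths):
        with pytest.raises(QueryError, match="NOPE"):
            list(vczarr.view(toy_paths["store"], samples=["NOPE"]))

    def test_view_with_region_equals_linear_filter(self, medium_paths, tmp_path):
        store = VczStore(medium_paths["store"])
        pos = store.array("variant_position")[:]
        lo, hi = int(np.percentile(pos, 25)), int(np.percentile(pos, 75))
        region = f"chr1:{lo}-{hi}"
        regioned = [
            l for l in vczarr.view(medium_paths["store"], regions=region)
            if not l.startswith("#")
        ]
        ends = store.record_ends(0, len(pos))
        contig = store.array("variant_contig")[:]
        keep = set(brute_region_scan(contig, pos, ends, 0, lo, hi))
        full = [
            l for l in vczarr.view(medium_paths["store"])
            if not l.startswith("#")
        ]
        expected = [l for i, l in enumerate(full) if i in keep]
        assert regioned == expected


class TestRegions:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("chr1", ("chr1", 1, None)),
            ("chr1:500", ("chr1", 500, 500)),
            ("chr1:500-", ("chr1", 500, None)),
            ("chr1:500-900", ("chr1", 500, 900)),
        ],
    )
    def test_parse_region_dialect(self, text, expected):
        q = parse_region(text)
        assert (q.contig, q.start, q.end) == expected

    def test_invalid_region_rejected(self):
        with pytest.raises(QueryError):
            parse_region("chr1:9-4")

    def test_unknown_contig_lists_known(self, toy_paths):
        store = VczStore(toy_paths["store"])
        with pytest.raises(QueryError, match="chr1"):
            vczarr.resolve_regions(store, [parse_region("chrX:1-10")])

    def test_single_chunk_mask(self, toy_paths):
        store = VczStore(toy_paths["store"])
        res = vczarr.resolve_regions(store, [parse_region("chr1:150-250")])
        assert len(res) == 1
        ci, mask = res[0]
        assert ci == 0
        assert mask.tolist() == [False, True, False]

    def test_empty_contig_region(self, medium_paths):
        store = VczStore(medium_paths["store"])
        # chr2 exists in the header; query far beyond any record
        res = vczarr.resolve_regions(
            store, [parse_region("chr2:79999-80000")]
        )
        total = sum(m.sum() for _, m in res)
        pos = store.array("variant_position")[:]
        contig = store.array("variant_contig")[:]
        ends = store.record_ends(0, len(pos))
        assert total == len(brute_region_scan(contig, pos, ends, 1, 79999, 80000))

    def test_region_results_independent_of_chunk_size(self, tmp_path):
        cfg = FixtureConfig(n_variants=50, n_samples=2, seed=13)
        vcf = os.path.join(tmp_path, "f.vcf")
        generate_vcf(cfg, path=vcf)
        icf = vczarr.explode(vcf, os.path.join(tmp_path, "f.icf"))
        results = []
        for chunk in (5, 50):
            store_path = os.path.join(tmp_path, f"s{chunk}.vcz")
            vczarr.encode(icf, store_path, variant_chunk=chunk)
            body = [
                l for l in vczarr.view(store_path, regions="chr1:20000-70000")
                if not l.startswith("#")
            ]
            results.append(body)
        assert results[0] == results[1]

    def test_superset_then_exact(self, medium_paths):
        """Candidate chunks are a superset; after masking the result equals
        a brute-force scan."""
        store = VczStore(medium_paths["store"])
        pos = store.array("variant_position")[:]
        contig = store.array("variant_contig")[:]
        ends = store.record_ends(0, len(pos))
        chunk = store.variant_chunk_size
        for q in ("chr1:1-30000", "chr2:1-80000", "chr1:55555"):
            r = parse_region(q)
            cid = store.contig_ids.index(r.contig)
            end = r.end if r.end is not None else 10**12
            brute = brute_region_scan(contig, pos, ends, cid, r.start, end)
            res = vczarr.resolve_regions(store, [r])
            got = sorted(ci * chunk + int(i) for ci, m in res
                         for i in np.nonzero(m)[0])
            assert got == brute
            candidate_chunks = {ci for ci, _ in res}
            assert candidate_chunks >= {i // chunk for i in brute}


class TestQueryTemplates:
    def test_pos_template(self, toy_paths):
        assert vczarr.query(toy_paths["store"], "%POS\n") == "100\n200\n300\n"

    def test_chrom_pos_composition(self, toy_paths):
        out = vczarr.query(toy_paths["store"], "%CHROM:%POS\n")
        assert out == "chr1:100\nchr1:200\nchr1:300\n"

    def test_info_missing_renders_dot(self, toy_paths):
        out = vczarr.query(toy_paths["store"], "%INFO/DP\n")
        assert out == "20\n11\n.\n"

    def test_id_ref_alt_qual_filter(self, toy_paths):
        out = vczarr.query(
            toy_paths["store"], "%ID\t%REF\t%ALT\t%QUAL\t%FILTER\n"
        )
        lines = out.strip().split("\n")
        assert lines[0] == "rs1\tA\tT\t30\tPASS"
        assert lines[1] == ".\tG\tA,C\t.\tq10"
        assert lines[2] == "rs3\tT\tG\t9.5\t."

    def test_unknown_token_rejected(self, toy_paths):
        with pytest.raises(QueryError, match="token"):
            vczarr.query(toy_paths["store"], "%BOGUS\n")

    def test_query_touches_only_referenced_arrays(self, toy_paths):
        store = VczStore(toy_paths["store"])
        vczarr.query(store, "%POS\n")
        assert store.accessed == {"variant_position"}

    def test_query_with_region(self, medium_paths):
        store = VczStore(medium_paths["store"])
        out = vczarr.query(store, "%POS\n", regions="chr1")
        pos = store.array("variant_position")[:]
        contig = store.array("variant_contig")[:]
        expected = "".join(f"{p}\n" for p, c in zip(pos, contig) if c == 0)
        assert out == expected


class TestIncludeExpressions:
    def test_dp_gq_conjunction_matches_brute_force(self, medium_paths):
        store = VczStore(medium_paths["store"])
        mask = vczarr.evaluate_include_expression(
            store, "FORMAT/DP>10 & FORMAT/GQ>20"
        )
        dp = store.array("call_DP")[:]
        gq = store.array("call_GQ")[:]
        brute = np.zeros(dp.shape[0], dtype=bool)
        for i in range(dp.shape[0]):
            for s in range(dp.shape[1]):
                if dp[i, s] > 10 and dp[i, s] > -1 and gq[i, s] > 20 \
                        and gq[i, s] > -1:
                    brute[i] = True
        assert np.array_equal(mask, brute)

    def test_missing_compares_false(self, toy_paths):
        # INFO/AF missing at record 2
        mask = vczarr.evaluate_include_expression(
            toy_paths["store"], "INFO/AF>0"
        )
        assert mask.tolist() == [True, False, True]

    def test_tautology_on_non_missing_data(self, toy_paths):
        mask = vczarr.evaluate_include_expression(
            toy_paths["store"], "INFO/DP>-1 | INFO/DP<=-1"
        )
        # records 1 and 2 have DP; record 3's DP is missing (compares false)
        assert mask.tolist() == [True, True, False]

    def test_parentheses_and_or(self, toy_paths):
        mask = vczarr.evaluate_include_expression(
            toy_paths["store"], "(INFO/DP>15 | INFO/DP<12) & FORMAT/DP>5"
        )
        assert mask.tolist() == [True, True, False]

    def test_reversed_comparison(self, toy_paths):
        a = vczarr.evaluate_include_expression(toy_paths["store"], "INFO/DP>15")
        b = vczarr.evaluate_include_expression(toy_paths["store"], "15<INFO/DP")
        assert a.tolist() == b.tolist()

    def test_per_call_mask(self, toy_paths):
        mask = vczarr.evaluate_include_expression(
            toy_paths["store"], "FORMAT/DP>8", per_call=True
        )
        assert mask.tolist() == [[True, False], [False, False], [True, True]]

    def test_syntax_error_reports_position(self, toy_paths):
        with pytest.raises(Exception, match="position"):
            vczarr.evaluate_include_expression(toy_paths["store"], "INFO/DP >>")

    def test_view_include_filters_records(self, medium_paths):
        expr = "FORMAT/DP>10 & FORMAT/GQ>20"
        body = [
            l for l in vczarr.view(medium_paths["store"], include=expr)
            if not l.startswith("#")
        ]
        mask = vczarr.evaluate_include_expression(medium_paths["store"], expr)
        assert len(body) == int(mask.sum())


class TestBcftoolsParity:
    def test_query_pos_matches_bcftools(self, medium_paths):
        """Independent oracle: bcftools query on the source VCF."""
        import subprocess

        ref = subprocess.run(
            ["bcftools", "query", "-f", "%CHROM\\t%POS\\n",
             medium_paths["vcf"]],
            capture_output=True, text=True, check=True,
        ).stdout
        ours = vczarr.query(medium_paths["store"], "%CHROM\t%POS\n")
        assert ours == ref

    def test_view_parses_with_bcftools(self, medium_paths, tmp_path):
        """Reconstructed VCF text is accepted by bcftools and carries the
        same number of records."""
        import subprocess

        out = _view_to_file(medium_paths["store"], tmp_path, "bt.vcf")
        r = subprocess.run(
            ["bcftools", "view", "-H", out], capture_output=True, text=True,
            check=True,
        )
        assert len(r.stdout.strip().split("\n")) == 60


class TestManyConfigsRoundTrip:
    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(max_alleles=2),
            dict(max_alleles=4, mixed_ploidy=True, missing_rate=0.25),
            dict(fields=("GT", "PL", "CLV", "DB"), max_alleles=3),
        ],
    )
    def test_varied_configs(self, tmp_path, seed, kwargs):
        cfg = FixtureConfig(n_variants=15, n_samples=3, seed=seed, **kwargs)
        vcf = os.path.join(tmp_path, "f.vcf")
        generate_vcf(cfg, path=vcf)
        icf = vczarr.explode(vcf, os.path.join(tmp_path, "f.icf"))
        store = os.path.join(tmp_path, "f.vcz")
        vczarr.encode(icf, store, variant_chunk=7)
        out = _view_to_file(store, tmp_path)
        assert_same_records(norm_records(vcf), norm_records(out))
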
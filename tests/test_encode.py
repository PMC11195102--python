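"""Tests for the encode phase: buffers, sentinels, local alleles, codecs,
precision filters and the region index."""

import itertools
import os

import numcodecs
import numpy as np
import pytest

import vczarr
from vczarr.encode import (
    EncodeError,
    encode_field,
    encode_finalise,
    encode_init,
    encode_partition,
    encode_partition_states,
)
from vczarr.fixtures import FixtureConfig, generate_vcf, toy_store
from vczarr.model import (
    FLOAT_FILL_BITS,
    FLOAT_MISSING_BITS,
    INT_FILL,
    INT_MISSING,
    float_bits,
)



class TestEncodeGenotypes:
    def test_unphased_diploid(self):
        g, ph, mask = vczarr.encode_genotypes([((0, 1), False)], 2, 2)
        assert g.tolist() == [[0, 1]]
        assert ph.tolist() == [False]
        assert mask.tolist() == [[False, False]]

    def test_missing_call(self):
        g, ph, mask = vczarr.encode_genotypes([((None, None), False)], 2, 2)
        assert g.tolist() == [[INT_MISSING, INT_MISSING]]
        assert mask.tolist() == [[True, True]]

    def test_haploid_padded_with_fill(self):
        g, _, mask = vczarr.encode_genotypes([((1,), True)], 2, 2)
        assert g.tolist() == [[1, INT_FILL]]
        assert mask.tolist() == [[False, True]]

    def test_phase_flag(self):
        _, ph, _ = vczarr.encode_genotypes([((0, 1), True), ((0, 0), False)], 2, 2)
        assert ph.tolist() == [True, False]

    def test_allele_out_of_range(self):
        with pytest.raises(EncodeError, match="allele index"):
            vczarr.encode_genotypes([((5,), False)], 2, 2)


class TestLocalAlleles:
    @pytest.mark.parametrize(
        "genotype,expected",
        [([0, 2], [0, 2]), ([0, 0], [0, INT_FILL]), ([2, 0], [0, 2]),
         ([INT_MISSING, INT_MISSING], [INT_FILL, INT_FILL]),
         ([1, INT_FILL], [1, INT_FILL])],
    )
    def test_compute_local_alleles(self, genotype, expected):
        out = vczarr.compute_local_alleles(np.array(genotype), 2)
        assert out.tolist() == expected

    def test_localize_R(self):
        la = np.array([0, 2])
        assert vczarr.localize_R_field([10, 0, 5], la, -1, -2) == [10, 5]
        la = np.array([0, INT_FILL])
        assert vczarr.localize_R_field([7], la, -1, -2) == [7, -2]

    @pytest.mark.parametrize(
        "pl,la,expected",
        [
            ([0, 10, 20, 30, 40, 50], [0, 2], [0, 30, 50]),
            ([0, 10, 20, 30, 40, 50], [0, 1], [0, 10, 20]),
            # la=[1,fill]: local pair (1,1) maps to global index 2
            ([0, 10, 20], [1, INT_FILL], [20, INT_FILL, INT_FILL]),
        ],
    )
    def test_localize_G(self, pl, la, expected):
        out = vczarr.localize_G_field(list(pl), np.array(la), -1, INT_FILL)
        assert out == expected

    def test_localize_G_matches_index_formula_oracle(self):
        """Enumerate all diploid pairs over 4 alleles and check the
        canonical ordering k(k+1)/2 + j against the localisation."""
        n = 4
        pl = list(range(n * (n + 1) // 2))
        for a, b in itertools.combinations_with_replacement(range(n), 2):
            la = np.array(sorted({a, b}) + [INT_FILL] * (2 - len({a, b})))
            out = vczarr.localize_G_field(pl, la[:2], -1, INT_FILL)
            j, k = min(a, b), max(a, b)
            assert k * (k + 1) // 2 + j in out

    def test_localize_G_rejects_non_diploid(self):
        with pytest.raises(EncodeError):
            vczarr.localize_G_field([0], np.array([0, 1, 2]), -1, -2)

    def test_truncated_source_treated_as_missing(self):
        out = vczarr.localize_G_field([0, 10], np.array([0, 2]), -1, -2)
        assert out == [0, -1, -1]  # indexes 3 and 5 beyond the list


class TestLocalAlleleStore:
    def test_global_fields_replaced(self, convert):
        cfg = FixtureConfig(n_variants=20, n_samples=3, max_alleles=4, seed=21)
        _, _, store = convert(cfg, local_alleles=True)
        root = vczarr.open_store(store)
        names = set(root.array_keys())
        assert {"call_LA", "call_LAD", "call_LPL"} <= names
        assert "call_AD" not in names and "call_PL" not in names

    def test_losslessness_when_alleles_covered(self, convert):
        """Reconstructing AD/PL entries referenced by the genotype from
        LAD/LPL is exact (the covered-alleles condition holds by
        construction: LA is derived from the genotype)."""
        cfg = FixtureConfig(n_variants=30, n_samples=4, max_alleles=4,
                            missing_rate=0.1, seed=22)
        _, icf, la_path = convert(cfg, local_alleles=True)
        g_path = la_path + ".global"
        vczarr.encode(icf, g_path)
        g = vczarr.open_store(g_path)
        l = vczarr.open_store(la_path)
        gt = g["call_genotype"][:]
        ad, pl = g["call_AD"][:], g["call_PL"][:]
        la, lad, lpl = l["call_LA"][:], l["call_LAD"][:], l["call_LPL"][:]
        for i in range(gt.shape[0]):
            for s in range(gt.shape[1]):
                for j, a in enumerate(la[i, s]):
                    if a < 0 or lad[i, s, j] < 0:
                        continue
                    assert ad[i, s, a] == lad[i, s, j]
                # reconstruct PL for local pairs
                pos = 0
                for b in range(2):
                    for a_ in range(b + 1):
                        ga, gb = la[i, s, a_], la[i, s, b]
                        if ga >= 0 and gb >= 0 and lpl[i, s, pos] >= 0:
                            j_, k_ = min(ga, gb), max(ga, gb)
                            assert pl[i, s, k_ * (k_ + 1) // 2 + j_] == \
                                lpl[i, s, pos]
                        pos += 1


class TestPrecisionFilters:
    def test_quantize_decimal_rounding(self):
        out = vczarr.apply_precision_filter(
            np.array([0.1234567], dtype=np.float32), ("quantize", 5)
        )
        assert abs(out[0] - 0.12346) < 1e-6

    def test_bit_round_exact_value_unchanged(self):
        out = vczarr.apply_precision_filter(
            np.array([1.0], dtype=np.float32), ("bit_round", 5)
        )
        assert out[0] == 1.0

    def test_bit_round_error_bound(self):
        """|v - out| <= 2^(e - b - 1) with e the binary exponent of v."""
        rng = np.random.RandomState(0)
        v = (rng.random_sample(1000).astype(np.float32) * 200 - 100).astype(
            np.float32
        )
        v = v[v != 0]
        for b in (2, 5, 10):
            out = vczarr.apply_precision_filter(v, ("bit_round", b))
            e = np.floor(np.log2(np.abs(v)))
            assert np.all(np.abs(v - out) <= 2.0 ** (e - b - 1) + 1e-30)

    def test_matches_numcodecs_bitround(self):
        """Independent oracle: numcodecs' BitRound on sentinel-free data."""
        rng = np.random.RandomState(1)
        v = rng.random_sample(500).astype(np.float32)
        for b in (3, 7):
            ours = vczarr.apply_precision_filter(v, ("bit_round", b))
            ref = numcodecs.BitRound(keepbits=b).decode(
                numcodecs.BitRound(keepbits=b).encode(v.copy())
            )
            assert np.array_equal(ours, ref)

    def test_quantize_matches_numcodecs_at_digit_level(self):
        # numcodecs' Quantize keeps >= d decimal digits via binary scaling,
        # ours rounds decimally: both must agree to within half an ulp of
        # the d-th digit.
        rng = np.random.RandomState(2)
        v = rng.random_sample(500).astype(np.float32)
        ours = vczarr.apply_precision_filter(v, ("quantize", 4))
        ref = numcodecs.Quantize(digits=4, dtype="f4").encode(v.copy())
        assert np.allclose(ours, ref, atol=1.01e-4)
        assert np.allclose(ours, v, atol=0.51e-4)
        assert np.allclose(ref, v, atol=0.51e-4)

    def test_nan_sentinels_pass_through_unchanged(self):
        from vczarr.model import FLOAT_FILL, FLOAT_MISSING

        v = np.array([FLOAT_MISSING, 0.123456, FLOAT_FILL], dtype=np.float32)
        for f in (("quantize", 2), ("bit_round", 3)):
            out = vczarr.apply_precision_filter(v, f)
            bits = float_bits(out)
            assert bits[0] == FLOAT_MISSING_BITS
            assert bits[2] == FLOAT_FILL_BITS

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            vczarr.apply_precision_filter(np.zeros(1, np.float32),
                                          ("quantize", -1))

    def test_filter_applied_during_encode(self, tmp_path):
        cfg = FixtureConfig(n_variants=10, n_samples=2, seed=30)
        vcf = os.path.join(tmp_path, "f.vcf")
        generate_vcf(cfg, path=vcf)
        icf = vczarr.explode(vcf, os.path.join(tmp_path, "f.icf"))
        schema = vczarr.schema_from_icf(icf)
        spec = schema.field("variant_AF")
        spec.codec_config.precision_filter = ("quantize", 2)
        store = os.path.join(tmp_path, "f.vcz")
        vczarr.encode(icf, store, schema=schema)
        af = vczarr.open_store(store)["variant_AF"][:]
        finite = af[np.isfinite(af)]
        assert np.allclose(finite, np.round(finite.astype(float), 2), atol=1e-6)


class TestEncodedArrays:
    def test_toy_worked_example(self, toy_paths):
        _, expected = toy_store()
        root = vczarr.open_store(toy_paths["store"])
        for name, exp in expected.items():
            got = root[name][:]
            if got.dtype == object:
                assert (got == exp).all(), name
            else:
                assert np.array_equal(got, exp), name

    def test_float_sentinels_bit_exact(self, toy_paths):
        root = vczarr.open_store(toy_paths["store"])
        qual = root["variant_quality"][:]
        # record 2 has QUAL "." -> missing NaN with payload 0x1
        assert float_bits(qual)[1] == FLOAT_MISSING_BITS
        af = root["variant_AF"][:]
        assert float_bits(af)[1, 0] == FLOAT_MISSING_BITS  # record 2 lacks AF

    def test_flag_and_string_fields(self, convert):
        cfg = FixtureConfig(n_variants=15, n_samples=2, seed=31)
        vcf, icf, store = convert(cfg)
        root = vczarr.open_store(store)
        assert root["variant_DB"].dtype == bool
        aa = root["variant_AA"][:]
        assert aa.dtype.kind in "OTU"  # variable-length string storage

    def test_chunk_size_invariance(self, tmp_path):
        """Encoding with different variant chunk sizes yields identical
        arrays element-wise."""
        cfg = FixtureConfig(n_variants=40, n_samples=3, max_alleles=3, seed=32)
        vcf = os.path.join(tmp_path, "f.vcf")
        generate_vcf(cfg, path=vcf)
        icf = vczarr.explode(vcf, os.path.join(tmp_path, "f.icf"))
        roots = []
        for chunk in (7, 100, 10_000):
            path = os.path.join(tmp_path, f"s{chunk}.vcz")
            vczarr.encode(icf, path, variant_chunk=chunk)
            roots.append(vczarr.open_store(path))
        names = set(roots[0].array_keys()) - {"region_index"}
        for name in names:
            a = roots[0][name][:]
            for r in roots[1:]:
                b = r[name][:]
                if a.dtype == object:
                    assert (a == b).all(), name
                elif a.dtype.kind == "f":
                    assert np.array_equal(float_bits(a), float_bits(b)), name
                else:
                    assert np.array_equal(a, b), name

    def test_icf_vcz_consistency(self, medium_paths):
        """Concatenated decompressed chunks equal the ICF stream."""
        icf = medium_paths["icf"]
        root = vczarr.open_store(medium_paths["store"])
        pos = root["variant_position"][:]
        assert pos.tolist() == icf.read_field_slice("POS", 0, icf.num_records)
        dp = root["call_DP"][:]
        raw = icf.read_field_slice("FORMAT/DP", 0, icf.num_records)
        for i, row in enumerate(raw):
            for s, v in enumerate(row):
                assert dp[i, s] == (INT_MISSING if v is None else v)

    def test_schema_defaults(self, medium_paths):
        """Narrowest dtypes, zstd everywhere, bit shuffle exactly on
        call_genotype and booleans, default chunks 10,000 x 1,000."""
        icf = medium_paths["icf"]
        schema = vczarr.schema_from_icf(icf)
        s = icf.metadata.summaries
        for spec in schema.fields:
            cc = spec.codec_config
            assert cc.codec == "zstd"
            expect_bit = spec.name == "call_genotype" or spec.dtype == "bool"
            assert cc.shuffle == ("bit" if expect_bit else "none"), spec.name
            if spec.dims[0] == "variants":
                assert spec.chunks[0] == min(10_000, spec.shape[0])
            if len(spec.dims) > 1 and spec.dims[1] == "samples":
                assert spec.chunks[1] == min(1_000, spec.shape[1])
            if spec.dtype.startswith("int") and spec.source_field in (
                "FORMAT/DP", "FORMAT/GQ", "INFO/CLV",
            ):
                summary = s[spec.source_field]
                assert spec.dtype == vczarr.select_integer_dtype(
                    int(summary.observed_min), int(summary.observed_max)
                )

    def test_value_count_exceeding_extent_rejected(self, toy_paths):
        icf = toy_paths["icf"]
        schema = vczarr.schema_from_icf(icf)
        spec = schema.field("call_AD")
        spec.shape[-1] = 2  # too small: record 2 has 3 AD values
        spec.chunks[-1] = 2
        with pytest.raises(EncodeError, match="exceed"):
            encode_field(icf, spec, 0, 3)


class TestRegionIndex:
    def test_single_chunk_single_contig(self):
        pos = np.arange(100, 301, 50)
        idx = vczarr.build_region_index(
            np.zeros(len(pos)), pos, pos, chunk_size=10
        )
        assert idx.tolist() == [[0, 0, 100, 300, len(pos)]]

    def test_chunk_spanning_contig_boundary(self):
        contig = np.array([0, 0, 1, 1])
        pos = np.array([10, 20, 5, 9])
        idx = vczarr.build_region_index(contig, pos, pos, chunk_size=10)
        assert idx.tolist() == [[0, 0, 10, 20, 2], [0, 1, 5, 9, 2]]

    def test_deletion_extends_end(self):
        pos = np.array([50, 95, 100])
        ends = np.array([50, 104, 100])  # 10-base REF at POS 95
        idx = vczarr.build_region_index(np.zeros(3), pos, ends, chunk_size=10)
        assert idx[0].tolist() == [0, 0, 50, 104, 3]

    def test_num_records_partition_chunk(self):
        contig = np.array([0] * 7 + [1] * 8)
        pos = np.concatenate([np.arange(7) + 1, np.arange(8) + 1])
        idx = vczarr.build_region_index(contig, pos, pos, chunk_size=6)
        by_chunk = {}
        for row in idx:
            by_chunk.setdefault(row[0], 0)
            by_chunk[row[0]] += row[4]
        assert by_chunk == {0: 6, 1: 6, 2: 3}

    def test_unsorted_positions_rejected(self):
        with pytest.raises(EncodeError, match="sorted"):
            vczarr.build_region_index(
                np.zeros(3), np.array([5, 3, 9]), np.array([5, 3, 9]), 10
            )

    def test_stored_in_encoded_store(self, medium_paths):
        root = vczarr.open_store(medium_paths["store"])
        idx = root["region_index"][:]
        assert idx.shape[1] == 5
        n = root["variant_position"].shape[0]
        assert idx[:, 4].sum() == n


class TestPartitionedEncode:
    def test_dencode_matches_one_shot(self, tmp_path):
        cfg = FixtureConfig(n_variants=40, n_samples=3, seed=33)
        vcf = os.path.join(tmp_path, "f.vcf")
        generate_vcf(cfg, path=vcf)
        icf_path = os.path.join(tmp_path, "f.icf")
        icf = vczarr.explode(vcf, icf_path)
        one = os.path.join(tmp_path, "one.vcz")
        vczarr.encode(icf, one, variant_chunk=10)
        multi = os.path.join(tmp_path, "multi.vcz")
        encode_init(icf, multi, variant_chunk=10, target_partitions=3)
        states = encode_partition_states(multi)
        with pytest.raises(EncodeError, match="not completed"):
            encode_finalise(multi)
        for i in states:
            encode_partition(multi, i)
        encode_finalise(multi)
        a, b = vczarr.open_store(one), vczarr.open_store(multi)
        for name in a.array_keys():
            x, y = a[name][:], b[name][:]
            if x.dtype == object:
                assert (x == y).all(), name
            elif x.dtype.kind == "f":
                assert np.array_equal(float_bits(x), float_bits(y)), name
            else:
                assert np.array_equal(x, y), name


class TestZipStore:
    def test_zip_view_identical(self, medium_paths, tmp_path):
        zp = vczarr.zip_store(medium_paths["store"],
                              os.path.join(tmp_path, "m.vcz.zip"))
        a = list(vczarr.view(medium_paths["store"]))
        b = list(vczarr.view(zp))
        assert a == b
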
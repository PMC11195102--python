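import os

import pytest

import vczarr
from vczarr.fixtures import TOY_VCF, FixtureConfig, generate_vcf


@pytest.fixture(scope="session")
def toy_paths(tmp_path_factory):
    """The worked-example VCF converted once per session."""
    d = tmp_path_factory.mktemp("toy")
    vcf = os.path.join(d, "toy.vcf")
    with open(vcf, "w") as f:
        f.write(TOY_VCF)
    icf = vczarr.explode(vcf, os.path.join(d, "toy.icf"))
    store = os.path.join(d, "toy.vcz")
    vczarr.encode(icf, store)
    return {"vcf": vcf, "icf": icf, "store": store}


@pytest.fixture(scope="session")
def medium_paths(tmp_path_factory):
    """A moderately rich generated fixture converted once per session."""
    d = tmp_path_factory.mktemp("medium")
    cfg = FixtureConfig(
        n_variants=60, n_samples=5, max_alleles=4, mixed_ploidy=True,
        missing_rate=0.15, seed=11,
    )
    vcf = os.path.join(d, "medium.vcf")
    generate_vcf(cfg, path=vcf, bgzip=True, tabix=True)
    icf = vczarr.explode(vcf, os.path.join(d, "medium.icf"))
    store = os.path.join(d, "medium.vcz")
    vczarr.encode(icf, store, variant_chunk=13)
    return {"vcf": vcf, "icf": icf, "store": store, "config": cfg}


@pytest.fixture()
def convert(tmp_path):
    """Factory converting a FixtureConfig into (vcf, icf, store) paths."""

    counter = {"n": 0}

    def _convert(config, variant_chunk=None, local_alleles=False, **explode_kwargs):
        counter["n"] += 1
        base = tmp_path / f"c{counter['n']}"
        base.mkdir()
        vcf = os.path.join(base, "f.vcf")
        generate_vcf(config, path=vcf)
        icf = vczarr.explode(vcf, os.path.join(base, "f.icf"), **explode_kwargs)
        store = os.path.join(base, "f.vcz")
        vczarr.encode(icf, store, variant_chunk=variant_chunk,
                      local_alleles=local_alleles)
        return vcf, icf, store

    return _convert
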
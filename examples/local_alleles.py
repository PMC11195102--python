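"""Local-allele encoding: bounding allele-indexed fields by ploidy.

Fields with one value per allele (Number=R, e.g. AD) or per genotype
(Number=G, e.g. PL) grow with the *maximum* allele count over the whole
dataset — quadratically for PL.  The local-allele transform stores, per
call, the (at most ploidy) alleles its genotype actually uses (call_LA)
and re-indexes AD/PL against that list, trading a bounded inner dimension
for the loss of values at alleles the call never references.
"""

import os
import tempfile

import vczarr
from vczarr.fixtures import FixtureConfig, generate_vcf
from vczarr.model import genotype_dim_size

print("unordered diploid genotypes by allele count:",
      {n: genotype_dim_size(n, 2) for n in (2, 3, 4, 10)})

workdir = tempfile.mkdtemp(prefix="vczarr_example_")
vcf = os.path.join(workdir, "example.vcf")
generate_vcf(
    FixtureConfig(n_variants=200, n_samples=10, max_alleles=4, seed=5),
    path=vcf,
)
icf = vczarr.explode(vcf, os.path.join(workdir, "example.icf"))
glob = vczarr.encode(icf, os.path.join(workdir, "global.vcz"))
loc = vczarr.encode(icf, os.path.join(workdir, "local.vcz"),
                    local_alleles=True)

print(f"global call_PL inner dimension: {glob['call_PL'].shape[-1]}")
print(f"local  call_LPL inner dimension: {loc['call_LPL'].shape[-1]}")

# Reconstruct one call's AD entries from the local representation:
# pick the first call whose genotype references a non-reference allele.
genotypes = glob["call_genotype"][:]
i, s = next(
    (i, s)
    for i in range(genotypes.shape[0])
    for s in range(genotypes.shape[1])
    if genotypes[i, s].max() > 0
)
gt = genotypes[i, s]
la = loc["call_LA"][i, s]
print(f"\ncall ({i},{s}): genotype {gt.tolist()}, local alleles {la.tolist()}")
print(f"global AD row: {glob['call_AD'][i, s].tolist()}")
print(f"local LAD row: {loc['call_LAD'][i, s].tolist()}")
print("LAD[j] equals AD[LA[j]]: every value the genotype references is")
print("preserved; values at unreferenced alleles are discarded (-2 = fill).")
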
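"""Pooling arithmetic for a 9,024-fish TILLING library.

Builds the two-tier pooling plan (6-fish subpools, 48-subpool superpools),
then prints the quantities that drive the screen: the coverage floor per
pool, the expected frequency of a unique heterozygous mutation, and the
deconvolution path for a hit in one pool.
"""

from tilling import (LibraryDesign, build_pools, deconvolution_candidates,
                     expected_carrier_frequency, min_depth)

design = LibraryDesign(n_fish=9024)
plans = build_pools(design)

print(f"library: {design.n_fish} fish = {design.n_alleles} alleles")
print(f"subpools of {design.subpool_size}: "
      f"{sum(len(p.subpool_ids) for p in plans)}")
sizes = [p.n_fish for p in plans]
print(f"superpools: {sizes.count(288)} x 288 fish + {sizes.count(192)} x 192 fish")

# A mutation heterozygous in one fish appears in exactly one superpool:
f = expected_carrier_frequency(288, design.ploidy)
print(f"expected singleton frequency in a 288-fish pool: 1/{round(1/f)}")
print(f"coverage floor (5 reads/allele): {min_depth(design, 288)} reads "
      f"per position per pool ({min_depth(design, 192)} for a 192-fish pool)")

# Deconvolution of a hit found in superpool 12: genotype its 48 subpools,
# then the 6 fish of the positive subpool.
subpools = deconvolution_candidates(plans, 12, "subpools")
print(f"hit in superpool 13 -> genotype subpools "
      f"{subpools[0] + 1}..{subpools[-1] + 1} (1-based labels)")
fish = deconvolution_candidates(plans, 12, "individuals", subpools[3])
print(f"positive subpool {subpools[3] + 1} -> genotype fish "
      f"{fish[0] + 1}..{fish[-1] + 1}")
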
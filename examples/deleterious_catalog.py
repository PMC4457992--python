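"""Enumerate the deleterious-substitution catalog for one amplicon.

Every single-base change that creates a stop codon in the annotated exon,
or hits a canonical splice dinucleotide, is listed; candidate calls that
land in this catalog are the ones worth deconvolving first.
"""

import numpy as np

from tilling import enumerate_deleterious, random_amplicon
from tilling.podata import classify_position

amp = random_amplicon(np.random.default_rng(7), "ex1", length=120,
                      exon_margin=20)
catalog = enumerate_deleterious(amp)

print(f"amplicon {amp.amplicon_id}: {len(amp)} bp, exon "
      f"{amp.exon_interval[0] + 1}-{amp.exon_interval[1]} (1-based), "
      f"strand {amp.cds_strand}")
nonsense = catalog.by_consequence("nonsense")
print(f"{len(nonsense)} stop-creating substitutions, "
      f"{len(catalog) - len(nonsense)} splice-site substitutions")
for pos, alt in nonsense[:5]:
    print(f"  {pos + 1} {amp.sequence[pos]}>{alt}  nonsense")
print("  ...")

# classify an arbitrary exonic change that is not in the catalog
pos = amp.exon_interval[0] + 2
alt = next(b for b in "ACGT"
           if b != amp.sequence[pos] and (pos, b) not in catalog.entries)
print(f"substitution {pos + 1} {amp.sequence[pos]}>{alt} is "
      f"{classify_position(amp, pos, alt, catalog)}")
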
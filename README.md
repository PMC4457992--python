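# tilling

Rare-mutation discovery in pooled amplicon deep sequencing, for
sequencing-based TILLING (Targeting Induced Local Lesions IN Genomes)
screens of chemically mutagenized libraries.

In such a screen, thousands of mutagenized diploid individuals — each
carrying a private set of heterozygous induced point mutations — are
pooled (e.g. 288 fish per sequencing pool), short exonic amplicons
(~210–270 bp) are PCR-amplified per pool and sequenced as fully
overlapping 2×250 bp read pairs, and the task is to find the one
individual in ~9,000 that carries a loss-of-function allele of a gene of
interest.  A singleton heterozygote in a 288-fish pool is expected at
allele frequency 1/576 — far below the ~1% per-base error rate of the
sequencer — so raw reads cannot distinguish a real mutation from noise.

The package implements the computational method that makes this feasible:

- **PELE merging** (`tilling.pele`): each read pair covers the same
  molecule from both ends; after reverse-complementing mate 2, the best
  ungapped offset is found, adapter read-through is trimmed, and any pair
  whose overlap identity falls below 0.97 is rejected.  A sequencing error
  arises independently in each mate, so this filter removes almost all
  sequencing error while keeping real variants, which appear identically
  in both mates.
- **Pileup and frequency calling** (`tilling.call`): merged consensus
  reads (one count per original pair) are assigned to their reference
  amplicon by exhaustive ungapped scan, counted per position into A/C/G/T
  pileups, and every non-reference base becomes a call with frequency
  `F = variant reads / total reads at that position in that pool`.
- **Screening** (`tilling.screen`): per-position coverage must reach
  `pool fish × ploidy × 5 reads/allele` (2,880 for a 288-fish pool);
  calls at `F > 1/100` are excluded as pre-existing polymorphisms and
  calls at `F < 1/1000` as PCR-introduced errors; the window
  `1/1000 ≤ F ≤ 1/100` is the candidate pass band.
- **PoDATA** (`tilling.podata`): enumerates every single-base substitution
  in an annotated amplicon that creates a stop codon or disrupts a
  canonical GT/AG splice dinucleotide, and classifies calls
  (nonsense / splice / missense / silent / noncoding) so candidates likely
  to be deleterious are deconvolved first.
- **Pool design and deconvolution** (`tilling.pool_design`): fish →
  6-fish subpools → 288-fish superpools, expected carrier frequencies,
  per-pool coverage floors, and the worksheets for two-round HRM
  deconvolution of a hit (48 subpools, then 6 fish).
- **Simulator** (`tilling.simulate`): generates the whole process —
  per-fish heterozygous mutations, founder polymorphisms, two-tier PCR
  errors (early-cycle jackpot lineages plus late per-read errors), and
  paired reads with independent per-mate errors — so every stage is
  testable end to end without sequencer data.

## Worked example

`python examples/simulate_and_screen.py` simulates one 288-fish pool in
which fish 37 carries a heterozygous planted mutation and a founder
polymorphism segregates at 5%, then runs merge → assign → call → screen:

```
simulated 10854 read pairs (129 PCR jackpot lineages)
merged 9740/10854 pairs (discard fraction 0.103)
133 raw calls at covered positions
  pos  41 T>A F=0.05135 (500/9738) -> polymorphism  <- founder polymorphism
  pos 121 C>G F=0.00277 (27/9740) -> pass  <- planted singleton (expected F = 1/576 = 0.00174)
  pos 155 C>T F=0.00062 (6/9740) -> pcr_noise
  pos  87 G>C F=0.00041 (4/9739) -> pcr_noise
  pos 211 G>A F=0.00041 (4/9739) -> pcr_noise
pass-band candidates: 1
```

About 10% of pairs are discarded by the identity filter (the price of
error suppression); the polymorphism is caught by the 1/100 ceiling; the
planted singleton is the only call in the pass band, at a frequency
consistent with one carrier allele in 576; everything else lands below the
1/1000 noise floor.  Skipping the merge instead floods the pass band with
hundreds of sequencing-error calls (each ~1%/3 per alternative base) —
the ablation is available as `no_merge=True` in the pipeline or
`tilling pipeline --no-merge`.

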
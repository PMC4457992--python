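# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the simulation-based tests do and do not
demonstrate.

## Pooling model

A library of `n_fish` diploid individuals is pooled twice: consecutive
fish into subpools of `subpool_size` (default 6, the unit genotyped during
deconvolution), consecutive subpools into superpools of
`subpools_per_superpool` (default 48, i.e. 288 fish sequenced under one
barcode).  All indices are 0-based internally; every user-facing surface
(CLI tables, worksheets, call tables, annotation files) is 1-based.

Two derived quantities drive the screen:

- expected carrier frequency of a variant on `c` alleles in a pool of `n`
  fish: `c / (n × ploidy)` — 1/576 for a singleton heterozygote in a full
  superpool, 1/18,048 across a 9,024-fish library;
- per-position coverage floor: `n × ploidy × reads_per_allele` (default 5
  reads per allele, 2,880 reads for a full superpool).  Short pools use
  their actual fish count (1,920 for 192 fish) since the rule is
  per-allele.

When the number of subpools is not a multiple of `subpools_per_superpool`,
a trailing remainder smaller than half a superpool is rebalanced with the
last full superpool into two near-equal pools instead of leaving a runt:
1,504 subpools at 48 per superpool yield 30 full 288-fish pools plus two
192-fish pools.  A runt pool would sit far from the others in template
complexity, changing its frequency statistics; near-equal pools keep one
screen configuration valid for the whole library.

## PELE merge

Mate 2 is reverse-complemented and scanned against mate 1 at every offset
with overlap ≥ `min_overlap` (default 50 bp, which precludes spurious
short overlaps at amplicon scale); the offset with the most matching bases
wins, ties broken toward the longer overlap and then the smaller offset.
The offset scan is exhaustive — reads are ≤ 300 bp, so O(L²) is trivial
and no seeding heuristics are needed.  Identity is
`matches / overlap_length`; N bases can never support a match (an
`n_policy="exclude"` variant drops them from the denominator instead).

Offset geometry encodes the fragment length: offset 0 is a perfectly
overlapping pair; a negative offset means the fragment was shorter than
the read and both mates read into adapter, which is trimmed (adapter
handling is purely geometric — no adapter-sequence matching is needed when
amplicon lengths are within ~40 bp of the read length); a positive offset
means the fragment was longer than the read, and the non-overlapping
flanks are genuine fragment sequence and are kept, so the consensus covers
the whole molecule.

Pairs whose best-offset identity is below `min_anchor_identity` (0.5) have
no plausible overlap at all and are reported `rejected_no_overlap`
(unrelated 250-mers score ~0.25); pairs that anchor but fall below
`min_identity` (0.97) are `rejected_identity`.  Accepted pairs tolerate up
to 3% mismatches, so the consensus must resolve disagreements: the
higher-quality base wins with quality `|q1 − q2|`, agreement gets
`min(99, q1 + q2)`, and a quality tie yields N (quality 2), which the
pileup then ignores.  Discarding disagreeing pairs outright would waste
the 3% tolerance the identity threshold deliberately grants.

For independent per-base error `e` on each mate, an overlap position
disagrees with probability `p = 2e(1−e) + (2/3)e²` (both mates hitting the
same wrong base still agree), so the probability that a pair is discarded
is the binomial tail `P[Bin(L, p) > floor((1−0.97)·L)]`.  This closed form
is validated against Monte-Carlo merges within 3 standard errors; at
e = 0.01 and L = 250 it predicts ~12.8% discard, the same order as
observed on real instruments (where the true error profile is
position-dependent and not exactly known).

## Assignment, pileup, calling

Merged consensus reads are assigned by exhaustive ungapped scan over every
reference amplicon and offset placing ≥ 80% of the read on-reference.  The
unique placement with fewest mismatches wins if its mismatch fraction is
≤ 10% (both bounds configurable); any tie is ambiguous and the read is
dropped, as are indel-bearing reads, which cannot align ungapped — the
mutagen induces substitutions only, and only single-base variants are
called.  Pileups count one per original pair (never per mate — that is the
substance of the error suppression), N bases count nowhere, and every
(position, non-reference base) with ≥ `min_alt_reads` (default 1) becomes
a raw call with `F = variant_reads / total_reads`.  Frequency filtering
belongs to the screen, not the caller, so the caller stays maximally
sensitive.

## Screen

Status assignment order: `low_coverage` if depth < `min_depth` (applied
per position, per pool), else `polymorphism` if `F > 1/100`, else
`pcr_noise` if `F < 1/1000`, else `pass`.  The thresholds are empirical
constants of the method, not fitted quantities.  F exactly equal to a
boundary passes by default: measured F on finite counts essentially never
hits a boundary, and the inclusive convention avoids dropping a
theoretical singleton at marginal depth (`boundary_inclusive=False`
flips to strict).  Polymorphism status is per-pool F only; an optional
cross-pool recurrence flag (`flag_recurrent`) exists but is off by
default, since uniqueness-in-one-pool is already implied by the library
construction.

## PoDATA

For each exonic position inside a complete codon, the three alternative
bases are substituted on the coding strand (honoring `cds_strand`;
`frame_offset` 0–2 is the phase of the first exonic base in coding order)
and a substitution is recorded as nonsense when the new codon is TAA/TAG/
TGA and the reference codon is not.  Codons truncated by the exon or
amplicon boundary have unknown flanking bases; those positions are skipped
and reported (`skipped_codon_positions`) rather than guessed.  "Splice
site" means the canonical GT donor / AG acceptor dinucleotide annotated
adjacent to the exon; all six substitutions per dinucleotide are
cataloged, and extended splice motifs are out of scope.  Only the standard
genetic code is supported.  The enumeration is verified against an
independent mutate–translate–diff oracle built on Biopython's translator.

The ENU substitution spectrum helper places 75% of probability mass,
uniformly, on the eight substitutions that flip A:T ↔ G:C pairing and the
remainder on the four that preserve pairing; within each class the split
is uniform because finer structure is not needed by anything downstream.

## Simulator

The generator emulates the study conditions end to end; its defaults are
the conditions under which the method operates:

| parameter | default | rationale |
|---|---|---|
| read_len | 250 bp | fully overlapping paired-end reads |
| amplicon length | 210–270 bp (240 in fixtures) | direct sequencing without shearing |
| design | 288 fish/pool, ploidy 2, 6-fish subpools | library construction |
| depth_per_pool | 10,854 pairs | observed mean per-pool coverage |
| seq_error_rate | 0.01 /base/mate | typical sequencer error rate |
| pcr_cycles | 30 | amplicon PCR protocol |
| pcr_error_rate | 1e-6 /base/cycle | high-fidelity polymerase scale |
| enu_rate | 0 (tests plant variants) | ~5,000 het mutations per ~1.4 Gb genome ≈ 9e-4 per 240 bp amplicon if random mutations are wanted |
| dispersion | ~10× across fragments, ~3× across pools (lognormal, median-preserving) | observed depth variability |

Genotypes: planted variants are heterozygous in their named fish; random
induced mutations are Poisson per fish per amplicon with spectrum-weighted
substitutions; founder polymorphisms are Hardy-Weinberg per fish at their
population frequency.

PCR errors use a two-tier approximation of the amplification tree rather
than a full branching process.  An error arising in cycle `c` on one of
`n0` template molecules ends up in a fraction `2^−(c−1)/n0` of final
molecules, so: for early cycles (while the molecule count is below
50× the sampled depth) error lineages are drawn as Poisson events per
cycle, attached to a template allele, and inherited by each read from that
allele with probability `2^−(c−1)` — this produces the recurring
"jackpot" errors that can reach the pass band, exactly the false-positive
class the screen cannot remove; later cycles are folded into an
independent per-read error rate, since such lineages are effectively
private to one read.  Realized PCR-variant frequencies concentrate (> 90%
of variants) below the 1/1000 noise floor at default rates, which is the
property the screen relies on; the fine structure of the model is
deliberately not load-bearing.

Reads are the fragment (or its reverse complement) padded with a fixed
transposase adapter when shorter than the read, with independent uniform
substitution errors per base per mate.  Qualities are two-valued (38 for
correct draws, 12 for error draws) — enough to exercise the consensus
rules; a realistic quality profile would only matter for quality-aware
calling, which the pipeline deliberately does not do.  All draws flow from
one seeded generator in documented order, so identical configurations are
byte-identical, including FASTQ output.

What the simulator does **not** emulate: position-dependent or
motif-dependent sequencer error, quality decay along the read, chimeric
reads, index hopping, primer-site artifacts, and indels.  Passing tests
therefore demonstrate the pipeline's behavior under idealized independent
errors at realistic rates, not performance on any particular instrument;
the empirically observed discard fraction of a real run, for example,
depends on the true error profile and is reproduced here only in order of
magnitude.

## Problem sizes and stochastic tests

Simulation-based tests run at the study's per-pool scale (one amplicon,
288 fish, ~10,900 pairs per replicate).  The planted-singleton recovery
check uses 100 seeded replicates and requires ≥ 95 recoveries; with
~9,700 merged reads the alt count is Binomial(9700, 1/576) and the
1/1000 floor sits ~1.8σ below its mean, so ~96% per-replicate recovery is
the statistically expected value — the criterion is tight by design, and
higher depth (as in well-covered real fragments) widens the margin.  The
merge-ablation comparison (unmerged mates vs merged consensus, same
simulated pools) uses 3 replicates; the observed ratio is in the hundreds
because every sequencing-error base (~0.33% per alternative base) lands in
the pass band, versus a handful of pass calls in the merged run.  Unit
variants of these properties run at reduced replicate counts; the
full-scale versions live in the acceptance suite.

## Known limitations

- Ungapped assignment drops indel-bearing reads by construction; indel
  calling is out of scope.
- One exon interval per amplicon; multi-exon amplicons need one record per
  exon segment.
- The deconvolution planner emits worksheets only; melt-curve analysis is
  an external assay.
- `expected_discard_fraction` assumes a uniform independent error model;
  it is an oracle for the simulator, not a calibration of any instrument.
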
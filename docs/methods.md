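# Methods

## Problem and scope

`ampliclone` analyzes single-molecule long-read (CCS) sequencing of the
BCR-ABL1 p210 fusion-transcript amplicon, the assay used to monitor
TKI-resistance mutations in CML. Because one CCS read is one cDNA molecule,
the analysis can do three things short-read pipelines cannot do directly:

1. call minor substitution variants (T315I, F359C, ...) down to sub-percent
   frequencies against a sequencing-error floor;
2. phase mutations per molecule, separating **compound** mutations (two
   changes in cis on one transcript) from **independent** clones;
3. detect splice isoforms (junction insertions such as the recurrent 35 nt
   insertion between ABL1 exons 8 and 9, partial exon deletions) from
   full-length reads.

No patient reads are distributed with any public record of this assay, so
the package carries a first-class simulator that generates clone mixtures,
serial dilutions and chimeric artifacts with known truth; assay performance
(detection limits, specificity, isoform sensitivity) is quantified on those
simulations.

## Reference model

The fusion transcript is an ordered exon list (BCR exons then ABL1 exons)
with two breakpoint variants: e13a2 and e14a2 (the latter includes BCR exon
14). The PCR product is reconstructed in silico by exact matching of the
forward primer on the sense strand and the reverse primer's reverse
complement downstream of it; zero or multiple matches are hard errors
("no product" / "ambiguous product"). Coordinates are 0-based half-open
internally; tables print 1-based positions.

Clinical ABL1 codon numbering (T315 etc.) cannot be derived from the
amplicon sequence alone, so every reference carries a **codon anchor** — the
codon index of one stated transcript position — from which all codon indices
follow along the reading frame. The shipped reference
(`ampliclone/data/synthetic_p210_*.yaml`) is **fully synthetic**: exon
lengths, junction layout, the 1578 bp e14a2 product length and the anchored
clinical codons (Y253, E255, D276, T315, F359, H396 with their wild-type
amino acids) mimic the real amplicon, but the sequence is generated from a
fixed seed with no in-frame stop codons. It exists so that every analysis,
test and figure can run without downloading the human reference mRNAs; a
user-supplied real reference drops into the same YAML format.

## Simulator

A sample is a list of clones, each a set of substitutions and/or isoform
events on the amplicon plus a fraction; fractions must sum to 1. Reads are
drawn per clone, sequencing error is injected i.i.d. per base —
substitution (default 0.013/base, uniform over the three alternatives),
insertion (0.010/base) and deletion (0.005/base) — and ~50% of reads are
emitted reverse-complemented. The defaults are CCS-like and deliberately
place the per-alternative noise (0.43%) just below the assay's claimed
0.5% detection floor, so the caller is stressed where it matters. Optional
PCR-mediated recombination emits single-switch chimeras: prefix from one
independently drawn clone template, suffix from another, breakpoint uniform
along the molecule. Read ids plus an attached truth object record the
originating clone, orientation and chimera structure for test oracles;
nothing in the analysis chain reads them.

The patient-like mixture used for dilution experiments has three clones —
primary mutation 91.8%, secondary mutation 4.2%, no mutation 4.0% — and a
dilution at mixing proportion m scales every clone by m with wild-type
diluent making up the rest, so a primary-expected-50% sample carries the
secondary at 50 x 4.2/91.8 ≈ 2.3%.

What the simulator does **not** model: context-dependent error profiles
(homopolymer-length-dependent indel rates beyond what left-alignment
induces), per-read quality variation (qualities are a constant
placeholder; no filter uses them), polymerase-pass structure, multi-switch
chimeras, and coverage ramps at amplicon ends. Passing tests therefore
demonstrate correctness of the analysis under a uniform error model, not
performance on any particular instrument chemistry.

## Alignment

Reads are aligned semi-globally (free end gaps on either sequence) with
affine gap penalties: match +2, mismatch -4, gap open -4, gap extend -1.
These defaults keep a 35-154 nt isoform insertion as one gap instead of a
scatter of mismatches. Orientation is chosen by a shared-16-mer hint
confirmed with a capped edit-distance pass (edlib); the affine optimum is
then computed by a banded Gotoh kernel (numba) whose band is sized from the
edit-distance prefilter (net diagonal drift + 24 + ed/8) and doubled
whenever the traceback touches a band edge. At the default margin no
sub-optimal alignment was observed in 8,000 reads even at twice the default
error rates; `semi_global` without a band argument runs the full matrix and
is exact by construction. Ties prefer mismatch over indel, and indel runs
are left-normalized after traceback (VCF convention), so alignments are
deterministic. Reads under 75% identity over aligned columns are unmapped.
A read is **full-length** when its reference span reaches within 5 bases
(`end_tolerance`) of both amplicon ends.

## Pileup and variant calling

The pileup keeps two tallies per position: raw counts (A/C/G/T/deletion,
plus insertion support keyed by position and sequence) and **indel-clean**
base counts restricted to read columns at least 2 reference bases from
every indel in the same read. The clean tally exists because alignment
ambiguity converts deletion errors near a true variant into systematic
mismatches one or two bases away (the variant's mismatch plus an adjacent
deletion admits an equal-scoring path that re-pairs the columns); at
30,000x this artifact is large enough to be called. Measured example: a
spurious G>T at 0.89% two bases from a 91.8% variant in raw counts,
absent in clean counts.

The caller tests each (position, alternative base) with a one-sided
binomial tail on the clean counts: P(X >= alt | n = clean coverage,
p = floor/3) < alpha / (3L), Bonferroni over all 3 x L hypotheses
(alpha default 0.05, L = amplicon length), plus guards
`min_frequency = 0.005` and `min_alt_count = 10`. The error floor is the
90th percentile across positions of the per-position clean mismatch rate
(candidate variant positions, rate > 5x the current floor, excluded over
two rounds). The percentile rather than the median makes the floor an
upper envelope against position-level error heterogeneity; since the
envelope's overshoot is ~1.3 per-position sampling standard deviations, it
tightens automatically at high depth and widens at low depth. At the
default simulation conditions this places the detection threshold near 175
alt reads at 30,000x — comfortably above the ~120-read noise expectation
(essentially zero false positives family-wise) and comfortably below the
~245 reads expected from a 0.46% clone plus noise (about 4 sigma of
detection margin). Reported frequency is clean alt count / clean coverage.
Indels are never called as variants: events >= 3 nt belong to the isoform
analysis, 1-2 nt indels are treated as noise.

Annotation rebuilds the codon from the anchor map, translates reference
and mutated codons, emits labels like `T315I`, and flags synonymous
changes; calls in codons clipped by the amplicon edge stay unannotated.

## Per-molecule composition (phasing)

A read contributes to clone composition only if, around **every** called
variant, its aligned columns across ±10 flanking positions (20 bases
total, the variant column itself excluded) are all matches with no indels
— insertions strictly between window columns also disqualify. The
half-width is the `window_half_width` parameter; reads need not be
full-length, only to align across each window. At the variant column the
read must show the reference or the alternative base; a third base
excludes the read. Excluded reads are counted and reported, never silently
dropped.

Evaluable reads are grouped by their signature set; frequencies are
percentages of evaluable reads. Each variant pair is classified with the
support bar max(2 reads, 0.5% of evaluable reads) — the assay's frequency
floor: double-positives at or above the bar → **compound**; both exclusive
singles at or above the bar with doubles below → **independent**; anything
else → **mixed**. The chimera diagnostic reports a pair's double-positive
rate next to each single rate and the product-of-singles baseline expected
from random template switching.

## Isoform detection

Only full-length reads enter. `strict` mode implements the literal
rule — groups of byte-identical full-length sequences (after orientation
normalization) with at least 2 supporting reads. At CCS-like error rates
near-identical full reads are rare, so the default `event` mode groups
reads by their indel event structure: alignment indel operations of at
least `min_event_length = 3` nt, keyed by (kind, position, length); point
errors and 1-2 nt indel noise are ignored, and the reported insertion
sequence is the majority sequence across supporting reads. Frequencies are
percentages of all full-length reads, so unreported minor groups appear as
unassigned mass. Events are anchored to exon junctions when within ±3 nt
(left-normalization can shift an insertion point a few bases when the
insert shares terminal bases with the reference), frame effect is length
mod 3, and truncation is decided by translating the event-modified
amplicon and scanning for a stop before the final codon. Labels: `WT`,
`35INS` for a single junction-anchored insertion of 35 nt, coordinate
labels otherwise.

## Sensitivity analysis

`run_sensitivity` runs align → pileup → call on every sample of a dilution
series and grades each tracked variant at its per-sample expected
frequency (from simulation truth). The detection limit is the smallest
expected fraction of an **unbroken** run of detections from the top of the
series; an isolated detection below a miss does not lower the limit. Calls
at untracked positions accumulate as false positives.

## Problem sizes

The single-seed dilution experiment runs at the assay-like depth of 30,000
reads per sample (five samples: undiluted + 50/10/1/0.5% expected primary
frequency). Multi-seed robustness checks in the test suite run at reduced
depth — specificity across 20 seeds at 1,200 reads per sample, because the
caller's binomial threshold is depth-calibrated and specificity does not
require full coverage — and the isoform-sensitivity check runs 5 seeds at
the stated 20,000 full-length reads. `scripts/acceptance.py` recomputes the
headline figures at full depth from scratch.

## Known limitations

* The aligner's banding is heuristic for long reads; exactness is verified
  empirically (and guaranteed only for the unbanded path). Pathological
  reads could in principle receive a sub-optimal alignment.
* The error floor assumes substitution noise spreads uniformly over the
  three alternative bases; strand-specific or context-specific miscall
  spectra would violate the floor/3 split (a strand-bias test is out of
  scope because simulated orientation is symmetric).
* Frequency estimates are biased low by a few percent relative to clone
  fractions (error on the variant base plus attribution loss at the site);
  the acceptance suite checks linearity of the response rather than
  identity.
* Compound/independent classification is per pair with a fixed support
  bar; no subclone phylogeny is inferred.
* The isoform event grouping fragments reads whose errors touch the event
  itself (an indel error inside a 35 nt insert changes its length), so
  isoform frequencies underestimate truth by roughly the per-event indel
  error probability; strict mode is exact only on error-free data.
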
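# ampliclone

Single-molecule long-read analysis of the **BCR-ABL1 p210 fusion-transcript
amplicon** — the assay used to monitor tyrosine-kinase-inhibitor (TKI)
resistance in chronic myeloid leukemia. Because each circular-consensus
(CCS) read is one cDNA molecule spanning the entire ~1.6 kb amplicon, the
package can:

* call **minor resistance substitutions** (T315I, F359C, ...) down to
  sub-percent frequencies against a statistically controlled
  sequencing-error floor;
* **phase mutations per molecule**, separating *compound* mutations (in cis
  on one transcript) from *independent* clones — the distinction that drives
  TKI choice, and one bulk Sanger sequencing cannot make;
* detect **splice isoforms** (e.g. the recurrent 35 nt insertion between
  ABL1 exons 8 and 9, partial exon deletions) from full-length reads with a
  ≥2-supporting-read rule;
* **simulate** clone mixtures, serial dilutions and PCR-recombination
  chimeras with hidden truth labels, and measure the assay's detection
  limits and specificity on them.

It is intended for method developers and diagnostic-lab bioinformaticians
who want an auditable, scriptable re-implementation of this analysis with
plain-text intermediates (FASTQ/SAM/TSV/VCF/JSON/FASTA) at every stage.

## The statistics at the core

**Variant calling.** For every position i and alternative base b the caller
tests the alt count k against a binomial null,

    P(X >= k | n = clean coverage, p = floor / 3)  <  alpha / (3 L),

Bonferroni-corrected over all 3L (position, alternative) hypotheses
(alpha = 0.05, L = amplicon length), with guards `min_frequency = 0.5%` and
`min_alt_count = 10`. Evidence comes from *indel-clean* pileup counts
(columns ≥ 2 bases from the nearest indel in the same read), which removes
the realignment artifacts that deletion errors create next to true
variants. The floor is the 90th percentile across positions of the clean
per-position mismatch rate — an upper envelope whose margin scales with
per-position sampling noise. At 30,000× and default CCS-like error rates
this yields essentially zero false positives genome-wide while detecting a
0.46% clone with ~4σ of margin.

**Phasing.** A read joins the clonal-composition analysis only if the 20
bases flanking every called variant (±10, variant column excluded) align as
perfect matches with no indels. Signature sets are tallied into clone
frequencies; a variant pair is *compound* when double-positive reads clear
the support bar max(2 reads, 0.5% of evaluable reads), *independent* when
both exclusive singles clear it and doubles do not.

**Isoforms.** Full-length reads (alignment reaching within 5 bases of both
amplicon ends) are grouped either by exact sequence identity (`strict`) or
by indel event structure ≥ 3 nt (`event`, default); groups need ≥ 2 reads.

See `docs/methods.md` for the full model description, parameter rationale
and limitations.

## Worked example

Simulate a three-clone sample — 12% of molecules carrying a T315I-like
substitution, 8% carrying the 35 nt junction insertion, 80% wild type —
and run the full analysis:

```python
import json
from ampliclone import refmodel, simulate, pipeline

amp = refmodel.synthetic_amplicon()
panel = simulate.resistance_panel(amp)
ins35 = simulate.junction_insertion(amp, "ABL1-a8", "ABL1-a9", 35)
clones = [
    simulate.CloneSpec("resistant", 0.12, (panel["T315I"],)),
    simulate.CloneSpec("spliced", 0.08, (), (ins35,)),
    simulate.CloneSpec("wild-type", 0.80),
]
reads = simulate.simulate_sample(amp, clones, 4000, seed=7)
report = pipeline.run_pipeline(reads, amp)
print(json.dumps(report.summary(), indent=2))
```

Output (isoform list truncated):

```json
{
  "reads": 4000,
  "mapped_pct": 100.0,
  "full_length_pct": 100.0,
  "error_floor": 0.015527,
  "variants": [
    {"label": "T315I", "position": 731, "ref": "C", "alt": "T",
     "frequency_pct": 11.84}
  ],
  "clones": [
    {"signature": ["none"],  "frequency_pct": 88.4109},
    {"signature": ["T315I"], "frequency_pct": 11.5891}
  ],
  "excluded_reads": 1722,
  "isoforms": [
    {"label": "WT",    "support": 3646, "frequency_pct": 91.15},
    {"label": "35INS", "support": 174,  "frequency_pct": 4.35},
    {"label": "36INS", "support": 52,   "frequency_pct": 1.3}
  ]
}
```

Reading it: the 12% resistant clone is called at 11.84% observed frequency
(sequencing error shaves a little off both numerator and denominator); the
per-molecule composition agrees (11.6% of evaluable reads carry T315I —
note 1,722 of 4,000 reads were excluded by the strict 20-base window, which
is the expected ~43% at the default ~2.8%/base combined error rate); the
35 nt insertion isoform is reported at 4.35% with satellite groups (36INS,
34INS, ...) holding reads whose indel *errors* landed inside the insert and
changed its apparent length — the simulated 8% splits across them. The
error floor 0.0155 is the 90th-percentile envelope over the 0.013/base
substitution rate.

The same analysis runs from the shell:

```bash
ampliclone write-reference --out ref.yaml
ampliclone simulate --reference ref.yaml --clones clones.yaml \
    --n-reads 4000 --seed 7 --out reads.fastq
ampliclone run --reference ref.yaml --reads reads.fastq --outdir out/
# or stage by stage: align -> call -> phase -> isoforms, via SAM/TSV files
```

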
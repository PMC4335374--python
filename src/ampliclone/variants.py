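"""Minor variant calling against the sequencing-error floor.

Substitution variants are called from the pileup by testing each
(position, alternative base) against a binomial null whose rate is the
sequencing-error floor. Two measures keep the test honest at ~10,000x
coverage, where even sub-percent biases matter:

* alt evidence comes from the pileup's indel-clean counts (columns at least
  two reference bases from the nearest indel in the same read), which
  removes the spurious mismatches that alignment ambiguity creates next to
  true variants when deletion errors realign;
* the floor is an upper envelope (90th percentile across positions, not the
  median) of the per-position clean mismatch rate, so position-level error
  heterogeneity is absorbed into the null instead of surfacing as false
  positives.

The per-alternative null rate is floor/3 (substitution errors spread evenly
over the three alternatives) and the one-sided binomial tail is
Bonferroni-corrected over all 3 x L (position, alternative) hypotheses.
Indels are never called here: events of 2 nt and more are isoform
territory, single-base indels are treated as noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .align import Pileup
from .refmodel import Amplicon, UntranslatablePosition, translate

BASES = "ACGT"


@dataclass(frozen=True)
class CallerConfig:
    """Knobs of the minor-variant caller.

    ``error_floor`` is the per-position non-reference rate; when None it is
    estimated from the pileup. ``alpha`` is the family-wise error rate after
    Bonferroni correction over 3 x amplicon-length hypotheses.
    """

    min_frequency: float = 0.005
    min_alt_count: int = 10
    error_floor: float | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.min_frequency <= 0.5:
            raise ValueError("min_frequency must lie in (0, 0.5]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class CodonAnnotation:
    gene: str
    codon: int
    ref_aa: str
    alt_aa: str
    label: str
    synonymous: bool


@dataclass(frozen=True)
class VariantCall:
    """A called substitution with its evidence and amino-acid annotation."""

    position: int  # 0-based amplicon coordinate
    ref: str
    alt: str
    alt_count: int
    coverage: int
    frequency: float
    p_adjusted: float
    annotation: CodonAnnotation | None = None

    @property
    def label(self) -> str:
        if self.annotation is not None:
            return self.annotation.label
        return f"{self.ref}{self.position + 1}{self.alt}"


def estimate_error_floor(pile: Pileup, rounds: int = 2, quantile: float = 0.9) -> float:
    """Robust per-position substitution-error floor from the pileup.

    The statistic is an upper envelope — the ``quantile`` (default 90th
    percentile) across positions — of the per-position mismatch rate in the
    indel-clean counts. The percentile rather than the median guards the
    binomial null against position-level error heterogeneity that a uniform
    model misses; because its overshoot scales with the per-position
    sampling noise, the guard automatically tightens at high depth and
    widens at low depth. Candidate variant positions (rate above 5x the
    current floor) are excluded iteratively for ``rounds`` rounds. Requires
    total coverage >= 1000 columns.
    """
    if int(pile.coverage.sum()) < 1000:
        raise ValueError("error-floor estimation requires >= 1000 pileup columns")
    cov = pile.clean_coverage
    L = len(pile.amplicon)
    ref_clean = pile.clean_counts[np.arange(L), pile._ref_codes]
    ok = cov > 0
    rate = np.zeros(L, float)
    rate[ok] = 1.0 - ref_clean[ok] / cov[ok]
    keep = ok.copy()
    floor = float(np.quantile(rate[keep], quantile))
    for _ in range(rounds):
        cand = rate > 5.0 * floor if floor > 0 else rate > 0
        keep = ok & ~cand
        if not keep.any():
            break
        floor = float(np.quantile(rate[keep], quantile))
    return floor


def call_variants(pile: Pileup, config: CallerConfig = CallerConfig()) -> list[VariantCall]:
    """Call substitution variants from the pileup; sorted by position.

    A (position, alt) is emitted when frequency >= min_frequency, alt count
    >= min_alt_count, and the one-sided binomial tail
    P(X >= alt | n=coverage, p=floor/3) clears alpha / (3 x L). Alt evidence
    and coverage come from the pileup's indel-clean counts; the floor (raw
    non-reference rate, deletions included) stays deliberately conservative.
    """
    floor = config.error_floor
    if floor is None:
        floor = estimate_error_floor(pile)
    p_alt = floor / 3.0
    L = len(pile.amplicon)
    n_tests = 3 * L
    cov = pile.clean_coverage
    ref_codes = pile._ref_codes

    calls: list[VariantCall] = []
    counts = pile.clean_counts
    # cheap prefilter on frequency/count before the exact tail
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = np.where(cov[:, None] > 0, counts[:, :4] / cov[:, None], 0.0)
    cand_pos, cand_base = np.nonzero(
        (freqs >= config.min_frequency) & (counts[:, :4] >= config.min_alt_count)
    )
    for pos, b in zip(cand_pos, cand_base):
        if b == ref_codes[pos]:
            continue
        k = int(counts[pos, b])
        n = int(cov[pos])
        tail = float(stats.binom.sf(k - 1, n, p_alt)) if p_alt > 0 else (1.0 if k == 0 else 0.0)
        if tail >= config.alpha / n_tests:
            continue
        calls.append(
            VariantCall(
                position=int(pos),
                ref=pile.amplicon.sequence[pos],
                alt=BASES[b],
                alt_count=k,
                coverage=n,
                frequency=k / n,
                p_adjusted=min(1.0, tail * n_tests),
            )
        )
    calls.sort(key=lambda c: (c.position, c.alt))
    return calls


def annotate_variant(call: VariantCall, amplicon: Amplicon) -> VariantCall:
    """Attach the amino-acid annotation (e.g. T315I); calls at partial codons
    come back unannotated."""
    try:
        gene, codon, pos_in_codon = amplicon.codon_at(call.position)
        ref_codon = amplicon.ref_codon(codon)
    except UntranslatablePosition:
        return call  # partial codon at the amplicon edge: flagged by absence
    alt_codon = ref_codon[:pos_in_codon] + call.alt + ref_codon[pos_in_codon + 1 :]
    ref_aa = translate(ref_codon)
    alt_aa = translate(alt_codon)
    ann = CodonAnnotation(
        gene=gene.value,
        codon=codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        label=f"{ref_aa}{codon}{alt_aa}",
        synonymous=ref_aa == alt_aa,
    )
    return replace(call, annotation=ann)


def annotate_all(calls, amplicon: Amplicon) -> list[VariantCall]:
    return [annotate_variant(c, amplicon) for c in calls]


# ---------------------------------------------------------------------------
# Tabular / VCF export
# ---------------------------------------------------------------------------

def variants_frame(calls) -> pd.DataFrame:
    """Variant table with 1-based positions, frequencies in percent."""
    rows = []
    for c in calls:
        rows.append(
            {
                "position": c.position + 1,
                "ref": c.ref,
                "alt": c.alt,
                "alt_count": c.alt_count,
                "coverage": c.coverage,
                "frequency_pct": round(100.0 * c.frequency, 4),
                "p_adjusted": c.p_adjusted,
                "label": c.label,
                "synonymous": bool(c.annotation.synonymous) if c.annotation else False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "position", "ref", "alt", "alt_count", "coverage",
            "frequency_pct", "p_adjusted", "label", "synonymous",
        ],
    )


def write_variants_tsv(calls, path) -> None:
    variants_frame(calls).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t")
    calls = []
    for _, row in df.iterrows():
        ann = None
        label = str(row["label"])
        expected_plain = f"{row['ref']}{int(row['position'])}{row['alt']}"
        if label != expected_plain and len(label) >= 3:
            ann = CodonAnnotation(
                gene="", codon=int("".join(ch for ch in label if ch.isdigit()) or 0),
                ref_aa=label[0], alt_aa=label[-1], label=label,
                synonymous=bool(row.get("synonymous", False)),
            )
        calls.append(
            VariantCall(
                position=int(row["position"]) - 1,
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                alt_count=int(row["alt_count"]),
                coverage=int(row["coverage"]),
                frequency=float(row["frequency_pct"]) / 100.0,
                p_adjusted=float(row["p_adjusted"]),
                annotation=ann,
            )
        )
    return calls


def write_vcf(calls, amplicon: Amplicon, path) -> None:
    """Minimal VCF in amplicon coordinates (INFO: AF, DP, LABEL)."""
    import pysam

    header = pysam.VariantHeader()
    header.contigs.add(amplicon.name, length=len(amplicon))
    header.info.add("AF", 1, "Float", "Alternate allele frequency")
    header.info.add("DP", 1, "Integer", "Pileup coverage at the site")
    header.info.add("LABEL", 1, "String", "Amino-acid label")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in calls:
            rec = vcf.new_record(
                contig=amplicon.name,
                start=c.position,
                stop=c.position + 1,
                alleles=(c.ref, c.alt),
            )
            rec.info["AF"] = c.frequency
            rec.info["DP"] = c.coverage
            rec.info["LABEL"] = c.label
            vcf.write(rec)
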
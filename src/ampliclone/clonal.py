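"""Per-molecule mutation phasing: compound vs independent clones.

Because each CCS read is one cDNA molecule, co-occurrence of mutations
within a read distinguishes compound mutations (same molecule, cis) from
independent clones. A read contributes to the composition analysis only if,
around every called variant, its 20 flanking bases (±10, the variant column
itself excluded) align as perfect matches with no indels — the
perfect-window quality filter that suppresses sequencing-error artifacts.
Reads failing the filter at any variant are excluded and reported, never
silently dropped.

The compound/independent call for a variant pair uses an explicit support
bar of max(2 reads, 0.5% of evaluable reads) — the assay's frequency floor:
double-positives above the bar mean compound; both singles above the bar
with doubles below it mean independent; anything else is 'mixed'. A chimera
diagnostic reports each pair's double-positive rate next to the
product-of-singles baseline expected from random PCR template switching.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .align import AlignmentRecord
from .variants import VariantCall

REF, ALT, EXCLUDED = "ref", "alt", "excluded"


@dataclass(frozen=True)
class ReadSignature:
    """Per-read status at every called variant; ``signature`` is the set of
    variant labels carried, defined only when no variant is excluded."""

    read_id: str
    status: dict[str, str]  # label -> ref | alt | excluded
    signature: frozenset[str] | None

    @property
    def evaluable(self) -> bool:
        return self.signature is not None


def read_signature(
    aln: AlignmentRecord,
    variants: list[VariantCall],
    window_half_width: int = 10,
) -> ReadSignature:
    """Classify one read at each called variant under the perfect-window rule.

    For each variant, the aligned columns over [pos-w, pos+w] excluding pos
    itself must all be matches with no indels; otherwise the variant status
    is 'excluded' and the read drops out of the composition analysis.
    """
    if not variants:
        raise ValueError("read_signature requires at least one called variant")
    w = window_half_width
    status: dict[str, str] = {}
    for v in variants:
        lo, hi = v.position - w, v.position + w + 1
        st, bases, ins = aln.ref_profile(lo, hi)
        verdict = None
        # insertions between two window columns break the window
        if any(lo + 1 <= j <= hi - 1 for j in ins):
            verdict = EXCLUDED
        if verdict is None:
            for off, s in enumerate(st):
                if lo + off == v.position:
                    continue
                if s != "=":
                    verdict = EXCLUDED
                    break
        if verdict is None:
            s_at = st[v.position - lo]
            b_at = bases[v.position - lo]
            if s_at in "=X":
                if b_at == v.alt:
                    verdict = ALT
                elif b_at == v.ref:
                    verdict = REF
                else:
                    verdict = EXCLUDED  # third allele: treated as error
            else:
                verdict = EXCLUDED  # deleted or uncovered variant column
        status[v.label] = verdict
    if all(s in (REF, ALT) for s in status.values()):
        sig = frozenset(lbl for lbl, s in status.items() if s == ALT)
    else:
        sig = None
    return ReadSignature(aln.read_id, status, sig)


@dataclass(frozen=True)
class PairClassification:
    classification: str  # compound | independent | mixed
    double_count: int
    single_counts: tuple[int, int]  # carrying exactly one of the pair
    support_bar: float


@dataclass
class CloneTable:
    """Signature-set frequency table over evaluable reads."""

    rows: list[tuple[frozenset[str], int, float]]  # (signature, count, % of evaluable)
    evaluable: int
    excluded: int
    pairs: dict[tuple[str, str], PairClassification]

    def frequency_of(self, signature) -> float:
        sig = frozenset(signature)
        for s, _, f in self.rows:
            if s == sig:
                return f
        return 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "signature": "+".join(sorted(sig)) if sig else "none",
                    "reads": n,
                    "frequency_pct": round(f, 4),
                }
                for sig, n, f in self.rows
            ],
            columns=["signature", "reads", "frequency_pct"],
        )

    def to_json(self) -> str:
        doc = {
            "evaluable_reads": self.evaluable,
            "excluded_reads": self.excluded,
            "clones": [
                {"signature": sorted(sig), "reads": n, "frequency_pct": round(f, 4)}
                for sig, n, f in self.rows
            ],
            "pairs": {
                f"{a}+{b}": {
                    "classification": pc.classification,
                    "double_count": pc.double_count,
                    "single_counts": list(pc.single_counts),
                    "support_bar": pc.support_bar,
                }
                for (a, b), pc in self.pairs.items()
            },
        }
        return json.dumps(doc, indent=2)


def composition(signatures, support_floor: float = 0.005) -> CloneTable:
    """Aggregate read signatures into clone frequencies and classify pairs.

    Frequencies are percentages of evaluable reads. For each pair of variant
    labels seen in the signatures, the pair is 'compound' when the
    double-positive count clears the support bar max(2, support_floor x
    evaluable), 'independent' when both exclusive singles clear the bar and
    doubles stay below it, 'mixed' otherwise.
    """
    signatures = list(signatures)
    evaluable = [s for s in signatures if s.evaluable]
    excluded = len(signatures) - len(evaluable)
    if not evaluable:
        raise ValueError("composition requires at least one evaluable read")
    n = len(evaluable)
    counts = Counter(s.signature for s in evaluable)
    rows = [
        (sig, cnt, 100.0 * cnt / n)
        for sig, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    ]
    labels = sorted({lbl for s in evaluable for lbl in s.status})
    bar = max(2.0, support_floor * n)
    pairs: dict[tuple[str, str], PairClassification] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            double = sum(cnt for sig, cnt in counts.items() if a in sig and b in sig)
            only_a = sum(cnt for sig, cnt in counts.items() if a in sig and b not in sig)
            only_b = sum(cnt for sig, cnt in counts.items() if b in sig and a not in sig)
            if double >= bar:
                cls = "compound"
            elif only_a >= bar and only_b >= bar:
                cls = "independent"
            else:
                cls = "mixed"
            pairs[(a, b)] = PairClassification(cls, double, (only_a, only_b), bar)
    return CloneTable(rows, n, excluded, pairs)


def signatures_for(
    alignments,
    variants: list[VariantCall],
    window_half_width: int = 10,
) -> list[ReadSignature]:
    """Signatures for every mapped alignment (reads need not be full-length;
    they must simply align across each variant's window to stay evaluable)."""
    return [read_signature(a, variants, window_half_width) for a in alignments]


@dataclass(frozen=True)
class ChimeraDiagnostic:
    """Observed co-occurrence of a variant pair vs the random-recombination
    baseline (product of total carrier frequencies)."""

    pair: tuple[str, str]
    double_rate: float  # fraction of evaluable reads carrying both
    rate_a: float  # total carrier fraction of first variant
    rate_b: float
    expected_by_chance: float

    @property
    def single_rates(self) -> tuple[float, float]:
        return (self.rate_a, self.rate_b)


def chimera_diagnostic(table: CloneTable, pair: tuple[str, str]) -> ChimeraDiagnostic:
    a, b = pair
    n = table.evaluable
    double = sum(cnt for sig, cnt, _ in table.rows if a in sig and b in sig)
    tot_a = sum(cnt for sig, cnt, _ in table.rows if a in sig)
    tot_b = sum(cnt for sig, cnt, _ in table.rows if b in sig)
    ra, rb = tot_a / n, tot_b / n
    return ChimeraDiagnostic(pair, double / n, ra, rb, ra * rb)
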
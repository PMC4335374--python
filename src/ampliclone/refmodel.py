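"""Reference model of the BCR-ABL1 p210 fusion transcript.

The assay targets the major (p210) fusion transcript of *BCR-ABL1*, amplified
as a single long-range PCR product spanning BCR exon 12 through ABL1 exon 9.
This module represents that reference as an ordered exon structure
(:class:`TranscriptModel`), reconstructs the PCR amplicon in silico from the
primer pair (:func:`in_silico_pcr`), and maps amplicon coordinates to exons
and to codons in the clinical ABL1 numbering (:func:`annotate_codon`).

Coordinates are 0-based, half-open throughout; 1-based positions appear only
in human-readable output. Clinical ABL1 codon numbering (T315, F359, ...)
cannot be derived from the amplicon alone, so each reference carries a codon
*anchor*: the codon index of one stated transcript position, from which all
other codon indices follow along the reading frame.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio.Seq import Seq

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a DNA string (length trimmed to a codon multiple)."""
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


class ValidationError(ValueError):
    """A reference component violates its structural invariants."""


class PrimerError(ValueError):
    """In-silico PCR produced no product or an ambiguous product."""


class UntranslatablePosition(ValueError):
    """Position falls in a partial codon at the amplicon edge."""


class Gene(str, enum.Enum):
    BCR = "BCR"
    ABL1 = "ABL1"


@dataclass(frozen=True)
class Exon:
    """One exon of the fusion transcript."""

    gene: Gene
    name: str
    ordinal: int
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"exon {self.name}: empty sequence")
        if not set(self.sequence) <= _DNA:
            raise ValidationError(f"exon {self.name}: alphabet must be ACGT")
        if self.ordinal < 1:
            raise ValidationError(f"exon {self.name}: ordinal must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CodonAnchor:
    """Pins clinical codon numbering: transcript ``position`` lies in codon ``codon``."""

    position: int
    codon: int


@dataclass(frozen=True)
class Junction:
    position: int  # transcript coordinate of the first base of the downstream exon
    upstream: str
    downstream: str


class TranscriptModel:
    """Ordered exon structure and sequence of the fusion transcript.

    Parameters
    ----------
    exons
        BCR exons first, then ABL1 exons, each gene in increasing ordinal order.
    breakpoint
        ``"e13a2"`` or ``"e14a2"`` — which BCR breakpoint variant this model
        represents (e14a2 includes one more BCR exon).
    frame_offset
        Reading-frame phase of transcript position 0 (0 means position 0 is
        the first base of a codon).
    codon_anchor
        Optional anchor fixing the clinical codon numbering.
    """

    def __init__(
        self,
        exons,
        breakpoint: str,
        frame_offset: int = 0,
        codon_anchor: CodonAnchor | None = None,
    ):
        exons = tuple(exons)
        if not exons:
            raise ValidationError("exon list is empty")
        if breakpoint not in ("e13a2", "e14a2"):
            raise ValidationError(f"unknown breakpoint variant {breakpoint!r}")
        if frame_offset not in (0, 1, 2):
            raise ValidationError("frame_offset must be 0, 1 or 2")
        seen = set()
        last_gene_rank = -1
        last_ordinal = 0
        for ex in exons:
            key = (ex.gene, ex.name)
            if key in seen:
                raise ValidationError(f"duplicate exon {ex.name}")
            seen.add(key)
            rank = 0 if ex.gene is Gene.BCR else 1
            if rank < last_gene_rank:
                raise ValidationError("BCR exons must precede ABL1 exons")
            if rank != last_gene_rank:
                last_gene_rank = rank
                last_ordinal = 0
            if ex.ordinal <= last_ordinal:
                raise ValidationError(
                    f"exon ordinals out of order at {ex.name} (gene {ex.gene.value})"
                )
            last_ordinal = ex.ordinal

        self.exons = exons
        self.breakpoint = breakpoint
        self.frame_offset = frame_offset
        self.codon_anchor = codon_anchor
        self.sequence = "".join(ex.sequence for ex in exons)
        starts = np.cumsum([0] + [len(ex) for ex in exons])
        self._starts = starts  # len(exons)+1 entries
        self.junctions = tuple(
            Junction(int(starts[i + 1]), exons[i].name, exons[i + 1].name)
            for i in range(len(exons) - 1)
        )

    def __len__(self) -> int:
        return len(self.sequence)

    def exon_at(self, position: int) -> tuple[Exon, int]:
        """Return (exon, offset within exon) for a transcript position."""
        if not 0 <= position < len(self):
            raise IndexError(f"position {position} outside transcript")
        i = int(np.searchsorted(self._starts, position, side="right")) - 1
        return self.exons[i], position - int(self._starts[i])


def build_transcript(
    exons, breakpoint: str, frame_offset: int = 0, codon_anchor: CodonAnchor | None = None
) -> TranscriptModel:
    """Assemble a :class:`TranscriptModel`; validates exon order and content."""
    return TranscriptModel(exons, breakpoint, frame_offset, codon_anchor)


@dataclass
class Amplicon:
    """The PCR product: a contiguous window of the transcript with coordinate maps."""

    transcript: TranscriptModel
    start: int  # transcript coordinate of amplicon position 0
    end: int
    fwd_primer: str
    rev_primer: str
    name: str = "amplicon"
    sequence: str = field(init=False)

    def __post_init__(self) -> None:
        self.sequence = self.transcript.sequence[self.start : self.end]

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def fwd_primer_span(self) -> tuple[int, int]:
        return (0, len(self.fwd_primer))

    @property
    def rev_primer_span(self) -> tuple[int, int]:
        return (len(self) - len(self.rev_primer), len(self))

    @property
    def junctions(self) -> tuple[Junction, ...]:
        """Exon junctions that fall strictly inside the amplicon, in amplicon coords."""
        return tuple(
            Junction(j.position - self.start, j.upstream, j.downstream)
            for j in self.transcript.junctions
            if self.start < j.position < self.end
        )

    # ---- exon map -------------------------------------------------------
    def exon_at(self, position: int) -> tuple[str, int]:
        """(exon name, offset in exon) for an amplicon position."""
        ex, off = self.transcript.exon_at(self.start + position)
        return ex.name, off

    # ---- codon map ------------------------------------------------------
    def _phase(self, position: int) -> int:
        return (self.start + position + self.transcript.frame_offset) % 3

    def codon_at(self, position: int) -> tuple[Gene, int, int]:
        """(gene, codon index, position-in-codon) for an amplicon position."""
        anchor = self.transcript.codon_anchor
        if anchor is None:
            raise ValidationError("reference has no codon anchor")
        if not 0 <= position < len(self):
            raise IndexError(f"position {position} outside amplicon")
        tp = self.start + position
        phase = (tp + self.transcript.frame_offset) % 3
        cs = tp - phase
        a_phase = (anchor.position + self.transcript.frame_offset) % 3
        a_cs = anchor.position - a_phase
        idx = anchor.codon + (cs - a_cs) // 3
        gene = self.transcript.exon_at(tp)[0].gene
        return gene, idx, phase

    def codon_span(self, codon_index: int) -> tuple[int, int]:
        """Half-open amplicon interval of a codon; raises if it is incomplete."""
        anchor = self.transcript.codon_anchor
        if anchor is None:
            raise ValidationError("reference has no codon anchor")
        a_phase = (anchor.position + self.transcript.frame_offset) % 3
        a_cs = anchor.position - a_phase
        cs = a_cs + 3 * (codon_index - anchor.codon) - self.start
        if cs < 0 or cs + 3 > len(self):
            raise UntranslatablePosition(
                f"codon {codon_index} is not complete within the amplicon"
            )
        return cs, cs + 3

    def ref_codon(self, codon_index: int) -> str:
        s, e = self.codon_span(codon_index)
        return self.sequence[s:e]


def in_silico_pcr(
    transcript: TranscriptModel, fwd_primer: str, rev_primer: str, name: str = "amplicon"
) -> Amplicon:
    """Reconstruct the PCR product from a primer pair, exact-match only.

    The forward primer must occur exactly once on the sense strand; the
    reverse complement of the reverse primer must occur exactly once
    downstream of it. The product includes both primer sites.
    """
    fwd = fwd_primer.upper().replace(" ", "")
    rev = rev_primer.upper().replace(" ", "")
    if len(fwd) < 10 or len(rev) < 10:
        raise ValidationError("primers must be at least 10 nt")
    seq = transcript.sequence

    fwd_hits = _find_all(seq, fwd)
    if not fwd_hits:
        raise PrimerError("no product: forward primer not found")
    if len(fwd_hits) > 1:
        raise PrimerError("ambiguous product: forward primer matches multiple sites")
    start = fwd_hits[0]

    rc = revcomp(rev)
    rev_hits = [p for p in _find_all(seq, rc) if p > start]
    if not rev_hits:
        raise PrimerError("no product: reverse primer site not found downstream")
    if len(rev_hits) > 1:
        raise PrimerError("ambiguous product: reverse primer matches multiple sites")
    end = rev_hits[0] + len(rc)
    return Amplicon(transcript, start, end, fwd, rev, name=name)


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def annotate_codon(amplicon: Amplicon, position: int) -> tuple[Gene, int, str]:
    """(gene, codon index, reference amino acid) for an amplicon position.

    Raises :class:`UntranslatablePosition` if the codon is clipped by the
    amplicon edge.
    """
    gene, idx, _phase = amplicon.codon_at(position)
    codon = amplicon.ref_codon(idx)  # raises UntranslatablePosition at edges
    return gene, idx, translate(codon)


# ---------------------------------------------------------------------------
# Reference description file (YAML)
# ---------------------------------------------------------------------------

def save_reference(transcript: TranscriptModel, fwd: str, rev: str, path) -> None:
    doc = {
        "breakpoint": transcript.breakpoint,
        "frame_offset": transcript.frame_offset,
        "primers": {"forward": fwd, "reverse": rev},
        "exons": [
            {
                "gene": ex.gene.value,
                "name": ex.name,
                "ordinal": ex.ordinal,
                "sequence": ex.sequence,
            }
            for ex in transcript.exons
        ],
    }
    if transcript.codon_anchor is not None:
        doc["codon_anchor"] = {
            "position": transcript.codon_anchor.position,
            "codon": transcript.codon_anchor.codon,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_reference(path) -> tuple[TranscriptModel, str, str]:
    """Load a reference description file; returns (transcript, fwd primer, rev primer)."""
    doc = yaml.safe_load(Path(path).read_text())
    exons = [
        Exon(Gene(e["gene"]), e["name"], int(e["ordinal"]), e["sequence"].upper())
        for e in doc["exons"]
    ]
    anchor = None
    if "codon_anchor" in doc:
        anchor = CodonAnchor(int(doc["codon_anchor"]["position"]), int(doc["codon_anchor"]["codon"]))
    model = TranscriptModel(exons, doc["breakpoint"], int(doc.get("frame_offset", 0)), anchor)
    primers = doc.get("primers", {})
    return model, primers.get("forward", ""), primers.get("reverse", "")


def load_amplicon(path, name: str = "amplicon") -> Amplicon:
    transcript, fwd, rev = load_reference(path)
    return in_silico_pcr(transcript, fwd, rev, name=name)


# ---------------------------------------------------------------------------
# Synthetic reference
# ---------------------------------------------------------------------------

# Exon lengths of the synthetic p210-like transcript (sum = 1578 for e14a2,
# mirroring the real amplicon length from BCR exon 12 to ABL1 exon 9).
_BCR_LENGTHS = {"BCR-e12": 129, "BCR-e13": 105, "BCR-e14": 75}
_ABL1_LENGTHS = {
    "ABL1-a2": 174, "ABL1-a3": 186, "ABL1-a4": 279, "ABL1-a5": 154,
    "ABL1-a6": 192, "ABL1-a7": 129, "ABL1-a8": 87, "ABL1-a9": 68,
}

# Clinical codons pinned in the synthetic frame so the canonical TKI-resistance
# substitutions exist with their wild-type amino acids. With the anchor below,
# codon c occupies transcript positions [3c-216, 3c-213).
_PINNED_CODONS = {
    253: "TAC",  # Y
    255: "GAA",  # E
    276: "GAT",  # D
    315: "ACT",  # T
    359: "TTT",  # F
    396: "CAT",  # H
}
_SYNTHETIC_ANCHOR = CodonAnchor(position=729, codon=315)

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def synthetic_transcript(breakpoint: str = "e14a2", seed: int = 20150212) -> TranscriptModel:
    """A fully synthetic ~1.6 kb stand-in for the p210 fusion transcript.

    Synthetic: the exon structure, lengths and codon anchors mimic the real
    1578 bp amplicon (BCR e12 -> ABL1 a9, e13a2/e14a2 breakpoint variants,
    clinical codons 253/255/276/315/359/396 carrying their wild-type amino
    acids), but the sequence itself is generated from a fixed seed and has no
    premature stop codons in frame. It lets every analysis run without the
    (undeposited) human reference mRNAs.
    """
    rng = np.random.default_rng(seed)
    n_codons = 1578 // 3
    codons = [_NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), n_codons)]
    for codon_idx, triplet in _PINNED_CODONS.items():
        codons[codon_idx - _SYNTHETIC_ANCHOR.codon + 729 // 3] = triplet
    seq = "".join(codons)

    lengths = dict(_BCR_LENGTHS)
    if breakpoint == "e13a2":
        del lengths["BCR-e14"]
    lengths.update(_ABL1_LENGTHS)
    if breakpoint == "e13a2":
        # drop the e14 block from the sequence so ABL1 content is shared
        e12e13 = _BCR_LENGTHS["BCR-e12"] + _BCR_LENGTHS["BCR-e13"]
        seq = seq[:e12e13] + seq[e12e13 + _BCR_LENGTHS["BCR-e14"]:]

    exons, offset = [], 0
    for name, ln in lengths.items():
        gene = Gene.BCR if name.startswith("BCR") else Gene.ABL1
        ordinal = int("".join(ch for ch in name.split("-")[1] if ch.isdigit()))
        exons.append(Exon(gene, name, ordinal, seq[offset : offset + ln]))
        offset += ln

    shift = 0 if breakpoint == "e14a2" else _BCR_LENGTHS["BCR-e14"]
    anchor = CodonAnchor(_SYNTHETIC_ANCHOR.position - shift, _SYNTHETIC_ANCHOR.codon)
    model = TranscriptModel(exons, breakpoint, frame_offset=0, codon_anchor=anchor)

    fwd, rev = synthetic_primers(model)
    assert len(_find_all(model.sequence, fwd)) == 1
    assert len(_find_all(model.sequence, revcomp(rev))) == 1
    return model


def synthetic_primers(transcript: TranscriptModel) -> tuple[str, str]:
    """Terminal primer pair of the synthetic reference (23 nt fwd / 25 nt rev,
    matching the printed assay primer lengths)."""
    return transcript.sequence[:23], revcomp(transcript.sequence[-25:])


def synthetic_amplicon(breakpoint: str = "e14a2") -> Amplicon:
    """In-silico PCR product of the synthetic reference (1578 bp for e14a2)."""
    model = synthetic_transcript(breakpoint)
    fwd, rev = synthetic_primers(model)
    return in_silico_pcr(model, fwd, rev, name=f"synthetic-p210-{breakpoint}")
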
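"""Splice-isoform detection from full-length reads.

Full-length reads (spanning primer to primer) are grouped into isoforms and
a group is reported once at least two independent reads support it. Two
grouping modes are provided:

* ``strict`` — the literal rule: reads are identical over their entire
  length (after orientation normalization). At realistic CCS error rates
  near-duplicate full reads are rare, so this mode is mainly useful on
  error-free or consensus data.
* ``event`` (default) — reads are grouped by their indel event structure
  (alignment indel operations of at least ``min_event_length`` nt; point
  errors and 1-2 nt indel noise are ignored), which preserves the >= 2-read
  support rule while remaining usable at CCS-like accuracy.

Point substitutions never define an isoform: variant and isoform analyses
are orthogonal outputs of the same alignments.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import pandas as pd

from .refmodel import Amplicon, translate


@dataclass(frozen=True)
class IsoformEvent:
    """One splice event: a junction insertion or an intra-amplicon deletion.

    ``truncating`` means the event-modified frame hits a stop codon before
    the amplicon's final codon.
    """

    kind: str  # 'insertion' | 'deletion'
    position: int  # insertion point / deletion start, amplicon coords
    length: int
    sequence: str | None = None  # insertions only
    anchor: str | None = None  # nearest junction name, if within +-3 nt
    frame_effect: str | None = None  # 'in-frame' | 'frameshift'
    truncating: bool | None = None

    @property
    def interval(self) -> tuple[int, int]:
        if self.kind == "deletion":
            return (self.position, self.position + self.length)
        return (self.position, self.position)

    def coordinate_label(self) -> str:
        if self.kind == "insertion":
            return f"ins{self.length}@{self.position + 1}"
        return f"del{self.length}@{self.position + 1}"


@dataclass
class IsoformRecord:
    """A reported isoform: its events, support and frequency."""

    events: tuple[IsoformEvent, ...]
    support: int
    frequency: float  # % of full-length reads
    label: str
    read_ids: tuple[str, ...] = field(default=(), repr=False)


@dataclass
class IsoformTable:
    records: list[IsoformRecord]
    n_full_length: int
    mode: str

    @property
    def unassigned_frequency(self) -> float:
        return 100.0 - sum(r.frequency for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": r.label,
                    "events": ";".join(e.coordinate_label() for e in r.events) or ".",
                    "support": r.support,
                    "frequency_pct": round(r.frequency, 4),
                }
                for r in self.records
            ],
            columns=["label", "events", "support", "frequency_pct"],
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "full_length_reads": self.n_full_length,
                "unassigned_pct": round(self.unassigned_frequency, 4),
                "isoforms": [
                    {
                        "label": r.label,
                        "support": r.support,
                        "frequency_pct": round(r.frequency, 4),
                        "events": [
                            {
                                "kind": e.kind,
                                "position": e.position,
                                "length": e.length,
                                "anchor": e.anchor,
                                "frame_effect": e.frame_effect,
                                "truncating": e.truncating,
                            }
                            for e in r.events
                        ],
                    }
                    for r in self.records
                ],
            },
            indent=2,
        )


def detect_isoforms(
    alignments,
    amplicon: Amplicon,
    mode: str = "event",
    min_support: int = 2,
    min_event_length: int = 3,
) -> IsoformTable:
    """Group full-length alignments into isoforms (>= ``min_support`` reads).

    Frequencies use all full-length reads as the denominator, so minor
    unreported groups show up as unassigned mass rather than inflating the
    reported isoforms.
    """
    full = [a for a in alignments if a.full_length]
    if not full:
        raise ValueError("isoform detection requires full-length reads")
    if mode not in ("strict", "event"):
        raise ValueError(f"unknown isoform mode {mode!r}")
    n = len(full)

    groups: dict = defaultdict(list)
    if mode == "strict":
        for a in full:
            groups[a.oriented_sequence].append(a)
    else:
        for a in full:
            key = tuple((k, p, ln) for k, p, ln, _ in a.events(min_event_length))
            groups[key].append(a)

    records: list[IsoformRecord] = []
    for key, members in groups.items():
        if len(members) < min_support:
            continue
        rep = members[0]
        raw = rep.events(min_event_length)
        if mode == "event":
            # majority inserted sequence across supporting reads, per event
            events = []
            for idx, (kind, pos, ln, _seq) in enumerate(raw):
                seq = None
                if kind == "insertion":
                    seqs = Counter(
                        m.events(min_event_length)[idx][3] for m in members
                    )
                    seq = seqs.most_common(1)[0][0]
                events.append(IsoformEvent(kind, pos, ln, seq))
        else:
            events = [IsoformEvent(k, p, ln, s) for k, p, ln, s in raw]
        events = tuple(annotate_event(e, amplicon) for e in events)
        records.append(
            IsoformRecord(
                events=events,
                support=len(members),
                frequency=100.0 * len(members) / n,
                label=label_for(events),
                read_ids=tuple(m.read_id for m in members),
            )
        )
    records.sort(key=lambda r: (-r.support, r.label))
    return IsoformTable(records, n, mode)


def annotate_event(event: IsoformEvent, amplicon: Amplicon, junction_tolerance: int = 3) -> IsoformEvent:
    """Anchor an event to the exon structure and flag frame/truncation.

    Insertions within ``junction_tolerance`` nt of an exon junction are
    anchored to it (alignment left-normalization can shift the insertion
    point by a few bases when the insert shares terminal bases with the
    reference). Truncation is decided by translating the event-modified
    amplicon and scanning for a stop before the final codon.
    """
    anchor = None
    if event.kind == "insertion":
        for j in amplicon.junctions:
            if abs(j.position - event.position) <= junction_tolerance:
                anchor = f"{j.upstream}/{j.downstream}"
                break
    else:
        lo, hi = event.interval
        ex_lo = amplicon.exon_at(lo)[0]
        ex_hi = amplicon.exon_at(hi - 1)[0]
        anchor = ex_lo if ex_lo == ex_hi else f"{ex_lo}..{ex_hi}"
    frame = "in-frame" if event.length % 3 == 0 else "frameshift"

    seq = amplicon.sequence
    if event.kind == "insertion":
        ins = event.sequence or ""
        modified = seq[: event.position] + ins + seq[event.position :]
    else:
        modified = seq[: event.position] + seq[event.position + event.length :]
    phase0 = (3 - amplicon._phase(0)) % 3  # first complete codon start
    aa = translate(modified[phase0:])
    truncating = "*" in aa[:-1] if aa else False
    return replace(event, anchor=anchor, frame_effect=frame, truncating=truncating)


def label_for(events) -> str:
    """Isoform label: 'WT' for no events, '<len>INS' for a single
    junction-anchored insertion, coordinate labels otherwise."""
    events = tuple(events)
    if not events:
        return "WT"
    if len(events) == 1 and events[0].kind == "insertion" and events[0].anchor:
        return f"{events[0].length}INS"
    return "+".join(e.coordinate_label() for e in events)


def write_isoform_fasta(table: IsoformTable, amplicon: Amplicon, path) -> None:
    """Per-isoform consensus sequences: the amplicon with each record's
    events applied."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = []
    for r in table.records:
        seq = amplicon.sequence
        for e in sorted(r.events, key=lambda e: e.position, reverse=True):
            if e.kind == "deletion":
                seq = seq[: e.position] + seq[e.position + e.length :]
            else:
                seq = seq[: e.position] + (e.sequence or "") + seq[e.position :]
        recs.append(
            SeqRecord(Seq(seq), id=r.label, description=f"support={r.support}")
        )
    SeqIO.write(recs, str(path), "fasta")


def write_events_bed(table: IsoformTable, amplicon: Amplicon, path) -> None:
    """Events as BED intervals in amplicon space (insertions as zero-length)."""
    with open(path, "w") as fh:
        for r in table.records:
            for e in r.events:
                lo, hi = e.interval
                name = f"{r.label}:{e.coordinate_label()}"
                fh.write(f"{amplicon.name}\t{lo}\t{hi}\t{name}\t{r.support}\t+\n")
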
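"""CCS read container and FASTA/FASTQ I/O (via Biopython)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class ReadTruth:
    """Hidden simulation truth attached to a read (test oracle only)."""

    clone: str
    strand: str  # orientation the read was emitted in
    chimera: tuple[str, str, float] | None = None  # (prefix clone, suffix clone, breakpoint frac)

    @property
    def clones(self) -> tuple[str, ...]:
        if self.chimera is not None:
            return (self.chimera[0], self.chimera[1])
        return (self.clone,)


@dataclass
class CcsRead:
    """One single-molecule circular-consensus read."""

    id: str
    sequence: str
    qualities: str | None = None
    truth: ReadTruth | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id}: empty sequence")
        if not set(self.sequence) <= _ALPHABET:
            raise ValueError(f"read {self.id}: alphabet must be ACGTN")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fastx(path) -> list[CcsRead]:
    """Read FASTA or FASTQ (by extension; .fq/.fastq treated as FASTQ)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fq", ".fastq") else "fasta"
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        qual = None
        if fmt == "fastq":
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(CcsRead(rec.id, str(rec.seq).upper(), qual))
    return reads


def _as_target(path):
    return path if hasattr(path, "write") else str(path)


def write_fastq(reads, path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        qual = r.qualities or "I" * len(r)
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        records.append(rec)
    SeqIO.write(records, _as_target(path), "fastq")


def write_fasta(reads, path) -> None:
    records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in reads]
    SeqIO.write(records, _as_target(path), "fasta")


def write_truth_sidecar(reads, path) -> None:
    """Tab-separated truth table (simulation oracle; not a pipeline input)."""
    with open(path, "w") as fh:
        fh.write("read_id\tclone\tstrand\tchimera\n")
        for r in reads:
            t = r.truth
            chim = ""
            if t and t.chimera:
                chim = f"{t.chimera[0]}:{t.chimera[1]}:{t.chimera[2]:.4f}"
            fh.write(f"{r.id}\t{t.clone if t else ''}\t{t.strand if t else ''}\t{chim}\n")


def read_truth_sidecar(path) -> dict[str, ReadTruth]:
    truths = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            rid, clone, strand, chim = line.rstrip("\n").split("\t")
            chimera = None
            if chim:
                a, b, f = chim.split(":")  # clone names never contain ':'
                chimera = (a, b, float(f))
            truths[rid] = ReadTruth(clone, strand, chimera)
    return truths
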
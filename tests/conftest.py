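from __future__ import annotations

import numpy as np
import pytest

from ampliclone import refmodel, simulate
from ampliclone.refmodel import CodonAnchor, Exon, Gene, build_transcript, in_silico_pcr


@pytest.fixture(scope="session")
def amplicon():
    """The shipped synthetic p210-like e14a2 amplicon (1578 bp)."""
    return refmodel.synthetic_amplicon()


@pytest.fixture(scope="session")
def panel(amplicon):
    return simulate.resistance_panel(amplicon)


@pytest.fixture(scope="session")
def mixture(amplicon):
    return simulate.patient_like_mixture(amplicon)


def make_toy_transcript(frame_offset: int = 0):
    """Small two-gene transcript with a codon anchor, for coordinate tests."""
    rng = np.random.default_rng(99)
    bases = "ACGT"
    seqs = ["".join(bases[b] for b in rng.integers(0, 4, ln)) for ln in (60, 45, 90)]
    exons = [
        Exon(Gene.BCR, "BCR-e13", 13, seqs[0]),
        Exon(Gene.BCR, "BCR-e14", 14, seqs[1]),
        Exon(Gene.ABL1, "ABL1-a2", 2, seqs[2]),
    ]
    # anchor: position 120 carries codon 50
    return build_transcript(exons, "e14a2", frame_offset, CodonAnchor(120, 50))


@pytest.fixture
def toy_transcript():
    return make_toy_transcript()


@pytest.fixture
def toy_amplicon(toy_transcript):
    seq = toy_transcript.sequence
    return in_silico_pcr(toy_transcript, seq[:15], refmodel.revcomp(seq[-15:]))


def random_dna(rng, length: int) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, length))
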
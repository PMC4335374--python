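"""Synthetic CCS read generator: clone mixtures, error model, chimeras, dilutions.

This module is the testbed standing in for patient samples: a sample is a
mixture of clones (each a set of point mutations and/or isoform events on the
amplicon), reads are drawn per clone fraction, sequencing error is injected
i.i.d. per base (substitutions uniform over the three alternatives), about
half the reads are emitted reverse-complemented, and an optional chimera
model splices two independently drawn clone templates at a uniform breakpoint
to emulate PCR-mediated recombination. Every read carries its hidden truth
(clone of origin, orientation, chimera structure) for test oracles.

Default error rates (substitution 0.013, insertion 0.010, deletion 0.005 per
base) are CCS-like and deliberately stress the caller at the 0.5-1% detection
limits probed by the dilution series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .refmodel import Amplicon, annotate_codon, translate
from .reads import CcsRead, ReadTruth

_DECODE = np.frombuffer(b"ACGT", np.uint8)
_CODE = np.zeros(256, np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


class SimulationError(ValueError):
    """A clone/sample specification violates its invariants."""


@dataclass(frozen=True)
class PointMutationSpec:
    """A substitution on the amplicon, e.g. a T315I-like change."""

    position: int
    ref: str
    alt: str
    label: str

    def validate(self, amplicon: Amplicon) -> None:
        if amplicon.sequence[self.position] != self.ref:
            raise SimulationError(
                f"{self.label}: reference base at {self.position} is "
                f"{amplicon.sequence[self.position]}, not {self.ref}"
            )
        if self.alt == self.ref:
            raise SimulationError(f"{self.label}: alt equals ref")


@dataclass(frozen=True)
class IsoformEventSpec:
    """A splice-like event: junction insertion or intra-amplicon deletion."""

    kind: str  # 'insertion' | 'deletion'
    position: int  # insertion point / deletion start (amplicon coords)
    length: int
    sequence: str | None = None  # insertions only

    def validate(self, amplicon: Amplicon) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise SimulationError(f"unknown event kind {self.kind!r}")
        if self.length < 1:
            raise SimulationError("event length must be >= 1")
        if self.kind == "insertion":
            if self.sequence is None or len(self.sequence) != self.length:
                raise SimulationError("insertion requires a sequence of the stated length")
            if not 0 <= self.position <= len(amplicon):
                raise SimulationError("insertion anchor outside amplicon")
        else:
            if not (0 <= self.position and self.position + self.length <= len(amplicon)):
                raise SimulationError("deletion outside amplicon")


@dataclass(frozen=True)
class CloneSpec:
    """One clone: its mutations/events and its fraction of the sample."""

    name: str
    fraction: float
    mutations: tuple[PointMutationSpec, ...] = ()
    events: tuple[IsoformEventSpec, ...] = ()

    def validate(self, amplicon: Amplicon) -> None:
        if ":" in self.name:
            raise SimulationError("clone names must not contain ':'")
        if not 0.0 <= self.fraction <= 1.0:
            raise SimulationError(f"clone {self.name}: fraction outside [0, 1]")
        positions = [m.position for m in self.mutations]
        if len(positions) != len(set(positions)):
            raise SimulationError(f"clone {self.name}: conflicting mutations at one position")
        for m in self.mutations:
            m.validate(amplicon)
        for e in self.events:
            e.validate(amplicon)


@dataclass(frozen=True)
class ErrorModel:
    """Per-base i.i.d. error rates (each in [0, 0.2])."""

    substitution: float = 0.013
    insertion: float = 0.010
    deletion: float = 0.005

    def __post_init__(self) -> None:
        for rate in (self.substitution, self.insertion, self.deletion):
            if not 0.0 <= rate <= 0.2:
                raise SimulationError("error rates must lie in [0, 0.2]")


NO_ERRORS = ErrorModel(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ChimeraModel:
    """Single-switch PCR recombination: with probability ``rate`` a read takes
    its prefix from one clone template and its suffix from another, at a
    breakpoint uniform over the molecule."""

    rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise SimulationError("chimera rate must lie in [0, 1]")


def clone_template(amplicon: Amplicon, clone: CloneSpec) -> str:
    """Amplicon sequence with the clone's mutations and events applied."""
    clone.validate(amplicon)
    seq = list(amplicon.sequence)
    for m in clone.mutations:
        seq[m.position] = m.alt
    for e in sorted(clone.events, key=lambda e: e.position, reverse=True):
        if e.kind == "deletion":
            del seq[e.position : e.position + e.length]
        else:
            seq[e.position:e.position] = list(e.sequence)
    return "".join(seq)


def _inject_errors(template: np.ndarray, error_model: ErrorModel, rng) -> np.ndarray:
    t = template
    if error_model.deletion > 0:
        t = t[rng.random(t.size) >= error_model.deletion]
    if error_model.substitution > 0:
        t = t.copy()
        mask = rng.random(t.size) < error_model.substitution
        k = int(mask.sum())
        if k:
            t[mask] = (t[mask] + rng.integers(1, 4, k, dtype=np.uint8)) % 4
    if error_model.insertion > 0:
        where = np.flatnonzero(rng.random(t.size + 1) < error_model.insertion)
        if where.size:
            t = np.insert(t, where, rng.integers(0, 4, where.size, dtype=np.uint8))
    return t


def simulate_sample(
    amplicon: Amplicon,
    clones,
    n_reads: int,
    error_model: ErrorModel = ErrorModel(),
    chimera: ChimeraModel | None = None,
    seed: int = 0,
    id_prefix: str = "r",
) -> list[CcsRead]:
    """Draw ``n_reads`` CCS reads from a clone mixture.

    Clone fractions must sum to 1 (±1e-9). Fully reproducible given ``seed``;
    read truth (clone, strand, chimera structure) is attached to each read.
    """
    clones = list(clones)
    if n_reads < 1:
        raise SimulationError("n_reads must be >= 1")
    fractions = np.array([c.fraction for c in clones], float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise SimulationError(f"clone fractions sum to {fractions.sum():.6f}, not 1")
    for c in clones:
        c.validate(amplicon)
    names = [c.name for c in clones]
    if len(set(names)) != len(names):
        raise SimulationError("duplicate clone names")

    templates = [_CODE[np.frombuffer(clone_template(amplicon, c).encode(), np.uint8)] for c in clones]
    rng = np.random.default_rng(seed)
    chimera_rate = chimera.rate if chimera else 0.0

    idx = rng.choice(len(clones), n_reads, p=fractions)
    is_chimera = rng.random(n_reads) < chimera_rate
    partner = rng.choice(len(clones), n_reads, p=fractions)
    bp_frac = rng.random(n_reads)
    flip = rng.random(n_reads) < 0.5

    reads = []
    for i in range(n_reads):
        a = int(idx[i])
        if is_chimera[i]:
            b = int(partner[i])
            f = float(bp_frac[i])
            ta, tb = templates[a], templates[b]
            cut_a = int(round(f * ta.size))
            cut_b = int(round(f * tb.size))
            mol = np.concatenate([ta[:cut_a], tb[cut_b:]])
            truth = ReadTruth(names[a], "-" if flip[i] else "+", (names[a], names[b], f))
        else:
            mol = templates[a]
            truth = ReadTruth(names[a], "-" if flip[i] else "+")
        out = _inject_errors(mol, error_model, rng)
        if flip[i]:
            out = (3 - out)[::-1]
        seq = bytes(_DECODE[out]).decode("ascii")
        reads.append(CcsRead(f"{id_prefix}{i:06d}", seq, "I" * len(seq), truth))
    return reads


# ---------------------------------------------------------------------------
# Presets mirroring the assay's resistance panel and isoform events
# ---------------------------------------------------------------------------

_PANEL = {
    # label: (codon, position-in-codon, alt base)
    "Y253H": (253, 0, "C"),
    "E255V": (255, 1, "T"),
    "D276G": (276, 1, "G"),
    "T315I": (315, 1, "T"),
    "F359C": (359, 1, "G"),
    "H396R": (396, 1, "G"),
}


def substitution_at_codon(
    amplicon: Amplicon, codon: int, pos_in_codon: int, alt: str, label: str | None = None
) -> PointMutationSpec:
    """Build a substitution spec from a clinical codon coordinate."""
    s, _ = amplicon.codon_span(codon)
    position = s + pos_in_codon
    ref = amplicon.sequence[position]
    if label is None:
        _, _, ref_aa = annotate_codon(amplicon, position)
        cod = list(amplicon.ref_codon(codon))
        cod[pos_in_codon] = alt
        label = f"{ref_aa}{codon}{translate(''.join(cod))}"
    return PointMutationSpec(position, ref, alt, label)


def resistance_panel(amplicon: Amplicon) -> dict[str, PointMutationSpec]:
    """The six TKI-resistance-like substitutions available on a reference whose
    codon anchors pin the clinical numbering (e.g. the synthetic reference)."""
    return {
        label: substitution_at_codon(amplicon, codon, pic, alt, label)
        for label, (codon, pic, alt) in _PANEL.items()
    }


def junction_insertion(
    amplicon: Amplicon, upstream: str, downstream: str, length: int, seed: int = 35
) -> IsoformEventSpec:
    """An insertion of ``length`` nt at a named exon junction (e.g. the
    recurrent 35 nt insertion between ABL1 exons 8 and 9)."""
    for j in amplicon.junctions:
        if j.upstream == upstream and j.downstream == downstream:
            rng = np.random.default_rng(seed)
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, length))
            return IsoformEventSpec("insertion", j.position, length, seq)
    raise SimulationError(f"no junction {upstream}/{downstream} in amplicon")


def patient_like_mixture(amplicon: Amplicon) -> list[CloneSpec]:
    """Three-clone mixture mirroring the assayed patient sample used for the
    dilution experiment: a dominant primary-mutation clone (91.8%), a minor
    independent secondary-mutation clone (4.2%) and a wild-type rest (4.0%)."""
    panel = resistance_panel(amplicon)
    return [
        CloneSpec("primary", 0.918, (panel["T315I"],)),
        CloneSpec("secondary", 0.042, (panel["F359C"],)),
        CloneSpec("none", 0.040),
    ]


# ---------------------------------------------------------------------------
# Dilution series
# ---------------------------------------------------------------------------

@dataclass
class DilutionSample:
    """One simulated dilution point."""

    mixing_fraction: float  # proportion of the mutant sample in the mix
    expected: dict[str, float]  # mutation label -> expected allele fraction
    reads: list[CcsRead] = field(repr=False)
    seed: int = 0


@dataclass
class DilutionSeries:
    samples: list[DilutionSample]

    def __post_init__(self) -> None:
        fracs = [s.mixing_fraction for s in self.samples]
        if any(b >= a for a, b in zip(fracs, fracs[1:])):
            raise SimulationError("dilution fractions must be strictly decreasing")

    def __iter__(self):
        return iter(self.samples)

    def __len__(self):
        return len(self.samples)


def make_dilution_series(
    amplicon: Amplicon,
    mutant_clones,
    fractions,
    n_reads: int,
    error_model: ErrorModel = ErrorModel(),
    chimera: ChimeraModel | None = None,
    seed: int = 0,
    diluent_name: str = "diluent-wt",
) -> DilutionSeries:
    """Serially dilute a mutant clone mixture into wild type.

    ``fractions`` are the mixing proportions of the mutant sample, strictly
    decreasing, each in (0, 1]; a fraction of 1.0 is the undiluted sample.
    Every clone of the mutant mixture is scaled by the mixing proportion and
    the remainder is wild-type diluent. Sub-seeds are derived
    deterministically from ``seed``.
    """
    fractions = list(fractions)
    if not fractions:
        raise SimulationError("empty fraction list")
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise SimulationError("fractions must lie in (0, 1]")
    if any(b >= a for a, b in zip(fractions, fractions[1:])):
        raise SimulationError("fractions must be strictly decreasing")
    mutant_clones = list(mutant_clones)
    if any(c.name == diluent_name for c in mutant_clones):
        raise SimulationError(f"clone name {diluent_name!r} is reserved for the diluent")

    sub_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, len(fractions))
    samples = []
    for f, sub_seed in zip(fractions, sub_seeds):
        scaled = [
            CloneSpec(c.name, c.fraction * f, c.mutations, c.events) for c in mutant_clones
        ]
        rest = 1.0 - sum(c.fraction for c in scaled)
        if rest > 1e-12:
            scaled.append(CloneSpec(diluent_name, rest))
        expected: dict[str, float] = {}
        for c in scaled:
            for m in c.mutations:
                expected[m.label] = expected.get(m.label, 0.0) + c.fraction
        reads = simulate_sample(
            amplicon, scaled, n_reads, error_model, chimera, seed=int(sub_seed)
        )
        samples.append(DilutionSample(f, expected, reads, seed=int(sub_seed)))
    return DilutionSeries(samples)
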
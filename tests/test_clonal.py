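"""Per-molecule phasing: the perfect-window rule, composition, chimera diagnostics."""

import numpy as np
import pytest

from ampliclone import simulate
from ampliclone.align import align_read, align_reads
from ampliclone.clonal import (
    ReadSignature,
    chimera_diagnostic,
    composition,
    read_signature,
    signatures_for,
)
from ampliclone.reads import CcsRead
from ampliclone.simulate import ChimeraModel, CloneSpec, NO_ERRORS, simulate_sample
from ampliclone.variants import VariantCall, annotate_variant

from _oracles import binomial_sd


def call_for(amplicon, m):
    """Annotated VariantCall for a simulated mutation spec."""
    return annotate_variant(
        VariantCall(m.position, m.ref, m.alt, 100, 1000, 0.1, 1e-9), amplicon
    )


@pytest.fixture(scope="module")
def t315i_call(amplicon, panel):
    return call_for(amplicon, panel["T315I"])


@pytest.fixture(scope="module")
def f359c_call(amplicon, panel):
    return call_for(amplicon, panel["F359C"])


def read_with(amplicon, substitutions):
    s = list(amplicon.sequence)
    for pos, base in substitutions:
        s[pos] = base
    return CcsRead("r", "".join(s))


def other_base(amplicon, pos, *avoid):
    banned = {amplicon.sequence[pos], *avoid}
    return next(b for b in "ACGT" if b not in banned)


class TestWindowRule:
    def test_perfect_alt_read_gets_signature(self, amplicon, t315i_call):
        read = read_with(amplicon, [(t315i_call.position, t315i_call.alt)])
        aln = align_read(read, amplicon)
        sig = read_signature(aln, [t315i_call])
        assert sig.signature == frozenset({"T315I"})

    def test_perfect_ref_read_gets_empty_signature(self, amplicon, t315i_call):
        aln = align_read(CcsRead("r", amplicon.sequence), amplicon)
        sig = read_signature(aln, [t315i_call])
        assert sig.signature == frozenset()

    def test_mismatch_five_bases_away_excludes(self, amplicon, t315i_call):
        pos = t315i_call.position
        read = read_with(
            amplicon,
            [(pos, t315i_call.alt), (pos + 5, other_base(amplicon, pos + 5))],
        )
        sig = read_signature(align_read(read, amplicon), [t315i_call])
        assert sig.signature is None
        assert sig.status["T315I"] == "excluded"

    def test_mismatch_fifteen_bases_away_keeps(self, amplicon, t315i_call):
        pos = t315i_call.position
        read = read_with(
            amplicon,
            [(pos, t315i_call.alt), (pos + 15, other_base(amplicon, pos + 15))],
        )
        sig = read_signature(align_read(read, amplicon), [t315i_call])
        assert sig.signature == frozenset({"T315I"})

    @pytest.mark.parametrize("offset", [-11, -10, 10, 11])
    def test_window_boundary_enumeration(self, amplicon, t315i_call, offset):
        pos = t315i_call.position
        read = read_with(
            amplicon,
            [(pos, t315i_call.alt), (pos + offset, other_base(amplicon, pos + offset))],
        )
        sig = read_signature(align_read(read, amplicon), [t315i_call])
        if abs(offset) <= 10:
            assert sig.signature is None
        else:
            assert sig.signature == frozenset({"T315I"})

    def test_third_allele_at_site_excludes(self, amplicon, t315i_call):
        pos = t315i_call.position
        third = other_base(amplicon, pos, t315i_call.alt)
        read = read_with(amplicon, [(pos, third)])
        sig = read_signature(align_read(read, amplicon), [t315i_call])
        assert sig.status["T315I"] == "excluded"

    def test_deletion_in_window_excludes(self, amplicon, t315i_call):
        pos = t315i_call.position
        s = amplicon.sequence
        read = CcsRead("r", s[: pos + 4] + s[pos + 5 :])  # 1 nt deletion at +4
        sig = read_signature(align_read(read, amplicon), [t315i_call])
        assert sig.signature is None

    def test_unaligned_variant_position_excludes(self, amplicon, t315i_call):
        read = CcsRead("r", amplicon.sequence[: t315i_call.position - 200])
        sig = read_signature(align_read(read, amplicon), [t315i_call])
        assert sig.status["T315I"] == "excluded"

    def test_widening_window_never_gains_evaluable_reads(self, amplicon, panel, mixture):
        reads = simulate_sample(amplicon, mixture, 400, seed=31)
        alns, _ = align_reads(reads, amplicon)
        calls = [call_for(amplicon, panel["T315I"])]
        counts = []
        for w in (2, 5, 10, 20, 40):
            sigs = signatures_for(alns, calls, window_half_width=w)
            counts.append(sum(s.evaluable for s in sigs))
        assert counts == sorted(counts, reverse=True)


def sig(read_id, labels, all_labels):
    status = {lbl: ("alt" if lbl in labels else "ref") for lbl in all_labels}
    return ReadSignature(read_id, status, frozenset(labels))


class TestComposition:
    def test_independent_pair(self):
        labels = ["A", "B"]
        sigs = (
            [sig(f"a{i}", {"A"}, labels) for i in range(90)]
            + [sig(f"b{i}", {"B"}, labels) for i in range(5)]
            + [sig(f"w{i}", set(), labels) for i in range(5)]
        )
        table = composition(sigs)
        assert {s: n for s, n, _ in table.rows} == {
            frozenset({"A"}): 90, frozenset({"B"}): 5, frozenset(): 5
        }
        assert table.rows[0][0] == frozenset({"A"})  # sorted by descending count
        assert {s: f for s, _, f in table.rows} == {
            frozenset({"A"}): pytest.approx(90.0),
            frozenset({"B"}): pytest.approx(5.0),
            frozenset(): pytest.approx(5.0),
        }
        assert table.pairs[("A", "B")].classification == "independent"

    def test_compound_pair(self):
        labels = ["A", "B"]
        sigs = [sig(f"c{i}", {"A", "B"}, labels) for i in range(50)] + [
            sig(f"w{i}", set(), labels) for i in range(50)
        ]
        table = composition(sigs)
        assert table.pairs[("A", "B")].classification == "compound"

    def test_mixed_when_one_single_below_bar(self):
        labels = ["A", "B"]
        sigs = [sig(f"a{i}", {"A"}, labels) for i in range(99)] + [sig("b0", {"B"}, labels)]
        table = composition(sigs)
        assert table.pairs[("A", "B")].classification == "mixed"

    def test_excluded_reads_reported_not_dropped(self):
        labels = ["A"]
        sigs = [sig(f"a{i}", {"A"}, labels) for i in range(10)]
        sigs.append(ReadSignature("x", {"A": "excluded"}, None))
        table = composition(sigs)
        assert table.evaluable == 10
        assert table.excluded == 1

    def test_zero_evaluable_reads_is_error(self):
        with pytest.raises(ValueError):
            composition([ReadSignature("x", {"A": "excluded"}, None)])

    def test_permutation_invariance(self):
        labels = ["A", "B"]
        sigs = (
            [sig(f"a{i}", {"A"}, labels) for i in range(20)]
            + [sig(f"b{i}", {"B"}, labels) for i in range(10)]
            + [sig(f"w{i}", set(), labels) for i in range(5)]
        )
        t1 = composition(sigs)
        rng = np.random.default_rng(1)
        rng.shuffle(sigs)
        t2 = composition(sigs)
        assert t1.rows == t2.rows
        assert t1.pairs == t2.pairs


class TestCompositionAgainstTruth:
    def test_zero_noise_composition_equals_truth_exactly(self, amplicon, panel):
        clones = [
            CloneSpec("primary", 0.918, (panel["T315I"],)),
            CloneSpec("secondary", 0.042, (panel["F359C"],)),
            CloneSpec("none", 0.040),
        ]
        reads = simulate_sample(amplicon, clones, 2000, NO_ERRORS, seed=32)
        alns, _ = align_reads(reads, amplicon)
        calls = [call_for(amplicon, panel["T315I"]), call_for(amplicon, panel["F359C"])]
        table = composition(signatures_for(alns, calls))
        # brute-force truth-label enumeration
        from collections import Counter

        truth = Counter(r.truth.clone for r in reads)
        expect = {
            frozenset({"T315I"}): truth["primary"],
            frozenset({"F359C"}): truth["secondary"],
            frozenset(): truth["none"],
        }
        got = {s: n for s, n, _ in table.rows}
        assert got == {k: v for k, v in expect.items() if v}
        assert table.excluded == 0
        assert table.pairs[("F359C", "T315I")].classification == "independent"

    def test_noisy_composition_within_three_binomial_sd(self, amplicon, panel):
        clones = [
            CloneSpec("primary", 0.918, (panel["T315I"],)),
            CloneSpec("secondary", 0.042, (panel["F359C"],)),
            CloneSpec("none", 0.040),
        ]
        n = 4000
        reads = simulate_sample(amplicon, clones, n, seed=33)
        alns, _ = align_reads(reads, amplicon)
        calls = [call_for(amplicon, panel["T315I"]), call_for(amplicon, panel["F359C"])]
        table = composition(signatures_for(alns, calls))
        # window exclusion is clone-agnostic, so evaluable fractions track the
        # simulated clone fractions
        for sig_set, frac in [
            (frozenset({"T315I"}), 0.918),
            (frozenset({"F359C"}), 0.042),
            (frozenset(), 0.040),
        ]:
            got = table.frequency_of(sig_set) / 100.0
            assert abs(got - frac) <= 4 * binomial_sd(frac, table.evaluable) + 0.005


class TestChimeraDiagnostic:
    def test_no_double_positives_rate_zero(self):
        labels = ["A", "B"]
        sigs = [sig(f"a{i}", {"A"}, labels) for i in range(50)] + [
            sig(f"b{i}", {"B"}, labels) for i in range(50)
        ]
        d = chimera_diagnostic(composition(sigs), ("A", "B"))
        assert d.double_rate == 0.0
        assert d.expected_by_chance == pytest.approx(0.25)

    def test_co_simulated_pair_cooccurs_at_clone_fraction(self, amplicon, panel):
        clones = [
            CloneSpec("double", 0.3, (panel["T315I"], panel["F359C"])),
            CloneSpec("wt", 0.7),
        ]
        reads = simulate_sample(amplicon, clones, 1500, NO_ERRORS, seed=34)
        alns, _ = align_reads(reads, amplicon)
        calls = [call_for(amplicon, panel["T315I"]), call_for(amplicon, panel["F359C"])]
        table = composition(signatures_for(alns, calls))
        d = chimera_diagnostic(table, ("T315I", "F359C"))
        assert abs(d.double_rate - 0.3) <= 3 * binomial_sd(0.3, table.evaluable)
        assert table.pairs[("F359C", "T315I")].classification == "compound"

    def test_recombination_rate_matches_monte_carlo_oracle(self, amplicon, panel):
        """Pipeline chimera co-occurrence equals a direct truth-level
        Monte-Carlo of the template-switching model."""
        rate = 0.02
        clones = [
            CloneSpec("a", 0.6, (panel["T315I"],)),
            CloneSpec("b", 0.4, (panel["F359C"],)),
        ]
        n = 4000
        reads = simulate_sample(
            amplicon, clones, n, NO_ERRORS, chimera=ChimeraModel(rate), seed=35
        )
        alns, _ = align_reads(reads, amplicon)
        calls = [call_for(amplicon, panel["T315I"]), call_for(amplicon, panel["F359C"])]
        table = composition(signatures_for(alns, calls))
        d = chimera_diagnostic(table, ("T315I", "F359C"))

        # independent Monte-Carlo oracle on the truth model: a chimera carries
        # both mutations iff its breakpoint separates the two sites in the
        # right clone order
        rng = np.random.default_rng(77)
        pos_a = panel["T315I"].position / len(amplicon)
        pos_b = panel["F359C"].position / len(amplicon)
        lo, hi = min(pos_a, pos_b), max(pos_a, pos_b)
        trials = 200_000
        chim = rng.random(trials) < rate
        pre = rng.choice(["a", "b"], trials, p=[0.6, 0.4])
        suf = rng.choice(["a", "b"], trials, p=[0.6, 0.4])
        bp = rng.random(trials)
        double = chim & (pre == "a") & (suf == "b") & (bp > lo) & (bp <= hi)
        # T315I sits before F359C, so prefix clone 'a' + suffix clone 'b'
        expected = double.sum() / trials
        sd = binomial_sd(expected, n)
        assert abs(d.double_rate - expected) <= 3 * sd + 1.0 / n
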
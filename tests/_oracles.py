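"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: the aligner oracle is a
full O(nm) dynamic program over plain Python lists, and the translation
oracle carries its own codon table.
"""

from __future__ import annotations

NEG = float("-inf")


def gotoh_overlap_score(read: str, ref: str, match=2, mismatch=-4, gap_open=-4, gap_extend=-1):
    """Exhaustive affine-gap overlap (semi-global) alignment score.

    Free end gaps on both sequences' prefixes and suffixes; an internal gap
    of length L costs gap_open + L * gap_extend. Full three-state Gotoh with
    all inter-state transitions, no banding.
    """
    n, m = len(read), len(ref)
    go_ge = gap_open + gap_extend
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in read (consumes ref)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (consumes read)
    for j in range(m + 1):
        M[0][j] = 0
    for i in range(n + 1):
        M[i][0] = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if read[i - 1] == ref[j - 1] else mismatch
            best_diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            if best_diag > NEG:
                M[i][j] = best_diag + s
            open_x = max(M[i][j - 1], Y[i][j - 1])
            X[i][j] = max(
                open_x + go_ge if open_x > NEG else NEG,
                X[i][j - 1] + gap_extend if X[i][j - 1] > NEG else NEG,
            )
            open_y = max(M[i - 1][j], X[i - 1][j])
            Y[i][j] = max(
                open_y + go_ge if open_y > NEG else NEG,
                Y[i - 1][j] + gap_extend if Y[i - 1][j] > NEG else NEG,
            )
    best = NEG
    for j in range(m + 1):
        best = max(best, M[n][j], X[n][j], Y[n][j])
    for i in range(n + 1):
        best = max(best, M[i][m], X[i][m], Y[i][m])
    return int(best)


_CODON_TABLE = {}


def _build_codon_table():
    bases = "TCAG"
    amino = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                _CODON_TABLE[b1 + b2 + b3] = amino[i]
                i += 1


_build_codon_table()


def translate_oracle(seq: str) -> str:
    """Standard-code translation from an independent codon table."""
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        out.append(_CODON_TABLE[seq[i : i + 3]])
    return "".join(out)


def has_premature_stop(seq: str, frame_start: int = 0) -> bool:
    """True if the frame from ``frame_start`` hits a stop before its final codon."""
    aa = translate_oracle(seq[frame_start:])
    return "*" in aa[:-1] if aa else False


def binomial_sd(p: float, n: int) -> float:
    return (p * (1.0 - p) / n) ** 0.5
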
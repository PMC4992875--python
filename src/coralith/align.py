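"""Global pairwise alignment and the identity measure used for OTU clustering.

Identity between two amplicon sequences is defined operationally: align
globally under match +1 / mismatch -1 / gap open -2 / gap extend -1 (an
opened gap of length L costs 2 + (L-1)), then count matching columns over
all alignment columns excluding terminal-gap columns. Terminal gaps are
penalised in the score but excluded from the identity denominator, which
keeps the measure stable under ragged amplicon ends.

The traceback is deterministic: ties prefer a substitution column over a
gap-in-second-sequence column over a gap-in-first-sequence column, so a
fixed input pair always yields the same alignment and identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

MATCH = 1
MISMATCH = -1
GAP_OPEN = -2   # cost of the first base of a gap
GAP_EXTEND = -1  # cost of each further base

_NEG = -(10 ** 9)


@dataclass(frozen=True)
class Alignment:
    """A global alignment: two equal-length gapped strings and the score."""

    aligned_a: str
    aligned_b: str
    score: int

    def columns(self) -> list[tuple[str, str]]:
        return list(zip(self.aligned_a, self.aligned_b))


def _forward(a: str, b: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill the three Gotoh matrices (substitution, gap-in-b, gap-in-a)."""
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)

    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Ix = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in b (consumes a)
    Iy = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in a (consumes b)
    M[0, 0] = 0
    if n:
        Ix[1:, 0] = GAP_OPEN + GAP_EXTEND * np.arange(n)
    if m:
        Iy[0, 1:] = GAP_OPEN + GAP_EXTEND * np.arange(m)

    ks = np.arange(m)  # helper index for the in-row gap recurrence
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], MATCH, MISMATCH)
        prev_best = np.maximum(np.maximum(M[i - 1, :m], Ix[i - 1, :m]), Iy[i - 1, :m])
        M[i, 1:] = prev_best + sub
        Ix[i, :] = np.maximum(M[i - 1, :] + GAP_OPEN, Ix[i - 1, :] + GAP_EXTEND)
        # Iy[i, j] = max_{k<j} M[i, k] + GAP_OPEN + GAP_EXTEND*(j-1-k),
        # computed with a running maximum (GAP_EXTEND is per-base linear).
        u = np.maximum.accumulate(M[i, :m] - GAP_EXTEND * ks)
        Iy[i, 1:] = GAP_OPEN + GAP_EXTEND * ks + u
        Iy[i, 0] = _NEG
    return M, Ix, Iy


def align(a: str, b: str) -> Alignment:
    """Optimal global alignment with deterministic tie-breaking."""
    if not a or not b:
        raise InputError("cannot align empty sequences")
    M, Ix, Iy = _forward(a, b)
    i, j = len(a), len(b)

    # state 0 = substitution, 1 = gap in b, 2 = gap in a; preference 0 > 1 > 2
    end_scores = (M[i, j], Ix[i, j], Iy[i, j])
    score = int(max(end_scores))
    state = end_scores.index(score)

    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            want = M[i, j] - s
            i, j = i - 1, j - 1
            if M[i, j] == want:
                state = 0
            elif Ix[i, j] == want:
                state = 1
            else:
                state = 2
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            # close the gap as early as possible (prefer the substitution state)
            closes = M[i - 1, j] + GAP_OPEN == Ix[i, j]
            i -= 1
            state = 0 if closes else 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            closes = M[i, j - 1] + GAP_OPEN == Iy[i, j]
            j -= 1
            state = 0 if closes else 2
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)), score)


def _trim_terminal_gaps(cols: list[tuple[str, str]]) -> list[tuple[str, str]]:
    start, end = 0, len(cols)
    if cols and "-" in cols[0]:
        side = 0 if cols[0][0] == "-" else 1
        while start < end and cols[start][side] == "-":
            start += 1
    if end > start and "-" in cols[end - 1]:
        side = 0 if cols[end - 1][0] == "-" else 1
        while end > start and cols[end - 1][side] == "-":
            end -= 1
    return cols[start:end]


def identity_from_alignment(aln: Alignment) -> float:
    cols = _trim_terminal_gaps(aln.columns())
    if not cols:
        return 0.0
    matches = sum(1 for x, y in cols if x == y and x != "-")
    return matches / len(cols)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in the global alignment of ``a`` and ``b``.

    Symmetric up to the deterministic tie-break; 1.0 for identical inputs.
    Internal gap columns count against identity, terminal-gap columns are
    excluded from the denominator.
    """
    if a == b:
        return 1.0
    return identity_from_alignment(align(a, b))
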
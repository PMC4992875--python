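"""Independent brute-force / plain-Python oracles used across the test suite.

These re-derive expected values from first principles (dict-based dynamic
programming, exhaustive enumeration) without sharing code with the package.
"""

from __future__ import annotations

MATCH, MISMATCH, GO, GE = 1, -1, -2, -1


def oracle_align(a: str, b: str) -> tuple[int, str, str]:
    """Plain-Python affine-gap global alignment.

    Same scoring and tie-break convention as the package documents
    (substitution preferred over gap-in-b over gap-in-a; gaps closed as
    early as possible), but implemented with dictionaries and explicit
    loops rather than vectorised matrices.
    """
    NEG = float("-inf")
    n, m = len(a), len(b)
    # best[(i, j, state)]: state "M" diagonal, "X" gap in b, "Y" gap in a
    best: dict[tuple[int, int, str], float] = {}
    best[(0, 0, "M")] = 0
    best[(0, 0, "X")] = best[(0, 0, "Y")] = NEG
    for i in range(1, n + 1):
        best[(i, 0, "M")] = NEG
        best[(i, 0, "X")] = GO + GE * (i - 1)
        best[(i, 0, "Y")] = NEG
    for j in range(1, m + 1):
        best[(0, j, "M")] = NEG
        best[(0, j, "X")] = NEG
        best[(0, j, "Y")] = GO + GE * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            best[(i, j, "M")] = s + max(
                best[(i - 1, j - 1, "M")],
                best[(i - 1, j - 1, "X")],
                best[(i - 1, j - 1, "Y")],
            )
            best[(i, j, "X")] = max(
                best[(i - 1, j, "M")] + GO, best[(i - 1, j, "X")] + GE
            )
            best[(i, j, "Y")] = max(
                best[(i, j - 1, "M")] + GO, best[(i, j - 1, "Y")] + GE
            )
    final = {st: best[(n, m, st)] for st in "MXY"}
    score = max(final.values())
    state = next(st for st in "MXY" if final[st] == score)  # M > X > Y

    ra: list[str] = []
    rb: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            want = best[(i, j, "M")] - s
            i, j = i - 1, j - 1
            state = next(st for st in "MXY" if best[(i, j, st)] == want)
        elif state == "X":
            ra.append(a[i - 1])
            rb.append("-")
            closes = best[(i - 1, j, "M")] + GO == best[(i, j, "X")]
            i -= 1
            state = "M" if closes else "X"
        else:
            ra.append("-")
            rb.append(b[j - 1])
            closes = best[(i, j - 1, "M")] + GO == best[(i, j, "Y")]
            j -= 1
            state = "M" if closes else "Y"
    return int(score), "".join(reversed(ra)), "".join(reversed(rb))


def oracle_identity(a: str, b: str) -> float:
    """Identity from the oracle alignment, terminal-gap columns excluded."""
    _, ga, gb = oracle_align(a, b)
    cols = list(zip(ga, gb))
    start, end = 0, len(cols)
    if cols and "-" in cols[0]:
        side = 0 if cols[0][0] == "-" else 1
        while start < end and cols[start][side] == "-":
            start += 1
    if end > start and "-" in cols[end - 1]:
        side = 0 if cols[end - 1][0] == "-" else 1
        while end > start and cols[end - 1][side] == "-":
            end -= 1
    cols = cols[start:end]
    if not cols:
        return 0.0
    return sum(1 for x, y in cols if x == y != "-") / len(cols)


def oracle_primer_scan(bases: str, primer: str, spacer_max: int,
                       max_mismatches: int, iupac: dict[str, frozenset[str]]
                       ) -> tuple[bool, int | None, int | None]:
    """Exhaustive offset x mismatch enumeration for primer matching.

    Returns the smallest offset achieving the minimum mismatch count that
    is <= max_mismatches (ties broken by fewest mismatches then smallest
    offset, matching the documented contract).
    """
    candidates: list[tuple[int, int]] = []  # (mismatches, offset)
    for off in range(spacer_max + 1):
        window = bases[off:off + len(primer)]
        if len(window) < len(primer):
            continue
        mm = sum(
            0 if not iupac.get(w, frozenset(w)).isdisjoint(
                iupac.get(p, frozenset(p))) else 1
            for w, p in zip(window, primer)
        )
        if mm <= max_mismatches:
            candidates.append((mm, off))
    if not candidates:
        return False, None, None
    mm, off = min(candidates)
    return True, off, mm


def enumerate_tree_loglik(tree, states: dict[str, int], q01: float, q10: float,
                          root_prior: tuple[float, float]) -> float:
    """Tiny-tree likelihood by summing over all internal-state assignments.

    ``tree`` is a dendropy Tree; exponential transition probabilities are
    computed from the closed form for a 2-state chain.
    """
    import math

    import numpy as np

    def pmat(t: float) -> np.ndarray:
        r = q01 + q10
        if r == 0:
            return np.eye(2)
        pi = np.array([q10 / r, q01 / r])
        e = math.exp(-r * t)
        return np.array([
            [pi[0] + (1 - pi[0]) * e, pi[1] - pi[1] * e],
            [pi[0] - pi[0] * e, pi[1] + (1 - pi[1]) * e],
        ])

    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    total = 0.0
    from itertools import product

    for combo in product((0, 1), repeat=len(internals)):
        assign = {id(nd): s for nd, s in zip(internals, combo)}
        p = root_prior[assign[id(tree.seed_node)]]
        for nd in tree.preorder_node_iter():
            if nd is tree.seed_node:
                continue
            parent_state = assign.get(id(nd.parent_node))
            child_state = (states[nd.taxon.label] if nd.is_leaf()
                           else assign[id(nd)])
            p *= pmat(nd.edge.length)[parent_state, child_state]
        total += p
    return math.log(total)
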
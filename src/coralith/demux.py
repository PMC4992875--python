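"""Marker demultiplexing: adapter read-through stripping and primer routing.

A pooled library yields one R1/R2 pair per sample containing reads from all
four loci mixed together. Two operations tease them apart:

* :func:`strip_readthrough` removes the reverse complement of the opposite
  mate's tailed primer (tail + primer, read through on amplicons shorter
  than the read length) from the 3' end of each read;
* :func:`demultiplex_sample` assigns a read pair to the unique marker whose
  forward primer matches read 1 and whose reverse primer matches read 2,
  tolerating the 0-3 nt heterogeneity spacer and a configurable number of
  IUPAC-aware mismatches. Pairs matching zero or several markers are kept
  in an ``unassigned`` bin, so the output is always a partition of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .markers import IUPAC, MarkerSpec, iupac_mismatches, revcomp, validate_panel
from .records import SequenceRead

#: no biological read-through can start before spacer_max + primer length;
#: 30 is a safe floor for any legal spec and prevents degenerate truncation
READTHROUGH_GUARD = 30

#: minimum number of pattern bases that must remain inside the read for a
#: partial (3'-end) read-through match to count
MIN_READTHROUGH_EVIDENCE = 10


def _pattern_tables(pattern: str) -> np.ndarray:
    """(len(pattern), 256) bool lookup: table[k, byte] = base satisfies code k."""
    table = np.zeros((len(pattern), 256), dtype=bool)
    for k, code in enumerate(pattern):
        exp = IUPAC.get(code, frozenset(code))
        for obs, obs_exp in IUPAC.items():
            if not exp.isdisjoint(obs_exp):
                table[k, ord(obs)] = True
    return table


@dataclass(frozen=True)
class _ReadthroughPattern:
    """Prepared sliding-window matcher for one read-through signature."""

    pattern: str
    table: np.ndarray
    max_mismatches: int


def readthrough_pattern(spec: MarkerSpec, mate: str) -> _ReadthroughPattern:
    """Signature left by reading through the opposite mate's tailed primer.

    The tailed primer is the oligo tail (5') + locus primer (3'); reading
    through the far end of a short amplicon produces its reverse complement:
    rc(primer) followed by rc(tail).
    """
    primer = spec.rev_primer if mate == "forward" else spec.fwd_primer
    pat = revcomp(spec.tail + primer)
    return _ReadthroughPattern(pat, _pattern_tables(pat), spec.max_primer_mismatches)


def _find_readthrough(bases: str, pat: _ReadthroughPattern) -> int | None:
    """Earliest start >= READTHROUGH_GUARD of a (possibly 3'-partial) match."""
    L, P = len(bases), len(pat.pattern)
    if L <= READTHROUGH_GUARD + MIN_READTHROUGH_EVIDENCE:
        return None
    padded = np.frombuffer((bases + "\0" * P).encode(), dtype=np.uint8)
    starts = np.arange(READTHROUGH_GUARD, L - MIN_READTHROUGH_EVIDENCE + 1)
    windows = np.lib.stride_tricks.sliding_window_view(padded, P)[starts]
    ok = pat.table[np.arange(P)[None, :], windows]
    mism = P - ok.sum(axis=1)
    overhang = np.maximum(0, starts + P - L)  # padded positions always mismatch
    mism = mism - overhang
    hit = np.flatnonzero(mism <= pat.max_mismatches)
    if hit.size == 0:
        return None
    return int(starts[hit[0]])


def strip_readthrough(read: SequenceRead, specs: list[MarkerSpec]) -> SequenceRead:
    """Truncate a read at the start of any marker's read-through signature.

    Matches are only honoured at or after position ``READTHROUGH_GUARD``;
    reads with no signature are returned unchanged.
    """
    if not read.bases:
        raise InputError(f"read {read.read_id} is empty")
    cut = None
    for spec in specs:
        pos = _find_readthrough(read.bases, readthrough_pattern(spec, read.mate))
        if pos is not None and (cut is None or pos < cut):
            cut = pos
    return read if cut is None else read.truncated(cut)


def match_primer(bases: str, primer: str, spacer_max: int,
                 max_mismatches: int) -> tuple[bool, int | None, int | None]:
    """Locate ``primer`` after a 0..spacer_max nt spacer.

    Among admissible offsets, the one with the fewest mismatches wins, ties
    going to the smallest offset. Returns (matched, spacer_len, mismatches).
    """
    best: tuple[int, int] | None = None
    for off in range(spacer_max + 1):
        window = bases[off:off + len(primer)]
        if len(window) < len(primer):
            break
        mm = iupac_mismatches(window, primer)
        if mm <= max_mismatches and (best is None or (mm, off) < best):
            best = (mm, off)
    if best is None:
        return False, None, None
    return True, best[1], best[0]


@dataclass
class DemuxResult:
    """Partition of a sample's read pairs into per-marker bins."""

    assigned: dict[str, list[tuple[SequenceRead, SequenceRead]]] = field(default_factory=dict)
    unassigned: list[tuple[SequenceRead, SequenceRead]] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out = {m: len(v) for m, v in self.assigned.items()}
        out["unassigned"] = len(self.unassigned)
        return out

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def demultiplex_sample(pairs: list[tuple[SequenceRead, SequenceRead]],
                       specs: list[MarkerSpec]) -> DemuxResult:
    """Route each pair to the single marker both mates' primers support.

    Assignment requires the marker's forward primer on read 1 AND its
    reverse primer on read 2; conflicting or absent evidence leaves the
    pair unassigned. The marker panel is validated for distinguishability.
    """
    validate_panel(specs)
    result = DemuxResult(assigned={s.name: [] for s in specs})
    for r1, r2 in pairs:
        hits = []
        for spec in specs:
            ok1, _, _ = match_primer(r1.bases, spec.fwd_primer,
                                     spec.spacer_max, spec.max_primer_mismatches)
            ok2, _, _ = match_primer(r2.bases, spec.rev_primer,
                                     spec.spacer_max, spec.max_primer_mismatches)
            if ok1 and ok2:
                hits.append(spec.name)
        if len(hits) == 1:
            result.assigned[hits[0]].append((r1, r2))
        else:
            result.unassigned.append((r1, r2))
    return result
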
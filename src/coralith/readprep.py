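"""Read preparation: 3' trimming, pair merging, quality and primer filters.

The chain mirrors a conventional amplicon QC workflow: fixed-length 3'
trimming of both mates, overlap merging with mismatch-ratio selection,
a mean-Phred filter on the merged sequence (default threshold 35), global
primer trimming that demands the forward primer at the 5' end and the
reverse-complemented reverse primer at the 3' end, and provenance headers
``<sample>.<run>_<serial>`` so one FASTA per marker can pool all samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .markers import MarkerSpec, iupac_mismatches, revcomp
from .records import MergedRead, SequenceRead

#: a mate trimmed below this many bases is dropped rather than merged
MIN_READ_AFTER_TRIM = 30


@dataclass(frozen=True)
class QCParams:
    three_prime_trim: int = 50
    min_overlap: int = 10
    max_overlap_mismatch_ratio: float = 0.25
    mean_quality_threshold: float = 35.0

    def __post_init__(self) -> None:
        if not 0 <= self.mean_quality_threshold <= 41:
            raise InputError("mean_quality_threshold must be in [0, 41]")
        if self.min_overlap < 4:
            raise InputError("min_overlap must be >= 4")
        if self.three_prime_trim < 0:
            raise InputError("three_prime_trim must be >= 0")


@dataclass(frozen=True)
class Rejection:
    reason: str  # too_short | no_overlap | overlap_mismatch | low_quality |
    #              missing_primer | short_after_trim


def trim_three_prime(read: SequenceRead, n: int) -> SequenceRead | None:
    """Drop the last ``n`` bases; returns None (read dropped) below 30 bases."""
    if n < 0:
        raise InputError("trim length must be >= 0")
    if n == 0:
        return read
    remaining = len(read) - n
    if remaining < MIN_READ_AFTER_TRIM:
        return None
    return read.truncated(remaining)


def merge_pair(r1: SequenceRead, r2: SequenceRead,
               params: QCParams) -> MergedRead | Rejection:
    """Overlap-merge a pair; read 2 is reverse-complemented before scanning.

    All overlap lengths >= ``min_overlap`` are scored by mismatch ratio;
    the lowest ratio wins, ties going to the longest overlap. In the
    overlap the higher-quality base is kept, with consensus quality max(Q)
    at agreements and \\|Q1-Q2\\| at disagreements.
    """
    b1 = np.frombuffer(r1.bases.encode(), dtype=np.uint8)
    b2 = np.frombuffer(revcomp(r2.bases).encode(), dtype=np.uint8)
    q1 = np.asarray(r1.quals, dtype=np.int32)
    q2 = np.asarray(r2.quals, dtype=np.int32)[::-1]
    n1, n2 = len(b1), len(b2)
    max_o = min(n1, n2)
    if max_o < params.min_overlap:
        return Rejection("no_overlap")

    best: tuple[float, int, int] | None = None  # (ratio, -overlap, mismatches)
    for o in range(params.min_overlap, max_o + 1):
        mm = int((b1[n1 - o:] != b2[:o]).sum())
        key = (mm / o, -o, mm)
        if best is None or key < best:
            best = key
    ratio, neg_o, _ = best
    o = -neg_o
    if ratio > params.max_overlap_mismatch_ratio:
        return Rejection("overlap_mismatch")

    s1, s2 = n1 - o, o  # r1 suffix start, r2 prefix end
    ov_q1, ov_q2 = q1[s1:], q2[:s2]
    ov_b1, ov_b2 = b1[s1:], b2[:s2]
    take1 = ov_q1 >= ov_q2  # r1 wins quality ties
    cons_b = np.where(take1, ov_b1, ov_b2)
    agree = ov_b1 == ov_b2
    cons_q = np.where(agree, np.maximum(ov_q1, ov_q2), np.abs(ov_q1 - ov_q2))

    bases = (r1.bases[:s1]
             + cons_b.astype(np.uint8).tobytes().decode()
             + revcomp(r2.bases)[o:])
    quals = tuple(int(x) for x in np.concatenate([q1[:s1], cons_q, q2[o:]]))
    return MergedRead(bases=bases, quals=quals,
                      sample_id=r1.sample_id, run_id=r1.run_id)


def mean_quality_filter(m: MergedRead, threshold: float) -> bool:
    """Keep iff the arithmetic mean Phred of the merged read is >= threshold."""
    if not m.quals:
        raise InputError("merged read has no qualities")
    return m.mean_quality >= threshold


def global_primer_trim(m: MergedRead, spec: MarkerSpec) -> MergedRead | Rejection:
    """Require and remove both primers (global-trim enforcement).

    The forward primer must sit within ``spacer_max`` bases of the 5' end
    and the reverse complement of the reverse primer within ``spacer_max``
    bases of the 3' end, each within ``max_primer_mismatches``. Both primer
    copies and flanking spacers are removed; cores shorter than
    ``min_merged_length`` are rejected.
    """
    fwd, rev_rc = spec.fwd_primer, revcomp(spec.rev_primer)
    L, Lf, Lr = len(m.bases), len(fwd), len(rev_rc)

    best5: tuple[int, int] | None = None
    for off in range(spec.spacer_max + 1):
        if off + Lf > L:
            break
        mm = iupac_mismatches(m.bases[off:off + Lf], fwd)
        if mm <= spec.max_primer_mismatches and (best5 is None or (mm, off) < best5):
            best5 = (mm, off)
    best3: tuple[int, int] | None = None
    for off in range(spec.spacer_max + 1):
        end = L - off
        if end - Lr < 0:
            break
        mm = iupac_mismatches(m.bases[end - Lr:end], rev_rc)
        if mm <= spec.max_primer_mismatches and (best3 is None or (mm, off) < best3):
            best3 = (mm, off)
    if best5 is None or best3 is None:
        return Rejection("missing_primer")

    start = best5[1] + Lf
    end = L - best3[1] - Lr
    if end - start < spec.min_merged_length:
        return Rejection("short_after_trim")
    return MergedRead(bases=m.bases[start:end], quals=m.quals[start:end],
                      sample_id=m.sample_id, run_id=m.run_id, serial=m.serial)


HEADER_DELIMS = (".", "_")


def format_header(m: MergedRead, sample_id: str, run_id: str, serial: int) -> str:
    """Provenance header ``<sample>.<run>_<serial>``; delimiters are reserved."""
    if serial < 1:
        raise InputError("serial must be >= 1")
    for name in (sample_id, run_id):
        if any(d in name for d in HEADER_DELIMS):
            raise InputError(
                f"name {name!r} contains a reserved delimiter {HEADER_DELIMS}"
            )
    return f"{sample_id}.{run_id}_{serial}"


@dataclass
class PrepCounts:
    """Per-stage conservation ledger for one (sample, marker) stream."""

    input_pairs: int = 0
    dropped_trim: int = 0
    rejected: dict[str, int] = field(default_factory=dict)
    merged_kept: int = 0

    def reject(self, reason: str) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + 1

    @property
    def balanced(self) -> bool:
        return (self.input_pairs
                == self.merged_kept + self.dropped_trim + sum(self.rejected.values()))


def prepare_marker_reads(pairs: list[tuple[SequenceRead, SequenceRead]],
                         spec: MarkerSpec, params: QCParams,
                         ) -> tuple[list[tuple[str, MergedRead]], PrepCounts]:
    """Steps 3-7 for one demultiplexed (sample, marker) stream.

    Returns ``(header, merged_core)`` records plus the conservation ledger;
    serials restart at 1 within each stream.
    """
    counts = PrepCounts(input_pairs=len(pairs))
    out: list[tuple[str, MergedRead]] = []
    serial = 0
    for r1, r2 in pairs:
        t1 = trim_three_prime(r1, params.three_prime_trim)
        t2 = trim_three_prime(r2, params.three_prime_trim)
        if t1 is None or t2 is None:
            counts.dropped_trim += 1
            continue
        merged = merge_pair(t1, t2, params)
        if isinstance(merged, Rejection):
            counts.reject(merged.reason)
            continue
        if not mean_quality_filter(merged, params.mean_quality_threshold):
            counts.reject("low_quality")
            continue
        core = global_primer_trim(merged, spec)
        if isinstance(core, Rejection):
            counts.reject(core.reason)
            continue
        serial += 1
        header = format_header(core, r1.sample_id, r1.run_id, serial)
        out.append((header, core))
        counts.merged_kept += 1
    return out, counts
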
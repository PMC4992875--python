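"""Greedy centroid OTU clustering with de novo chimera screening.

Unique sequences are visited in decreasing abundance. Each is either
recruited by the most similar existing centroid (identity at or above the
marker threshold, 0.98 for tufA and 0.97 otherwise), discarded as a
two-parent chimera, or promoted to a new centroid. Centroids are never
re-centred, so the outcome is a deterministic function of the input order.

The chimera verdict follows the abundance-skew logic of de novo screening:
only centroids at least twice as abundant as the query are candidate
parents, and a query is chimeric when some breakpoint splits it into a
left segment >= 99% identical to one parent and a right segment >= 99%
identical to another, while no single parent explains it at > 97%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import align, pairwise_identity
from .errors import InputError, ParameterError


@dataclass
class UniqueSequence:
    bases: str
    abundance: int
    members: list[str] = field(default_factory=list)


@dataclass
class OTUCentroid:
    otu_id: str
    bases: str
    size: int  # reads recruited during clustering


@dataclass(frozen=True)
class ChimeraVerdict:
    chimeric: bool
    parent_a: str | None = None
    parent_b: str | None = None
    breakpoint: int | None = None


@dataclass(frozen=True)
class ChimeraParams:
    parent_skew: float = 2.0       # parents must be >= skew x query abundance
    segment_identity: float = 0.99
    max_parent_identity: float = 0.97


def dereplicate(seqs: list[tuple[str, str]]) -> list[UniqueSequence]:
    """Collapse exact duplicates; sort by abundance then lexicographic bases.

    ``seqs`` are (label, bases) records; the member labels of each unique
    sequence are preserved for downstream provenance.
    """
    groups: dict[str, list[str]] = {}
    for label, bases in seqs:
        groups.setdefault(bases, []).append(label)
    uniques = [
        UniqueSequence(bases=b, abundance=len(mem), members=mem)
        for b, mem in groups.items()
    ]
    uniques.sort(key=lambda u: (-u.abundance, u.bases))
    return uniques


def _segment_profile(query: str, centroid: str) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (columns, matches) of the query/centroid alignment.

    Index i gives the alignment columns and matching columns attributable
    to query positions < i; terminal-gap columns are excluded, columns with
    a gap in the query are charged to the current query position.
    """
    aln = align(query, centroid)
    cols = aln.columns()
    # trim terminal gaps as the identity measure does
    start, end = 0, len(cols)
    if cols and "-" in cols[0]:
        side = 0 if cols[0][0] == "-" else 1
        while start < end and cols[start][side] == "-":
            start += 1
    if end > start and "-" in cols[end - 1]:
        side = 0 if cols[end - 1][0] == "-" else 1
        while end > start and cols[end - 1][side] == "-":
            end -= 1
    n = len(query)
    ncols = np.zeros(n + 1, dtype=np.int64)
    nmatch = np.zeros(n + 1, dtype=np.int64)
    qpos = sum(1 for c, _ in cols[:start] if c != "-")
    for qc, cc in cols[start:end]:
        ncols[min(qpos, n)] += 1
        if qc == cc and qc != "-":
            nmatch[min(qpos, n)] += 1
        if qc != "-":
            qpos += 1
    return np.cumsum(ncols), np.cumsum(nmatch)


def chimera_check(query: UniqueSequence, centroids: list[OTUCentroid],
                  params: ChimeraParams = ChimeraParams()) -> ChimeraVerdict:
    """Two-parent chimera test against more abundant centroids."""
    eligible = [c for c in centroids
                if c.size >= params.parent_skew * query.abundance]
    if len(eligible) < 2:
        return ChimeraVerdict(False)
    full = {c.otu_id: pairwise_identity(query.bases, c.bases) for c in eligible}
    if max(full.values()) > params.max_parent_identity:
        return ChimeraVerdict(False)

    profiles = {c.otu_id: _segment_profile(query.bases, c.bases) for c in eligible}
    n = len(query.bases)
    bps = np.arange(1, n)  # candidate breakpoints in query coordinates
    best: tuple[float, int, str, str] | None = None
    for a in eligible:
        ca, ma = profiles[a.otu_id]
        with np.errstate(invalid="ignore", divide="ignore"):
            left = np.where(ca[bps] > 0, ma[bps] / np.maximum(ca[bps], 1), 0.0)
        for b in eligible:
            if b.otu_id == a.otu_id:
                continue
            cb, mb = profiles[b.otu_id]
            rc_cols = cb[n] - cb[bps]
            right = np.where(rc_cols > 0,
                             (mb[n] - mb[bps]) / np.maximum(rc_cols, 1), 0.0)
            score = np.minimum(left, right)
            # the junction is unidentifiable inside a run where both parents
            # agree: report the centre of the maximal-score plateau
            top = np.flatnonzero(score == score.max())
            k = int(top[len(top) // 2])
            if score[k] >= params.segment_identity:
                cand = (float(score[k]), int(bps[k]), a.otu_id, b.otu_id)
                if best is None or cand[0] > best[0]:
                    best = cand
    if best is None:
        return ChimeraVerdict(False)
    return ChimeraVerdict(True, parent_a=best[2], parent_b=best[3],
                          breakpoint=best[1])


@dataclass
class ClusterResult:
    centroids: list[OTUCentroid]
    #: unique bases -> otu_id for every recruited or promoted unique
    assignment: dict[str, str]
    #: bases of uniques discarded as chimeras, with their verdicts
    chimeras: dict[str, ChimeraVerdict]


def greedy_cluster(uniques: list[UniqueSequence], threshold: float,
                   chimera_params: ChimeraParams = ChimeraParams()
                   ) -> ClusterResult:
    """Abundance-ordered greedy clustering at the marker identity threshold.

    ``uniques`` must already be in dereplication order (abundance
    descending). Recruiting ties prefer the larger centroid, then the
    earlier otu_id.
    """
    if not 0.5 < threshold <= 1.0:
        raise ParameterError(f"threshold {threshold} outside (0.5, 1.0]")
    centroids: list[OTUCentroid] = []
    assignment: dict[str, str] = {}
    chimeras: dict[str, ChimeraVerdict] = {}
    for u in uniques:
        best: tuple[float, int, int] | None = None  # (identity, size, -index)
        for idx, c in enumerate(centroids):
            ident = pairwise_identity(u.bases, c.bases)
            key = (ident, c.size, -idx)
            if best is None or key > best:
                best = key
        if best is not None and best[0] >= threshold:
            c = centroids[-best[2]]
            c.size += u.abundance
            assignment[u.bases] = c.otu_id
            continue
        verdict = chimera_check(u, centroids, chimera_params)
        if verdict.chimeric:
            chimeras[u.bases] = verdict
            continue
        otu_id = f"OTU_{len(centroids) + 1:04d}"
        centroids.append(OTUCentroid(otu_id=otu_id, bases=u.bases,
                                     size=u.abundance))
        assignment[u.bases] = otu_id
    return ClusterResult(centroids, assignment, chimeras)


@dataclass
class OTUTable:
    """OTU x sample count matrix for one marker, with a filter provenance log."""

    marker: str
    df: pd.DataFrame  # rows: otu_id, columns: sample_id, integer counts
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates or self.df.columns.has_duplicates:
            raise InputError("OTU table labels must be unique")
        if (self.df.to_numpy() < 0).any():
            raise InputError("OTU table counts must be >= 0")

    def copy_with(self, df: pd.DataFrame, note: str) -> "OTUTable":
        return OTUTable(self.marker, df, self.log + [note])

    @property
    def n_otus(self) -> int:
        return len(self.df.index)

    @property
    def n_reads(self) -> int:
        return int(self.df.to_numpy().sum())


@dataclass
class MappingSummary:
    mapped: int
    unmapped: int
    chimera_discarded: int


def build_otu_table(reads_by_sample: dict[str, list[tuple[str, str]]],
                    result: ClusterResult, threshold: float,
                    marker: str = "") -> tuple[OTUTable, MappingSummary]:
    """Map every retained read to its best centroid and tabulate counts.

    Reads identical to a chimera-discarded unique are counted as chimeric;
    other reads failing the identity threshold against every centroid are
    counted as unmapped. The same tie rules as clustering apply.
    """
    if not result.centroids:
        raise InputError("cannot build an OTU table with no centroids")
    samples = sorted(reads_by_sample)
    otu_ids = [c.otu_id for c in result.centroids]
    counts = pd.DataFrame(0, index=otu_ids, columns=samples, dtype=np.int64)
    unmapped = chimeric = 0
    cache: dict[str, str | None] = {
        c.bases: c.otu_id for c in result.centroids
    }
    for sample in samples:
        for _, bases in reads_by_sample[sample]:
            if bases in result.chimeras:
                chimeric += 1
                continue
            if bases not in cache:
                best: tuple[float, int, int] | None = None
                for idx, c in enumerate(result.centroids):
                    key = (pairwise_identity(bases, c.bases), c.size, -idx)
                    if best is None or key > best:
                        best = key
                cache[bases] = (result.centroids[-best[2]].otu_id
                                if best[0] >= threshold else None)
            otu = cache[bases]
            if otu is None:
                unmapped += 1
            else:
                counts.loc[otu, sample] += 1
    mapped = int(counts.to_numpy().sum())
    table = OTUTable(marker=marker, df=counts,
                     log=[f"built: {mapped} mapped, {unmapped} unmapped, "
                          f"{chimeric} chimera-discarded"])
    return table, MappingSummary(mapped, unmapped, chimeric)
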
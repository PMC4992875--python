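"""Marker (amplicon) definitions and IUPAC-aware primer utilities.

A metabarcoding library here pools four loci per sample — plastid 16S rDNA,
nuclear 18S rDNA, plastid 23S rDNA and the plastid elongation-factor gene
tufA — amplified with tailed primers carrying 0-3 nt heterogeneity spacers.
Each :class:`MarkerSpec` bundles everything a downstream stage needs to know
about one locus: the primer pair, the 33 nt overhang tail used to detect
adapter read-through, the primer-mismatch tolerance, the OTU identity
threshold (0.98 for tufA, 0.97 otherwise) and the minimum merged length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio.Seq import Seq

from .errors import ConfigError, ParameterError

# IUPAC nucleotide codes -> set of plain bases they stand for.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Sequencing-primer binding site appended 5' of every locus primer; its
#: reverse complement marks adapter read-through on short amplicons.
DEFAULT_TAIL = "ACACTCTTTCCCTACACGACGCTCTTCCGATCT"  # 33 nt


def revcomp(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return str(Seq(seq).reverse_complement())


def base_matches(observed: str, code: str) -> bool:
    """True if an observed base is compatible with an IUPAC primer code.

    Both sides may be degenerate; compatibility means their expansion sets
    intersect (an observed N is compatible with any primer code).
    """
    obs = IUPAC.get(observed)
    exp = IUPAC.get(code)
    if obs is None or exp is None:
        return observed == code
    return not obs.isdisjoint(exp)


def iupac_mismatches(observed: str, pattern: str) -> int:
    """Number of positions of ``pattern`` the observed bases cannot satisfy.

    ``observed`` must be at least as long as ``pattern``; only the first
    ``len(pattern)`` observed bases are compared.
    """
    return sum(
        0 if base_matches(o, p) else 1 for o, p in zip(observed, pattern)
    )


def primer_set_distance(p: str, q: str) -> int:
    """Positions (over the shared prefix) where two IUPAC primers are disjoint.

    Used to validate that a marker panel is demultiplexable: two primers
    whose expansion sets overlap nearly everywhere cannot be told apart.
    """
    d = abs(len(p) - len(q))  # length difference always separates
    for a, b in zip(p, q):
        if IUPAC.get(a, frozenset(a)).isdisjoint(IUPAC.get(b, frozenset(b))):
            d += 1
    return d


@dataclass(frozen=True)
class MarkerSpec:
    """Configuration of one amplified locus."""

    name: str
    fwd_primer: str
    rev_primer: str
    tail: str = DEFAULT_TAIL
    spacer_max: int = 3
    max_primer_mismatches: int = 2
    identity_threshold: float = 0.97
    min_merged_length: int = 100
    #: target amplicon length (primers included) used by the read simulator
    amplicon_length: int = 400

    def __post_init__(self) -> None:
        for primer in (self.fwd_primer, self.rev_primer):
            if len(primer) < 15:
                raise ParameterError(
                    f"{self.name}: primer {primer!r} shorter than 15 nt"
                )
            bad = set(primer) - set(IUPAC)
            if bad:
                raise ParameterError(f"{self.name}: non-IUPAC primer codes {bad}")
        if not (0.5 < self.identity_threshold <= 1.0):
            raise ParameterError(
                f"{self.name}: identity_threshold {self.identity_threshold} not in (0.5, 1]"
            )
        if self.spacer_max < 0:
            raise ParameterError(f"{self.name}: spacer_max must be >= 0")

    def with_(self, **kw) -> "MarkerSpec":
        return replace(self, **kw)


def default_marker_panel() -> list[MarkerSpec]:
    """The four-locus panel, with published primer pairs for each locus.

    Amplicon lengths are set so that 16S behaves as a short amplicon
    (adapter read-through on 2x300 runs) while the other three require
    overlap merging of the mates.
    """
    return [
        MarkerSpec("16S", "GTGYCAGCMGCCGCGGTAA", "GGACTACNVGGGTWTCTAAT",
                   identity_threshold=0.97, amplicon_length=290),
        MarkerSpec("18S", "CCAGCASCYGCGGTAATTCC", "ACTTTCGTTCTTGATYRA",
                   identity_threshold=0.97, amplicon_length=380),
        MarkerSpec("23S", "GGACAGAAAGACCCTATGAA", "TCAGCCTGTTATCCCTAGAG",
                   identity_threshold=0.97, amplicon_length=410),
        MarkerSpec("tufA", "GGNGCNGCNCAAATGGAYGG", "CCTTCNCGAATMGCRAAWCGC",
                   identity_threshold=0.98, amplicon_length=450),
    ]


def validate_panel(specs: list[MarkerSpec]) -> None:
    """Reject marker panels whose primers cannot be distinguished.

    Requires pairwise IUPAC set distance > 2 * max_primer_mismatches for the
    forward primers and likewise for the reverse primers.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate marker names in panel")
    for i, a in enumerate(specs):
        for b in specs[i + 1:]:
            tol = 2 * max(a.max_primer_mismatches, b.max_primer_mismatches)
            if (primer_set_distance(a.fwd_primer, b.fwd_primer) <= tol
                    and primer_set_distance(a.rev_primer, b.rev_primer) <= tol):
                raise ConfigError(
                    f"primers of markers {a.name!r} and {b.name!r} are not "
                    f"distinguishable at {tol} mismatches"
                )
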
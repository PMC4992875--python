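"""Synthetic amplicon communities and trait-bearing phylogenies.

Everything the pipeline consumes can be generated here with known ground
truth: reference taxa with hierarchical six-rank lineages and one amplicon
per marker, per-sample paired-end reads that reproduce the structural
features of a pooled multi-marker MiSeq library (0-3 nt heterogeneity
spacers, tailed primers, adapter read-through on short amplicons, linearly
decaying 3' quality, PCR chimeras, cross-contamination into negative
controls), and birth-death trees carrying a binary character evolved under
a two-state continuous-time Markov chain.

All generators are deterministic functions of their seed: the same seed
reproduces byte-identical FASTQ files and newick strings.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.model import birthdeath

from .errors import InputError, ParameterError
from .markers import MarkerSpec, revcomp, IUPAC
from .records import SequenceRead

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: filler appended past the overhang tail when a short construct is read through
_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

_BASES = "ACGT"


def derive_seed(*parts) -> int:
    """Stable sub-seed (< 2^31) from a tuple of seed components."""
    digest = hashlib.sha256(":".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass(frozen=True)
class ReferenceTaxon:
    taxon_id: str
    lineage: tuple[str, ...]  # domain..genus, exactly 6 ranks
    marker_seqs: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.lineage) != 6 or not all(self.lineage):
            raise ParameterError(f"{self.taxon_id}: lineage must have 6 non-empty ranks")

    @property
    def genus(self) -> str:
        return self.lineage[-1]


@dataclass(frozen=True)
class CommunityProfile:
    sample_id: str
    is_negative_control: bool
    abundances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # an empty table is legal at construction (the read simulator
        # rejects it for non-controls); a non-empty one must be normalised
        if not self.is_negative_control and self.abundances:
            total = sum(self.abundances.values())
            if abs(total - 1.0) > 1e-9:
                raise ParameterError(
                    f"{self.sample_id}: abundances sum to {total}, expected 1"
                )


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    read_length: int = 300
    spacer_lengths: tuple[int, ...] = (0, 1, 2, 3)
    substitution_rate_per_base: float = 0.001
    quality_start: int = 38
    quality_slope: float = 0.02  # Phred units lost per base toward 3'
    quality_floor: int = 2
    quality_errors: bool = True  # draw sequencing errors at 10^(-Q/10)
    chimera_fraction: float = 0.01
    negcontrol_contamination_reads: int = 5
    reads_per_sample: int = 2000

    def __post_init__(self) -> None:
        if self.read_length < 50:
            raise ParameterError("read_length must be >= 50")
        for name in ("substitution_rate_per_base", "chimera_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.reads_per_sample < 0 or self.negcontrol_contamination_reads < 0:
            raise ParameterError("read counts must be >= 0")


@dataclass
class ChimeraRecord:
    read_id: str
    marker: str
    parent_a: str
    parent_b: str
    breakpoint: int  # position in the amplicon, parent A left of it


@dataclass
class GroundTruth:
    """Per (sample, marker) template counts plus chimera/contaminant records."""

    template_counts: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)
    #: read_id -> (sample, marker, taxon) for every non-chimeric template
    read_truth: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    chimeras: list[ChimeraRecord] = field(default_factory=list)
    contaminant_read_ids: dict[str, list[str]] = field(default_factory=dict)

    def total_reads(self, sample_id: str) -> int:
        n = sum(
            sum(counts.values())
            for (s, _), counts in self.template_counts.items()
            if s == sample_id
        )
        n += sum(1 for c in self.chimeras if c.read_id.startswith(sample_id + ":"))
        n += len(self.contaminant_read_ids.get(sample_id, []))
        return n


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES)) for _ in range(int(n)))


def _concretize(primer: str, rng: np.random.Generator) -> str:
    """Replace IUPAC degeneracies with one concrete base each."""
    return "".join(
        c if c in _BASES else rng.choice(sorted(IUPAC[c])) for c in primer
    )


def _lineage_for(genus_index: int) -> tuple[str, ...]:
    g = genus_index
    return (
        "Eukaryota",
        f"Phylum{g // 16:02d}",
        f"Class{g // 8:02d}",
        f"Order{g // 4:02d}",
        f"Family{g // 2:02d}",
        f"Genus{g:02d}",
    )


def build_reference_set(n_genera: int, seqs_per_genus: int,
                        marker_specs: list[MarkerSpec], seed: int
                        ) -> list[ReferenceTaxon]:
    """Reference taxa with divergent genera and near-identical congeners.

    Genus ancestor sequences are independent random DNA (well below 90%
    identity after alignment); within a genus each sequence carries at most
    1% random substitutions relative to the ancestor, so within-genus
    pairwise identity stays >= 97%.
    """
    if n_genera < 1 or seqs_per_genus < 1:
        raise ParameterError("n_genera and seqs_per_genus must be >= 1")
    rng = np.random.default_rng(derive_seed(seed, "refs"))
    core_lens: dict[str, int] = {}
    for spec in marker_specs:
        core = spec.amplicon_length - len(spec.fwd_primer) - len(spec.rev_primer)
        if core < 50:
            raise ParameterError(
                f"{spec.name}: amplicon_length {spec.amplicon_length} leaves a "
                f"core of {core} nt (< 50); divergence targets unattainable"
            )
        core_lens[spec.name] = core

    taxa: list[ReferenceTaxon] = []
    for g in range(n_genera):
        lineage = _lineage_for(g)
        primers = {
            spec.name: (_concretize(spec.fwd_primer, rng),
                        _concretize(spec.rev_primer, rng))
            for spec in marker_specs
        }
        ancestors = {
            spec.name: _random_dna(rng, core_lens[spec.name])
            for spec in marker_specs
        }
        for s in range(seqs_per_genus):
            marker_seqs = {}
            for spec in marker_specs:
                core = list(ancestors[spec.name])
                n_mut = int(0.01 * len(core)) if s > 0 else 0
                for pos in rng.choice(len(core), size=n_mut, replace=False):
                    alternatives = [b for b in _BASES if b != core[pos]]
                    core[pos] = alternatives[int(rng.integers(3))]
                fwd, rev = primers[spec.name]
                marker_seqs[spec.name] = fwd + "".join(core) + revcomp(rev)
            taxa.append(ReferenceTaxon(
                taxon_id=f"{lineage[-1]}_sp{s + 1}",
                lineage=lineage,
                marker_seqs=marker_seqs,
            ))
    return taxa


def _quality_profile(cfg: SimConfig, n: int) -> tuple[int, ...]:
    return tuple(
        max(cfg.quality_floor, int(round(cfg.quality_start - cfg.quality_slope * i)))
        for i in range(n)
    )


def _apply_errors(bases: str, quals: tuple[int, ...],
                  rng: np.random.Generator) -> str:
    out = list(bases)
    u = rng.random(len(out))
    for i, q in enumerate(quals):
        if u[i] < 10 ** (-q / 10):
            alternatives = [b for b in _BASES if b != out[i]]
            out[i] = alternatives[int(rng.integers(3))]
    return "".join(out)


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    u = rng.random(len(out))
    for i in range(len(out)):
        if u[i] < rate:
            alternatives = [b for b in _BASES if b != out[i]]
            out[i] = alternatives[int(rng.integers(3))]
    return "".join(out)


def _make_pair(template: str, spec: MarkerSpec, cfg: SimConfig, read_id: str,
               sample_id: str, run_id: str, rng: np.random.Generator
               ) -> tuple[SequenceRead, SequenceRead]:
    """Paired reads off one amplicon template (primers included in template)."""
    L = cfg.read_length
    sp_f = _random_dna(rng, rng.choice(cfg.spacer_lengths))
    sp_r = _random_dna(rng, rng.choice(cfg.spacer_lengths))
    readthrough = revcomp(spec.tail)

    def one(construct: str, mate: str) -> SequenceRead:
        while len(construct) < L:
            construct += _ADAPTER
        bases = construct[:L]
        quals = _quality_profile(cfg, L)
        if cfg.quality_errors:
            bases = _apply_errors(bases, quals, rng)
        return SequenceRead(read_id=read_id, bases=bases, quals=quals,
                            mate=mate, sample_id=sample_id, run_id=run_id)

    r1 = one(sp_f + template + readthrough, "forward")
    r2 = one(sp_r + revcomp(template) + readthrough, "reverse")
    return r1, r2


def simulate_sample_reads(profile: CommunityProfile,
                          refs: list[ReferenceTaxon],
                          specs: list[MarkerSpec],
                          cfg: SimConfig,
                          run_id: str = "RUN1",
                          ) -> tuple[list[tuple[SequenceRead, SequenceRead]], GroundTruth]:
    """Simulate one sample's pooled multi-marker read pairs with ground truth.

    Negative controls emit exactly ``cfg.negcontrol_contamination_reads``
    pairs drawn uniformly from all (taxon, marker) templates; real samples
    emit ``cfg.reads_per_sample`` pairs with taxa drawn from the profile and
    markers drawn uniformly. A ``chimera_fraction`` of templates are
    two-parent recombinants with a uniform breakpoint >= 50 nt from each end.
    """
    rng = np.random.default_rng(derive_seed(cfg.seed, "reads", profile.sample_id))
    by_id = {t.taxon_id: t for t in refs}
    truth = GroundTruth()
    pairs: list[tuple[SequenceRead, SequenceRead]] = []

    if profile.is_negative_control:
        ids = sorted(by_id)
        contaminants = truth.contaminant_read_ids.setdefault(profile.sample_id, [])
        for i in range(cfg.negcontrol_contamination_reads):
            read_id = f"{profile.sample_id}:{i:06d}"
            taxon = by_id[ids[int(rng.integers(len(ids)))]]
            spec = specs[int(rng.integers(len(specs)))]
            template = _substitute(taxon.marker_seqs[spec.name],
                                   cfg.substitution_rate_per_base, rng)
            pairs.append(_make_pair(template, spec, cfg, read_id,
                                    profile.sample_id, run_id, rng))
            contaminants.append(read_id)
        return pairs, truth

    if not profile.abundances:
        raise InputError(f"{profile.sample_id}: empty abundance profile")
    taxon_ids = sorted(profile.abundances)
    weights = np.array([profile.abundances[t] for t in taxon_ids])
    weights = weights / weights.sum()

    for i in range(cfg.reads_per_sample):
        read_id = f"{profile.sample_id}:{i:06d}"
        spec = specs[int(rng.integers(len(specs)))]
        tid = taxon_ids[int(rng.choice(len(taxon_ids), p=weights))]
        is_chimera = (len(taxon_ids) > 1
                      and float(rng.random()) < cfg.chimera_fraction)
        if is_chimera:
            others = [t for t in taxon_ids if t != tid]
            tid_b = others[int(rng.integers(len(others)))]
            seq_a = by_id[tid].marker_seqs[spec.name]
            seq_b = by_id[tid_b].marker_seqs[spec.name]
            bp = int(rng.integers(50, len(seq_a) - 50))
            template = seq_a[:bp] + seq_b[bp:]
            truth.chimeras.append(ChimeraRecord(
                read_id=read_id, marker=spec.name,
                parent_a=tid, parent_b=tid_b, breakpoint=bp))
        else:
            template = by_id[tid].marker_seqs[spec.name]
            key = (profile.sample_id, spec.name)
            truth.template_counts.setdefault(key, {})
            truth.template_counts[key][tid] = truth.template_counts[key].get(tid, 0) + 1
            truth.read_truth[read_id] = (profile.sample_id, spec.name, tid)
        template = _substitute(template, cfg.substitution_rate_per_base, rng)
        pairs.append(_make_pair(template, spec, cfg, read_id,
                                profile.sample_id, run_id, rng))
    return pairs, truth


def merge_truth(parts: list[GroundTruth]) -> GroundTruth:
    out = GroundTruth()
    for t in parts:
        for key, counts in t.template_counts.items():
            dst = out.template_counts.setdefault(key, {})
            for tid, n in counts.items():
                dst[tid] = dst.get(tid, 0) + n
        out.read_truth.update(t.read_truth)
        out.chimeras.extend(t.chimeras)
        for s, ids in t.contaminant_read_ids.items():
            out.contaminant_read_ids.setdefault(s, []).extend(ids)
    return out


# --------------------------------------------------------------------------
# trait-bearing phylogenies


@dataclass
class TransitionEvent:
    branch: str      # label of the child node of the branch
    time: float      # time from the branch's parent end
    from_state: int
    to_state: int


def simulate_phylogeny_with_character(
    n_tips: int, birth_rate: float, death_rate: float,
    q01: float, q10: float, root_state: int, seed: int,
) -> tuple[dendropy.Tree, dict[str, int], list[TransitionEvent]]:
    """Ultrametric birth-death tree plus an exactly simulated binary character.

    The character evolves along each branch as a continuous-time Markov
    chain with rates ``q01`` (gain) and ``q10`` (loss); every transition is
    recorded in the returned history.
    """
    if n_tips < 2:
        raise ParameterError("n_tips must be >= 2")
    if death_rate >= birth_rate:
        raise ParameterError("death_rate >= birth_rate: non-viable process")
    if q01 < 0 or q10 < 0:
        raise ParameterError("transition rates must be >= 0")
    if root_state not in (0, 1):
        raise ParameterError("root_state must be 0 or 1")

    # GSA conditioning: plain n-tip conditioning stops exactly at the n-th
    # birth and yields zero-length pendant branches
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate, death_rate=death_rate,
        num_extant_tips=n_tips, gsa_ntax=n_tips + 2,
        rng=random.Random(derive_seed(seed, "tree")),
    )
    tree.seed_node.edge.length = None  # no stem branch
    # stable internal labels for history reporting
    for idx, nd in enumerate(tree.preorder_node_iter()):
        if nd.taxon is None:
            nd.label = f"nd{idx}"

    rng = np.random.default_rng(derive_seed(seed, "char"))
    history: list[TransitionEvent] = []
    node_state: dict[int, int] = {id(tree.seed_node): root_state}
    rates = {0: q01, 1: q10}

    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        state = node_state[id(nd.parent_node)]
        t, blen = 0.0, nd.edge.length
        label = nd.taxon.label if nd.taxon is not None else nd.label
        while True:
            rate = rates[state]
            if rate <= 0:
                break
            t += float(rng.exponential(1.0 / rate))
            if t >= blen:
                break
            history.append(TransitionEvent(label, t, state, 1 - state))
            state = 1 - state
        node_state[id(nd)] = state

    tip_states = {
        lf.taxon.label: node_state[id(lf)] for lf in tree.leaf_node_iter()
    }
    return tree, tip_states, history
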
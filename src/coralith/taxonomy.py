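"""Naive Bayes k-mer taxonomy with bootstrap confidence.

An RDP-style classifier: each genus is summarised by the probability that
one of its sequences contains each k-mer word (presence/absence, not
multiplicity). For a genus with M training sequences of which m(w) contain
word w, and a corpus of N sequences of which n(w) contain it,

    P(w | genus) = (m(w) + Pr(w)) / (M + 1),   Pr(w) = (n(w) + 0.5) / (N + 1).

A query is scored by the log product of its words' genus-conditional
probabilities; confidence comes from bootstrap trials that re-score a
random one-eighth subsample of the query's words and vote their top genus.
The confidence reported at each rank is the fraction of trials whose voted
genus agrees with the assignment at that rank, which makes confidences
non-increasing from domain to genus. Ranks below the reporting threshold
(default 0.7) render as ``unclassified_<parent>``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError, StateError
from .simulate import RANKS, ReferenceTaxon

DEFAULT_K = 8
DEFAULT_BOOTSTRAP = 100
DEFAULT_CONFIDENCE = 0.7


def _words(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


@dataclass
class TrainedClassifier:
    k: int
    genera: list[str]                      # sorted genus labels
    lineages: dict[str, tuple[str, ...]]   # genus -> 6-rank lineage
    #: log P(w | genus) for every word observed in the corpus, shape (W, G)
    log_probs: np.ndarray
    word_index: dict[str, int]
    #: log probability of a word never seen in the corpus, per genus
    log_unseen: np.ndarray
    n_train: int

    def genus_log_scores(self, words: list[str]) -> np.ndarray:
        idx = [self.word_index.get(w, -1) for w in words]
        scores = np.zeros(len(self.genera))
        for i in idx:
            scores += self.log_probs[i] if i >= 0 else self.log_unseen
        return scores


def train(refs: list[ReferenceTaxon], marker: str,
          k: int = DEFAULT_K) -> TrainedClassifier:
    """Train the word model from reference taxa for one marker."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    if not refs:
        raise ParameterError("training requires at least one reference taxon")
    seqs: list[tuple[str, set[str]]] = []  # (genus, word set)
    lineages: dict[str, tuple[str, ...]] = {}
    for taxon in refs:
        seq = taxon.marker_seqs.get(marker)
        if seq is None:
            continue
        if len(seq) < k:
            raise InputError(
                f"training sequence {taxon.taxon_id} shorter than k={k}"
            )
        seqs.append((taxon.genus, _words(seq, k)))
        prev = lineages.setdefault(taxon.genus, taxon.lineage)
        if prev != taxon.lineage:
            raise InputError(f"genus {taxon.genus} has conflicting lineages")
    if not seqs:
        raise ParameterError(f"no reference sequences for marker {marker!r}")

    genera = sorted(lineages)
    g_index = {g: i for i, g in enumerate(genera)}
    vocab = sorted(set().union(*(w for _, w in seqs)))
    word_index = {w: i for i, w in enumerate(vocab)}

    N = len(seqs)
    n_w = np.zeros(len(vocab))
    m_wg = np.zeros((len(vocab), len(genera)))
    M_g = np.zeros(len(genera))
    for genus, words in seqs:
        gi = g_index[genus]
        M_g[gi] += 1
        for w in words:
            wi = word_index[w]
            n_w[wi] += 1
            m_wg[wi, gi] += 1

    prior = (n_w + 0.5) / (N + 1)
    probs = (m_wg + prior[:, None]) / (M_g[None, :] + 1)
    unseen = (0.5 / (N + 1)) / (M_g + 1)
    return TrainedClassifier(
        k=k, genera=genera, lineages=dict(lineages),
        log_probs=np.log(probs), word_index=word_index,
        log_unseen=np.log(unseen), n_train=N,
    )


@dataclass(frozen=True)
class RankCall:
    rank: str
    label: str
    confidence: float


@dataclass
class TaxonomicAssignment:
    otu_id: str
    calls: list[RankCall]
    threshold: float = DEFAULT_CONFIDENCE

    def reported(self) -> list[RankCall]:
        """Labels with sub-threshold ranks rendered as unclassified."""
        out: list[RankCall] = []
        parent = "root"
        for call in self.calls:
            if call.confidence >= self.threshold:
                out.append(call)
                parent = call.label
            else:
                out.append(RankCall(call.rank, f"unclassified_{parent}",
                                    call.confidence))
        return out

    @property
    def genus_confidence(self) -> float:
        return self.calls[-1].confidence


def classify(query: str, clf: TrainedClassifier, otu_id: str = "",
             n_bootstrap: int = DEFAULT_BOOTSTRAP,
             subsample_fraction: float = 1 / 8,
             threshold: float = DEFAULT_CONFIDENCE,
             seed: int = 0) -> TaxonomicAssignment:
    """Assign a query sequence and attach per-rank bootstrap confidences."""
    if clf is None or not clf.genera:
        raise StateError("classifier is not trained")
    if len(query) < clf.k:
        raise InputError(f"query shorter than k={clf.k}")
    words = sorted(_words(query, clf.k))
    scores = clf.genus_log_scores(words)
    assigned = clf.genera[int(np.argmax(scores))]
    lineage = clf.lineages[assigned]

    rng = np.random.default_rng(seed)
    n_sub = max(1, math.ceil(len(words) * subsample_fraction))
    votes: dict[str, int] = {}
    for _ in range(n_bootstrap):
        picks = rng.integers(0, len(words), size=n_sub)
        sub = [words[i] for i in picks]
        voted = clf.genera[int(np.argmax(clf.genus_log_scores(sub)))]
        votes[voted] = votes.get(voted, 0) + 1

    calls: list[RankCall] = []
    for level, rank in enumerate(RANKS):
        agree = sum(
            n for g, n in votes.items()
            if clf.lineages[g][level] == lineage[level]
        )
        calls.append(RankCall(rank, lineage[level], agree / n_bootstrap))
    return TaxonomicAssignment(otu_id=otu_id, calls=calls, threshold=threshold)
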
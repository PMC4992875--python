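"""Two-state Mk inference and stochastic character mapping on dated trees.

The coral-endolithic lifestyle is coded as a binary tip character (0 =
non-endolithic, 1 = endolithic) on a rooted, dated, binary phylogeny with
branch lengths in million years. The character evolves as a continuous-
time Markov chain with gain rate q01 and loss rate q10; the transition
probability over a branch of length t has the closed form

    P(t) = pi + (I - pi) * exp(-(q01 + q10) t),   pi = (q10, q01)/(q01+q10)

(rows of pi). Likelihoods use Felsenstein's pruning recursion with per-node
rescaling; rates are fitted by bounded maximum likelihood. Stochastic maps
are drawn exactly: joint node states from the conditional distributions
(pruning partials plus the root prior), then endpoint-conditioned branch
histories by uniformization, which introduces no discretisation error.
Counting the 0 -> 1 transitions over a map (plus one if the root itself
starts in state 1) gives the number of independent origins of the
endolithic lifestyle in that sampled history; the set of maps yields its
posterior distribution and per-node ancestral state probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import CoralithError, InputError, ParameterError
from .simulate import derive_seed


@dataclass(frozen=True)
class MkModel:
    q01: float
    q10: float
    variant: str = "equal_rates"        # or "all_rates_different"
    root_prior: str = "stationary"      # or "flat"

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0:
            raise ParameterError("rates must be >= 0")
        if self.variant not in ("equal_rates", "all_rates_different"):
            raise ParameterError(f"unknown variant {self.variant!r}")
        if self.root_prior not in ("stationary", "flat"):
            raise ParameterError(f"unknown root prior {self.root_prior!r}")

    def pmat(self, t: float) -> np.ndarray:
        r = self.q01 + self.q10
        if r == 0:
            return np.eye(2)
        pi1 = self.q01 / r
        e = math.exp(-r * t)
        return np.array([
            [1 - pi1 + pi1 * e, pi1 - pi1 * e],
            [1 - pi1 - (1 - pi1) * e, pi1 + (1 - pi1) * e],
        ])

    def root_pi(self) -> np.ndarray:
        r = self.q01 + self.q10
        if self.root_prior == "flat" or r == 0:
            return np.array([0.5, 0.5])
        return np.array([self.q10 / r, self.q01 / r])


def _check_tree(tree: dendropy.Tree, states: dict[str, int]) -> None:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or leaf.taxon.label not in states:
            label = leaf.taxon.label if leaf.taxon else "<unlabelled>"
            raise InputError(f"tip {label!r} has no trait state")
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        if nd.edge.length is None or nd.edge.length <= 0:
            raise InputError("all non-root branch lengths must be > 0")


def _node_label(nd: dendropy.Node) -> str:
    if nd.taxon is not None:
        return nd.taxon.label
    return nd.label if nd.label else f"node{id(nd) % 100000}"


def _partials(tree: dendropy.Tree, states: dict[str, int],
              model: MkModel) -> tuple[dict[int, np.ndarray], float]:
    """Post-order conditional likelihoods, rescaled; returns (partials, logscale)."""
    partials: dict[int, np.ndarray] = {}
    logscale = 0.0
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            p = np.zeros(2)
            p[states[nd.taxon.label]] = 1.0
        else:
            p = np.ones(2)
            for child in nd.child_nodes():
                p = p * (model.pmat(child.edge.length) @ partials[id(child)])
        mx = p.max()
        if mx <= 0:
            raise CoralithError(
                f"zero likelihood at node {_node_label(nd)} (incompatible "
                f"states under zero rates?)")
        partials[id(nd)] = p / mx
        logscale += math.log(mx)
    return partials, logscale


def tip_likelihood(tree: dendropy.Tree, states: dict[str, int],
                   model: MkModel) -> float:
    """Log-likelihood of the tip states by the pruning recursion."""
    _check_tree(tree, states)
    partials, logscale = _partials(tree, states, model)
    root = partials[id(tree.seed_node)]
    return math.log(float(model.root_pi() @ root)) + logscale


def node_marginals(tree: dendropy.Tree, states: dict[str, int],
                   model: MkModel) -> dict[str, float]:
    """Analytic marginal P(state = 1) for every node (up-down algorithm)."""
    _check_tree(tree, states)
    partials, _ = _partials(tree, states, model)
    down: dict[int, np.ndarray] = {id(tree.seed_node): model.root_pi()}
    out: dict[str, float] = {}
    for nd in tree.preorder_node_iter():
        marg = down[id(nd)] * partials[id(nd)]
        out[_node_label(nd)] = float(marg[1] / marg.sum())
        for child in nd.child_nodes():
            above = down[id(nd)].copy()
            for sib in nd.child_nodes():
                if sib is not child:
                    above = above * (model.pmat(sib.edge.length)
                                     @ partials[id(sib)])
            down[id(child)] = model.pmat(child.edge.length).T @ above
    return out


@dataclass
class MkFit:
    model: MkModel
    log_likelihood: float
    converged: bool
    warnings: list[str] = field(default_factory=list)


_LOG10_LO, _LOG10_HI = -8.0, 2.0


def fit_mk(tree: dendropy.Tree, states: dict[str, int],
           variant: str = "equal_rates",
           root_prior: str = "stationary") -> MkFit:
    """Maximum-likelihood Mk rates by bounded search on the log scale."""
    from scipy.optimize import minimize, minimize_scalar

    _check_tree(tree, states)
    tip_vals = {states[lf.taxon.label] for lf in tree.leaf_node_iter()}
    warnings: list[str] = []
    if len(tip_vals) < 2:
        warnings.append(
            "all tips share one state: rates at the zero boundary")
        model = MkModel(0.0, 0.0, variant=variant, root_prior=root_prior)
        return MkFit(model, tip_likelihood(tree, states, model), True, warnings)

    def loglik(q01: float, q10: float) -> float:
        return tip_likelihood(
            tree, states,
            MkModel(q01, q10, variant=variant, root_prior=root_prior))

    if variant == "equal_rates":
        res = minimize_scalar(lambda x: -loglik(10 ** x, 10 ** x),
                              bounds=(_LOG10_LO, _LOG10_HI), method="bounded",
                              options={"xatol": 1e-7})
        q01 = q10 = 10 ** float(res.x)
        converged = bool(res.success)
    else:
        start = np.array([math.log10(max(len(tip_vals), 1) / 2
                                     / max(tree.length(), 1e-9))] * 2)
        res = minimize(lambda x: -loglik(10 ** x[0], 10 ** x[1]), start,
                       method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        x = np.clip(res.x, _LOG10_LO, _LOG10_HI)
        q01, q10 = 10 ** x[0], 10 ** x[1]
        converged = bool(res.success)
    for name, q in (("q01", q01), ("q10", q10)):
        if math.log10(q) <= _LOG10_LO + 0.01 or math.log10(q) >= _LOG10_HI - 0.01:
            warnings.append(f"{name} at search boundary ({q:.3g})")
    model = MkModel(q01, q10, variant=variant, root_prior=root_prior)
    return MkFit(model, loglik(q01, q10), converged, warnings)


# --------------------------------------------------------------------------
# stochastic mapping


@dataclass
class StochasticMap:
    """One sampled character history."""

    root_state: int
    node_states: dict[str, int]                      # label -> state
    segments: dict[str, list[tuple[int, float]]]     # branch -> (state, dwell)

    def n_gains(self) -> int:
        events = sum(
            1
            for segs in self.segments.values()
            for (a, _), (b, _) in zip(segs, segs[1:])
            if a == 0 and b == 1
        )
        # a branch whose initial state differs from its parent's final state
        # is impossible by construction, so branch-internal events suffice
        return events

    def origins(self) -> int:
        return self.n_gains() + (1 if self.root_state == 1 else 0)


@dataclass
class StochasticMapSet:
    maps: list[StochasticMap]
    model: MkModel
    seed: int

    @property
    def n_maps(self) -> int:
        return len(self.maps)


class _Uniformizer:
    """Endpoint-conditioned CTMC path sampler (exact, via uniformization)."""

    def __init__(self, model: MkModel):
        self.model = model
        self.Q = np.array([[-model.q01, model.q01],
                           [model.q10, -model.q10]])
        self.omega = max(model.q01, model.q10)
        if self.omega > 0:
            self.R = np.eye(2) + self.Q / self.omega
        else:
            self.R = np.eye(2)
        self._powers = [np.eye(2), self.R.copy()]

    def _rpow(self, n: int) -> np.ndarray:
        while len(self._powers) <= n:
            self._powers.append(self._powers[-1] @ self.R)
        return self._powers[n]

    def sample_path(self, a: int, b: int, t: float, branch: str,
                    rng: np.random.Generator) -> list[tuple[int, float]]:
        if self.omega == 0:
            if a != b:
                raise CoralithError(
                    f"branch {branch}: endpoints {a}->{b} incompatible with "
                    f"zero rates")
            return [(a, t)]
        p_ab = self.model.pmat(t)[a, b]
        if p_ab <= 0:
            raise CoralithError(
                f"branch {branch}: endpoint pair {a}->{b} has zero probability")
        # number of uniformized jumps
        u = float(rng.random()) * p_ab
        ot = self.omega * t
        log_pois = -ot
        n = 0
        acc = math.exp(log_pois) * self._rpow(0)[a, b]
        while acc < u:
            n += 1
            log_pois += math.log(ot) - math.log(n)
            acc += math.exp(log_pois) * self._rpow(n)[a, b]
            if n > 100000:
                raise CoralithError(f"branch {branch}: uniformization overflow")
        if n == 0:
            return [(a, t)]
        times = np.sort(rng.random(n)) * t
        seq = [a]
        for k in range(1, n):
            w = self.R[seq[-1], :] * self._rpow(n - k)[:, b]
            seq.append(0 if float(rng.random()) * w.sum() < w[0] else 1)
        seq.append(b)
        # collapse virtual (self) jumps into dwell segments
        segments: list[tuple[int, float]] = []
        cur_state, cur_start = a, 0.0
        for state, when in zip(seq[1:], list(times)):
            if state != cur_state:
                segments.append((cur_state, when - cur_start))
                cur_state, cur_start = state, when
        segments.append((cur_state, t - cur_start))
        return segments


def sample_maps(tree: dendropy.Tree, states: dict[str, int], model: MkModel,
                n_maps: int = 1000, seed: int = 0) -> StochasticMapSet:
    """Draw stochastic character maps conditional on the tip states."""
    _check_tree(tree, states)
    partials, _ = _partials(tree, states, model)
    rng = np.random.default_rng(derive_seed(seed, "maps"))
    sampler = _Uniformizer(model)
    pri = model.root_pi()

    nodes = list(tree.preorder_node_iter())
    labels = {id(nd): _node_label(nd) for nd in nodes}
    maps: list[StochasticMap] = []
    for _ in range(n_maps):
        node_state: dict[int, int] = {}
        segments: dict[str, list[tuple[int, float]]] = {}
        w = pri * partials[id(tree.seed_node)]
        root_state = int(rng.choice(2, p=w / w.sum()))
        node_state[id(tree.seed_node)] = root_state
        for nd in nodes:
            if nd is tree.seed_node:
                continue
            parent_state = node_state[id(nd.parent_node)]
            w = (model.pmat(nd.edge.length)[parent_state, :]
                 * partials[id(nd)])
            s = int(rng.choice(2, p=w / w.sum()))
            node_state[id(nd)] = s
            segments[labels[id(nd)]] = sampler.sample_path(
                parent_state, s, nd.edge.length, labels[id(nd)], rng)
        maps.append(StochasticMap(
            root_state=root_state,
            node_states={labels[k]: v for k, v in node_state.items()},
            segments=segments))
    return StochasticMapSet(maps=maps, model=model, seed=seed)


@dataclass
class OriginsSummary:
    per_map: list[int]
    mean: float
    median: float
    q025: float
    q975: float
    node_prob: dict[str, float]   # P(node in state 1) across maps


def count_origins(mapset: StochasticMapSet) -> OriginsSummary:
    """Independent 0 -> 1 origins per map, summarised across the map set."""
    counts = [m.origins() for m in mapset.maps]
    arr = np.array(counts, dtype=float)
    node_prob: dict[str, float] = {}
    n = len(mapset.maps)
    for m in mapset.maps:
        for label, s in m.node_states.items():
            node_prob[label] = node_prob.get(label, 0.0) + s
    node_prob = {k: v / n for k, v in node_prob.items()}
    return OriginsSummary(
        per_map=counts,
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        q025=float(np.percentile(arr, 2.5)),
        q975=float(np.percentile(arr, 97.5)),
        node_prob=node_prob,
    )


def read_trait_table(path) -> dict[str, int]:
    """Read a two-column (tip, state) TSV into a state map."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("tip\t"):
                continue
            tip, state = line.split("\t")[:2]
            if state not in ("0", "1"):
                raise InputError(f"tip {tip!r}: state must be 0 or 1")
            out[tip] = int(state)
    return out


def annotated_newick(tree: dendropy.Tree, node_prob: dict[str, float]) -> str:
    """Newick with per-internal-node posterior P(endolithic) as node comments."""
    work = tree.clone(depth=1)
    for nd in work.preorder_node_iter():
        label = _node_label(nd)
        if label in node_prob and not nd.is_leaf():
            nd.annotations.add_new("p_endolithic", round(node_prob[label], 4))
    return work.as_string(schema="newick", suppress_annotations=False)
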
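"""Equal-rates Mk likelihood, rate fitting, marginal ancestral posteriors and
stochastic character mapping.

Model.  A k-state character evolves on a rooted tree under the equal-rates
("ER") continuous-time Markov process: the total leaving rate from any state
is ``alpha``, split equally among the k-1 target states, so

    Q[i][j] = alpha / (k-1)   (i != j),    Q[i][i] = -alpha.

Transition probabilities have the closed form

    P_same(t) = 1/k + (1 - 1/k) * exp(-lam * t)
    P_diff(t) = 1/k - (1/k)   * exp(-lam * t),      lam = alpha * k / (k-1),

so no matrix exponentials are needed.  The root prior is uniform by default.

Likelihoods use Felsenstein pruning with per-node scaling; ancestral node
posteriors come from exact up/down passes; stochastic maps sample complete
character histories by backward filtering / forward sampling of node states
followed by endpoint-conditioned path sampling on each branch via
uniformization.  Because every state's leaving rate equals the
uniformization rate, the uniformized chain never self-transitions: each
sampled jump is a real state change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .trees import Node, Phylo

__all__ = [
    "MkModel",
    "NodePosterior",
    "StochasticMap",
    "StochasticMapSet",
    "MapSummary",
    "ERFit",
    "mk_loglik",
    "fit_er_rate",
    "marginal_posteriors",
    "sample_stochastic_maps",
    "summarize_maps",
]


@dataclass(frozen=True)
class MkModel:
    """Equal-rates Mk model: ``k`` states, total leaving rate ``alpha``."""

    k: int
    alpha: float
    root_prior: Optional[tuple[float, ...]] = None

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.root_prior is not None:
            pi = np.asarray(self.root_prior, float)
            if len(pi) != self.k or abs(pi.sum() - 1.0) > 1e-12 or (pi < 0).any():
                raise ValueError("root_prior must be a length-k probability vector")

    @property
    def prior(self) -> np.ndarray:
        if self.root_prior is None:
            return np.full(self.k, 1.0 / self.k)
        return np.asarray(self.root_prior, float)

    def transition_matrix(self, t: float) -> np.ndarray:
        k = self.k
        if self.alpha == 0 or t == 0:
            return np.eye(k)
        lam = self.alpha * k / (k - 1)
        e = math.exp(-lam * t)
        P = np.full((k, k), (1.0 - e) / k)
        np.fill_diagonal(P, 1.0 / k + (1.0 - 1.0 / k) * e)
        return P


def _check_character(tree: Phylo, character: Mapping[str, int], k: int) -> None:
    for leaf in tree.leaves():
        if leaf.label not in character:
            raise ValueError(f"leaf {leaf.label!r} has no observed state")
        s = character[leaf.label]
        if not 0 <= s < k:
            raise ValueError(f"state {s} at {leaf.label!r} outside 0..{k-1}")


def _pruning_partials(
    tree: Phylo, character: Mapping[str, int], model: MkModel
) -> tuple[dict[Node, np.ndarray], float]:
    """Post-order scaled partial likelihoods; returns (partials, log scale)."""
    k = model.k
    partials: dict[Node, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            v = np.zeros(k)
            v[character[node.label]] = 1.0
        else:
            v = np.ones(k)
            for child in node.children:
                P = model.transition_matrix(child.length or 0.0)
                v = v * (P @ partials[child])
        m = v.max()
        if m > 0:
            v = v / m
            log_scale += math.log(m)
        partials[node] = v
    return partials, log_scale


def mk_loglik(tree: Phylo, character: Mapping[str, int], model: MkModel) -> float:
    """Log-likelihood of the tip states under the ER Mk model (Felsenstein
    pruning with per-node scaling).  Returns ``-inf`` when the data are
    impossible (alpha = 0 with polymorphic tips)."""
    _check_character(tree, character, model.k)
    partials, log_scale = _pruning_partials(tree, character, model)
    lik = float(model.prior @ partials[tree.root])
    if lik <= 0:
        return float("-inf")
    return math.log(lik) + log_scale


@dataclass
class ERFit:
    alpha: float
    loglik: float
    boundary: bool  # True when the optimum sits on the search boundary


def fit_er_rate(
    tree: Phylo,
    character: Mapping[str, int],
    k: int = 2,
    alpha_max: float = 100.0,
    tol: float = 1e-8,
) -> ERFit:
    """Maximum-likelihood ER rate by bounded one-dimensional optimization.

    A monomorphic character gives alpha_hat = 0 with a boundary flag."""
    _check_character(tree, character, k)
    observed = {character[l.label] for l in tree.leaves()}
    if len(observed) < 2:
        model = MkModel(k, 0.0)
        return ERFit(0.0, mk_loglik(tree, character, model), boundary=True)

    def nll(alpha: float) -> float:
        return -mk_loglik(tree, character, MkModel(k, alpha))

    res = minimize_scalar(
        nll, bounds=(1e-12, alpha_max), method="bounded", options={"xatol": tol}
    )
    alpha_hat = float(res.x)
    boundary = alpha_hat <= 10 * tol or alpha_hat >= alpha_max * (1 - 1e-6)
    return ERFit(alpha_hat, -float(res.fun), boundary)


@dataclass
class NodePosterior:
    """Posterior state probabilities on internal nodes, keyed by the sorted
    leaf set of each node's clade.  ``state_labels`` maps the internal state
    indices back to user-facing values (e.g. domain counts)."""

    probs: dict[frozenset, np.ndarray]
    state_labels: tuple = ()

    def __getitem__(self, clade) -> np.ndarray:
        return self.probs[frozenset(clade)]

    def to_rows(self) -> list[dict]:
        labels = self.state_labels or tuple(range(len(next(iter(self.probs.values())))))
        out = []
        for clade in sorted(self.probs, key=lambda c: sorted(c)):
            row = {"clade": ",".join(sorted(clade))}
            for lab, p in zip(labels, self.probs[clade]):
                row[f"p_{lab}"] = float(p)
            out.append(row)
        return out


def marginal_posteriors(
    tree: Phylo, character: Mapping[str, int], model: MkModel
) -> NodePosterior:
    """Exact marginal ancestral-state posteriors via up/down passes."""
    _check_character(tree, character, model.k)
    up, _ = _pruning_partials(tree, character, model)
    # lifted[c] = P(t_c) @ up[c], the message a child sends its parent
    lifted: dict[Node, np.ndarray] = {}
    for node in tree.preorder():
        for child in node.children:
            lifted[child] = model.transition_matrix(child.length or 0.0) @ up[child]
    outside: dict[Node, np.ndarray] = {tree.root: model.prior.copy()}
    for node in tree.preorder():
        base = outside[node]
        for child in node.children:
            sib = base.copy()
            for other in node.children:
                if other is not child:
                    sib = sib * lifted[other]
            P = model.transition_matrix(child.length or 0.0)
            o = P.T @ sib
            m = o.max()
            outside[child] = o / m if m > 0 else o
    probs: dict[frozenset, np.ndarray] = {}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        v = up[node] * outside[node]
        total = v.sum()
        if total <= 0:
            raise ValueError("zero posterior mass (impossible data under model)")
        probs[tree.leaf_set(node)] = v / total
    return NodePosterior(probs)


# ---------------------------------------------------------------------------
# Stochastic mapping
# ---------------------------------------------------------------------------


@dataclass
class StochasticMap:
    """One complete character history: realized node states (keyed by clade
    leaf set; leaves keyed by their own singleton set) and, per branch
    (keyed by the child clade), ordered (state, duration) segments from the
    parent end to the child end."""

    node_states: dict[frozenset, int]
    branch_segments: dict[frozenset, list[tuple[int, float]]]

    def n_transitions(self) -> int:
        return sum(len(segs) - 1 for segs in self.branch_segments.values())

    def dwell_times(self, k: int) -> np.ndarray:
        out = np.zeros(k)
        for segs in self.branch_segments.values():
            for state, dur in segs:
                out[state] += dur
        return out


@dataclass
class StochasticMapSet:
    maps: list[StochasticMap]
    model: MkModel
    tree_total_length: float

    @property
    def n_maps(self) -> int:
        return len(self.maps)


def _sample_bridge(
    a: int, b: int, t: float, model: MkModel, rng: np.random.Generator
) -> list[tuple[int, float]]:
    """Endpoint-conditioned ER path on one branch via uniformization.

    Under the ER model the uniformized jump chain R = I + Q/alpha has zero
    diagonal and off-diagonal 1/(k-1); its n-step probabilities are closed
    form, so the conditional jump count and the bridge states are sampled
    exactly.  Returns merged (state, duration) segments parent->child.
    """
    k, alpha = model.k, model.alpha
    if alpha == 0 or t == 0:
        if a != b:
            raise ValueError("impossible endpoint pair with alpha*t = 0")
        return [(a, t)]

    def rn(n: int, same: bool) -> float:
        # n-step probability of the uniformized chain between two states
        x = (-1.0 / (k - 1)) ** n
        return 1.0 / k + (1.0 - 1.0 / k) * x if same else (1.0 - x) / k

    p_ab = model.transition_matrix(t)[a, b]
    mu = alpha * t
    # sample N | endpoints: P(N=n) = pois(n; mu) * rn(n) / p_ab
    u = rng.random() * p_ab
    n, acc = 0, 0.0
    pois = math.exp(-mu)
    while True:
        acc += pois * rn(n, a == b)
        if u <= acc or n > 10000:
            break
        n += 1
        pois *= mu / n
    # bridge states: R has zero diagonal, so every jump changes state
    states = [a]
    cur = a
    for m in range(1, n):
        left = n - m
        weights = np.empty(k)
        for c in range(k):
            w = 0.0 if c == cur else 1.0 / (k - 1)
            weights[c] = w * rn(left, c == b)
        weights /= weights.sum()
        cur = int(rng.choice(k, p=weights))
        states.append(cur)
    if n > 0:
        states.append(b)
    times = np.sort(rng.random(n)) * t
    bounds = np.concatenate([[0.0], times, [t]])
    segments: list[tuple[int, float]] = []
    for state, lo, hi in zip(states, bounds[:-1], bounds[1:]):
        dur = float(hi - lo)
        if segments and segments[-1][0] == state:
            segments[-1] = (state, segments[-1][1] + dur)
        else:
            segments.append((state, dur))
    return segments


def sample_stochastic_maps(
    tree: Phylo,
    character: Mapping[str, int],
    model: MkModel,
    n_maps: int = 1000,
    seed: int = 0,
) -> StochasticMapSet:
    """Sample complete character histories conditional on the tip states.

    Node states are drawn from the joint conditional distribution (backward
    filtering / forward sampling); branch histories are then sampled
    conditional on their endpoint states by uniformization.
    """
    _check_character(tree, character, model.k)
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    observed = {character[l.label] for l in tree.leaves()}
    if model.alpha == 0 and len(observed) > 1:
        raise ValueError("alpha = 0 cannot produce polymorphic tip states")
    rng = np.random.default_rng(seed)
    up, _ = _pruning_partials(tree, character, model)
    clades = {node: tree.leaf_set(node) for node in tree.preorder()}
    maps: list[StochasticMap] = []
    for _ in range(n_maps):
        states: dict[Node, int] = {}
        w = model.prior * up[tree.root]
        w = w / w.sum()
        states[tree.root] = int(rng.choice(model.k, p=w))
        for node in tree.preorder():
            for child in node.children:
                P = model.transition_matrix(child.length or 0.0)
                w = P[states[node]] * up[child]
                w = w / w.sum()
                states[child] = int(rng.choice(model.k, p=w))
        segments: dict[frozenset, list[tuple[int, float]]] = {}
        for node in tree.preorder():
            for child in node.children:
                segments[clades[child]] = _sample_bridge(
                    states[node], states[child], child.length or 0.0, model, rng
                )
        maps.append(
            StochasticMap(
                node_states={clades[n]: s for n, s in states.items()},
                branch_segments=segments,
            )
        )
    return StochasticMapSet(maps, model, tree.total_length())


@dataclass
class MapSummary:
    posterior: NodePosterior
    dwell_times: np.ndarray  # expected time in each state, summed over tree
    n_transitions: float  # expected number of state changes
    n_maps: int


def summarize_maps(maps: StochasticMapSet) -> MapSummary:
    """Empirical node-state posteriors, expected per-state dwell times and
    expected transition counts across the sampled histories."""
    if maps.n_maps < 1:
        raise ValueError("empty stochastic map set")
    k = maps.model.k
    counts: dict[frozenset, np.ndarray] = {}
    dwell = np.zeros(k)
    n_trans = 0.0
    for m in maps.maps:
        for clade, state in m.node_states.items():
            if len(clade) == 1:
                continue
            counts.setdefault(clade, np.zeros(k))[state] += 1
        dwell += m.dwell_times(k)
        n_trans += m.n_transitions()
    n = maps.n_maps
    posterior = NodePosterior({c: v / n for c, v in counts.items()})
    return MapSummary(posterior, dwell / n, n_trans / n, n)
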
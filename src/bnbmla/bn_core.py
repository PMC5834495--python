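"""Discrete Bayesian-network scoring and structural queries.

Implements the Cooper-Herskovits (K2) marginal likelihood for complete
discrete data, Markov-blanket extraction for a target set, and exhaustive
DAG enumeration with exact structural-feature posteriors on small networks.
The exact posteriors serve as the oracle against which the structure-MCMC
estimates are validated.

Scoring model
-------------
For node i with cardinality r_i and parent set Pa_i inducing q_i observed
parent configurations, the local marginal likelihood under a uniform
Dirichlet(1, ..., 1) parameter prior is

    P(D_i | Pa_i) = prod_j [ (r_i - 1)! / (N_ij + r_i - 1)! * prod_k N_ijk! ]

where N_ijk counts cases with node i in state k under parent configuration j
and N_ij = sum_k N_ijk.  All arithmetic is in log space via log-gamma.  Under
a uniform structure prior the unnormalized log posterior of a DAG is the sum
of local log scores, so posterior ratios reduce to score differences.

A BDeu alternative (Dirichlet(ess / (r_i * q_i))) is available through the
``prior``/``ess`` arguments for sensitivity checks; the Cooper-Herskovits
form is the default and the canonical choice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

MAX_ENUM_NODES = 5

#: Number of labeled DAGs on n nodes (OEIS A003024), used as an enumeration check.
LABELED_DAG_COUNTS = {0: 1, 1: 1, 2: 3, 3: 25, 4: 543, 5: 29281}


@dataclass
class DiscreteDataset:
    """Complete-case discrete data: category-index matrix plus cardinalities."""

    names: list[str]
    cardinalities: np.ndarray  # shape (n_vars,), each >= 2
    data: np.ndarray  # shape (n_cases, n_vars), integer category indices

    def __post_init__(self) -> None:
        self.cardinalities = np.asarray(self.cardinalities, dtype=np.int64)
        self.data = np.asarray(self.data, dtype=np.int64)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.names):
            raise ValueError("data shape does not match variable names")
        if (self.cardinalities < 2).any():
            raise ValueError("every variable needs cardinality >= 2")
        if self.data.size and (
            (self.data < 0).any() or (self.data >= self.cardinalities[None, :]).any()
        ):
            raise ValueError("category index out of range (missing values not allowed)")

    @property
    def n_cases(self) -> int:
        return self.data.shape[0]

    @property
    def n_vars(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, levels: Mapping[str, Sequence] | None = None
    ) -> "DiscreteDataset":
        """Encode dataframe columns as category indices.

        ``levels`` fixes the level order per column; unlisted columns are
        factorized in sorted-value order so the encoding is deterministic.
        """
        levels = levels or {}
        names = list(df.columns)
        cols, cards = [], []
        for name in names:
            if name in levels:
                cat = pd.Categorical(df[name], categories=list(levels[name]))
            else:
                cat = pd.Categorical(df[name], categories=sorted(pd.unique(df[name])))
            if (cat.codes < 0).any():
                raise ValueError(f"column {name!r} has values outside declared levels")
            n_levels = len(cat.categories)
            if n_levels < 2:
                raise ValueError(f"column {name!r} is constant; cardinality must be >= 2")
            cols.append(cat.codes.astype(np.int64))
            cards.append(n_levels)
        return cls(names, np.array(cards), np.column_stack(cols) if cols else np.empty((0, 0)))


@dataclass(frozen=True)
class DAGStructure:
    """Directed acyclic graph given as per-node parent sets."""

    nodes: tuple[str, ...]
    parents: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for node, pa in self.parents.items():
            if node in pa:
                raise ValueError(f"node {node!r} is its own parent")
        if self._has_cycle():
            raise ValueError("graph contains a directed cycle")

    def _has_cycle(self) -> bool:
        indeg = {n: len(self.parents.get(n, frozenset())) for n in self.nodes}
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for child, pas in self.parents.items():
            for p in pas:
                children[p].append(child)
        queue = [n for n, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            n = queue.pop()
            seen += 1
            for c in children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        return seen != len(self.nodes)

    @classmethod
    def from_edges(cls, nodes: Sequence[str], edges: Iterable[tuple[str, str]]) -> "DAGStructure":
        parents: dict[str, set[str]] = {n: set() for n in nodes}
        for u, v in edges:
            parents[v].add(u)
        return cls(tuple(nodes), {n: frozenset(p) for n, p in parents.items()})

    def edges(self) -> list[tuple[str, str]]:
        return sorted((p, n) for n, pas in self.parents.items() for p in pas)

    def to_adjacency(self, order: Sequence[str] | None = None) -> np.ndarray:
        order = list(order or self.nodes)
        idx = {n: i for i, n in enumerate(order)}
        adj = np.zeros((len(order), len(order)), dtype=bool)
        for parent, child in self.edges():
            adj[idx[parent], idx[child]] = True
        return adj

    @classmethod
    def from_adjacency(cls, adj: np.ndarray, nodes: Sequence[str]) -> "DAGStructure":
        parents = {
            n: frozenset(nodes[u] for u in np.flatnonzero(adj[:, v]))
            for v, n in enumerate(nodes)
        }
        return cls(tuple(nodes), parents)


class ScoreCache:
    """Memoizes local log scores keyed by (node index, sorted parent indices)."""

    def __init__(self) -> None:
        self._store: dict[tuple[int, tuple[int, ...]], float] = {}
        self.hits = 0
        self.misses = 0

    def get_or_compute(
        self, key: tuple[int, tuple[int, ...]], compute: Callable[[], float]
    ) -> float:
        try:
            value = self._store[key]
            self.hits += 1
            return value
        except KeyError:
            self.misses += 1
            value = compute()
            self._store[key] = value
            return value

    def __len__(self) -> int:
        return len(self._store)


def _local_logscore_indexed(
    data: np.ndarray,
    cards: np.ndarray,
    node: int,
    parent_idx: tuple[int, ...],
    prior: str = "ch",
    ess: float = 1.0,
) -> float:
    """Local log marginal likelihood of ``node`` given parents, by index."""
    r = int(cards[node])
    child = data[:, node]
    if parent_idx:
        q = int(np.prod(cards[list(parent_idx)]))
        code = np.zeros(data.shape[0], dtype=np.int64)
        for p in parent_idx:
            code = code * cards[p] + data[:, p]
        counts = np.bincount(code * r + child, minlength=q * r).reshape(q, r)
    else:
        q = 1
        counts = np.bincount(child, minlength=r).reshape(1, r)
    n_ij = counts.sum(axis=1)
    if prior == "ch":
        # Cooper-Herskovits / K2: Dirichlet(1,...,1) per parent configuration.
        score = gammaln(r) - gammaln(n_ij + r) + gammaln(counts + 1).sum(axis=1)
    elif prior == "bdeu":
        a_ij = ess / q
        a_ijk = ess / (q * r)
        score = (
            gammaln(a_ij)
            - gammaln(n_ij + a_ij)
            + (gammaln(counts + a_ijk) - gammaln(a_ijk)).sum(axis=1)
        )
    else:
        raise ValueError(f"unknown parameter prior {prior!r}")
    return float(score.sum())


def ch_local_logscore(
    data: DiscreteDataset,
    node: str,
    parent_set: Iterable[str],
    prior: str = "ch",
    ess: float = 1.0,
) -> float:
    """Log local score of ``node`` given ``parent_set`` (Cooper-Herskovits default)."""
    parents = tuple(sorted(parent_set))
    if node in parents:
        raise ValueError(f"node {node!r} in its own parent set")
    i = data.index(node)
    pidx = tuple(data.index(p) for p in parents)
    return _local_logscore_indexed(data.data, data.cardinalities, i, pidx, prior, ess)


def dag_logscore(
    data: DiscreteDataset,
    dag: DAGStructure,
    cache: ScoreCache | None = None,
    prior: str = "ch",
    ess: float = 1.0,
) -> float:
    """Log marginal likelihood of a DAG: sum of local scores (decomposable)."""
    total = 0.0
    for node in dag.nodes:
        i = data.index(node)
        pidx = tuple(sorted(data.index(p) for p in dag.parents.get(node, frozenset())))
        if cache is not None:
            total += cache.get_or_compute(
                (i, pidx),
                lambda i=i, pidx=pidx: _local_logscore_indexed(
                    data.data, data.cardinalities, i, pidx, prior, ess
                ),
            )
        else:
            total += _local_logscore_indexed(data.data, data.cardinalities, i, pidx, prior, ess)
    return total


def markov_blanket(dag: DAGStructure, targets: Iterable[str]) -> frozenset[str]:
    """Markov blanket of a target set: parents, children and co-parents of children.

    The union is taken over all targets; the targets themselves are excluded.
    """
    targets = set(targets)
    unknown = targets - set(dag.nodes)
    if unknown:
        raise KeyError(f"unknown target(s): {sorted(unknown)}")
    blanket: set[str] = set()
    for t in targets:
        blanket |= dag.parents.get(t, frozenset())
        for child, pas in dag.parents.items():
            if t in pas:
                blanket.add(child)
                blanket |= pas
    return frozenset(blanket - targets)


def mb_adjacency(adj: np.ndarray, target_idx: np.ndarray) -> np.ndarray:
    """Boolean Markov-blanket membership vector from an adjacency matrix.

    Vectorized equivalent of :func:`markov_blanket` used in the MCMC inner
    loop: parents (incoming), children (outgoing) and co-parents of children.
    """
    is_target = np.zeros(adj.shape[0], dtype=bool)
    is_target[target_idx] = True
    parents = adj[:, target_idx].any(axis=1)
    children = adj[target_idx, :].any(axis=0)
    spouses = adj[:, children].any(axis=1) if children.any() else np.zeros_like(parents)
    return (parents | children | spouses) & ~is_target


def enumerate_dags(
    n_nodes: int, max_parents: int | None = None, names: Sequence[str] | None = None
) -> Iterator[DAGStructure]:
    """Yield every labeled DAG on ``n_nodes`` nodes once (parent bound optional).

    Guarded at 5 nodes: the labeled-DAG count grows super-exponentially
    (29 281 at five nodes) and this enumeration exists as a small-instance
    oracle, not a scalable algorithm.
    """
    if n_nodes > MAX_ENUM_NODES:
        raise ValueError(f"enumeration limited to {MAX_ENUM_NODES} nodes, got {n_nodes}")
    names = list(names or [f"X{i}" for i in range(n_nodes)])
    if len(names) != n_nodes:
        raise ValueError("names length mismatch")
    max_parents = n_nodes - 1 if max_parents is None else min(max_parents, n_nodes - 1)
    all_nodes = list(range(n_nodes))
    # Candidate parent sets per node, as bitmasks.
    candidate_sets = [
        [
            sum(1 << p for p in combo)
            for size in range(max_parents + 1)
            for combo in itertools.combinations([p for p in all_nodes if p != v], size)
        ]
        for v in all_nodes
    ]

    def acyclic(parent_masks: tuple[int, ...]) -> bool:
        remaining = set(all_nodes)
        removed_mask = 0
        while remaining:
            sinks = [v for v in remaining if parent_masks[v] & ~removed_mask == 0]
            if not sinks:
                return False
            for v in sinks:
                remaining.discard(v)
                removed_mask |= 1 << v
        return True

    for combo in itertools.product(*candidate_sets):
        if acyclic(combo):
            parents = {
                names[v]: frozenset(names[p] for p in all_nodes if combo[v] >> p & 1)
                for v in all_nodes
            }
            yield DAGStructure(tuple(names), parents)


def exact_feature_posterior(
    data: DiscreteDataset,
    targets: Iterable[str],
    feature: Callable[[DAGStructure], bool],
    max_parents: int | None = None,
    prior: str = "ch",
    ess: float = 1.0,
) -> float:
    """Exact posterior of a structural feature by full DAG enumeration.

    Computes sum of exp(log score) over DAGs satisfying ``feature`` divided
    by the sum over all DAGs (uniform structure prior cancels), with both
    sums evaluated through log-sum-exp.  Only feasible on <= 5 variables.
    """
    if data.n_vars > MAX_ENUM_NODES:
        raise ValueError("exact enumeration limited to 5 variables")
    targets = set(targets)
    cache = ScoreCache()
    log_all: list[float] = []
    log_hit: list[float] = []
    for dag in enumerate_dags(data.n_vars, max_parents, names=data.names):
        ls = dag_logscore(data, dag, cache, prior, ess)
        log_all.append(ls)
        if feature(dag):
            log_hit.append(ls)
    if not log_hit:
        return 0.0
    return float(np.exp(logsumexp(log_hit) - logsumexp(log_all)))


def exact_mbm_posteriors(
    data: DiscreteDataset,
    targets: Iterable[str],
    max_parents: int | None = None,
    prior: str = "ch",
    ess: float = 1.0,
) -> tuple[dict[str, float], dict[frozenset[str], float]]:
    """Exact Markov-blanket-membership and joint-pair posteriors for every variable.

    One enumeration pass shared across all features; returns
    ``(marginals, pair_posteriors)`` where pair posteriors cover unordered
    non-target pairs both belonging to MB(targets).
    """
    targets = set(targets)
    others = [n for n in data.names if n not in targets]
    cache = ScoreCache()
    log_all: list[float] = []
    log_member: dict[str, list[float]] = {n: [] for n in others}
    pairs = [frozenset(p) for p in itertools.combinations(others, 2)]
    log_pair: dict[frozenset[str], list[float]] = {p: [] for p in pairs}
    for dag in enumerate_dags(data.n_vars, max_parents, names=data.names):
        ls = dag_logscore(data, dag, cache, prior, ess)
        log_all.append(ls)
        mb = markov_blanket(dag, targets)
        for n in mb:
            if n in log_member:
                log_member[n].append(ls)
        for p in pairs:
            if p <= mb:
                log_pair[p].append(ls)
    z = logsumexp(log_all)
    marg = {
        n: float(np.exp(logsumexp(v) - z)) if v else 0.0 for n, v in log_member.items()
    }
    joint = {p: float(np.exp(logsumexp(v) - z)) if v else 0.0 for p, v in log_pair.items()}
    return marg, joint
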
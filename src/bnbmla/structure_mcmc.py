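"""Metropolis-Hastings structure MCMC over DAGs with feature counting.

The sampler performs a random walk in the space of directed acyclic graphs
via single-edge moves (add, delete, reverse), scores states with the
decomposable Cooper-Herskovits marginal likelihood, and accumulates counts
of structural features — Markov-blanket membership of each variable with
respect to a target set, joint membership of variable pairs, and directed
edges — over the post-burn-in samples.  Sample frequencies of these counts
estimate the corresponding posterior probabilities under the uniform
structure prior.

Proposals are drawn uniformly from the valid single-edge neighborhood of
the current DAG (moves that would create a cycle or exceed the parent bound
are excluded before sampling), so the Hastings correction is the log ratio
of neighborhood sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .bn_core import (
    DAGStructure,
    DiscreteDataset,
    ScoreCache,
    _local_logscore_indexed,
    mb_adjacency,
)

logger = logging.getLogger(__name__)

ADD, DELETE, REVERSE = 0, 1, 2


@dataclass
class McmcConfig:
    """Sampler settings.

    The paper-faithful profile is 10^6 burn-in and 5 x 10^6 sampling steps
    with at most 5 parents per node; the desk profile (default here) is a
    scaled-down run for tests and iteration.  ``n_chains`` independent
    chains are run from per-chain seeds split off the master seed and their
    counters pooled.
    """

    burn_in: int = 10_000
    n_steps: int = 50_000
    max_parents: int = 5
    seed: int = 0
    thinning: int = 1
    n_chains: int = 3
    prior: str = "ch"
    ess: float = 1.0

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.n_steps < 0:
            raise ValueError("burn_in and n_steps must be non-negative")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @classmethod
    def paper_faithful(cls, seed: int = 0) -> "McmcConfig":
        return cls(burn_in=1_000_000, n_steps=5_000_000, max_parents=5, seed=seed)


@dataclass
class ChainCounters:
    """Feature counters for one chain."""

    mbm_counts: np.ndarray  # (n_vars,)
    pair_counts: np.ndarray  # (n_vars, n_vars), symmetric, zero diagonal
    edge_counts: np.ndarray  # (n_vars, n_vars) ordered
    n_recorded: int
    n_accepted: int
    n_proposed: int
    logscore_trace: np.ndarray

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else 0.0


@dataclass
class McmcRun:
    """Pooled feature counters from one or more chains.

    Posterior estimates are sample frequencies: ``mbm_counts[i] /
    n_recorded`` estimates the probability that variable i lies in the
    Markov blanket of the targets, and ``pair_counts[i, j] / n_recorded``
    the probability that i and j are members jointly.
    """

    names: list[str]
    targets: list[str]
    chains: list[ChainCounters]
    config: McmcConfig

    @property
    def n_recorded(self) -> int:
        return sum(c.n_recorded for c in self.chains)

    @property
    def mbm_counts(self) -> np.ndarray:
        return np.sum([c.mbm_counts for c in self.chains], axis=0)

    @property
    def pair_counts(self) -> np.ndarray:
        return np.sum([c.pair_counts for c in self.chains], axis=0)

    @property
    def edge_counts(self) -> np.ndarray:
        return np.sum([c.edge_counts for c in self.chains], axis=0)

    @property
    def acceptance_rate(self) -> float:
        proposed = sum(c.n_proposed for c in self.chains)
        accepted = sum(c.n_accepted for c in self.chains)
        return accepted / proposed if proposed else 0.0

    def check_counters(self) -> None:
        """Assert the internal consistency invariants of the counters."""
        for c in self.chains + [self]:
            if (np.asarray(c.mbm_counts) > c.n_recorded).any():
                raise AssertionError("mbm count exceeds n_recorded")
            pc = np.asarray(c.pair_counts)
            if not np.array_equal(pc, pc.T) or np.diagonal(pc).any():
                raise AssertionError("pair_counts not symmetric/hollow")
            mb = np.asarray(c.mbm_counts)
            if (pc > np.minimum(mb[:, None], mb[None, :])).any():
                raise AssertionError("pair count exceeds a marginal count")


def _transitive_closure(adj: np.ndarray) -> np.ndarray:
    """Reachability by paths of length >= 1, via boolean matrix squaring."""
    reach = adj.copy()
    n = adj.shape[0]
    steps = max(1, int(np.ceil(np.log2(n)))) if n > 1 else 1
    for _ in range(steps):
        new = reach | (reach @ reach)
        if np.array_equal(new, reach):
            break
        reach = new
    return reach


def _valid_moves(adj: np.ndarray, max_parents: int) -> np.ndarray:
    """Stacked boolean masks (3, n, n) of valid add/delete/reverse moves.

    add(u, v): no edge either way, no existing path v -> u (cycle guard),
    v under the parent bound.  delete(u, v): the edge exists.  reverse(u, v):
    the edge exists, u is under the parent bound (it gains v as a parent),
    and no alternate directed path u -> v of length >= 2 exists — in a DAG
    any such path avoids the edge (u, v) itself, so A @ reach detects it.
    """
    n = adj.shape[0]
    reach = _transitive_closure(adj)
    indeg = adj.sum(axis=0)
    off_diag = ~np.eye(n, dtype=bool)
    can_add = off_diag & ~adj & ~adj.T & ~reach.T & (indeg[None, :] < max_parents)
    can_delete = adj.copy()
    two_step = adj @ reach
    can_reverse = adj & ~two_step & (indeg[:, None] < max_parents)
    return np.stack([can_add, can_delete, can_reverse])


def propose_move(
    dag: DAGStructure, max_parents: int, rng: np.random.Generator
) -> tuple[DAGStructure, float]:
    """Propose a uniform single-edge move; return (candidate, log Hastings ratio).

    The ratio is log q(dag | candidate) - log q(candidate | dag) =
    log(|N(dag)| / |N(candidate)|) for uniform proposals over the valid
    neighborhoods N.  If no valid move exists the identity move is returned
    with ratio 0 (unreachable in practice for max_parents >= 1).
    """
    nodes = list(dag.nodes)
    adj = dag.to_adjacency(nodes)
    moves = _valid_moves(adj, max_parents)
    n_current = int(moves.sum())
    if n_current == 0:
        return dag, 0.0
    flat = np.flatnonzero(moves.reshape(-1))
    choice = int(rng.integers(n_current))
    kind, u, v = np.unravel_index(flat[choice], moves.shape)
    cand = adj.copy()
    _apply_move(cand, int(kind), int(u), int(v))
    n_candidate = int(_valid_moves(cand, max_parents).sum())
    log_ratio = float(np.log(n_current) - np.log(n_candidate))
    return DAGStructure.from_adjacency(cand, nodes), log_ratio


def _apply_move(adj: np.ndarray, kind: int, u: int, v: int) -> None:
    if kind == ADD:
        adj[u, v] = True
    elif kind == DELETE:
        adj[u, v] = False
    else:
        adj[u, v] = False
        adj[v, u] = True


def _run_chain(
    data: DiscreteDataset,
    target_idx: np.ndarray,
    config: McmcConfig,
    seed: np.random.SeedSequence,
    cache: ScoreCache,
    initial_adj: np.ndarray | None = None,
) -> ChainCounters:
    rng = np.random.default_rng(seed)
    n = data.n_vars
    X, cards = data.data, data.cardinalities
    adj = np.zeros((n, n), dtype=bool) if initial_adj is None else initial_adj.copy()

    def local(node: int, parent_mask: np.ndarray) -> float:
        pidx = tuple(np.flatnonzero(parent_mask))
        return cache.get_or_compute(
            (node, pidx),
            lambda: _local_logscore_indexed(X, cards, node, pidx, config.prior, config.ess),
        )

    node_scores = np.array([local(v, adj[:, v]) for v in range(n)])

    mbm = np.zeros(n, dtype=np.int64)
    pairs = np.zeros((n, n), dtype=np.int64)
    edges = np.zeros((n, n), dtype=np.int64)
    n_recorded = 0
    n_accepted = 0
    total_steps = config.burn_in + config.n_steps
    trace_every = max(1, total_steps // 1000)
    trace: list[float] = []

    moves = _valid_moves(adj, config.max_parents)
    n_moves = int(moves.sum())
    for step in range(total_steps):
        if n_moves == 0:  # pragma: no cover - unreachable for max_parents >= 1
            accepted = False
        else:
            flat = np.flatnonzero(moves.reshape(-1))
            kind, u, v = np.unravel_index(flat[int(rng.integers(n_moves))], moves.shape)
            kind, u, v = int(kind), int(u), int(v)
            cand = adj.copy()
            _apply_move(cand, kind, u, v)
            # Only the child nodes of the touched edge change local score.
            delta = local(v, cand[:, v]) - node_scores[v]
            if kind == REVERSE:
                delta += local(u, cand[:, u]) - node_scores[u]
            cand_moves = _valid_moves(cand, config.max_parents)
            n_cand_moves = int(cand_moves.sum())
            log_alpha = delta + np.log(n_moves) - np.log(n_cand_moves)
            accepted = log_alpha >= 0 or rng.random() < np.exp(log_alpha)
            if accepted:
                adj = cand
                node_scores[v] = local(v, adj[:, v])
                if kind == REVERSE:
                    node_scores[u] = local(u, adj[:, u])
                moves, n_moves = cand_moves, n_cand_moves
                n_accepted += 1
        if step >= config.burn_in and (step - config.burn_in) % config.thinning == 0:
            mb = mb_adjacency(adj, target_idx)
            mbm += mb
            pairs += mb[:, None] & mb[None, :]
            edges += adj
            n_recorded += 1
        if step % trace_every == 0:
            trace.append(float(node_scores.sum()))
    np.fill_diagonal(pairs, 0)
    return ChainCounters(
        mbm_counts=mbm,
        pair_counts=pairs,
        edge_counts=edges,
        n_recorded=n_recorded,
        n_accepted=n_accepted,
        n_proposed=total_steps,
        logscore_trace=np.array(trace),
    )


def run_structure_mcmc(
    data: DiscreteDataset, targets: Iterable[str], config: McmcConfig
) -> McmcRun:
    """Run the structure MCMC and return pooled feature counters.

    Chains start from the empty DAG with seeds spawned deterministically
    from ``config.seed``; the score cache is shared across chains (cached
    local scores are exact, so sharing does not couple the chains
    statistically).
    """
    targets = list(targets)
    if not targets:
        raise ValueError("empty target set")
    if data.n_cases == 0:
        raise ValueError("empty dataset")
    target_idx = np.array([data.index(t) for t in targets])
    cache = ScoreCache()
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = [
        _run_chain(data, target_idx, config, seed, cache) for seed in seeds
    ]
    run = McmcRun(list(data.names), targets, chains, config)
    if run.n_recorded == 0:
        logger.warning("no recorded states (n_steps=%d): posteriors undefined", config.n_steps)
    run.check_counters()
    return run


def mbm_posterior(run: McmcRun, variable: str) -> float:
    """Markov-blanket-membership posterior of one variable (pooled chains)."""
    if run.n_recorded == 0:
        raise ValueError("no recorded samples: posterior undefined")
    return float(run.mbm_counts[run.names.index(variable)] / run.n_recorded)


def pair_posterior(run: McmcRun, var_a: str, var_b: str) -> float:
    """Posterior that two variables are jointly in the target Markov blanket."""
    if run.n_recorded == 0:
        raise ValueError("no recorded samples: posterior undefined")
    i, j = run.names.index(var_a), run.names.index(var_b)
    if i == j:
        raise ValueError("pair posterior needs two distinct variables")
    return float(run.pair_counts[i, j] / run.n_recorded)


def edge_posterior(run: McmcRun, parent: str, child: str) -> float:
    """Posterior probability of the directed edge parent -> child."""
    if run.n_recorded == 0:
        raise ValueError("no recorded samples: posterior undefined")
    return float(run.edge_counts[run.names.index(parent), run.names.index(child)] / run.n_recorded)


@dataclass
class ConvergenceReport:
    """Between-chain agreement diagnostics for the MBM posteriors."""

    per_chain_posteriors: np.ndarray  # (n_chains, n_vars)
    max_spread: float
    acceptance_rate: float
    warn: bool
    degraded: bool  # single chain: spread not assessable
    logscore_final: float

    def __str__(self) -> str:
        status = "DEGRADED (single chain)" if self.degraded else (
            "WARN" if self.warn else "ok"
        )
        return (
            f"convergence: max between-chain MBM spread {self.max_spread:.4f} "
            f"[{status}], acceptance rate {self.acceptance_rate:.3f}"
        )


def convergence_report(run: McmcRun, warn_threshold: float = 0.05) -> ConvergenceReport:
    """Between-chain spread of MBM posteriors; warns when the range exceeds 0.05."""
    posteriors = np.array(
        [
            c.mbm_counts / c.n_recorded if c.n_recorded else np.full(len(run.names), np.nan)
            for c in run.chains
        ]
    )
    degraded = len(run.chains) < 2
    if degraded:
        spread = float("nan")
        warn = True
    else:
        spread = float((posteriors.max(axis=0) - posteriors.min(axis=0)).max())
        warn = spread > warn_threshold
    final = float(np.mean([c.logscore_trace[-1] for c in run.chains if len(c.logscore_trace)]))
    return ConvergenceReport(
        per_chain_posteriors=posteriors,
        max_spread=spread,
        acceptance_rate=run.acceptance_rate,
        warn=warn,
        degraded=degraded,
        logscore_final=final,
    )
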
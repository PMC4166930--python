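"""Metropolis–Hastings kernel, Metropolis-coupled chains and run driver.

Heated chains target the likelihood-tempered posterior
``pi_i(x) ∝ L(x)^{beta_i} · prior(x)`` with incremental heating
``beta_i = 1/(1 + i·Δ)``; the cold chain (``beta_0 = 1``) is the one
sampled.  Tempering only the likelihood keeps every heated target proper
under the unbounded branch-length prior, and makes the state-swap
acceptance ratio ``min(1, exp((beta_a − beta_b)(ℓ_b − ℓ_a)))`` — the prior
terms cancel because all chains share the same (untempered) prior.

Swaps are organized by a ticketed, nonblocking scheduler: every swap
interval one uniformly random adjacent-heat pair receives a ticket that
resolves a configurable number of generations (the lag) later, using the
chains' states at resolution time; chains never wait on one another.  With
lag 0 the scheduler is the classic synchronous coupling; any lag leaves
the cold chain's stationary distribution unchanged, because a swap between
two chains is a valid joint-kernel move at whatever generation it happens.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evolmodel import LinkageMap, ModelState, PriorConfig, log_prior
from .likelihood import LikelihoodEngine, LikelihoodError
from .msa_io import PatternMatrix
from .parsimony import stepwise_addition_tree
from .proposals import Proposal, autotune, default_move_set
from .tree import Tree

__all__ = [
    "heat", "PhyloChain", "DiscreteChain", "attempt_swap", "SwapTicket",
    "SwapScheduler", "RunConfig", "RunResult", "run",
    "write_trace_tsv", "write_topologies_nexus",
]


def heat(i: int, delta: float) -> float:
    """Incremental-heating inverse temperature: beta_i = 1 / (1 + i·Δ)."""
    if i < 0 or delta <= 0:
        raise ValueError("need chain index >= 0 and Δ > 0")
    return 1.0 / (1.0 + i * delta)


class PhyloChain:
    """One MCMC chain over (tree, substitution parameters) at heat β."""

    def __init__(self, tree: Tree, model_state: ModelState,
                 pattern_matrix: PatternMatrix | None,
                 priors: PriorConfig, proposals: list[Proposal] | None = None,
                 beta: float = 1.0, rng: np.random.Generator | None = None,
                 mem_mode: str = "full", sample_model_params: bool = True):
        self.tree = tree
        self.model_state = model_state
        self.patterns = pattern_matrix
        self.priors = priors
        self.beta = beta
        self.rng = rng or np.random.default_rng()
        self.sample_model_params = sample_model_params
        self.proposals = [p for p in (proposals or default_move_set())
                          if p.applicable(self)]
        self._weights = np.array([p.weight for p in self.proposals])
        self._weights = self._weights / self._weights.sum()
        self.engine = (LikelihoodEngine(pattern_matrix, model_state=model_state,
                                        mem_mode=mem_mode)
                       if pattern_matrix is not None else None)
        self.generation = 0
        self.log_like = self.engine.loglik(tree) if self.engine else 0.0
        self.log_prior = log_prior(model_state, tree, priors)
        if not math.isfinite(self.log_prior):
            raise ValueError("initial state has zero prior density")

    # state swapping support (MC³ exchanges states, chain keeps its heat)
    _SWAPPED = ("tree", "model_state", "engine", "log_like", "log_prior")

    def step(self) -> bool:
        """One Metropolis–Hastings update; returns acceptance."""
        rng = self.rng
        idx = int(rng.choice(len(self.proposals), p=self._weights))
        prop = self.proposals[idx]
        prop.attempts += 1
        if self.engine is not None:
            self.engine.begin()
        rec = prop.propose(self, rng)
        new_lp = log_prior(self.model_state, self.tree, self.priors)
        accepted = False
        if math.isfinite(new_lp):
            try:
                new_ll = self.engine.loglik(self.tree) if self.engine else 0.0
                log_ratio = (self.beta * (new_ll - self.log_like)
                             + (new_lp - self.log_prior) + rec.log_hastings)
                accepted = log_ratio >= 0 or rng.random() < math.exp(log_ratio)
            except LikelihoodError as exc:
                warnings.warn(f"move {rec.name} rejected: {exc}")
        if accepted:
            self.log_like = new_ll
            self.log_prior = new_lp
            prop.accepts += 1
            if self.engine is not None:
                self.engine.commit()
        else:
            rec.undo()
            if self.engine is not None:
                self.engine.rollback()
        self.generation += 1
        return accepted

    def audit(self, tol: float = 1e-6) -> None:
        """Verify cached log-likelihood/prior against from-scratch values."""
        if self.engine is not None:
            fresh = LikelihoodEngine(self.patterns, model_state=self.model_state)
            ll = fresh.loglik(self.tree)
            if abs(ll - self.log_like) > tol:
                raise LikelihoodError(
                    f"cached log-likelihood {self.log_like} deviates from "
                    f"recomputed {ll} at generation {self.generation}")
        lp = log_prior(self.model_state, self.tree, self.priors)
        if abs(lp - self.log_prior) > tol:
            raise LikelihoodError("cached log-prior deviates from recomputation")

    def tune(self, window: int = 100) -> None:
        for p in self.proposals:
            if p.attempts >= window:
                autotune(p, p.accepts / p.attempts)
                p.attempts = 0
                p.accepts = 0


class DiscreteChain:
    """A chain on a small enumerable target (for sampler validation).

    States are ``0..m-1`` with posterior masses ``target``; the proposal is
    uniform over the other states (symmetric).  ``log_like`` is the log
    target mass and the prior is flat, so the same MH and swap rules apply
    as for tree chains.
    """

    def __init__(self, target, beta: float = 1.0,
                 rng: np.random.Generator | None = None, state: int = 0):
        self.target = np.asarray(target, dtype=float)
        self.target = self.target / self.target.sum()
        self.beta = beta
        self.rng = rng or np.random.default_rng()
        self.state = state
        self.generation = 0

    _SWAPPED = ("state",)

    @property
    def log_like(self) -> float:
        return float(np.log(self.target[self.state]))

    @property
    def log_prior(self) -> float:
        return 0.0

    def step(self) -> bool:
        m = self.target.size
        prop = int(self.rng.integers(m - 1))
        if prop >= self.state:
            prop += 1
        log_ratio = self.beta * (math.log(self.target[prop])
                                 - math.log(self.target[self.state]))
        accepted = log_ratio >= 0 or self.rng.random() < math.exp(log_ratio)
        if accepted:
            self.state = prop
        self.generation += 1
        return accepted


def attempt_swap(chain_a, chain_b, rng: np.random.Generator) -> bool:
    """Propose exchanging the states of two coupled chains.

    Acceptance ``min(1, exp((β_a − β_b)(ℓ_b − ℓ_a)))``; the shared untempered
    prior cancels.  On acceptance the chains trade states (each chain keeps
    its heat and RNG stream), so the cold chain's identity is preserved.
    """
    if chain_a.generation != chain_b.generation:
        raise RuntimeError("swap between chains at different generations "
                           "(scheduler bug)")
    log_ratio = (chain_a.beta - chain_b.beta) * (chain_b.log_like - chain_a.log_like)
    accepted = log_ratio >= 0 or rng.random() < math.exp(log_ratio)
    if accepted:
        for attr in type(chain_a)._SWAPPED:
            tmp = getattr(chain_a, attr)
            setattr(chain_a, attr, getattr(chain_b, attr))
            setattr(chain_b, attr, tmp)
    return accepted


@dataclass
class SwapTicket:
    pair: tuple[int, int]
    issued_generation: int
    resolve_generation: int
    status: str = "pending"      # pending | resolved
    accepted: bool | None = None


class SwapScheduler:
    """Ticketed (nonblocking) swap scheduling between coupled chains.

    Every ``interval`` generations one uniformly random adjacent-heat pair
    without a pending ticket is ticketed; the ticket resolves ``lag``
    generations later using both chains' states at that generation.  All
    chains advance every generation regardless of pending tickets.
    """

    def __init__(self, n_chains: int, interval: int = 1, lag: int = 0,
                 rng: np.random.Generator | None = None):
        if n_chains < 2:
            raise ValueError("need at least two coupled chains")
        self.n_chains = n_chains
        self.interval = interval
        self.lag = lag
        self.rng = rng or np.random.default_rng()
        self.tickets: list[SwapTicket] = []
        self.pair_attempts: dict[tuple[int, int], int] = {}
        self.pair_accepts: dict[tuple[int, int], int] = {}

    def _pending_members(self) -> set[int]:
        return {i for t in self.tickets if t.status == "pending" for i in t.pair}

    def tick(self, generation: int) -> None:
        """Issue a ticket if due this generation."""
        if generation % self.interval != 0:
            return
        busy = self._pending_members()
        free_pairs = [(i, i + 1) for i in range(self.n_chains - 1)
                      if i not in busy and i + 1 not in busy]
        if not free_pairs:
            return
        pair = free_pairs[int(self.rng.integers(len(free_pairs)))]
        self.tickets.append(SwapTicket(pair, generation, generation + self.lag))

    def resolve(self, chains, generation: int) -> list[SwapTicket]:
        """Resolve due tickets with the chains' current states."""
        done = []
        for t in self.tickets:
            if t.status == "pending" and generation >= t.resolve_generation:
                i, j = t.pair
                acc = attempt_swap(chains[i], chains[j], self.rng)
                t.status = "resolved"
                t.accepted = acc
                self.pair_attempts[t.pair] = self.pair_attempts.get(t.pair, 0) + 1
                if acc:
                    self.pair_accepts[t.pair] = self.pair_accepts.get(t.pair, 0) + 1
                done.append(t)
        self.tickets = [t for t in self.tickets if t.status == "pending"]
        return done


def run_coupled(chains, n_generations: int, scheduler: SwapScheduler | None,
                sample_every: int = 0, on_sample=None,
                tune_until: int = 0, audit_every: int = 1000):
    """Advance coupled chains for ``n_generations``, swapping via the
    scheduler and sampling the cold chain."""
    if sample_every and on_sample is not None:
        on_sample(chains[0])
    for gen in range(1, n_generations + 1):
        for chain in chains:
            chain.step()
        if scheduler is not None:
            scheduler.tick(gen)
            scheduler.resolve(chains, gen)
        if tune_until and gen <= tune_until:
            for chain in chains:
                chain.tune()
        if audit_every and gen % audit_every == 0:
            for chain in chains:
                if hasattr(chain, "audit"):
                    chain.audit()
        if sample_every and gen % sample_every == 0 and on_sample is not None:
            on_sample(chains[0])
    return chains


# ----------------------------------------------------------------- run API

@dataclass
class RunConfig:
    n_runs: int = 2
    n_coupled_chains: int = 1
    n_generations: int = 10000
    sample_every: int = 100
    heat_increment: float = 0.1
    swap_interval: int = 1
    swap_lag: int = 0
    seed: int = 0
    burnin_fraction: float = 0.33
    mem_mode: str = "full"
    start: str = "parsimony"          # parsimony | random | <newick string>
    n_gamma_cats: int = 4
    tune: bool = True
    audit_every: int = 1000
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self):
        if min(self.n_runs, self.n_coupled_chains, self.sample_every,
               self.swap_interval) < 1 or self.n_generations < 0:
            raise ValueError("run configuration fields must be positive")


@dataclass
class RunResult:
    trace: pd.DataFrame
    topologies: list[str]
    chains: list[PhyloChain]
    scheduler: SwapScheduler | None


def _start_tree(config: RunConfig, pattern_matrix: PatternMatrix | None,
                taxon_names: list[str], rng: np.random.Generator) -> Tree:
    if config.start == "parsimony" and pattern_matrix is not None:
        return stepwise_addition_tree(pattern_matrix, rng)
    if config.start == "random" or pattern_matrix is None:
        return Tree.from_random_joins(taxon_names, rng)
    if config.start.lstrip().startswith("("):
        from .tree import parse_newick
        return parse_newick(config.start, taxon_names)
    raise ValueError(f"unknown start option {config.start!r}")


def _trace_row(chain: PhyloChain) -> dict:
    ms = chain.model_state
    row = {
        "generation": chain.generation,
        "log_likelihood": chain.log_like,
        "log_prior": chain.log_prior,
        "tree_length": chain.tree.tree_length(),
    }
    for g, a in enumerate(ms.alpha_groups):
        row[f"alpha{{{g}}}"] = a
    for g, pi in enumerate(ms.freq_groups):
        labels = "ACGT" if pi.size == 4 else [f"s{i}" for i in range(pi.size)]
        for lab, v in zip(labels, pi):
            row[f"pi{{{g}}}({lab})"] = v
    for g, r in enumerate(ms.exch_groups):
        if r.size == 6:
            labels = ["AC", "AG", "AT", "CG", "CT", "GT"]
        else:
            labels = [str(i) for i in range(r.size)]
        for lab, v in zip(labels, r):
            row[f"r{{{g}}}({lab})"] = v
    return row


def run(config: RunConfig, pattern_matrix: PatternMatrix | None,
        taxon_names: list[str] | None = None,
        linkage: LinkageMap | None = None) -> list[RunResult]:
    """Execute ``n_runs`` independent MC³ analyses.

    Each run derives decorrelated RNG streams from ``(seed, run index)``
    via :class:`numpy.random.SeedSequence` spawning, so results are exactly
    reproducible and independent runs share no stream.  Returns one
    :class:`RunResult` per run with a Tracer-style parameter trace and the
    cold chain's sampled topologies (Newick).
    """
    if pattern_matrix is not None:
        taxon_names = pattern_matrix.taxon_names
    if taxon_names is None:
        raise ValueError("taxon names required for prior-only runs")
    n_parts = len(pattern_matrix.partitions) if pattern_matrix is not None else 1
    results = []
    for r in range(config.n_runs):
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(r,))
        streams = ss.spawn(config.n_coupled_chains + 2)
        start_rng = np.random.default_rng(streams[0])
        sched_rng = np.random.default_rng(streams[1])
        chains = []
        for i in range(config.n_coupled_chains):
            lk = linkage if linkage is not None else LinkageMap.linked(n_parts)
            data_types = ([p.data_type for p in pattern_matrix.partitions]
                          if pattern_matrix is not None else ["DNA"])
            ms = ModelState(data_types, lk, n_gamma_cats=config.n_gamma_cats)
            tree = _start_tree(config, pattern_matrix, list(taxon_names),
                               start_rng)
            chains.append(PhyloChain(
                tree, ms, pattern_matrix, config.priors,
                beta=heat(i, config.heat_increment),
                rng=np.random.default_rng(streams[2 + i]),
                mem_mode=config.mem_mode))
        scheduler = (SwapScheduler(len(chains), config.swap_interval,
                                   config.swap_lag, sched_rng)
                     if len(chains) > 1 else None)
        rows: list[dict] = []
        trees: list[str] = []

        def on_sample(cold: PhyloChain):
            rows.append(_trace_row(cold))
            trees.append(cold.tree.newick())

        tune_until = (int(config.burnin_fraction * config.n_generations)
                      if config.tune else 0)
        run_coupled(chains, config.n_generations, scheduler,
                    sample_every=config.sample_every, on_sample=on_sample,
                    tune_until=tune_until, audit_every=config.audit_every)
        results.append(RunResult(pd.DataFrame(rows), trees, chains, scheduler))
    return results


# ------------------------------------------------------------ output files

def write_trace_tsv(trace: pd.DataFrame, path) -> None:
    """Tracer-compatible parameter trace: tab-separated, header row, one
    row per sample."""
    trace.to_csv(path, sep="\t", index=False)


def write_topologies_nexus(newicks: list[str], taxon_names: list[str],
                           path) -> None:
    """FigTree-compatible Nexus trees block with a translate table."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nbegin trees;\n\ttranslate\n")
        for i, name in enumerate(taxon_names, 1):
            sep = "," if i < len(taxon_names) else ";"
            fh.write(f"\t\t{i} {name}{sep}\n")
        for g, nwk in enumerate(newicks):
            fh.write(f"\ttree gen{g} = [&U] {_translate(nwk, taxon_names)}\n")
        fh.write("end;\n")


def _translate(newick: str, taxon_names: list[str]) -> str:
    import re
    index = {name: str(i) for i, name in enumerate(taxon_names, 1)}
    return re.sub(r"[^(),:;]+(?=:)",
                  lambda m: index.get(m.group(0), m.group(0)), newick)
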
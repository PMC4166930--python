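"""Substitution models, discrete-Γ rate heterogeneity, priors and linkage.

DNA partitions use the general time-reversible (GTR) model with six
exchangeabilities (order AC, AG, AT, CG, CT, GT) constrained to the simplex
so a Dirichlet prior on them is proper.  Protein partitions use named
empirical fixed-rate matrices (JTT, WAG, LG, DAYHOFF shipped; the table is
extensible).  Rate matrices are normalized to one expected substitution per
site so branch lengths are in substitution units.

Across-site rate variation follows the discrete-Γ model: ``k`` equally
probable categories whose rates are the means of the equal-probability bins
of a Gamma(α, α) density (mean 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc, gammaln
from scipy.stats import gamma as gamma_dist

from ._aa_data import AA_MODELS

__all__ = [
    "SubstModel", "GammaRates", "LinkageMap", "ModelState",
    "build_model", "transition_probs", "discretize_gamma",
    "DirichletPrior", "ExponentialPrior", "UniformPrior", "PriorConfig",
    "log_prior",
]

DNA_EXCH_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")


class ModelError(ValueError):
    pass


class SubstModel:
    """A reversible substitution model with cached eigendecomposition.

    Parameters are the upper-triangle exchangeabilities ``r`` and stationary
    frequencies ``pi``; the generator is ``Q_ij = r_ij * pi_j`` (i != j),
    rows summing to zero, rescaled so ``-sum_i pi_i Q_ii = 1``.
    """

    def __init__(self, data_type: str, exchangeabilities, frequencies):
        self.data_type = data_type
        n = 4 if data_type == "DNA" else 20
        self.n_states = n
        r = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        n_exch = n * (n - 1) // 2
        if r.shape != (n_exch,):
            raise ModelError(f"expected {n_exch} exchangeabilities, got {r.shape}")
        # empirical AA tables may carry exact zeros for unobserved pairs
        if np.any(r < 0) or r.sum() <= 0:
            raise ModelError("exchangeabilities must be non-negative and not all zero")
        if pi.shape != (n,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ModelError("frequencies must be a positive simplex vector")
        self.exchangeabilities = r / r.sum()
        self.frequencies = pi / pi.sum()
        self._build()

    def _build(self):
        n, r, pi = self.n_states, self.exchangeabilities, self.frequencies
        R = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        R[iu] = r
        R = R + R.T
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))
        Q /= mu
        self.Q = Q
        # symmetrize for a stable real eigendecomposition (reversibility)
        sq = np.sqrt(pi)
        S = (sq[:, None] * Q) / sq[None, :]
        eigval, V = np.linalg.eigh((S + S.T) / 2)
        self.eigval = eigval
        self._right = V / sq[:, None]          # D^{-1/2} V
        self._left = (V * sq[:, None]).T       # V^T D^{1/2}

    def transition_probs(self, t: float, rates=1.0) -> np.ndarray:
        """P(t * rate) for one or more rate multipliers.

        Returns shape (n, n) for a scalar rate, else (k, n, n).
        """
        if t < 0:
            raise ModelError("negative branch length")
        rates_arr = np.atleast_1d(np.asarray(rates, dtype=float))
        ew = np.exp(np.outer(rates_arr * t, self.eigval))          # (k, n)
        P = np.einsum("ij,kj,jl->kil", self._right, ew, self._left)
        np.clip(P, 0.0, 1.0, out=P)
        if np.isscalar(rates) or np.asarray(rates).ndim == 0:
            return P[0]
        return P


def build_model(data_type: str, exchangeabilities=None, frequencies=None,
                named_matrix: str | None = None) -> SubstModel:
    """Construct a substitution model, either parametric (GTR) or from a
    named empirical amino-acid table."""
    if named_matrix is not None:
        key = named_matrix.upper()
        if key not in AA_MODELS:
            raise ModelError(f"unknown substitution matrix {named_matrix!r}; "
                             f"available: {sorted(AA_MODELS)}")
        ex, bf = AA_MODELS[key]
        if exchangeabilities is None:
            exchangeabilities = np.asarray(ex, dtype=float)
        if frequencies is None:
            frequencies = np.asarray(bf, dtype=float)
            frequencies = frequencies / frequencies.sum()
        return SubstModel("AA", exchangeabilities, frequencies)
    n = 4 if data_type == "DNA" else 20
    if exchangeabilities is None:
        exchangeabilities = np.full(n * (n - 1) // 2, 1.0)
    if frequencies is None:
        frequencies = np.full(n, 1.0 / n)
    return SubstModel(data_type, exchangeabilities, frequencies)


def transition_probs(model: SubstModel, branch_length: float,
                     rate_multiplier: float = 1.0) -> np.ndarray:
    if rate_multiplier <= 0:
        raise ModelError("rate multiplier must be positive")
    return model.transition_probs(branch_length, rate_multiplier)


# --------------------------------------------------------------- discrete Γ

@dataclass(frozen=True)
class GammaRates:
    shape: float
    rates: np.ndarray          # (k,), mean exactly 1
    probs: np.ndarray          # (k,), uniform 1/k

    @property
    def n_categories(self) -> int:
        return self.rates.size


def discretize_gamma(alpha: float, k: int = 4) -> GammaRates:
    """Discrete-Γ rates: means of the k equal-probability bins of
    Gamma(shape=α, rate=α)."""
    if alpha <= 0:
        raise ModelError("Γ shape must be positive")
    if k < 1:
        raise ModelError("need at least one rate category")
    if k == 1:
        return GammaRates(alpha, np.array([1.0]), np.array([1.0]))
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    # E[X · 1(X < c)] = mean · I(α+1, αc) for X ~ Gamma(α, α), mean 1
    cum = gammainc(alpha + 1, alpha * bounds[1:-1])
    cum = np.concatenate([[0.0], cum, [1.0]])
    rates = k * np.diff(cum)
    rates = rates / (rates.mean())
    return GammaRates(alpha, rates, np.full(k, 1.0 / k))


# -------------------------------------------------------------------- priors

@dataclass(frozen=True)
class DirichletPrior:
    concentration: np.ndarray

    def logpdf(self, x) -> float:
        x = np.asarray(x, dtype=float)
        a = np.asarray(self.concentration, dtype=float)
        if x.shape != a.shape or np.any(x <= 0) or abs(x.sum() - 1) > 1e-8:
            return -np.inf
        return float(gammaln(a.sum()) - gammaln(a).sum() + np.dot(a - 1, np.log(x)))


@dataclass(frozen=True)
class ExponentialPrior:
    rate: float

    def logpdf(self, x) -> float:
        x = float(x)
        if x < 0:
            return -np.inf
        return float(np.log(self.rate) - self.rate * x)


@dataclass(frozen=True)
class UniformPrior:
    low: float
    high: float

    def logpdf(self, x) -> float:
        if not (self.low <= float(x) <= self.high):
            return -np.inf
        return float(-np.log(self.high - self.low))


@dataclass
class PriorConfig:
    """Priors per parameter class.  Defaults: flat Dirichlet on frequencies
    and exchangeabilities, Exp(10) on each branch length, Exp(1) on the Γ
    shape, uniform on topologies (constant, omitted from densities)."""

    frequencies: DirichletPrior | None = None
    exchangeabilities: DirichletPrior | None = None
    branch_lengths: ExponentialPrior = field(default_factory=lambda: ExponentialPrior(10.0))
    alpha: ExponentialPrior | UniformPrior = field(default_factory=lambda: ExponentialPrior(1.0))

    def freq_prior(self, n_states: int) -> DirichletPrior:
        return self.frequencies or DirichletPrior(np.ones(n_states))

    def exch_prior(self, n_states: int) -> DirichletPrior:
        return self.exchangeabilities or DirichletPrior(np.ones(n_states * (n_states - 1) // 2))


# ------------------------------------------------------------------- linkage

@dataclass
class LinkageMap:
    """Partition-to-group assignment per parameter class.

    Partitions sharing a group share (and jointly sample) that parameter;
    each class has its own grouping, so e.g. frequencies may be unlinked
    while the Γ shape stays linked.
    """

    frequencies: np.ndarray
    exchangeabilities: np.ndarray
    alpha: np.ndarray
    branch_lengths: np.ndarray

    @classmethod
    def linked(cls, n_partitions: int) -> "LinkageMap":
        z = np.zeros(n_partitions, dtype=int)
        return cls(z.copy(), z.copy(), z.copy(), z.copy())

    @classmethod
    def unlinked(cls, n_partitions: int, branch_lengths: bool = False) -> "LinkageMap":
        a = np.arange(n_partitions, dtype=int)
        bl = a.copy() if branch_lengths else np.zeros(n_partitions, dtype=int)
        return cls(a.copy(), a.copy(), a.copy(), bl)

    def n_groups(self, cls_name: str) -> int:
        return int(getattr(self, cls_name).max()) + 1

    def validate(self, n_partitions: int) -> None:
        for name in ("frequencies", "exchangeabilities", "alpha", "branch_lengths"):
            arr = getattr(self, name)
            if arr.shape != (n_partitions,):
                raise ModelError(f"linkage class {name} must assign every partition")


class ModelState:
    """Sampled substitution-model parameters for all partitions.

    Holds one parameter vector per linkage group and lazily builds the
    per-group :class:`SubstModel` / :class:`GammaRates` objects the
    likelihood engine consumes.
    """

    def __init__(self, data_types: list[str], linkage: LinkageMap,
                 n_gamma_cats: int = 4):
        self.data_types = list(data_types)
        n_parts = len(self.data_types)
        linkage.validate(n_parts)
        self.linkage = linkage
        self.n_gamma_cats = n_gamma_cats
        nf = linkage.n_groups("frequencies")
        ne = linkage.n_groups("exchangeabilities")
        na = linkage.n_groups("alpha")
        state_count = [4 if self._group_dtype("frequencies", g) == "DNA" else 20
                       for g in range(nf)]
        self.freq_groups = [np.full(s, 1.0 / s) for s in state_count]
        self.exch_groups = []
        for g in range(ne):
            s = 4 if self._group_dtype("exchangeabilities", g) == "DNA" else 20
            m = s * (s - 1) // 2
            self.exch_groups.append(np.full(m, 1.0 / m))
        self.alpha_groups = [1.0] * na
        self._model_cache: dict[int, SubstModel] = {}
        self._gamma_cache: dict[int, GammaRates] = {}

    def _group_dtype(self, cls_name: str, group: int) -> str:
        arr = getattr(self.linkage, cls_name)
        parts = np.nonzero(arr == group)[0]
        types = {self.data_types[p] for p in parts}
        if len(types) > 1:
            raise ModelError(f"linkage group {group} mixes data types {types}")
        return types.pop()

    # groups are keyed (freq_group, exch_group) — invalidate on mutation
    def model_for_partition(self, p: int) -> SubstModel:
        fg = int(self.linkage.frequencies[p])
        eg = int(self.linkage.exchangeabilities[p])
        key = fg * 1000 + eg
        model = self._model_cache.get(key)
        if model is None:
            model = SubstModel(self.data_types[p], self.exch_groups[eg],
                               self.freq_groups[fg])
            self._model_cache[key] = model
        return model

    def gamma_for_partition(self, p: int) -> GammaRates:
        ag = int(self.linkage.alpha[p])
        g = self._gamma_cache.get(ag)
        if g is None:
            g = discretize_gamma(self.alpha_groups[ag], self.n_gamma_cats)
            self._gamma_cache[ag] = g
        return g

    def set_frequencies(self, group: int, value: np.ndarray) -> None:
        self.freq_groups[group] = np.asarray(value, dtype=float)
        self._model_cache = {k: v for k, v in self._model_cache.items()
                             if k // 1000 != group}

    def set_exchangeabilities(self, group: int, value: np.ndarray) -> None:
        self.exch_groups[group] = np.asarray(value, dtype=float)
        self._model_cache = {k: v for k, v in self._model_cache.items()
                             if k % 1000 != group}

    def set_alpha(self, group: int, value: float) -> None:
        self.alpha_groups[group] = float(value)
        self._gamma_cache.pop(group, None)

    def copy(self) -> "ModelState":
        other = ModelState.__new__(ModelState)
        other.data_types = self.data_types
        other.linkage = self.linkage
        other.n_gamma_cats = self.n_gamma_cats
        other.freq_groups = [v.copy() for v in self.freq_groups]
        other.exch_groups = [v.copy() for v in self.exch_groups]
        other.alpha_groups = list(self.alpha_groups)
        other._model_cache = dict(self._model_cache)
        other._gamma_cache = dict(self._gamma_cache)
        return other


def log_prior(model_state: ModelState, tree, priors: PriorConfig) -> float:
    """Joint log prior density: one term per unlinked parameter group plus an
    independent exponential term per branch length (per linkage class)."""
    total = 0.0
    for g, pi in enumerate(model_state.freq_groups):
        total += priors.freq_prior(pi.size).logpdf(pi)
    for g, r in enumerate(model_state.exch_groups):
        n = 4 if r.size == 6 else 20
        total += priors.exch_prior(n).logpdf(r)
    for a in model_state.alpha_groups:
        total += priors.alpha.logpdf(a)
    if tree is not None:
        for eid in tree.edges:
            for grp in range(tree.n_bl_groups):
                total += priors.branch_lengths.logpdf(tree.lengths[eid][grp])
    return float(total)
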
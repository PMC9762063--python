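"""Hybrid (conditional-Gaussian) Bayesian networks.

The model class is the classical CG-BN: discrete nodes are multinomial
given their (necessarily discrete) parents; continuous nodes are
Gaussian with a linear mean in their continuous parents and a separate
(intercept, coefficients, variance) triple for every configuration of
their discrete parents.  Arcs from continuous to discrete nodes are
forbidden, so the joint density factorises into a discrete part and a
conditional multivariate normal per discrete configuration.

This module provides the structure container, maximum-likelihood
parameter fitting, the (decomposable) BIC structure score, forward
sampling, exact conditional imputation of missing cells, and plain-text
serialisation (DOT arc lists, JSON parameters).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np
import pandas as pd

from .variables import Continuous, Discrete, VariableSpec, by_name

Arc = Tuple[str, str]

_VAR_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# structure


@dataclass(frozen=True)
class NetworkStructure:
    """A directed acyclic graph over named variables."""

    nodes: Tuple[str, ...]
    arcs: frozenset

    def __init__(self, nodes: Iterable[str], arcs: Iterable[Arc] = ()):
        nodes = tuple(nodes)
        arcs = frozenset((str(u), str(v)) for u, v in arcs)
        nodeset = set(nodes)
        if len(nodes) != len(nodeset):
            raise ValueError("duplicate nodes")
        for u, v in arcs:
            if u not in nodeset or v not in nodeset:
                raise ValueError(f"arc ({u}, {v}) references unknown node")
            if u == v:
                raise ValueError("self-loops are not allowed")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "arcs", arcs)
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("structure contains a cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g

    def parents(self, node: str) -> Tuple[str, ...]:
        return tuple(sorted(u for u, v in self.arcs if v == node))

    def children(self, node: str) -> Tuple[str, ...]:
        return tuple(sorted(v for u, v in self.arcs if u == node))

    def topological_order(self) -> Tuple[str, ...]:
        # lexicographic tie-break for determinism
        return tuple(nx.lexicographical_topological_sort(self.to_networkx()))

    def with_arcs(self, arcs: Iterable[Arc]) -> "NetworkStructure":
        return NetworkStructure(self.nodes, arcs)


def validate_type_rule(structure: NetworkStructure, variables: Sequence[VariableSpec]) -> None:
    """Raise if any arc points from a continuous to a discrete node."""
    vmap = by_name(variables)
    for u, v in structure.arcs:
        if not vmap[u].is_discrete and vmap[v].is_discrete:
            raise ValueError(f"illegal arc {u} -> {v}: continuous parent of discrete node")


# ---------------------------------------------------------------------------
# data view (level coding + float columns)


def _encode(values: np.ndarray, levels: Sequence) -> np.ndarray:
    lookup = {lv: i for i, lv in enumerate(levels)}
    try:
        return np.fromiter((lookup[v] for v in values.tolist()), dtype=np.int64, count=len(values))
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"value {exc} not among declared levels {levels}") from exc


class DataView:
    """Column-coded view of a complete table, shared by fitting and scoring."""

    def __init__(self, data: pd.DataFrame, variables: Sequence[VariableSpec]):
        self.specs = by_name(variables)
        missing_cols = [v.name for v in variables if v.name not in data.columns]
        if missing_cols:
            raise ValueError(f"data lacks columns {missing_cols}")
        self.n = len(data)
        self.codes: Dict[str, np.ndarray] = {}
        self.cont: Dict[str, np.ndarray] = {}
        self.levels: Dict[str, tuple] = {}
        for v in variables:
            col = data[v.name].to_numpy()
            if v.is_discrete:
                self.levels[v.name] = tuple(v.vtype.levels)
                self.codes[v.name] = _encode(col, v.vtype.levels)
            else:
                arr = np.asarray(col, dtype=np.float64)
                if np.isnan(arr).any():
                    raise ValueError(f"column {v.name} contains missing values")
                self.cont[v.name] = arr

    def card(self, name: str) -> int:
        return len(self.levels[name])

    def config_index(self, dparents: Sequence[str]) -> Tuple[np.ndarray, int]:
        """Flat configuration index per record over the given discrete parents."""
        if not dparents:
            return np.zeros(self.n, dtype=np.int64), 1
        dims = tuple(self.card(p) for p in dparents)
        idx = np.ravel_multi_index(tuple(self.codes[p] for p in dparents), dims)
        return idx.astype(np.int64), int(np.prod(dims))


def _split_parents(parents: Iterable[str], specs: Mapping[str, VariableSpec]):
    dpar = tuple(sorted(p for p in parents if specs[p].is_discrete))
    cpar = tuple(sorted(p for p in parents if not specs[p].is_discrete))
    return dpar, cpar


# ---------------------------------------------------------------------------
# parameters


@dataclass
class DiscreteLocal:
    """Multinomial local model: CPT rows indexed by flat parent config."""

    levels: tuple
    parents: Tuple[str, ...]
    plevels: Tuple[int, ...]
    cpt: np.ndarray  # shape (n_configs, n_levels)


@dataclass
class GaussianLocal:
    """Linear-Gaussian local model, one triple per discrete-parent config."""

    dparents: Tuple[str, ...]
    plevels: Tuple[int, ...]
    cparents: Tuple[str, ...]
    b0: np.ndarray   # (n_configs,)
    coef: np.ndarray  # (n_configs, n_cont_parents)
    var: np.ndarray  # (n_configs,)


Local = Union[DiscreteLocal, GaussianLocal]


@dataclass
class CGParameters:
    """Parameter set of a CG-BN, keyed by node name."""

    locals: Dict[str, Local] = field(default_factory=dict)

    def __getitem__(self, node: str) -> Local:
        return self.locals[node]

    def __contains__(self, node: str) -> bool:
        return node in self.locals


def fit_parameters(
    structure: NetworkStructure,
    data: pd.DataFrame,
    variables: Sequence[VariableSpec],
    *,
    pseudo_count: float = 1.0,
    on_insufficient: str = "error",
) -> CGParameters:
    """Maximum-likelihood CG parameters from a complete table.

    CPTs are empirical conditional frequencies smoothed by
    ``pseudo_count`` per cell; continuous locals are per-configuration
    least-squares fits with maximum-likelihood (1/n) noise variance.

    ``on_insufficient`` controls what happens when a discrete-parent
    configuration has fewer observations than the local regression needs
    (continuous-parent count + 2): ``"error"`` raises, ``"pool"`` falls
    back to the regression pooled over all configurations.
    """
    if on_insufficient not in ("error", "pool"):
        raise ValueError("on_insufficient must be 'error' or 'pool'")
    validate_type_rule(structure, variables)
    view = DataView(data, variables)
    specs = view.specs
    params = CGParameters()
    for node in structure.nodes:
        parents = structure.parents(node)
        dpar, cpar = _split_parents(parents, specs)
        cfg, n_cfg = view.config_index(dpar)
        if specs[node].is_discrete:
            if cpar:
                raise ValueError(f"discrete node {node} has continuous parents {cpar}")
            L = view.card(node)
            counts = np.bincount(cfg * L + view.codes[node], minlength=n_cfg * L)
            counts = counts.reshape(n_cfg, L).astype(np.float64) + pseudo_count
            rowsum = counts.sum(axis=1, keepdims=True)
            if np.any(rowsum == 0):
                if on_insufficient == "error":
                    raise ValueError(f"unobserved parent configuration for {node}")
                marg = np.bincount(view.codes[node], minlength=L).astype(np.float64)
                marg = (marg + max(pseudo_count, 1.0)) / (marg.sum() + L * max(pseudo_count, 1.0))
                counts[rowsum[:, 0] == 0] = marg
                rowsum = counts.sum(axis=1, keepdims=True)
            params.locals[node] = DiscreteLocal(
                levels=view.levels[node],
                parents=dpar,
                plevels=tuple(view.card(p) for p in dpar),
                cpt=counts / rowsum,
            )
        else:
            y = view.cont[node]
            p = len(cpar)
            X = np.column_stack([np.ones(view.n)] + [view.cont[c] for c in cpar])
            # pooled fit, used as fallback for thin configurations
            beta_pool, var_pool = _ols(X, y)
            b0 = np.empty(n_cfg)
            coef = np.empty((n_cfg, p))
            var = np.empty(n_cfg)
            for c in range(n_cfg):
                mask = cfg == c
                n_g = int(mask.sum())
                if n_g < p + 2:
                    if on_insufficient == "error":
                        raise ValueError(
                            f"insufficient observations ({n_g}) for node {node}, "
                            f"parent configuration {c}"
                        )
                    beta, v = beta_pool, var_pool
                else:
                    beta, v = _ols(X[mask], y[mask])
                b0[c] = beta[0]
                coef[c] = beta[1:]
                var[c] = v
            params.locals[node] = GaussianLocal(
                dparents=dpar,
                plevels=tuple(view.card(pn) for pn in dpar),
                cparents=cpar,
                b0=b0,
                coef=coef,
                var=var,
            )
    return params


def _ols(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid / len(y))


# ---------------------------------------------------------------------------
# likelihood and BIC


def log_likelihood(
    params: CGParameters,
    data: pd.DataFrame,
    variables: Sequence[VariableSpec],
) -> float:
    """Log joint density/mass of a complete table, summed over records."""
    view = DataView(data, variables)
    total = 0.0
    for node, loc in params.locals.items():
        if isinstance(loc, DiscreteLocal):
            cfg, _ = view.config_index(loc.parents)
            pr = loc.cpt[cfg, view.codes[node]]
            if np.any(pr <= 0):
                raise ValueError(f"zero-probability observation for node {node}")
            total += float(np.log(pr).sum())
        else:
            cfg, _ = view.config_index(loc.dparents)
            mean = loc.b0[cfg]
            for j, c in enumerate(loc.cparents):
                mean = mean + loc.coef[cfg, j] * view.cont[c]
            v = np.maximum(loc.var[cfg], _VAR_FLOOR)
            resid = view.cont[node] - mean
            total += float(-0.5 * np.sum(np.log(2 * np.pi * v) + resid * resid / v))
    return total


class BICScorer:
    """Cached decomposable BIC over one complete dataset.

    The score of a structure is the sum over nodes of local scores
    ``ll_hat(node | parents) - (k/2) ln n``, where ``k`` counts the free
    parameters of the local model and ``ll_hat`` is the maximised local
    log-likelihood.  Higher is better.  Local scores are cached by
    (node, parent set), which is what makes greedy search affordable.
    """

    def __init__(self, data: pd.DataFrame, variables: Sequence[VariableSpec]):
        self.view = DataView(data, variables)
        self.specs = self.view.specs
        self._cache: Dict[Tuple[str, frozenset], float] = {}

    def local(self, node: str, parents: Iterable[str]) -> float:
        key = (node, frozenset(parents))
        if key in self._cache:
            return self._cache[key]
        val = self._local(node, key[1])
        self._cache[key] = val
        return val

    def _local(self, node: str, parents: frozenset) -> float:
        view = self.view
        n = view.n
        dpar, cpar = _split_parents(parents, self.specs)
        if self.specs[node].is_discrete and cpar:
            return -np.inf  # type rule: no continuous parent of a discrete node
        cfg, n_cfg = view.config_index(dpar)
        logn = math.log(n)
        if self.specs[node].is_discrete:
            L = view.card(node)
            counts = np.bincount(cfg * L + view.codes[node], minlength=n_cfg * L)
            counts = counts.reshape(n_cfg, L).astype(np.float64)
            rowsum = counts.sum(axis=1, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = np.where(counts > 0, counts * np.log(counts / rowsum), 0.0).sum()
            k = n_cfg * (L - 1)
            return float(ll) - 0.5 * k * logn
        y = view.cont[node]
        p = len(cpar)
        X = np.column_stack([np.ones(n)] + [view.cont[c] for c in cpar])
        ll = 0.0
        for c in range(n_cfg):
            mask = cfg == c
            n_g = int(mask.sum())
            if n_g == 0:
                continue
            if n_g < p + 2:
                return -np.inf  # unfittable local model: reject the structure
            _, v = _ols(X[mask], y[mask])
            v = max(v, _VAR_FLOOR)
            ll += -0.5 * n_g * (math.log(2 * math.pi * v) + 1.0)
        k = n_cfg * (p + 2)
        return ll - 0.5 * k * logn

    def score(self, structure: NetworkStructure) -> float:
        return float(sum(self.local(v, structure.parents(v)) for v in structure.nodes))


def bic_score(
    structure: NetworkStructure,
    data: pd.DataFrame,
    variables: Sequence[VariableSpec],
) -> float:
    """BIC of a structure on a complete table (higher is better)."""
    scorer = BICScorer(data, variables)
    return float(sum(scorer.local(v, structure.parents(v)) for v in structure.nodes))


# ---------------------------------------------------------------------------
# sampling


def sample(
    structure: NetworkStructure,
    params: CGParameters,
    variables: Sequence[VariableSpec],
    n: int,
    seed: int,
    *,
    clip_to_range: bool = False,
) -> pd.DataFrame:
    """Forward (ancestral) sampling of ``n`` records.

    With ``clip_to_range`` each continuous node is clipped to its
    declared scale range immediately after it is drawn, so descendants
    see the clipped value (bounded psychometric scales, non-negative
    activity minutes).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    specs = by_name(variables)
    rng = np.random.default_rng(seed)
    codes: Dict[str, np.ndarray] = {}
    values: Dict[str, np.ndarray] = {}
    for node in structure.topological_order():
        loc = params.locals.get(node)
        if loc is None:
            raise ValueError(f"parameters missing for node {node}")
        if isinstance(loc, DiscreteLocal):
            if loc.parents:
                cfg = np.ravel_multi_index(tuple(codes[p] for p in loc.parents), loc.plevels)
                probs = loc.cpt[cfg]
            else:
                probs = np.broadcast_to(loc.cpt[0], (n, len(loc.levels)))
            u = rng.random(n)
            cum = np.cumsum(probs, axis=1)
            code = np.minimum((u[:, None] >= cum).sum(axis=1), len(loc.levels) - 1)
            codes[node] = code
            values[node] = np.asarray(loc.levels)[code]
        else:
            if loc.dparents:
                cfg = np.ravel_multi_index(tuple(codes[p] for p in loc.dparents), loc.plevels)
            else:
                cfg = np.zeros(n, dtype=np.int64)
            mean = loc.b0[cfg].copy()
            for j, c in enumerate(loc.cparents):
                mean += loc.coef[cfg, j] * values[c]
            x = mean + rng.standard_normal(n) * np.sqrt(loc.var[cfg])
            if clip_to_range:
                rng_spec = specs[node].vtype
                assert isinstance(rng_spec, Continuous)
                x = np.clip(
                    x,
                    -np.inf if rng_spec.lo is None else rng_spec.lo,
                    np.inf if rng_spec.hi is None else rng_spec.hi,
                )
            values[node] = x
    return pd.DataFrame({v.name: values[v.name] for v in variables if v.name in values})


# ---------------------------------------------------------------------------
# exact conditional imputation


class _GaussianSystem:
    """Joint Gaussian over the continuous nodes, per discrete configuration."""

    def __init__(self, structure: NetworkStructure, params: CGParameters,
                 variables: Sequence[VariableSpec]):
        specs = by_name(variables)
        self.specs = specs
        self.dnodes = tuple(sorted(v.name for v in variables
                                   if v.is_discrete and v.name in params.locals))
        order = [v for v in structure.topological_order() if not specs[v].is_discrete]
        self.cnodes = tuple(order)
        self.cpos = {v: i for i, v in enumerate(order)}
        self.params = params
        self.structure = structure
        self._cache: Dict[tuple, Tuple[np.ndarray, np.ndarray]] = {}

    def moments(self, dassign: Mapping[str, int]) -> Tuple[np.ndarray, np.ndarray]:
        """(mu, Sigma) of the continuous block given a full discrete assignment."""
        key = tuple(dassign[d] for d in self.dnodes)
        if key in self._cache:
            return self._cache[key]
        m = len(self.cnodes)
        B = np.zeros((m, m))
        c = np.zeros(m)
        noise = np.zeros(m)
        for i, node in enumerate(self.cnodes):
            loc = self.params.locals[node]
            assert isinstance(loc, GaussianLocal)
            if loc.dparents:
                cfg = int(np.ravel_multi_index(
                    tuple(np.asarray(dassign[p]) for p in loc.dparents), loc.plevels))
            else:
                cfg = 0
            c[i] = loc.b0[cfg]
            noise[i] = loc.var[cfg]
            for j, p in enumerate(loc.cparents):
                B[i, self.cpos[p]] = loc.coef[cfg, j]
        A = np.linalg.solve(np.eye(m) - B, np.eye(m))
        mu = A @ c
        Sigma = A @ np.diag(noise) @ A.T
        self._cache[key] = (mu, Sigma)
        return mu, Sigma

    def log_prior(self, dassign: Mapping[str, int]) -> float:
        """Log joint mass of a full discrete assignment."""
        total = 0.0
        for node in self.dnodes:
            loc = self.params.locals[node]
            assert isinstance(loc, DiscreteLocal)
            if loc.parents:
                cfg = int(np.ravel_multi_index(
                    tuple(np.asarray(dassign[p]) for p in loc.parents), loc.plevels))
            else:
                cfg = 0
            pr = loc.cpt[cfg, dassign[node]]
            if pr <= 0:
                return -np.inf
            total += math.log(pr)
        return total


def _gauss_logpdf(x: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> float:
    if len(x) == 0:
        return 0.0
    S = Sigma + _VAR_FLOOR * np.eye(len(x))
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:  # pragma: no cover - defensive
        return -np.inf
    d = x - mu
    sol = np.linalg.solve(S, d)
    return float(-0.5 * (len(x) * math.log(2 * math.pi) + logdet + d @ sol))


def _cond_moments(mu, Sigma, obs_idx, mis_idx, x_obs):
    """Conditional mean/cov of the missing block given the observed block."""
    if len(obs_idx) == 0:
        return mu[mis_idx], Sigma[np.ix_(mis_idx, mis_idx)]
    Soo = Sigma[np.ix_(obs_idx, obs_idx)] + _VAR_FLOOR * np.eye(len(obs_idx))
    Smo = Sigma[np.ix_(mis_idx, obs_idx)]
    W = np.linalg.solve(Soo, Smo.T).T
    mean = mu[mis_idx] + W @ (x_obs - mu[obs_idx])
    cov = Sigma[np.ix_(mis_idx, mis_idx)] - W @ Smo.T
    return mean, cov


_MAX_DISCRETE_ENUM = 4096


def impute_table(
    structure: NetworkStructure,
    params: CGParameters,
    variables: Sequence[VariableSpec],
    table: pd.DataFrame,
    *,
    mode: str = "expectation",
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Fill every missing cell by exact conditional inference.

    Missing discrete cells are handled by enumerating their level
    combinations and weighting each by prior mass times the Gaussian
    evidence of the observed continuous cells; missing continuous cells
    are filled with the (mixture) conditional mean in ``expectation``
    mode or a conditional draw in ``draw`` mode.  Observed cells are
    never touched.
    """
    if mode not in ("expectation", "draw"):
        raise ValueError("mode must be 'expectation' or 'draw'")
    rng = np.random.default_rng(seed)
    specs = by_name(variables)
    sys = _GaussianSystem(structure, params, variables)
    out = table.copy()
    names = [v.name for v in variables if v.name in params.locals]
    dnodes = sys.dnodes
    cnodes = sys.cnodes
    col_arrays = {nm: out[nm].to_numpy(dtype=object if specs[nm].is_discrete else np.float64,
                                      copy=True)
                  for nm in names}
    level_codes = {nm: {lv: i for i, lv in enumerate(specs[nm].vtype.levels)}
                   for nm in dnodes}
    n = len(out)
    for i in range(n):
        mis_d = [nm for nm in dnodes if _ismissing(col_arrays[nm][i])]
        mis_c = [nm for nm in cnodes if np.isnan(col_arrays[nm][i])]
        if not mis_d and not mis_c:
            continue
        obs_d = {nm: level_codes[nm][col_arrays[nm][i]] for nm in dnodes if nm not in mis_d}
        obs_c_idx = np.array([sys.cpos[nm] for nm in cnodes if nm not in mis_c], dtype=int)
        mis_c_idx = np.array([sys.cpos[nm] for nm in mis_c], dtype=int)
        x_obs = np.array([col_arrays[nm][i] for nm in cnodes if nm not in mis_c], dtype=float)

        # enumerate assignments of missing discrete cells
        combos: list = [()]
        for nm in mis_d:
            L = len(specs[nm].vtype.levels)
            combos = [c + (l,) for c in combos for l in range(L)]
            if len(combos) > _MAX_DISCRETE_ENUM:
                raise ValueError("too many missing-discrete combinations to enumerate")
        logw = np.empty(len(combos))
        cond_means = []
        cond_covs = []
        for k, combo in enumerate(combos):
            dassign = dict(obs_d)
            dassign.update({nm: lv for nm, lv in zip(mis_d, combo)})
            mu, Sigma = sys.moments(dassign)
            logw[k] = sys.log_prior(dassign) + _gauss_logpdf(
                x_obs, mu[obs_c_idx], Sigma[np.ix_(obs_c_idx, obs_c_idx)])
            mean, cov = _cond_moments(mu, Sigma, obs_c_idx, mis_c_idx, x_obs)
            cond_means.append(mean)
            cond_covs.append(cov)
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        if mode == "expectation":
            if mis_c:
                mix = np.einsum("k,kj->j", w, np.array(cond_means))
                for nm, val in zip(mis_c, mix):
                    col_arrays[nm][i] = val
            for j, nm in enumerate(mis_d):
                L = len(specs[nm].vtype.levels)
                marg = np.zeros(L)
                for k, combo in enumerate(combos):
                    marg[combo[j]] += w[k]
                col_arrays[nm][i] = specs[nm].vtype.levels[int(np.argmax(marg))]
        else:
            k = int(rng.choice(len(combos), p=w))
            for j, nm in enumerate(mis_d):
                col_arrays[nm][i] = specs[nm].vtype.levels[combos[k][j]]
            if mis_c:
                cov = cond_covs[k] + _VAR_FLOOR * np.eye(len(mis_c))
                draw = rng.multivariate_normal(cond_means[k], cov, method="cholesky")
                for nm, val in zip(mis_c, draw):
                    col_arrays[nm][i] = val
    for nm in names:
        out[nm] = col_arrays[nm]
        if not specs[nm].is_discrete:
            out[nm] = out[nm].astype(float)
    return out


def n_free_parameters(params: CGParameters) -> int:
    """Free-parameter count of a CG parameterisation (BIC penalty k)."""
    k = 0
    for loc in params.locals.values():
        if isinstance(loc, DiscreteLocal):
            k += loc.cpt.shape[0] * (loc.cpt.shape[1] - 1)
        else:
            k += len(loc.b0) * (loc.coef.shape[1] + 2)
    return k


def observed_log_likelihood(
    structure: NetworkStructure,
    params: CGParameters,
    variables: Sequence[VariableSpec],
    table: pd.DataFrame,
) -> float:
    """Log-likelihood of a table with missing cells, marginalised exactly.

    Missing continuous cells are integrated out of the joint Gaussian
    (per discrete configuration); missing discrete cells are summed out
    by enumeration.  This is the evidence that structural EM uses to
    accept or reject an iteration.
    """
    specs = by_name(variables)
    sys = _GaussianSystem(structure, params, variables)
    dnodes, cnodes = sys.dnodes, sys.cnodes
    level_codes = {nm: {lv: i for i, lv in enumerate(specs[nm].vtype.levels)}
                   for nm in dnodes}
    darr = {nm: table[nm].to_numpy() for nm in dnodes}
    carr = {nm: table[nm].to_numpy(dtype=float) for nm in cnodes}
    total = 0.0
    for i in range(len(table)):
        mis_d = [nm for nm in dnodes if _ismissing(darr[nm][i])]
        obs_d = {nm: level_codes[nm][darr[nm][i]] for nm in dnodes if nm not in mis_d}
        obs_idx = np.array([sys.cpos[nm] for nm in cnodes
                            if not np.isnan(carr[nm][i])], dtype=int)
        x_obs = np.array([carr[nm][i] for nm in cnodes if not np.isnan(carr[nm][i])])
        combos: list = [()]
        for nm in mis_d:
            L = len(specs[nm].vtype.levels)
            combos = [c + (l,) for c in combos for l in range(L)]
            if len(combos) > _MAX_DISCRETE_ENUM:
                raise ValueError("too many missing-discrete combinations to enumerate")
        logw = np.empty(len(combos))
        for k, combo in enumerate(combos):
            dassign = dict(obs_d)
            dassign.update({nm: lv for nm, lv in zip(mis_d, combo)})
            mu, Sigma = sys.moments(dassign)
            logw[k] = sys.log_prior(dassign) + _gauss_logpdf(
                x_obs, mu[obs_idx], Sigma[np.ix_(obs_idx, obs_idx)])
        m = logw.max()
        total += float(m + math.log(np.exp(logw - m).sum()))
    return total


def _ismissing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v)


def impute_record(
    structure: NetworkStructure,
    params: CGParameters,
    variables: Sequence[VariableSpec],
    record: Mapping,
    *,
    mode: str = "expectation",
    seed: Optional[int] = None,
) -> dict:
    """Impute one record (see :func:`impute_table`)."""
    frame = pd.DataFrame([dict(record)])
    done = impute_table(structure, params, variables, frame, mode=mode, seed=seed)
    return done.iloc[0].to_dict()


# ---------------------------------------------------------------------------
# serialisation


def structure_to_dot(structure: NetworkStructure, name: str = "network") -> str:
    lines = [f"digraph {name} {{"]
    for node in structure.nodes:
        lines.append(f'  "{node}";')
    for u, v in sorted(structure.arcs):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


_DOT_NODE = re.compile(r'^\s*"([^"]+)"\s*(\[[^\]]*\])?\s*;\s*$')
_DOT_ARC = re.compile(r'^\s*"([^"]+)"\s*->\s*"([^"]+)"\s*(\[[^\]]*\])?\s*;\s*$')


def structure_from_dot(text: str) -> NetworkStructure:
    nodes: list = []
    arcs: list = []
    for line in text.splitlines():
        m = _DOT_ARC.match(line)
        if m:
            arcs.append((m.group(1), m.group(2)))
            continue
        m = _DOT_NODE.match(line)
        if m:
            nodes.append(m.group(1))
    for u, v in arcs:
        for x in (u, v):
            if x not in nodes:
                nodes.append(x)
    return NetworkStructure(nodes, arcs)


def params_to_json(params: CGParameters) -> str:
    obj = {}
    for node, loc in params.locals.items():
        if isinstance(loc, DiscreteLocal):
            obj[node] = {
                "kind": "discrete",
                "levels": list(loc.levels),
                "parents": list(loc.parents),
                "plevels": list(loc.plevels),
                "cpt": loc.cpt.tolist(),
            }
        else:
            obj[node] = {
                "kind": "gaussian",
                "dparents": list(loc.dparents),
                "plevels": list(loc.plevels),
                "cparents": list(loc.cparents),
                "b0": loc.b0.tolist(),
                "coef": loc.coef.tolist(),
                "var": loc.var.tolist(),
            }
    return json.dumps(obj, indent=2, sort_keys=True)


def params_from_json(text: str) -> CGParameters:
    obj = json.loads(text)
    params = CGParameters()
    for node, rec in obj.items():
        if rec["kind"] == "discrete":
            params.locals[node] = DiscreteLocal(
                levels=tuple(rec["levels"]),
                parents=tuple(rec["parents"]),
                plevels=tuple(rec["plevels"]),
                cpt=np.array(rec["cpt"], dtype=float),
            )
        else:
            params.locals[node] = GaussianLocal(
                dparents=tuple(rec["dparents"]),
                plevels=tuple(rec["plevels"]),
                cparents=tuple(rec["cparents"]),
                b0=np.array(rec["b0"], dtype=float),
                coef=np.array(rec["coef"], dtype=float).reshape(len(rec["b0"]), -1),
                var=np.array(rec["var"], dtype=float),
            )
    return params
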
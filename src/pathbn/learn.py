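"""Constrained structure learning: BIC hill-climbing and structural EM.

Structure search is greedy add/delete/reverse hill-climbing over the
decomposable BIC, restricted by a constraint system that encodes the
temporal design of longitudinal intervention studies:

* no arc may point to an earlier measurement wave;
* demographics accept no parents other than demographics;
* baseline (T0) measurements accept only demographics and other
  baseline measurements as parents;
* the randomised intervention indicator accepts only demographics and
  baseline measurements as parents;
* a continuous node can never parent a discrete node (CG model class).

Missing data are handled by structural EM over expected sufficient
statistics: an exact conditional-Gaussian E-step accumulates expected
first and second moments of the continuous block given the observed
cells, and the M-step hill-climbs the expected BIC computed from those
moments, iterating until the expected score stops improving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import math

import numpy as np
import pandas as pd

from .cgbn import (
    BICScorer,
    CGParameters,
    DiscreteLocal,
    GaussianLocal,
    NetworkStructure,
    _GaussianSystem,
    impute_table,
)
from .variables import VariableSpec, by_name

logger = logging.getLogger(__name__)

Arc = Tuple[str, str]


# ---------------------------------------------------------------------------
# constraints


@dataclass
class ConstraintSet:
    """Per-arc legality rules; acyclicity is enforced separately by search."""

    nodes: Tuple[str, ...]
    tier_of: Dict[str, Optional[int]]
    role_of: Dict[str, str]
    discrete: Dict[str, bool]

    def is_legal(self, u: str, v: str) -> bool:
        """Whether the single arc ``u -> v`` violates no declarative rule."""
        if u == v or u not in self.role_of or v not in self.role_of:
            return False
        # type rule: continuous parents of discrete nodes are outside the model class
        if not self.discrete[u] and self.discrete[v]:
            return False
        tu, tv = self.tier_of[u], self.tier_of[v]
        if tu is not None and tv is not None and tu > tv:
            return False
        rv, ru = self.role_of[v], self.role_of[u]
        if rv == "demographic":
            return ru == "demographic"
        if rv == "baseline":
            return ru in ("demographic", "baseline")
        if rv == "intervention":
            return ru in ("demographic", "baseline")
        return True

    @property
    def forbidden(self) -> frozenset:
        return frozenset((u, v) for u in self.nodes for v in self.nodes
                         if u != v and not self.is_legal(u, v))

    def legal_arcs(self) -> List[Arc]:
        return [(u, v) for u in self.nodes for v in self.nodes
                if u != v and self.is_legal(u, v)]

    def validate(self, structure: NetworkStructure) -> None:
        bad = [(u, v) for u, v in structure.arcs if not self.is_legal(u, v)]
        if bad:
            raise ValueError(f"structure violates constraints on arcs {sorted(bad)}")


def build_constraints(variables: Sequence[VariableSpec]) -> ConstraintSet:
    """Derive the full constraint system from variable metadata."""
    vmap = by_name(variables)
    return ConstraintSet(
        nodes=tuple(vmap),
        tier_of={n: s.tier_index for n, s in vmap.items()},
        role_of={n: s.role for n, s in vmap.items()},
        discrete={n: s.is_discrete for n, s in vmap.items()},
    )


# ---------------------------------------------------------------------------
# hill climbing


@dataclass
class Move:
    kind: str  # "add" | "delete" | "reverse"
    arc: Arc
    delta: float


def _creates_cycle(parents: Dict[str, set], u: str, v: str) -> bool:
    """Would adding u -> v close a cycle (i.e. is u reachable from v)?"""
    stack = [v]
    seen = {v}
    children: Dict[str, list] = {}
    for child, ps in parents.items():
        for p in ps:
            children.setdefault(p, []).append(child)
    while stack:
        x = stack.pop()
        if x == u:
            return True
        for c in children.get(x, ()):
            if c not in seen:
                seen.add(c)
                stack.append(c)
    return False


def hill_climb(
    data: pd.DataFrame,
    variables: Sequence[VariableSpec],
    constraints: Optional[ConstraintSet] = None,
    *,
    seed: int = 0,
    restarts: int = 0,
    epsilon: float = 1e-9,
    move_log: Optional[list] = None,
) -> NetworkStructure:
    """Greedy BIC ascent over single-arc moves on complete data.

    Starting from the empty graph, repeatedly apply the best strictly
    improving legal move (add, delete, or reverse one arc) until no such
    move exists.  Optional random restarts perturb the start graph and
    keep the best-scoring local optimum.  Ties are broken
    lexicographically by (move kind, child, parent), making the result
    deterministic for a fixed seed.
    """
    if constraints is None:
        constraints = build_constraints(variables)
    return _hill_climb_scored(BICScorer(data, variables), variables, constraints,
                              seed=seed, restarts=restarts, epsilon=epsilon,
                              move_log=move_log)


def _hill_climb_scored(scorer, variables, constraints, *, seed=0, restarts=0,
                       epsilon=1e-9, move_log=None) -> NetworkStructure:
    rng = np.random.default_rng(seed)
    legal = sorted(constraints.legal_arcs())

    best_struct, best_score = _climb(scorer, variables, legal, constraints,
                                     set(), epsilon, move_log)
    for _ in range(restarts):
        init: set = set()
        for arc in legal:
            if rng.random() < 0.15:
                parents = _parents_map(variables, init)
                if not _creates_cycle(parents, *arc):
                    init.add(arc)
        struct, score = _climb(scorer, variables, legal, constraints,
                               init, epsilon, None)
        if score > best_score + epsilon:
            best_struct, best_score = struct, score
    return best_struct


def _parents_map(variables: Sequence[VariableSpec], arcs: Iterable[Arc]) -> Dict[str, set]:
    parents: Dict[str, set] = {v.name: set() for v in variables}
    for u, v in arcs:
        parents[v].add(u)
    return parents


def _climb(scorer, variables, legal, constraints, init_arcs, epsilon, move_log):
    names = [v.name for v in variables]
    parents = _parents_map(variables, init_arcs)
    arcs = set(init_arcs)
    legal_set = set(legal)

    def local(node):
        return scorer.local(node, parents[node])

    current = {n: local(n) for n in names}
    while True:
        best: Optional[Move] = None
        # adds
        for u, v in legal:
            if (u, v) in arcs:
                continue
            if _creates_cycle(parents, u, v):
                continue
            delta = scorer.local(v, parents[v] | {u}) - current[v]
            best = _better(best, Move("add", (u, v), delta), epsilon)
        # deletes and reverses
        for u, v in sorted(arcs):
            delta = scorer.local(v, parents[v] - {u}) - current[v]
            best = _better(best, Move("delete", (u, v), delta), epsilon)
            if (v, u) in legal_set:
                parents[v].discard(u)
                cyc = _creates_cycle(parents, v, u)
                parents[v].add(u)
                if not cyc:
                    delta = (
                        scorer.local(v, parents[v] - {u}) - current[v]
                        + scorer.local(u, parents[u] | {v}) - current[u]
                    )
                    best = _better(best, Move("reverse", (u, v), delta), epsilon)
        if best is None or best.delta <= epsilon:
            break
        u, v = best.arc
        if best.kind == "add":
            arcs.add((u, v))
            parents[v].add(u)
        elif best.kind == "delete":
            arcs.discard((u, v))
            parents[v].discard(u)
        else:
            arcs.discard((u, v))
            parents[v].discard(u)
            arcs.add((v, u))
            parents[u].add(v)
        current[v] = local(v)
        current[u] = local(u)
        if move_log is not None:
            move_log.append((best.kind, best.arc, best.delta, sum(current.values())))
    structure = NetworkStructure(names, arcs)
    constraints.validate(structure)
    return structure, sum(current.values())


def _better(best: Optional[Move], cand: Move, epsilon: float) -> Optional[Move]:
    if cand.delta <= epsilon:
        return best
    if best is None or cand.delta > best.delta + epsilon:
        return cand
    if cand.delta >= best.delta - epsilon:
        # tie: lexicographic by (child, parent, kind) for determinism
        kb = (best.arc[1], best.arc[0], best.kind)
        kc = (cand.arc[1], cand.arc[0], cand.kind)
        if kc < kb:
            return cand
    return best


# ---------------------------------------------------------------------------
# structural EM (expected sufficient statistics)


class _Moments:
    """Expected sufficient statistics of the continuous block.

    Per configuration of the discrete variables: the record count ``N``
    and the expected augmented second-moment matrix
    ``A = sum_i E[(1, x_i)(1, x_i)^T | observed_i]`` over the continuous
    columns.  Any linear-Gaussian local model (coefficients, ML noise
    variance, and expected log-likelihood) is a closed-form function of
    sub-blocks of ``A``, which is what makes moment-based hill-climbing
    cheap: no data passes per candidate move.
    """

    def __init__(self, cont_names, dnodes, dlevels):
        self.cont_names = tuple(cont_names)
        self.pos = {nm: i + 1 for i, nm in enumerate(cont_names)}  # 0 = intercept
        self.dnodes = tuple(dnodes)
        self.dlevels = tuple(dlevels)
        self.groups: Dict[tuple, list] = {}
        self.n = 0

    def add(self, dconfig: tuple, z: np.ndarray, cov_block=None, mis_idx=None):
        k = len(self.cont_names) + 1
        entry = self.groups.setdefault(dconfig, [0, np.zeros((k, k))])
        entry[0] += 1
        entry[1] += np.outer(z, z)
        if cov_block is not None and len(mis_idx):
            idx = np.asarray(mis_idx) + 1
            entry[1][np.ix_(idx, idx)] += cov_block
        self.n += 1


def _expected_moments(table, variables, structure=None, params=None):
    """E-step: accumulate expected moments under the current model.

    With ``structure``/``params`` of ``None``, missing cells are treated
    under the empty-graph marginal model (observed column means and
    variances, zero cross-covariances) — the initial completion.
    Discrete cells must be observed (they are never design-masked in
    this pipeline).
    """
    specs = by_name(variables)
    dnodes = tuple(sorted(nm for nm, s in specs.items() if s.is_discrete))
    cnodes = tuple(nm for nm in (v.name for v in variables) if not specs[nm].is_discrete)
    level_codes = {nm: {lv: i for i, lv in enumerate(specs[nm].vtype.levels)}
                   for nm in dnodes}
    for nm in dnodes:
        if table[nm].isna().any():
            raise ValueError(f"discrete variable {nm} has missing cells; "
                             "structural EM expects observed discrete columns")
    mom = _Moments(cnodes, dnodes, tuple(len(specs[d].vtype.levels) for d in dnodes))
    carr = {nm: table[nm].to_numpy(dtype=float) for nm in cnodes}
    dcode = {nm: np.array([level_codes[nm][v] for v in table[nm]]) for nm in dnodes}
    n = len(table)
    cpos = {nm: i for i, nm in enumerate(cnodes)}
    if structure is not None:
        sys = _GaussianSystem(structure, params, variables)
        sys_pos = [sys.cpos[nm] for nm in cnodes]
    else:
        means = np.array([np.nanmean(carr[nm]) for nm in cnodes])
        var = np.array([np.nanvar(carr[nm]) for nm in cnodes])
    cond_cache: Dict[tuple, tuple] = {}
    x = np.empty(len(cnodes))
    for i in range(n):
        dconfig = tuple(int(dcode[nm][i]) for nm in dnodes)
        for j, nm in enumerate(cnodes):
            x[j] = carr[nm][i]
        mis = np.flatnonzero(np.isnan(x))
        obs = np.flatnonzero(~np.isnan(x))
        if len(mis) == 0:
            mom.add(dconfig, np.concatenate([[1.0], x]))
            continue
        if structure is None:
            fill = x.copy()
            fill[mis] = means[mis]
            cov = np.diag(var[mis]) if len(mis) else None
            mom.add(dconfig, np.concatenate([[1.0], fill]), cov, mis)
            continue
        key = (dconfig, mis.tobytes())
        if key not in cond_cache:
            dassign = {nm: dconfig[j] for j, nm in enumerate(dnodes)}
            mu, Sigma = sys.moments(dassign)
            perm = np.asarray(sys_pos)
            mu = mu[perm]
            Sigma = Sigma[np.ix_(perm, perm)]
            Soo = Sigma[np.ix_(obs, obs)] + 1e-12 * np.eye(len(obs))
            Smo = Sigma[np.ix_(mis, obs)]
            W = np.linalg.solve(Soo, Smo.T).T
            cov = Sigma[np.ix_(mis, mis)] - W @ Smo.T
            cond_cache[key] = (mu, W, cov)
        mu, W, cov = cond_cache[key]
        fill = x.copy()
        fill[mis] = mu[mis] + W @ (x[obs] - mu[obs])
        mom.add(dconfig, np.concatenate([[1.0], fill]), cov, mis)
    return mom


class MomentScorer:
    """Decomposable expected BIC over expected sufficient statistics.

    On complete data this coincides with :class:`~pathbn.cgbn.BICScorer`
    (the moments are then the exact empirical moments).
    """

    def __init__(self, moments: _Moments, variables, dcodes, var_floor=1e-9):
        self.m = moments
        self.specs = by_name(variables)
        self.dcodes = dcodes  # complete discrete code arrays for discrete locals
        self.var_floor = var_floor
        self._cache: Dict[Tuple[str, frozenset], float] = {}

    def local(self, node: str, parents) -> float:
        key = (node, frozenset(parents))
        if key in self._cache:
            return self._cache[key]
        val = self._local(node, key[1])
        self._cache[key] = val
        return val

    def _subset_groups(self, dpar):
        """Aggregate (N, A) over full configs by the sub-configuration of
        ``dpar``; cached per parent set."""
        out: Dict[tuple, list] = {}
        idx = [self.m.dnodes.index(p) for p in dpar]
        for cfg, (N, A) in self.m.groups.items():
            sub = tuple(cfg[j] for j in idx)
            entry = out.setdefault(sub, [0, 0.0])
            entry[0] += N
            entry[1] = entry[1] + A
        return out

    def _local(self, node: str, parents: frozenset) -> float:
        dpar = tuple(sorted(p for p in parents if self.specs[p].is_discrete))
        cpar = tuple(sorted(p for p in parents if not self.specs[p].is_discrete))
        n = self.m.n
        logn = math.log(n)
        if self.specs[node].is_discrete:
            if cpar:
                return -np.inf
            codes = self.dcodes[node]
            L = len(self.specs[node].vtype.levels)
            if dpar:
                dims = tuple(len(self.specs[p].vtype.levels) for p in dpar)
                cfg = np.ravel_multi_index(tuple(self.dcodes[p] for p in dpar), dims)
                n_cfg = int(np.prod(dims))
            else:
                cfg = np.zeros(n, dtype=np.int64)
                n_cfg = 1
            counts = np.bincount(cfg * L + codes, minlength=n_cfg * L)
            counts = counts.reshape(n_cfg, L).astype(float)
            rowsum = counts.sum(axis=1, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = np.where(counts > 0, counts * np.log(counts / rowsum), 0.0).sum()
            return float(ll) - 0.5 * n_cfg * (L - 1) * logn
        p = len(cpar)
        yi = self.m.pos[node]
        pidx = np.array([0] + [self.m.pos[c] for c in cpar])
        ll = 0.0
        n_possible = 1
        for pn in dpar:
            n_possible *= len(self.specs[pn].vtype.levels)
        for sub, (N, A) in self._subset_groups(dpar).items():
            if N == 0:
                continue
            if N < p + 2:
                return -np.inf
            Axx = A[np.ix_(pidx, pidx)]
            Axy = A[pidx, yi]
            try:
                beta = np.linalg.solve(Axx, Axy)
            except np.linalg.LinAlgError:
                beta = np.linalg.lstsq(Axx, Axy, rcond=None)[0]
            v = (A[yi, yi] - beta @ Axy) / N
            v = max(v, self.var_floor)
            ll += -0.5 * N * (math.log(2 * math.pi * v) + 1.0)
        k = n_possible * (p + 2)
        return ll - 0.5 * k * logn

    def score(self, structure: NetworkStructure) -> float:
        return float(sum(self.local(v, structure.parents(v)) for v in structure.nodes))


def _params_from_moments(structure, moments, variables, dcodes, *,
                         pseudo_count=1.0, var_floor=1e-9) -> CGParameters:
    """M-step parameter update from expected sufficient statistics."""
    specs = by_name(variables)
    params = CGParameters()
    n = moments.n
    for node in structure.nodes:
        parents = structure.parents(node)
        dpar = tuple(sorted(p for p in parents if specs[p].is_discrete))
        cpar = tuple(sorted(p for p in parents if not specs[p].is_discrete))
        plevels = tuple(len(specs[p].vtype.levels) for p in dpar)
        n_cfg = int(np.prod(plevels)) if plevels else 1
        if specs[node].is_discrete:
            codes = dcodes[node]
            L = len(specs[node].vtype.levels)
            if dpar:
                cfg = np.ravel_multi_index(tuple(dcodes[p] for p in dpar), plevels)
            else:
                cfg = np.zeros(n, dtype=np.int64)
            counts = np.bincount(cfg * L + codes, minlength=n_cfg * L)
            counts = counts.reshape(n_cfg, L).astype(float) + pseudo_count
            params.locals[node] = DiscreteLocal(
                levels=tuple(specs[node].vtype.levels), parents=dpar,
                plevels=plevels, cpt=counts / counts.sum(axis=1, keepdims=True))
            continue
        yi = moments.pos[node]
        pidx = np.array([0] + [moments.pos[c] for c in cpar])
        p = len(cpar)
        # pooled fallback over every configuration
        tot = [0, 0.0]
        for _, (N, A) in moments.groups.items():
            tot[0] += N
            tot[1] = tot[1] + A
        pool_beta, pool_var = _moment_ols(tot[1], pidx, yi, tot[0], var_floor)
        b0 = np.empty(n_cfg)
        coef = np.empty((n_cfg, p))
        var = np.empty(n_cfg)
        subs: Dict[tuple, list] = {}
        idx = [moments.dnodes.index(pn) for pn in dpar]
        for cfg_full, (N, A) in moments.groups.items():
            sub = tuple(cfg_full[j] for j in idx)
            entry = subs.setdefault(sub, [0, 0.0])
            entry[0] += N
            entry[1] = entry[1] + A
        for c in range(n_cfg):
            sub = tuple(np.unravel_index(c, plevels)) if plevels else ()
            N, A = subs.get(sub, (0, None))
            if N < p + 2:
                beta, v = pool_beta, pool_var
            else:
                beta, v = _moment_ols(A, pidx, yi, N, var_floor)
            b0[c] = beta[0]
            coef[c] = beta[1:]
            var[c] = v
        params.locals[node] = GaussianLocal(dparents=dpar, plevels=plevels,
                                            cparents=cpar, b0=b0, coef=coef, var=var)
    return params


def _moment_ols(A, pidx, yi, N, var_floor):
    Axx = A[np.ix_(pidx, pidx)]
    Axy = A[pidx, yi]
    try:
        beta = np.linalg.solve(Axx, Axy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(Axx, Axy, rcond=None)[0]
    v = max((A[yi, yi] - beta @ Axy) / N, var_floor)
    return beta, v


@dataclass
class SEMResult:
    structure: NetworkStructure
    parameters: CGParameters
    completed: pd.DataFrame
    score_trace: List[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def structural_em(
    data: pd.DataFrame,
    variables: Sequence[VariableSpec],
    constraints: Optional[ConstraintSet] = None,
    *,
    max_iter: int = 25,
    score_tol: float = 1e-4,
    seed: int = 0,
    restarts: int = 0,
    pseudo_count: float = 1.0,
    min_observed_frac: float = 0.05,
) -> SEMResult:
    """Structural EM over expected sufficient statistics.

    Alternates an E-step that accumulates the expected first and second
    moments of the continuous block given the observed cells (exact
    conditional-Gaussian inference per record, per discrete
    configuration) with an M-step that hill-climbs the expected BIC
    computed from those moments and refits parameters by moment
    regressions.  The first E-step uses the empty-graph marginal model.
    Using expected second moments — rather than a single conditional
    -mean completion — keeps the noise variances honest, which is what
    prevents spurious arcs from imputation-induced shrinkage.

    Iteration stops when the expected BIC improves by at most
    ``score_tol`` (or ``max_iter`` is reached); the recorded trace
    contains only accepted, improving iterations and is therefore
    non-decreasing.  On complete data the moments are the exact
    empirical moments, so the result coincides with a single
    hill-climb.  The returned table is the expectation-mode completion
    under the final model.
    """
    if constraints is None:
        constraints = build_constraints(variables)
    vnames = [v.name for v in variables]
    frac = data[vnames].notna().mean()
    thin = frac[frac < min_observed_frac]
    if len(thin):
        raise ValueError(
            f"variables observed in under {min_observed_frac:.0%} of records: "
            f"{sorted(thin.index)}"
        )
    observed = data[vnames]
    specs = by_name(variables)
    level_codes = {v.name: {lv: i for i, lv in enumerate(v.vtype.levels)}
                   for v in variables if v.is_discrete}
    dcodes = {}
    for nm, codes in level_codes.items():
        if observed[nm].isna().any():
            raise ValueError(f"discrete variable {nm} has missing cells")
        dcodes[nm] = np.array([codes[v] for v in observed[nm]])

    moments = _expected_moments(observed, variables)  # empty-graph E-step
    best: Optional[SEMResult] = None
    prev_score = -np.inf
    trace: List[float] = []
    structure = params = None
    for it in range(1, max_iter + 1):
        scorer = MomentScorer(moments, variables, dcodes)
        structure = _hill_climb_scored(scorer, variables, constraints,
                                       seed=seed, restarts=restarts)
        params = _params_from_moments(structure, moments, variables, dcodes,
                                      pseudo_count=pseudo_count)
        score = scorer.score(structure)
        logger.info("SEM iteration %d: expected BIC %.4f, %d arcs",
                    it, score, len(structure.arcs))
        if score <= prev_score + score_tol:
            assert best is not None
            best.converged = True
            best.n_iter = it
            break
        trace.append(score)
        best = SEMResult(structure, params, observed, list(trace), it, False)
        prev_score = score
        if it == max_iter:
            break
        moments = _expected_moments(observed, variables, structure, params)
    assert best is not None
    best.completed = impute_table(best.structure, best.parameters, variables,
                                  observed, mode="expectation", seed=seed)
    best.score_trace = trace
    return best
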
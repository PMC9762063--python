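"""Intervention-to-outcome path fragments and their annotation.

From a thresholded consensus network, the subgraph of interest is the
union of all directed paths from the intervention indicator to the
physical-activity outcomes (short-term T2 and long-term T3): these are
the routes along which the intervention can influence behaviour.  Each
arc of the fragment carries two annotations:

* a *width band* (1-4) from its bootstrap confidence, with cut-offs at
  0.7, 0.8 and 0.9 above the display threshold;
* an *asterisk band* (1-3) from its jackknife bias-corrected mutual
  information, cut relative to the fragment at the 33% and 67%
  quantiles.

Mutual information is estimated on pairwise complete cases with the
plug-in estimator matching the type pair (Gaussian for
continuous-continuous, pooled-versus-conditional Gaussian entropies for
discrete-continuous, contingency-table plug-in for discrete-discrete)
and corrected by the leave-one-out jackknife.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .cgbn import NetworkStructure
from .stability import ArcConfidenceTable, AveragedNetwork
from .variables import VariableSpec, by_name

Arc = Tuple[str, str]

#: Determinant-category colouring used in DOT exports, following the
#: awareness / initiation / maintenance phases of behaviour-change theory.
CONCEPT_CATEGORY = {
    "awareness": "pre-motivational",
    "knowledge": "pre-motivational",
    "risk_perception": "pre-motivational",
    "attitude": "motivational",
    "self_efficacy": "motivational",
    "intrinsic_motivation": "motivational",
    "social_modelling": "motivational",
    "social_support": "motivational",
    "intention": "motivational",
    "commitment": "post-motivational",
    "strategic_planning": "post-motivational",
    "action_planning": "post-motivational",
    "coping_planning": "post-motivational",
    "habit": "post-motivational",
    "pa": "outcome",
    "intervention": "intervention",
    "age": "demographic",
    "gender": "demographic",
    "education": "demographic",
}

_CATEGORY_COLOUR = {
    "pre-motivational": "#c6dbef",
    "motivational": "#fdd0a2",
    "post-motivational": "#c7e9c0",
    "outcome": "#fcbba1",
    "intervention": "#dadaeb",
    "demographic": "#f0f0f0",
    "other": "#ffffff",
}


@dataclass
class FragmentGraph:
    """Directed-path subgraph from the intervention to the outcomes."""

    structure: NetworkStructure
    source: str
    targets: Tuple[str, ...]
    stability_threshold: float
    confidence: Dict[Arc, float] = field(default_factory=dict)
    mi: Dict[Arc, float] = field(default_factory=dict)
    mi_band: Dict[Arc, int] = field(default_factory=dict)
    width_band: Dict[Arc, int] = field(default_factory=dict)
    node_category: Dict[str, str] = field(default_factory=dict)
    mi_cutoffs: Optional[Tuple[float, float]] = None
    mi_range: Optional[Tuple[float, float]] = None

    @property
    def arcs(self) -> frozenset:
        return self.structure.arcs

    def summary(self) -> dict:
        """Stability and MI summary in the style of a model report."""
        conf = [self.confidence[a] for a in sorted(self.arcs) if a in self.confidence]
        out = {
            "n_nodes": len(self.structure.nodes),
            "n_arcs": len(self.arcs),
            "mean_stability": float(np.mean(conf)) if conf else float("nan"),
            "median_stability": float(np.median(conf)) if conf else float("nan"),
        }
        if self.mi_cutoffs is not None:
            out["mi_cutoff_33"] = self.mi_cutoffs[0]
            out["mi_cutoff_67"] = self.mi_cutoffs[1]
        if self.mi_range is not None:
            out["mi_min"], out["mi_max"] = self.mi_range
        return out


def extract_fragment(
    net: AveragedNetwork,
    source: str,
    targets: Iterable[str],
    stability_threshold: Optional[float] = None,
) -> FragmentGraph:
    """Distil the union of directed ``source -> target`` paths.

    Arcs below ``stability_threshold`` are dropped first (defaults to
    the averaging threshold of ``net``); an arc survives iff its tail is
    reachable from the source and some target is reachable from its
    head, which in a DAG is exactly membership of some simple directed
    path.  The fragment is empty when no path exists.
    """
    targets = tuple(sorted(set(targets)))
    if stability_threshold is None:
        stability_threshold = net.threshold
    nodes = set(net.structure.nodes)
    if source not in nodes:
        raise ValueError(f"source {source!r} not in network")
    missing = [t for t in targets if t not in nodes]
    if missing:
        raise ValueError(f"targets {missing} not in network")
    if source in targets:
        raise ValueError("source must not be a target")
    arcs = [a for a in net.structure.arcs
            if net.confidence.get(a, 1.0) >= stability_threshold - 1e-12]
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(arcs)
    from_source = nx.descendants(g, source) | {source}
    to_target: Set[str] = set()
    rg = g.reverse(copy=False)
    for t in targets:
        to_target |= nx.descendants(rg, t) | {t}
    kept = [(u, v) for u, v in arcs if u in from_source and v in to_target]
    # source and targets stay in the node set even when no path exists,
    # which keeps re-extraction total (idempotence on empty fragments)
    frag_nodes = sorted({x for a in kept for x in a} | {source} | set(targets))
    structure = NetworkStructure(frag_nodes, kept)
    conf = {a: net.confidence[a] for a in kept if a in net.confidence}
    return FragmentGraph(
        structure=structure,
        source=source,
        targets=targets,
        stability_threshold=stability_threshold,
        confidence=conf,
    )


# ---------------------------------------------------------------------------
# mutual information


def _is_discrete_column(x: np.ndarray) -> bool:
    return not np.issubdtype(np.asarray(x).dtype, np.floating)


def _complete_pairs(x, y):
    xs = pd.Series(x)
    ys = pd.Series(y)
    ok = xs.notna() & ys.notna()
    return xs[ok].to_numpy(), ys[ok].to_numpy()


def _mi_gaussian(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    vx = sxx - sx * sx / n
    vy = syy - sy * sy / n
    cxy = sxy - sx * sy / n
    if vx <= 0 or vy <= 0:
        raise ValueError("zero variance in a continuous column")
    r2 = min(cxy * cxy / (vx * vy), 1 - 1e-12)
    return -0.5 * math.log1p(-r2)


def _loo_gaussian(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    m = n - 1
    sx_, sy_ = sx - x, sy - y
    vx = (sxx - x * x) - sx_ * sx_ / m
    vy = (syy - y * y) - sy_ * sy_ / m
    cxy = (sxy - x * y) - sx_ * sy_ / m
    denom = np.maximum(vx * vy, 1e-300)
    r2 = np.minimum(cxy * cxy / denom, 1 - 1e-12)
    return -0.5 * np.log1p(-r2)


def _entropy_terms(y: np.ndarray) -> float:
    v = y.var()
    return 0.5 * math.log(max(v, 1e-300))


def _mi_disc_cont(d: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    total = _entropy_terms(y)
    cond = 0.0
    for lv in pd.unique(d):
        yl = y[d == lv]
        cond += len(yl) / n * _entropy_terms(yl)
    return total - cond


def _mi_disc_disc(a: np.ndarray, b: np.ndarray) -> float:
    tab = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy(dtype=float)
    n = tab.sum()
    p = tab / n
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / (pi * pj)), 0.0)
    return float(terms.sum())


def jackknife_mi(
    x,
    y,
    *,
    x_discrete: Optional[bool] = None,
    y_discrete: Optional[bool] = None,
    min_n: int = 10,
) -> float:
    """Jackknife bias-corrected mutual information (nats), floored at 0.

    Complete pairs only; column type is inferred from dtype (floating
    point means continuous) unless given explicitly.  The correction is
    the standard leave-one-out form ``n*I - (n-1)*mean_i I_(-i)`` on the
    plug-in estimate matching the type pair.
    """
    xv, yv = _complete_pairs(x, y)
    n = len(xv)
    if n < min_n:
        raise ValueError(f"fewer than {min_n} complete pairs (got {n})")
    xd = _is_discrete_column(xv) if x_discrete is None else x_discrete
    yd = _is_discrete_column(yv) if y_discrete is None else y_discrete
    if not xd and not yd:
        xf = xv.astype(float)
        yf = yv.astype(float)
        full = _mi_gaussian(xf, yf)
        loo = _loo_gaussian(xf, yf)
    elif xd and yd:
        full = _mi_disc_disc(xv, yv)
        loo = np.array([_mi_disc_disc(np.delete(xv, i), np.delete(yv, i))
                        for i in range(n)])
    else:
        d, c = (xv, yv.astype(float)) if xd else (yv, xv.astype(float))
        if c.var() <= 0:
            raise ValueError("zero variance in a continuous column")
        full = _mi_disc_cont(d, c)
        loo = np.array([_mi_disc_cont(np.delete(d, i), np.delete(c, i))
                        for i in range(n)])
    corrected = n * full - (n - 1) * float(np.mean(loo))
    return max(corrected, 0.0)


# ---------------------------------------------------------------------------
# annotation


def annotate_fragment(
    frag: FragmentGraph,
    data,
    conf: ArcConfidenceTable,
    variables: Optional[Sequence[VariableSpec]] = None,
) -> FragmentGraph:
    """Attach MI values, asterisk bands and width bands to a fragment.

    MI is computed per arc on pairwise complete cases; the 33% and 67%
    quantiles of the fragment's MI values set the asterisk cut-offs
    (values on a cut-off go to the higher band).  Width bands partition
    confidence at [threshold, 0.7), [0.7, 0.8), [0.8, 0.9), [0.9, 1].
    The realised cut-offs and MI range are stored on the fragment so
    reports can quote them alongside the graph.
    """
    records = getattr(data, "records", data)
    if variables is None:
        variables = getattr(data, "variables", None)
    vmap = by_name(variables) if variables is not None else {}
    arcs = sorted(frag.arcs)
    for u, v in arcs:
        for col in (u, v):
            if col not in records.columns:
                raise ValueError(f"arc endpoint {col!r} missing from data")
    mi_vals: Dict[Arc, float] = {}
    for u, v in arcs:
        kw = {}
        if u in vmap:
            kw["x_discrete"] = vmap[u].is_discrete
        if v in vmap:
            kw["y_discrete"] = vmap[v].is_discrete
        mi_vals[(u, v)] = jackknife_mi(records[u], records[v], **kw)
    confidence: Dict[Arc, float] = {}
    for a in arcs:
        if a in frag.confidence:
            confidence[a] = frag.confidence[a]
        elif conf is not None and a in conf.entries:
            confidence[a] = conf.confidence(a)
        else:
            raise ValueError(f"arc {a} has no confidence entry")

    values = np.array([mi_vals[a] for a in arcs], dtype=float)
    if len(values):
        c33, c67 = np.quantile(values, [0.33, 0.67])
        mi_band = {a: 1 + int(mi_vals[a] >= c33 - 1e-12) + int(mi_vals[a] >= c67 - 1e-12)
                   for a in arcs}
        mi_range = (float(values.min()), float(values.max()))
        cutoffs = (float(c33), float(c67))
    else:
        mi_band, mi_range, cutoffs = {}, None, None
    width_band = {}
    for a in arcs:
        c = confidence[a]
        width_band[a] = 1 + sum(c >= cut - 1e-12 for cut in (0.7, 0.8, 0.9))
    category = {}
    for node in frag.structure.nodes:
        concept = vmap[node].concept if node in vmap else node.split("@")[0]
        category[node] = CONCEPT_CATEGORY.get(concept, "other")
    return FragmentGraph(
        structure=frag.structure,
        source=frag.source,
        targets=frag.targets,
        stability_threshold=frag.stability_threshold,
        confidence=confidence,
        mi=mi_vals,
        mi_band=mi_band,
        width_band=width_band,
        node_category=category,
        mi_cutoffs=cutoffs,
        mi_range=mi_range,
    )


# ---------------------------------------------------------------------------
# export


def fragment_to_frame(frag: FragmentGraph) -> pd.DataFrame:
    rows = []
    for u, v in sorted(frag.arcs):
        rows.append({
            "parent": u,
            "child": v,
            "confidence": frag.confidence.get((u, v), float("nan")),
            "mi": frag.mi.get((u, v), float("nan")),
            "mi_band": frag.mi_band.get((u, v)),
            "width_band": frag.width_band.get((u, v)),
        })
    return pd.DataFrame(rows, columns=["parent", "child", "confidence", "mi",
                                       "mi_band", "width_band"])


def fragment_to_dot(frag: FragmentGraph, name: str = "fragment") -> str:
    """DOT render: fill colour by concept category, label by asterisks,
    penwidth by stability band."""
    lines = [f"digraph {name} {{", "  rankdir=LR;",
             '  node [style=filled, shape=box, fontname="Helvetica"];']
    for node in frag.structure.nodes:
        colour = _CATEGORY_COLOUR.get(frag.node_category.get(node, "other"), "#ffffff")
        lines.append(f'  "{node}" [fillcolor="{colour}"];')
    for u, v in sorted(frag.arcs):
        stars = "*" * frag.mi_band.get((u, v), 0)
        width = 0.5 + 0.8 * frag.width_band.get((u, v), 1)
        lines.append(f'  "{u}" -> "{v}" [label="{stars}", penwidth={width:.1f}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
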
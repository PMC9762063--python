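"""Bootstrap arc confidence, SHD diagnostics, and model averaging.

A single learned structure is a noisy estimate: resampling the records
with replacement and relearning gives, for every directed arc, the
fraction of bootstrap models containing it ("arc confidence" or
stability).  A consensus ("averaged") network keeps the arcs whose
confidence reaches a threshold — 0.6 by default, inclusive.  The number
of bootstrap replicates is chosen by watching when the thresholded
consensus stops changing, measured by the structural Hamming distance
between consecutive candidate counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .cgbn import NetworkStructure

logger = logging.getLogger(__name__)

Arc = Tuple[str, str]
Learner = Callable[[pd.DataFrame, int], NetworkStructure]


@dataclass
class ArcConfidenceTable:
    """Directed-arc bootstrap frequencies; absent arcs read as 0."""

    counts: Dict[Arc, int]
    n_boot: int
    learner_config: dict = field(default_factory=dict)
    structures: Optional[List[NetworkStructure]] = None
    nodes: Tuple[str, ...] = ()

    @property
    def entries(self) -> Dict[Arc, float]:
        return {arc: c / self.n_boot for arc, c in self.counts.items()}

    def confidence(self, arc: Arc) -> float:
        return self.counts.get(tuple(arc), 0) / self.n_boot

    def to_frame(self) -> pd.DataFrame:
        rows = [(u, v, c / self.n_boot) for (u, v), c in sorted(self.counts.items())]
        return pd.DataFrame(rows, columns=["parent", "child", "confidence"])


@dataclass
class AveragedNetwork:
    """Thresholded consensus graph with per-arc confidence."""

    structure: NetworkStructure
    confidence: Dict[Arc, float]
    threshold: float
    removed_in_repair: List[Arc] = field(default_factory=list)


def bootstrap_confidence(
    data: pd.DataFrame,
    n_boot: int,
    learner: Learner,
    seed: int,
    *,
    strata: Optional[pd.Series] = None,
    keep_structures: bool = False,
    max_retries: int = 3,
    learner_config: Optional[dict] = None,
) -> ArcConfidenceTable:
    """Efron bootstrap of a structure learner.

    For each replicate, records are resampled with replacement to the
    original size — stratified by ``strata`` (study provenance) when
    given, so every study keeps its share of the resample — and the
    learner is run on the resample with a replicate-specific seed.
    Directed-arc occurrence counts across replicates give the table.
    A learner failure on a resample is logged and the resample redrawn,
    up to ``max_retries`` times.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    structures = _bootstrap_structures(data, n_boot, learner, seed,
                                       strata=strata, max_retries=max_retries)
    counts: Dict[Arc, int] = {}
    for s in structures:
        for arc in s.arcs:
            counts[arc] = counts.get(arc, 0) + 1
    nodes = structures[0].nodes if structures else ()
    return ArcConfidenceTable(
        counts=counts,
        n_boot=n_boot,
        learner_config=dict(learner_config or {}),
        structures=structures if keep_structures else None,
        nodes=nodes,
    )


def _bootstrap_structures(data, n_boot, learner, seed, *, strata=None, max_retries=3):
    n = len(data)
    structures: List[NetworkStructure] = []
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            rng = np.random.default_rng([seed, b, attempt])
            if strata is not None:
                idx_parts = []
                values = np.asarray(strata)
                for g in sorted(pd.unique(values).tolist()):
                    rows = np.flatnonzero(values == g)
                    idx_parts.append(rng.choice(rows, size=len(rows), replace=True))
                idx = np.concatenate(idx_parts)
            else:
                idx = rng.integers(0, n, size=n)
            resample = data.iloc[np.sort(idx)].reset_index(drop=True)
            try:
                structures.append(learner(resample, int(rng.integers(0, 2**31 - 1))))
                break
            except Exception as exc:  # pragma: no cover - rare resample pathologies
                logger.warning("bootstrap replicate %d failed (attempt %d): %s",
                               b, attempt, exc)
        else:  # pragma: no cover
            raise RuntimeError(f"bootstrap replicate {b} failed after retries")
    return structures


def shd(g1: NetworkStructure, g2: NetworkStructure) -> int:
    """Structural Hamming distance between two DAGs on the same nodes.

    Counts arc insertions, deletions and reversals needed to turn
    ``g1`` into ``g2``; a reversal counts as one operation.
    """
    if set(g1.nodes) != set(g2.nodes):
        raise ValueError("graphs have differing node sets")
    a1, a2 = g1.arcs, g2.arcs
    dist = 0
    seen = set()
    for u, v in a1 | a2:
        if frozenset((u, v)) in seen:
            continue
        seen.add(frozenset((u, v)))
        fwd1, rev1 = (u, v) in a1, (v, u) in a1
        fwd2, rev2 = (u, v) in a2, (v, u) in a2
        # per unordered pair: 0 if identical, 1 per differing directed arc,
        # except a pure reversal which counts once
        if (fwd1, rev1) == (fwd2, rev2):
            continue
        if (fwd1 or rev1) and (fwd2 or rev2) and (fwd1, rev1) == (rev2, fwd2):
            dist += 1
        else:
            dist += int(fwd1 != fwd2) + int(rev1 != rev2)
    return dist


def average_network(conf: ArcConfidenceTable, threshold: float = 0.6) -> AveragedNetwork:
    """Keep arcs with confidence >= ``threshold`` (inclusive); repair cycles.

    The temporal constraints make cycles possible only among same-tier
    variables; if one arises, the lowest-confidence arc in each cycle is
    removed (and logged) until the consensus is acyclic.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    kept = {arc: c / conf.n_boot for arc, c in conf.counts.items()
            if c / conf.n_boot >= threshold - 1e-12}
    nodes = conf.nodes or tuple(sorted({x for arc in kept for x in arc}))
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(kept)
    removed: List[Arc] = []
    while True:
        try:
            cycle = nx.find_cycle(g, orientation="original")
        except nx.NetworkXNoCycle:
            break
        arcs = [(u, v) for u, v, _ in cycle]
        worst = min(arcs, key=lambda a: (kept[a], a))
        g.remove_edge(*worst)
        removed.append(worst)
        logger.info("cycle repair: removed %s -> %s (confidence %.3f)",
                    worst[0], worst[1], kept[worst])
        del kept[worst]
    structure = NetworkStructure(nodes, kept)
    return AveragedNetwork(structure=structure, confidence=dict(kept),
                           threshold=threshold, removed_in_repair=removed)


def select_n_boot(
    data: pd.DataFrame,
    learner: Learner,
    candidates: Sequence[int],
    threshold: float,
    seed: int,
    *,
    strata: Optional[pd.Series] = None,
) -> Tuple[int, pd.DataFrame]:
    """Choose a bootstrap count at which the consensus graph stabilises.

    Learns ``max(candidates)`` bootstrap structures once (replicate
    seeds depend only on the replicate index, so a prefix of the run
    equals a smaller run), forms the thresholded averaged network at
    each candidate count, and returns the smallest candidate whose
    consensus has SHD 0 to the next candidate's, together with the
    SHD-versus-count diagnostic series.  Falls back to the largest
    candidate if the series never reaches 0.
    """
    cands = list(candidates)
    if not cands or any(b <= 0 for b in cands) or sorted(cands) != cands:
        raise ValueError("candidates must be a non-empty ascending list of positive ints")
    structures = _bootstrap_structures(data, max(cands), learner, seed, strata=strata)

    def averaged(k: int) -> NetworkStructure:
        counts: Dict[Arc, int] = {}
        for s in structures[:k]:
            for arc in s.arcs:
                counts[arc] = counts.get(arc, 0) + 1
        table = ArcConfidenceTable(counts=counts, n_boot=k, nodes=structures[0].nodes)
        return average_network(table, threshold).structure

    nets = {k: averaged(k) for k in cands}
    series = []
    chosen = None
    for a, b in zip(cands[:-1], cands[1:]):
        d = shd(nets[a], nets[b])
        series.append({"n_boot": a, "n_boot_next": b, "shd": d})
        if d == 0 and chosen is None:
            chosen = a
    if chosen is None:
        chosen = cands[-1]
    return chosen, pd.DataFrame(series, columns=["n_boot", "n_boot_next", "shd"])
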
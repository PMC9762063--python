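"""End-to-end orchestration: simulate/ingest, learn, bootstrap, distil.

`run_full_analysis` reproduces the whole analysis workflow on one
dataset: learn a constrained hybrid network with structural EM (plain
hill-climbing when the table is complete), bootstrap it for arc
confidence, threshold into an averaged network, and distil the
annotated intervention-to-outcome fragment — for the full population
and for each stratum of an optional demographic (strata drop the
stratifying variable, which is constant within them).  All artifacts
are plain text (CSV, DOT, JSON) plus a manifest sufficient to replay
the run bit-exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__, cgbn, dataio, fragment as frag_mod, stability, synthetic
from .dataio import STUDY_COLUMN, IntegratedDataset
from .learn import build_constraints, hill_climb, structural_em
from .variables import VariableSpec

TRUTHS = {
    "demo": synthetic.demo_truth,
    "compact": synthetic.compact_truth,
    "default": synthetic.build_default_truth,
}


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    out_dir: str
    seed: int = 0
    # input: either a simulation spec name or CSV + schema paths
    truth: str = "demo"
    n_records: int = 500
    input_csv: Optional[str] = None
    schema: Optional[str] = None
    # learner
    score_tol: float = 1e-4
    max_iter: int = 10
    restarts: int = 0
    pseudo_count: float = 1.0
    # bootstrap
    n_boot: int = 50
    boot_candidates: Optional[List[int]] = None
    threshold: float = 0.6
    # fragment
    source: str = "intervention"
    targets: Tuple[str, ...] = ("pa@T2", "pa@T3")
    display_threshold: float = 0.6
    # stratification
    stratify: Optional[str] = None
    stratify_levels: Optional[List] = None

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1 or not 0 < self.display_threshold <= 1:
            raise ValueError("thresholds must be in (0, 1]")
        if self.display_threshold < self.threshold:
            raise ValueError("display threshold must be >= averaging threshold")


def _load_input(config: RunConfig) -> Tuple[IntegratedDataset, dict]:
    if config.input_csv is not None:
        if config.schema is None:
            raise ValueError("input_csv requires a schema file")
        variables, _ = dataio.read_schema(config.schema)
        records = dataio.read_table(config.input_csv)
        return IntegratedDataset(variables=variables, records=records), {
            "input_csv": str(config.input_csv)}
    spec = TRUTHS[config.truth](config.seed)
    complete = synthetic.simulate_cohort(spec, config.n_records, config.seed)
    observed = synthetic.apply_missingness(complete, spec, config.seed + 1)
    data = IntegratedDataset(variables=list(spec.variables), records=observed)
    return data, {"truth": config.truth, "n_records": config.n_records,
                  "true_arcs": sorted(map(list, spec.true_dag.arcs))}


def _make_learner(variables: Sequence[VariableSpec], config: RunConfig,
                  has_missing: bool):
    constraints = build_constraints(variables)
    names = [v.name for v in variables]

    def learner(table: pd.DataFrame, seed: int):
        cols = table[names]
        if has_missing and cols.isna().any().any():
            res = structural_em(cols, variables, constraints,
                                max_iter=config.max_iter,
                                score_tol=config.score_tol, seed=seed,
                                restarts=config.restarts,
                                pseudo_count=config.pseudo_count)
            return res.structure
        return hill_climb(cols, variables, constraints, seed=seed,
                          restarts=config.restarts)

    return learner, constraints


def _analyse_population(name: str, data: IntegratedDataset, config: RunConfig,
                        out: Path, seed: int) -> dict:
    t0 = time.perf_counter()
    variables = data.variables
    names = [v.name for v in variables]
    has_missing = bool(data.records[names].isna().any().any())
    learner, constraints = _make_learner(variables, config, has_missing)
    strata = data.records[STUDY_COLUMN] if STUDY_COLUMN in data.records else None

    if config.boot_candidates:
        n_boot, series = stability.select_n_boot(
            data.records, learner, config.boot_candidates, config.threshold,
            seed, strata=strata)
    else:
        n_boot, series = config.n_boot, pd.DataFrame(
            columns=["n_boot", "n_boot_next", "shd"])
    conf = stability.bootstrap_confidence(data.records, n_boot, learner, seed,
                                          strata=strata)
    for arc in conf.counts:
        if not constraints.is_legal(*arc):  # pragma: no cover - invariant
            raise AssertionError(f"bootstrap produced illegal arc {arc}")
    avg = stability.average_network(conf, config.threshold)

    targets = [t for t in config.targets if t in avg.structure.nodes]
    fragment = frag_mod.extract_fragment(avg, config.source, targets,
                                         config.display_threshold)
    fragment = frag_mod.annotate_fragment(fragment, data, conf)

    pop_dir = out / name
    pop_dir.mkdir(parents=True, exist_ok=True)
    conf.to_frame().to_csv(pop_dir / "confidence.csv", index=False)
    (pop_dir / "averaged.dot").write_text(cgbn.structure_to_dot(avg.structure))
    pd.DataFrame(
        [(u, v, avg.confidence[(u, v)]) for u, v in sorted(avg.structure.arcs)],
        columns=["parent", "child", "confidence"],
    ).to_csv(pop_dir / "averaged.csv", index=False)
    series.to_csv(pop_dir / "shd_series.csv", index=False)
    (pop_dir / "fragment.dot").write_text(frag_mod.fragment_to_dot(fragment))
    frag_mod.fragment_to_frame(fragment).to_csv(pop_dir / "fragment.csv", index=False)
    report = {
        "population": name,
        "n_records": int(len(data.records)),
        "n_variables": len(variables),
        "n_boot": int(n_boot),
        "threshold": config.threshold,
        "display_threshold": config.display_threshold,
        "fragment": fragment.summary(),
        "averaged_arcs": len(avg.structure.arcs),
        "cycle_repairs": list(map(list, avg.removed_in_repair)),
        "wall_clock_s": round(time.perf_counter() - t0, 3),
    }
    (pop_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return {"report": report, "fragment": fragment, "averaged": avg,
            "confidence": conf}


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage for the full population and each stratum."""
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data, input_meta = _load_input(config)

    populations: List[Tuple[str, IntegratedDataset]] = [("all", data)]
    if config.stratify:
        levels = config.stratify_levels
        if levels is None:
            levels = sorted(data.records[config.stratify].dropna().unique().tolist())
        for lv in levels:
            sub = dataio.filter_subpopulation(data, config.stratify, lv)
            populations.append((f"{config.stratify}={lv}", sub))

    results = {}
    for i, (name, pop) in enumerate(populations):
        results[name] = _analyse_population(name, pop, config, out,
                                            seed=config.seed * 1000 + i)

    manifest = {
        "config": asdict(config),
        "input": input_meta,
        "package_version": __version__,
        "populations": {
            name: {"n_records": r["report"]["n_records"],
                   "wall_clock_s": r["report"]["wall_clock_s"]}
            for name, r in results.items()
        },
        "total_wall_clock_s": round(time.perf_counter() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results


def compare_fragments(frag_a: frag_mod.FragmentGraph,
                      frag_b: frag_mod.FragmentGraph) -> dict:
    """Difference report between two fragments (e.g. male vs female)."""
    arcs_a, arcs_b = frag_a.arcs, frag_b.arcs
    shared = sorted(arcs_a & arcs_b)
    band_diffs = []
    for a in shared:
        da = {"arc": list(a)}
        for attr in ("mi_band", "width_band"):
            va = getattr(frag_a, attr).get(a)
            vb = getattr(frag_b, attr).get(a)
            if va != vb:
                da[attr] = [va, vb]
        if len(da) > 1:
            band_diffs.append(da)
    return {
        "arcs_only_a": sorted(map(list, arcs_a - arcs_b)),
        "arcs_only_b": sorted(map(list, arcs_b - arcs_a)),
        "shared_band_differences": band_diffs,
        "nodes_only_a": sorted(set(frag_a.structure.nodes) - set(frag_b.structure.nodes)),
        "nodes_only_b": sorted(set(frag_b.structure.nodes) - set(frag_a.structure.nodes)),
    }
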
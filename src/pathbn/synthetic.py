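"""Synthetic multi-study cohorts with known ground-truth networks.

The generator emulates the statistical shape of an integrated pooled
dataset from five e-health physical-activity intervention trials:

* demographics (age in years, Boolean gender, 3-level education), a
  randomised binary intervention indicator;
* socio-cognitive determinant concept scales on 1-5 (intention: 1-10),
  measured at up to four waves T0/T1/T2/T3;
* a minutes-per-week moderate-to-vigorous activity outcome at every
  wave, truncated at 0;
* per-study measurement designs: each study measures only a subset of
  (concept, wave) pairs, so pooling leaves design-driven blocks of
  missing values; optional extra record-level MCAR missingness on top.

The ground-truth DAG routes intervention effects through determinants
into the outcomes (direct weak effects on determinants, stronger
autoregressive and cross-concept effects), so that every downstream
stage — learning, bootstrap, fragment extraction — can be tested
against a known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import cgbn
from .cgbn import CGParameters, DiscreteLocal, GaussianLocal, NetworkStructure
from .dataio import STUDY_COLUMN, _vtype_from_obj, _vtype_to_obj
from .learn import build_constraints
from .variables import Continuous, Discrete, VariableSpec, by_name, measurement_spec

#: (concept, tier) -> studies measuring it, mirroring the published
#: measurement-design table of the five pooled trials.  Study 3 had no
#: 12-month wave at all.
AVAILABILITY: Dict[str, Dict[str, Set[int]]] = {
    "self_efficacy": {"T0": {1, 2, 3, 4, 5}, "T1": {1, 2, 3, 5}, "T2": {5}, "T3": {4}},
    "attitude": {"T0": {1, 2, 3, 4, 5}, "T1": {1, 2, 3, 5}, "T2": {5}, "T3": {4}},
    "intrinsic_motivation": {"T0": {1, 2, 5}, "T1": {1, 2}, "T2": {5}},
    "intention": {"T0": {1, 2, 3, 4, 5}, "T1": {1, 2, 3}, "T2": {1, 2, 4, 5},
                  "T3": {1, 2, 4, 5}},
    "commitment": {"T0": {1, 2}, "T1": {1, 2}, "T2": {1, 2}},
    "strategic_planning": {"T0": {1, 2, 3, 4, 5}, "T1": {1, 2}, "T2": {1, 2, 5},
                           "T3": {1, 4}},
    "action_planning": {"T0": {1, 2, 5}, "T1": {1, 2}, "T2": {1, 2, 5}},
    "coping_planning": {"T0": {1, 2, 5}, "T1": {1, 2}, "T2": {1, 2, 5}},
    "habit": {"T0": {1, 2, 4, 5}, "T2": {1, 2, 4, 5}, "T3": {1, 2, 4, 5}},
    "social_modelling": {"T0": {1, 2, 3, 4, 5}, "T1": {1, 2, 3}, "T2": {1, 3},
                         "T3": {4}},
    "social_support": {"T0": {1, 2, 3, 4, 5}, "T1": {1, 2, 3}, "T2": {3, 5},
                       "T3": {4}},
    "pa": {"T0": {1, 2, 3, 4, 5}, "T1": {1, 2, 3, 5}, "T2": {1, 2, 3, 4, 5},
           "T3": {1, 2, 4, 5}},
}

#: Published per-study enrolment, used as default study-size proportions.
STUDY_SIZES = {1: 1976, 2: 2140, 3: 766, 4: 623, 5: 478}

#: Share of participants in the intervention arm across the pooled trials
#: (4405 of 5975).
INTERVENTION_SHARE = 4405 / 5975


@dataclass
class StudyDesign:
    """One study's size and measurement availability."""

    study_id: str
    n_participants: int
    measured: Set[str]  # variable names, incl. demographics + intervention


@dataclass
class GroundTruthSpec:
    """A complete generating model for synthetic cohorts."""

    variables: List[VariableSpec]
    true_dag: NetworkStructure
    parameters: CGParameters
    study_designs: List[StudyDesign]
    extra_missing_rate: float = 0.0
    strong_arcs: Set[Tuple[str, str]] = field(default_factory=set)

    def validate(self) -> None:
        vmap = by_name(self.variables)  # raises on duplicates
        if set(self.true_dag.nodes) != set(vmap):
            raise ValueError("DAG nodes and variable list disagree")
        constraints = build_constraints(self.variables)
        constraints.validate(self.true_dag)
        always = {v.name for v in self.variables
                  if v.role in ("demographic", "intervention")}
        for d in self.study_designs:
            lacking = always - d.measured
            if lacking:
                raise ValueError(
                    f"study {d.study_id} marks {sorted(lacking)} unmeasured")
        if not 0 <= self.extra_missing_rate < 1:
            raise ValueError("extra_missing_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# parameter builder


class _Builder:
    def __init__(self, variables: Sequence[VariableSpec]):
        self.specs = by_name(variables)
        self.variables = list(variables)
        self.arcs: List[Tuple[str, str]] = []
        self.params = CGParameters()

    def discrete_root(self, name: str, probs: Sequence[float]) -> None:
        spec = self.specs[name]
        self.params.locals[name] = DiscreteLocal(
            levels=tuple(spec.vtype.levels), parents=(), plevels=(),
            cpt=np.array([probs], dtype=float))

    def gaussian(self, name: str, b0: float, var: float,
                 coef: Optional[Mapping[str, float]] = None,
                 dshift: Optional[Mapping[str, Mapping[object, float]]] = None) -> None:
        """Linear-Gaussian node: continuous parents via ``coef``; discrete
        parents shift the intercept additively via ``dshift``."""
        coef = dict(coef or {})
        dshift = {k: dict(v) for k, v in (dshift or {}).items()}
        dparents = tuple(sorted(dshift))
        cparents = tuple(sorted(coef))
        plevels = tuple(len(self.specs[p].vtype.levels) for p in dparents)
        n_cfg = int(np.prod(plevels)) if plevels else 1
        b0_arr = np.full(n_cfg, float(b0))
        for cfgi in range(n_cfg):
            idx = np.unravel_index(cfgi, plevels) if plevels else ()
            for p, li in zip(dparents, idx):
                level = self.specs[p].vtype.levels[li]
                b0_arr[cfgi] += dshift[p].get(level, 0.0)
        coef_arr = np.tile(np.array([coef[c] for c in cparents], dtype=float),
                           (n_cfg, 1))
        self.params.locals[name] = GaussianLocal(
            dparents=dparents, plevels=plevels, cparents=cparents,
            b0=b0_arr, coef=coef_arr, var=np.full(n_cfg, float(var)))
        for p in list(dparents) + list(cparents):
            self.arcs.append((p, name))

    def build(self) -> Tuple[NetworkStructure, CGParameters]:
        return NetworkStructure([v.name for v in self.variables], self.arcs), self.params


def _scale_vars(concepts_tiers: Sequence[Tuple[str, str]]) -> List[VariableSpec]:
    out = []
    for concept, tier in concepts_tiers:
        hi = 10.0 if concept == "intention" else 5.0
        if concept == "pa":
            out.append(measurement_spec("pa", tier, lo=0.0, hi=None, outcome=True)
                       if tier != "T0" else
                       VariableSpec("pa@T0", "pa", "T0", Continuous(0.0, None), "baseline"))
        else:
            out.append(measurement_spec(concept, tier, lo=1.0, hi=hi))
    return out


def _demographics() -> List[VariableSpec]:
    return [
        VariableSpec("age", "age", "static", Continuous(18.0, 100.0), "demographic"),
        VariableSpec("gender", "gender", "static", Discrete(("male", "female")),
                     "demographic"),
        VariableSpec("education", "education", "static", Discrete((0, 1, 2)),
                     "demographic"),
    ]


def _intervention() -> VariableSpec:
    return VariableSpec("intervention", "intervention", "static", Discrete((0, 1)),
                        "intervention")


# ---------------------------------------------------------------------------
# ground truths


def build_default_truth(seed: int = 0, *, extra_missing_rate: float = 0.05,
                        study_scale: float = 1.0) -> GroundTruthSpec:
    """Full-inventory ground truth mirroring the pooled five-study design.

    Deterministic for a fixed seed: the structure is fixed, coefficient
    magnitudes receive a small seed-dependent jitter so different seeds
    give different (equally legal) truths.  Intervention effects on
    determinants are weak-to-moderate (about a quarter scale point);
    autoregressive and within-wave cross-concept effects are stronger,
    so intervention influence reaches the outcomes mostly through
    mediation chains.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    rng = np.random.default_rng(seed)

    def j(x: float) -> float:  # +-10% deterministic jitter
        return float(x * (1.0 + 0.1 * (rng.random() * 2 - 1)))

    inventory = [(c, t) for c, tiers in AVAILABILITY.items() for t in tiers]
    variables = _demographics() + [_intervention()] + _scale_vars(inventory)
    b = _Builder(variables)

    b.gaussian("age", 65.0, 9.32 ** 2)
    b.discrete_root("gender", [0.45, 0.55])
    b.discrete_root("education", [0.3, 0.4, 0.3])
    b.discrete_root("intervention", [1 - INTERVENTION_SHARE, INTERVENTION_SHARE])

    cross = {  # within-wave concept influences (theory-guided chains)
        "attitude": {},
        "self_efficacy": {},
        "social_modelling": {},
        "social_support": {"social_modelling": j(0.35)},
        "intrinsic_motivation": {"attitude": j(0.3), "social_support": j(0.25)},
        "commitment": {"strategic_planning": j(0.3)},
        "strategic_planning": {"intrinsic_motivation": j(0.25),
                               "action_planning": j(0.3)},
        "action_planning": {},
        "coping_planning": {"action_planning": j(0.35)},
        "intention": {"attitude": j(0.4), "self_efficacy": j(0.35),
                      "strategic_planning": j(0.3), "commitment": j(0.3)},
        "habit": {"commitment": j(0.3), "intention": j(0.3)},
    }
    tiers = ("T0", "T1", "T2", "T3")
    concept_order = ["attitude", "self_efficacy", "social_modelling", "social_support",
                     "intrinsic_motivation", "action_planning", "coping_planning",
                     "strategic_planning", "commitment", "intention", "habit"]
    for tier in tiers:
        for concept in concept_order:
            name = f"{concept}@{tier}"
            if name not in b.specs:
                continue
            mean = 6.0 if concept == "intention" else 3.2
            coef: Dict[str, float] = {}
            prev = _previous_measured(concept, tier)
            if prev is not None:
                coef[prev] = j(0.55)
            for src, c in cross[concept].items():
                src_name = f"{src}@{tier}"
                if src_name in b.specs:
                    coef[src_name] = c
            dshift = {}
            if tier != "T0":
                dshift["intervention"] = {1: j(0.25 if concept == "intention" else 0.22)}
            b.gaussian(name, _centre(mean, coef, b), j(0.45), coef=coef, dshift=dshift)
    # outcomes: minutes/week of moderate-to-vigorous activity
    for tier in tiers:
        name = f"pa@{tier}"
        coef = {}
        prev = _previous_measured("pa", tier)
        if prev is not None:
            coef[prev] = j(0.5)
        for det in ("intention", "habit"):
            det_name = f"{det}@{tier}"
            if det_name in b.specs:
                coef[det_name] = j(12.0)
        if tier == "T0":
            coef["age"] = j(-0.8)
            b.gaussian(name, 150.0 + 0.8 * 65 - _dot(coef, b), 55.0 ** 2, coef=coef,
                       dshift={"education": {1: j(8.0), 2: j(15.0)}})
        else:
            b.gaussian(name, 150.0 - _dot(coef, b), 45.0 ** 2, coef=coef,
                       dshift={"intervention": {1: j(10.0)}})
    dag, params = b.build()
    designs = default_study_designs(variables, scale=study_scale)
    spec = GroundTruthSpec(variables=variables, true_dag=dag, parameters=params,
                           study_designs=designs,
                           extra_missing_rate=extra_missing_rate,
                           strong_arcs=set())
    spec.strong_arcs = _standardised_strong_arcs(spec)
    spec.validate()
    return spec


def _previous_measured(concept: str, tier: str) -> Optional[str]:
    tiers = ("T0", "T1", "T2", "T3")
    avail = AVAILABILITY[concept]
    i = tiers.index(tier)
    for prev in reversed(tiers[:i]):
        if prev in avail:
            return f"{concept}@{prev}"
    return None


def _centre(mean: float, coef: Mapping[str, float], b: "_Builder") -> float:
    """Intercept that keeps the node's marginal mean at ``mean`` given the
    (approximate) means of its continuous parents."""
    return mean - _dot(coef, b)


def _dot(coef: Mapping[str, float], b: "_Builder") -> float:
    total = 0.0
    for parent, c in coef.items():
        if parent == "age":
            pm = 65.0
        elif parent.startswith("pa@"):
            pm = 150.0
        elif parent.startswith("intention@"):
            pm = 6.0
        else:
            pm = 3.2
        total += c * pm
    return total


def default_study_designs(variables: Sequence[VariableSpec],
                          scale: float = 1.0) -> List[StudyDesign]:
    """Five designs with the published availability pattern and sizes."""
    always = {v.name for v in variables if v.role in ("demographic", "intervention")}
    vnames = {v.name for v in variables}
    designs = []
    for sid, size in STUDY_SIZES.items():
        measured = set(always)
        for concept, tiers in AVAILABILITY.items():
            for tier, studies in tiers.items():
                name = f"{concept}@{tier}"
                if sid in studies and name in vnames:
                    measured.add(name)
        designs.append(StudyDesign(study_id=f"study{sid}",
                                   n_participants=max(1, round(size * scale)),
                                   measured=measured))
    return designs


def compact_truth(seed: int = 0) -> GroundTruthSpec:
    """Fixed 14-node tiered truth used for learning experiments.

    One binary intervention, four determinant concepts over three
    follow-up waves, and the activity outcome at all three follow-ups.
    Effects are moderate: weak direct intervention effects on the
    determinants, standardised autoregressive/cross effects of roughly
    0.3-0.6, and outcome effects near 12 minutes/week per determinant
    scale point against a 40 minutes/week noise standard deviation.
    """
    concepts = [
        ("self_efficacy", "T1"), ("self_efficacy", "T2"),
        ("intention", "T1"), ("intention", "T2"), ("intention", "T3"),
        ("strategic_planning", "T1"), ("strategic_planning", "T2"),
        ("commitment", "T2"),
        ("habit", "T2"), ("habit", "T3"),
        ("pa", "T1"), ("pa", "T2"), ("pa", "T3"),
    ]
    variables = [_intervention()] + _scale_vars(concepts)
    b = _Builder(variables)
    b.discrete_root("intervention", [1 - INTERVENTION_SHARE, INTERVENTION_SHARE])
    # intervention effects enter at T1 and propagate purely by mediation;
    # downstream effects are continuous-continuous, so every true arc is
    # comfortably detectable at a few thousand records and no pair of
    # nodes shares a parent set (no covered-edge orientation ambiguity)
    iv = {"intervention": {1: 0.5}}
    b.gaussian("self_efficacy@T1", 3.2, 0.55, dshift=iv)
    b.gaussian("intention@T1", 6.0, 0.7, dshift=iv)
    b.gaussian("strategic_planning@T1", 3.2, 0.55, dshift=iv)
    b.gaussian("self_efficacy@T2", 3.2 * 0.4, 0.4,
               coef={"self_efficacy@T1": 0.6})
    b.gaussian("strategic_planning@T2", 3.2 * 0.4, 0.4,
               coef={"strategic_planning@T1": 0.6})
    b.gaussian("commitment@T2", 3.2 - 0.5 * 3.2, 0.5,
               coef={"strategic_planning@T1": 0.5})
    b.gaussian("intention@T2", 6.0 - 0.55 * 6.0 - 0.45 * 3.2 - 0.4 * 3.2, 0.45,
               coef={"intention@T1": 0.55, "self_efficacy@T2": 0.45,
                     "strategic_planning@T2": 0.4})
    b.gaussian("habit@T2", 3.2 - 0.5 * 3.2 - 0.3 * 6.0, 0.5,
               coef={"commitment@T2": 0.5, "intention@T2": 0.3})
    b.gaussian("intention@T3", 6.0 - 0.6 * 6.0, 0.5,
               coef={"intention@T2": 0.6})
    b.gaussian("habit@T3", 3.2 - 0.6 * 3.2, 0.45,
               coef={"habit@T2": 0.6})
    b.gaussian("pa@T1", 150.0 - 12.0 * 6.0, 42.0 ** 2,
               coef={"intention@T1": 12.0})
    b.gaussian("pa@T2", 150.0 - 0.5 * 150 - 12.0 * 6.0 - 14.0 * 3.2, 40.0 ** 2,
               coef={"pa@T1": 0.5, "intention@T2": 12.0, "habit@T2": 14.0})
    b.gaussian("pa@T3", 150.0 - 0.55 * 150 - 12.0 * 6.0, 40.0 ** 2,
               coef={"pa@T2": 0.55, "intention@T3": 12.0})
    dag, params = b.build()
    designs = [StudyDesign("study1", 1, {v.name for v in variables})]
    spec = GroundTruthSpec(variables=variables, true_dag=dag, parameters=params,
                           study_designs=designs, extra_missing_rate=0.0,
                           strong_arcs=set())
    spec.strong_arcs = _standardised_strong_arcs(spec)
    spec.validate()
    return spec


def demo_truth(seed: int = 0, *, extra_missing_rate: float = 0.05) -> GroundTruthSpec:
    """Small truth with demographics, for end-to-end pipeline runs.

    Ten substantive nodes across two studies whose designs differ (the
    second study does not measure habit at T2), so integration-style
    block missingness arises even at demo scale.
    """
    concepts = [("intention", "T1"), ("intention", "T2"), ("habit", "T2"),
                ("pa", "T1"), ("pa", "T2"), ("pa", "T3")]
    variables = _demographics() + [_intervention()] + _scale_vars(concepts)
    b = _Builder(variables)
    b.gaussian("age", 65.0, 9.32 ** 2)
    b.discrete_root("gender", [0.45, 0.55])
    b.discrete_root("education", [0.3, 0.4, 0.3])
    b.discrete_root("intervention", [1 - INTERVENTION_SHARE, INTERVENTION_SHARE])
    iv = {"intervention": {1: 0.45}}
    b.gaussian("intention@T1", 6.0, 0.7, dshift=iv)
    b.gaussian("intention@T2", 6.0 - 0.6 * 6.0, 0.5,
               coef={"intention@T1": 0.6}, dshift=iv)
    b.gaussian("habit@T2", 3.2 - 0.12 * 6.0, 0.5,
               coef={"intention@T2": 0.12}, dshift=iv)
    b.gaussian("pa@T1", 150.0 - 12.0 * 6.0 + 0.8 * 65, 42.0 ** 2,
               coef={"intention@T1": 12.0, "age": -0.8},
               dshift={"intervention": {1: 12.0}, "gender": {"female": -10.0}})
    b.gaussian("pa@T2", 150.0 - 0.5 * 150 - 12.0 * 6.0 - 14.0 * 3.2, 40.0 ** 2,
               coef={"pa@T1": 0.5, "intention@T2": 12.0, "habit@T2": 14.0},
               dshift={"intervention": {1: 12.0}})
    b.gaussian("pa@T3", 150.0 - 0.6 * 150, 40.0 ** 2,
               coef={"pa@T2": 0.6}, dshift={"intervention": {1: 10.0}})
    dag, params = b.build()
    all_vars = {v.name for v in variables}
    designs = [
        StudyDesign("studyA", 3, set(all_vars)),
        StudyDesign("studyB", 2, set(all_vars) - {"habit@T2"}),
    ]
    spec = GroundTruthSpec(variables=variables, true_dag=dag, parameters=params,
                           study_designs=designs,
                           extra_missing_rate=extra_missing_rate,
                           strong_arcs=set(dag.arcs))
    spec.validate()
    return spec


def random_truth(seed: int, *, n_concepts: int = 3, tiers: Sequence[str] = ("T1", "T2"),
                 arc_prob: float = 0.4, extra_missing_rate: float = 0.1) -> GroundTruthSpec:
    """A random legal tiered truth (for randomised robustness checks)."""
    rng = np.random.default_rng(seed)
    pool = ["intention", "habit", "self_efficacy", "strategic_planning",
            "commitment", "attitude"]
    chosen = list(rng.choice(pool, size=n_concepts, replace=False))
    concepts = [(c, t) for c in chosen for t in tiers] + [("pa", t) for t in tiers]
    variables = [_intervention()] + _scale_vars(concepts)
    b = _Builder(variables)
    b.discrete_root("intervention", [0.4, 0.6])
    constraints = build_constraints(variables)
    names = [v.name for v in variables if v.name != "intervention"]
    order = sorted(names, key=lambda n: (n.split("@")[1], n))
    assigned: Dict[str, Dict[str, float]] = {n: {} for n in order}
    for i, v in enumerate(order):
        for u in order[:i]:
            if constraints.is_legal(u, v) and rng.random() < arc_prob:
                assigned[v][u] = float(rng.uniform(0.3, 0.6) * rng.choice([-1, 1]))
    def nominal_sd(name: str) -> float:
        return 45.0 if name.startswith("pa@") else 0.8

    for v in order:
        is_pa = v.startswith("pa@")
        # standardised coefficients rescaled to the raw measurement units
        coef = {u: c * nominal_sd(v) / nominal_sd(u) for u, c in assigned[v].items()}
        mean = 150.0 if is_pa else (6.0 if v.startswith("intention") else 3.2)
        var = 40.0 ** 2 if is_pa else 0.5
        dshift = {"intervention": {1: float(rng.uniform(0.25, 0.5)) * nominal_sd(v)}} \
            if rng.random() < 0.7 else {}
        b.gaussian(v, mean - _dot(coef, b), var, coef=coef, dshift=dshift)
    dag, params = b.build()
    designs = [StudyDesign("study1", 1, {v.name for v in variables})]
    spec = GroundTruthSpec(variables=variables, true_dag=dag, parameters=params,
                           study_designs=designs,
                           extra_missing_rate=extra_missing_rate,
                           strong_arcs=set())
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# simulation


def simulate_cohort(spec: GroundTruthSpec, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` complete records by ancestral sampling from the truth.

    Study labels are allocated proportionally to the design sizes
    (largest-remainder rounding); continuous scales are clipped to
    their declared ranges as they are drawn.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for v in spec.variables:
        if v.name not in spec.parameters.locals:
            raise ValueError(f"spec parameters incomplete: missing {v.name}")
    table = cgbn.sample(spec.true_dag, spec.parameters, spec.variables, n, seed,
                        clip_to_range=True)
    sizes = np.array([d.n_participants for d in spec.study_designs], dtype=float)
    share = sizes / sizes.sum()
    alloc = np.floor(share * n).astype(int)
    rem = n - alloc.sum()
    order = np.argsort(-(share * n - alloc))
    alloc[order[:rem]] += 1
    labels = np.repeat([d.study_id for d in spec.study_designs], alloc)
    table.insert(0, STUDY_COLUMN, labels)
    table.insert(0, "participant_id",
                 [f"{sid}_{i:05d}" for i, sid in enumerate(labels)])
    return table


def apply_missingness(table: pd.DataFrame, spec: GroundTruthSpec,
                      seed: int) -> pd.DataFrame:
    """Mask cells per study design, plus extra MCAR missingness.

    Every (variable, record) cell whose study design does not measure
    the variable becomes missing; each surviving measurement cell is
    additionally masked with probability ``spec.extra_missing_rate``.
    Demographics and the intervention indicator are never masked.
    """
    designs = {d.study_id: d for d in spec.study_designs}
    unknown = set(table[STUDY_COLUMN]) - set(designs)
    if unknown:
        raise ValueError(f"unknown study_id values {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = table.copy()
    protected = {v.name for v in spec.variables
                 if v.role in ("demographic", "intervention")}
    maskable = [v for v in spec.variables if v.name not in protected]
    study = table[STUDY_COLUMN].to_numpy()
    for v in maskable:
        col = out[v.name].to_numpy(dtype=float if not v.is_discrete else object,
                                   copy=True)
        design_missing = np.isin(study, [sid for sid, d in designs.items()
                                         if v.name not in d.measured])
        col[design_missing] = np.nan
        if spec.extra_missing_rate > 0:
            eligible = ~design_missing
            extra = rng.random(len(col)) < spec.extra_missing_rate
            col[eligible & extra] = np.nan
        out[v.name] = col
    return out


# ---------------------------------------------------------------------------
# serialisation


def spec_to_json(spec: GroundTruthSpec) -> str:
    obj = {
        "variables": [
            {"name": v.name, "concept": v.concept, "tier": v.tier,
             "role": v.role, "vtype": _vtype_to_obj(v.vtype)}
            for v in spec.variables
        ],
        "arcs": sorted(list(a) for a in spec.true_dag.arcs),
        "parameters": json.loads(cgbn.params_to_json(spec.parameters)),
        "study_designs": [
            {"study_id": d.study_id, "n_participants": d.n_participants,
             "measured": sorted(d.measured)}
            for d in spec.study_designs
        ],
        "extra_missing_rate": spec.extra_missing_rate,
        "strong_arcs": sorted(list(a) for a in spec.strong_arcs),
    }
    return json.dumps(obj, indent=2, sort_keys=True)


def spec_from_json(text: str) -> GroundTruthSpec:
    obj = json.loads(text)
    variables = [
        VariableSpec(name=r["name"], concept=r["concept"], tier=r["tier"],
                     vtype=_vtype_from_obj(r["vtype"]), role=r["role"])
        for r in obj["variables"]
    ]
    # JSON stringifies discrete level values; restore declared level types
    params = cgbn.params_from_json(json.dumps(obj["parameters"]))
    vmap = by_name(variables)
    for node, loc in params.locals.items():
        if isinstance(loc, DiscreteLocal):
            loc.levels = tuple(vmap[node].vtype.levels)
    spec = GroundTruthSpec(
        variables=variables,
        true_dag=NetworkStructure([v.name for v in variables],
                                  [tuple(a) for a in obj["arcs"]]),
        parameters=params,
        study_designs=[StudyDesign(d["study_id"], d["n_participants"],
                                   set(d["measured"]))
                       for d in obj["study_designs"]],
        extra_missing_rate=obj["extra_missing_rate"],
        strong_arcs={tuple(a) for a in obj["strong_arcs"]},
    )
    spec.validate()
    return spec


def _standardised_strong_arcs(spec: GroundTruthSpec,
                              threshold: float = 0.2) -> Set[Tuple[str, str]]:
    """Arcs whose standardised effect (coefficient x parent sd / child sd,
    estimated on a large forward sample) is at least ``threshold``."""
    sample = cgbn.sample(spec.true_dag, spec.parameters, spec.variables, 4000, 12345)
    sds = {}
    for v in spec.variables:
        if not v.is_discrete:
            sds[v.name] = float(sample[v.name].std())
        else:
            codes = pd.Categorical(sample[v.name]).codes
            sds[v.name] = float(np.std(codes))
    strong = set()
    for node, loc in spec.parameters.locals.items():
        if not isinstance(loc, GaussianLocal):
            continue
        child_sd = max(sds[node], 1e-9)
        for jx, p in enumerate(loc.cparents):
            if abs(loc.coef[0, jx]) * sds[p] / child_sd >= threshold:
                strong.add((p, node))
        for p in loc.dparents:
            shift = loc.b0.reshape(loc.plevels)
            span = float(shift.max() - shift.min()) if shift.size > 1 else 0.0
            if span * sds[p] / child_sd >= threshold:
                strong.add((p, node))
    return strong
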
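"""Concept-scale construction, recoding, study integration, filtering.

Intervention studies measure each psycho-social determinant with a
small questionnaire battery; the analysed variable is the concept scale
(mean of the item scores, valid when at most 25% of the items are
missing).  Different studies measure different concepts at different
waves, so pooling them leaves design-driven blocks of missing values in
the integrated table; those blocks are explicit NaNs here and are dealt
with downstream by structural EM.

CSV conventions: missing cells are written as empty fields; empty
fields and the string ``NA`` are read back as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .variables import Continuous, Discrete, VariableSpec, by_name

#: Sidecar column carrying study provenance in integrated tables.
STUDY_COLUMN = "study_id"

_NA_STRINGS = ("", "NA")


# ---------------------------------------------------------------------------
# item-level operations


def compute_concept_scale(item_scores: Sequence, max_missing_frac: float = 0.25):
    """Mean of a concept's item scores, or missing.

    Returns the mean of the observed items when the fraction of missing
    items is at most ``max_missing_frac`` (inclusive: a 25% rule admits
    exactly one missing item out of four), otherwise ``nan``.
    """
    items = pd.Series(list(item_scores), dtype=float)
    if len(items) == 0:
        raise ValueError("empty item list")
    if not 0 <= max_missing_frac < 1:
        raise ValueError("max_missing_frac must be in [0, 1)")
    frac_missing = items.isna().mean()
    if frac_missing > max_missing_frac:
        return float("nan")
    return float(items.mean(skipna=True))


def recode_unipolar(item_scores: Sequence, source_scale: Tuple[float, float],
                    target_scale: Tuple[float, float]):
    """Affine rescaling of item scores between declared (min, max) ranges.

    Used to bring bipolar items (e.g. -2..2) onto the unipolar 1..5
    convention; missing values pass through untouched.
    """
    s_lo, s_hi = source_scale
    t_lo, t_hi = target_scale
    if s_lo == s_hi:
        raise ValueError("degenerate source scale")
    arr = pd.Series(list(item_scores), dtype=float)
    out = t_lo + (arr - s_lo) * (t_hi - t_lo) / (s_hi - s_lo)
    return out.tolist()


# ---------------------------------------------------------------------------
# datasets


@dataclass
class StudyDataset:
    """One study's participant table plus its measurement design."""

    study_id: str
    records: pd.DataFrame
    measured: Set[str]  # variable names (concept@tier or static names)

    def __post_init__(self) -> None:
        extra = [c for c in self.records.columns
                 if c not in self.measured and c != STUDY_COLUMN]
        bad = [c for c in extra if self.records[c].notna().any()]
        if bad:
            raise ValueError(
                f"study {self.study_id}: non-missing values in unmeasured columns {bad}")


@dataclass
class IntegratedDataset:
    """Pooled participant table over the union variable set."""

    variables: List[VariableSpec]
    records: pd.DataFrame  # includes STUDY_COLUMN

    @property
    def provenance(self) -> pd.Series:
        return self.records[STUDY_COLUMN]

    @property
    def data(self) -> pd.DataFrame:
        """Measurement columns only, in variable order."""
        return self.records[[v.name for v in self.variables]]


def integrate_studies(
    datasets: Sequence[StudyDataset],
    variables: Sequence[VariableSpec],
) -> IntegratedDataset:
    """Pool study tables over the union variable set.

    A cell is missing iff the study did not measure the variable or the
    source value was missing; observed cells are carried over
    unchanged.  Record counts add up and provenance is kept per record.
    """
    vmap = by_name(variables)
    ids = [d.study_id for d in datasets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate study_id")
    frames = []
    for ds in datasets:
        unknown = [c for c in ds.measured if c not in vmap]
        if unknown:
            raise ValueError(f"study {ds.study_id} measures undeclared variables {unknown}")
        block = pd.DataFrame(index=range(len(ds.records)))
        for v in variables:
            if v.name in ds.records.columns and v.name in ds.measured:
                block[v.name] = ds.records[v.name].to_numpy()
            else:
                block[v.name] = np.nan if not v.is_discrete else pd.Series(
                    [pd.NA] * len(ds.records), dtype=object)
        block[STUDY_COLUMN] = ds.study_id
        frames.append(block)
    records = pd.concat(frames, ignore_index=True)
    return IntegratedDataset(variables=list(variables), records=records)


def filter_subpopulation(
    data: IntegratedDataset,
    predicate: Union[Callable[[pd.DataFrame], pd.Series], str],
    value=None,
) -> IntegratedDataset:
    """Select records matching a demographic predicate; drop constants.

    ``predicate`` is either a callable on the record table returning a
    boolean mask, or a demographic column name combined with ``value``
    (``filter_subpopulation(d, "gender", "female")``).  Any variable
    that is constant over the selected records — in particular the
    stratifying demographic itself — is dropped from the variable list,
    since a constant carries no information for the network.
    """
    if callable(predicate):
        mask = predicate(data.records)
    else:
        vmap = by_name(data.variables)
        if predicate not in vmap or vmap[predicate].role != "demographic":
            raise ValueError(f"{predicate!r} is not a declared demographic")
        mask = data.records[predicate] == value
    sub = data.records[np.asarray(mask, dtype=bool)].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError("predicate selects zero records")
    kept_vars = []
    for v in data.variables:
        col = sub[v.name]
        observed = col.dropna()
        if len(observed) == 0:
            continue  # entirely missing in this stratum
        if observed.nunique() <= 1 and len(observed) == len(col):
            continue  # constant (e.g. the stratifying demographic itself)
        kept_vars.append(v)
    cols = [v.name for v in kept_vars] + [STUDY_COLUMN]
    return IntegratedDataset(variables=kept_vars, records=sub[cols])


# ---------------------------------------------------------------------------
# file formats


def write_table(frame: pd.DataFrame, path) -> None:
    """CSV with empty fields for missing values (deterministic layout)."""
    frame.to_csv(path, index=False, na_rep="")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=list(_NA_STRINGS), keep_default_na=False)


def _vtype_to_obj(vtype) -> dict:
    if isinstance(vtype, Discrete):
        return {"kind": "discrete", "levels": list(vtype.levels)}
    return {"kind": "continuous", "lo": vtype.lo, "hi": vtype.hi}


def _vtype_from_obj(obj) -> Union[Discrete, Continuous]:
    if obj["kind"] == "discrete":
        return Discrete(tuple(obj["levels"]))
    return Continuous(obj.get("lo"), obj.get("hi"))


def write_schema(variables: Sequence[VariableSpec], path,
                 availability: Optional[dict] = None) -> None:
    """YAML schema of variable declarations (+ optional per-study availability)."""
    obj = {
        "variables": [
            {"name": v.name, "concept": v.concept, "tier": v.tier,
             "role": v.role, "vtype": _vtype_to_obj(v.vtype)}
            for v in variables
        ]
    }
    if availability is not None:
        obj["availability"] = {str(k): sorted(vs) for k, vs in availability.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_schema(path) -> Tuple[List[VariableSpec], Optional[dict]]:
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    variables = [
        VariableSpec(name=rec["name"], concept=rec["concept"], tier=rec["tier"],
                     vtype=_vtype_from_obj(rec["vtype"]), role=rec["role"])
        for rec in obj["variables"]
    ]
    avail = obj.get("availability")
    if avail is not None:
        avail = {k: set(v) for k, v in avail.items()}
    return variables, avail
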
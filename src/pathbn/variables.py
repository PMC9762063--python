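"""Variable metadata for longitudinal intervention datasets.

Every column of an integrated intervention dataset is described by a
:class:`VariableSpec`: what concept it measures (a socio-cognitive
determinant, a physical-activity outcome, a demographic, or the
intervention indicator), at which measurement wave it was collected,
whether it is discrete or continuous, and which causal role it plays.
The role drives the structural constraints used during network learning:
demographics may only be explained by other demographics, baseline (T0)
measurements only by demographics and other baseline measurements, and
the randomised intervention indicator only by demographics and baseline
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

#: Measurement waves, in temporal order.  T0 is baseline; T1, T2, T3 are
#: the 3-, 6- and 12-month follow-ups (short- and long-term outcomes are
#: read at T2 and T3).
TIERS = ("T0", "T1", "T2", "T3")

#: Tier label for variables without a measurement wave (demographics and
#: the intervention indicator).
STATIC = "static"

ROLES = ("demographic", "baseline", "intervention", "determinant", "outcome")


@dataclass(frozen=True)
class Discrete:
    """A discrete (multinomial) measurement type with named levels."""

    levels: tuple

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError("discrete variables need at least 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("duplicate levels")


@dataclass(frozen=True)
class Continuous:
    """A continuous (Gaussian) measurement type with an optional range.

    ``lo``/``hi`` record the admissible scale range (e.g. a 1-5 concept
    scale, or 0..inf for minutes of activity per week); ``None`` means
    unbounded on that side.
    """

    lo: Optional[float] = None
    hi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lo is not None and self.hi is not None and not self.lo < self.hi:
            raise ValueError("empty range")


VarType = Union[Discrete, Continuous]


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one dataset column.

    Parameters
    ----------
    name:
        Column identifier, conventionally ``"<concept>@<tier>"`` for
        repeated measurements (``"intention@T2"``) and the bare concept
        name for static variables (``"age"``).
    concept:
        The measured concept, shared across waves (``"intention"``).
    tier:
        ``"T0"``..``"T3"`` or ``"static"``.
    vtype:
        :class:`Discrete` or :class:`Continuous`.
    role:
        One of ``demographic``, ``baseline``, ``intervention``,
        ``determinant``, ``outcome``.
    """

    name: str
    concept: str
    tier: str
    vtype: VarType
    role: str

    def __post_init__(self) -> None:
        if self.tier not in TIERS and self.tier != STATIC:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role in ("demographic", "intervention") and self.tier != STATIC:
            raise ValueError(f"{self.role} variables must have tier 'static'")
        if self.role == "baseline" and self.tier != "T0":
            raise ValueError("baseline role is reserved for T0 measurements")
        if self.role in ("determinant", "outcome") and self.tier not in TIERS[1:]:
            raise ValueError(f"{self.role} variables must sit at T1..T3")

    @property
    def is_discrete(self) -> bool:
        return isinstance(self.vtype, Discrete)

    @property
    def tier_index(self) -> Optional[int]:
        """0..3 for T0..T3, ``None`` for static variables."""
        return TIERS.index(self.tier) if self.tier in TIERS else None


def by_name(variables: Sequence[VariableSpec]) -> dict:
    """Index a variable list by name, rejecting duplicates."""
    out: dict = {}
    for v in variables:
        if v.name in out:
            raise ValueError(f"duplicate variable name {v.name!r}")
        out[v.name] = v
    return out


def measurement_spec(
    concept: str,
    tier: str,
    *,
    lo: float = 1.0,
    hi: float = 5.0,
    outcome: bool = False,
) -> VariableSpec:
    """Convenience constructor for a continuous repeated measurement.

    T0 measurements automatically receive the ``baseline`` role.
    """
    role = "baseline" if tier == "T0" else ("outcome" if outcome else "determinant")
    return VariableSpec(
        name=f"{concept}@{tier}",
        concept=concept,
        tier=tier,
        vtype=Continuous(lo, hi),
        role=role,
    )
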
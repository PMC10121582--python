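"""Two-high-threshold (2-HT) eyewitness identification model.

The model is a multinomial processing tree (MPT) over the six outcome
categories of a lineup identification task: suspect identification, filler
identification and lineup rejection, observed separately for culprit-present
(CP) and culprit-absent (CA) lineups.

Four latent-process probabilities govern the outcome per experimental
condition:

``dP``
    detection of the presence of the culprit (CP lineups only),
``dA``
    detection of the absence of the culprit (CA lineups only),
``b``
    biased selection of the suspect, i.e. the suspect stands out from the
    fillers and is picked without memory for the culprit,
``g``
    guessing-based selection of some lineup member.

When a guessing-based selection occurs, it lands on the suspect with a known
sampling probability ``c = 1 / lineup size`` (the suspect constant) and on a
filler with probability ``1 - c``.  The category probabilities are

.. math::

    P(\\text{suspect} \\mid CP) &= d_P + (1-d_P)\\,[b + (1-b)\\,g\\,c] \\\\
    P(\\text{filler} \\mid CP)  &= (1-d_P)(1-b)\\,g\\,(1-c) \\\\
    P(\\text{reject} \\mid CP)  &= (1-d_P)(1-b)(1-g) \\\\
    P(\\text{suspect} \\mid CA) &= (1-d_A)\\,[b + (1-b)\\,g\\,c] \\\\
    P(\\text{filler} \\mid CA)  &= (1-d_A)(1-b)\\,g\\,(1-c) \\\\
    P(\\text{reject} \\mid CA)  &= d_A + (1-d_A)(1-b)(1-g)

Several experimental conditions are modelled jointly (one tree pair per
condition, product-multinomial likelihood); equality and fixed-value
restrictions across conditions are expressed with :class:`RestrictionMap`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "PARAM_NAMES",
    "CATEGORY_LABELS",
    "LineupDesign",
    "Equal",
    "Fix",
    "RestrictionMap",
    "ModelSpec",
    "category_probabilities",
    "base_model_spec",
]

#: Canonical parameter order; also the order of blocks in the free vector.
PARAM_NAMES: tuple[str, ...] = ("dP", "g", "b", "dA")

#: Flat order of the six outcome categories used throughout the package.
CATEGORY_LABELS: tuple[str, ...] = (
    "cp_suspect",
    "cp_filler",
    "cp_rejection",
    "ca_suspect",
    "ca_filler",
    "ca_rejection",
)


@dataclass(frozen=True)
class LineupDesign:
    """Lineup size and the derived suspect constant.

    Parameters
    ----------
    lineup_size
        Number of persons shown in the lineup (suspect plus fillers), >= 2.
    mode
        ``"paper"`` rounds ``1 / lineup_size`` to five decimals (0.16667 for
        a six-person lineup, the multiTree reporting convention), ``"exact"``
        uses the exact fraction.
    """

    lineup_size: int = 6
    mode: str = "paper"

    def __post_init__(self) -> None:
        if int(self.lineup_size) != self.lineup_size or self.lineup_size < 2:
            raise ValueError(f"lineup_size must be an integer >= 2, got {self.lineup_size!r}")
        if self.mode not in ("paper", "exact"):
            raise ValueError(f"mode must be 'paper' or 'exact', got {self.mode!r}")

    @property
    def suspect_constant(self) -> float:
        """Probability that a guessing-based selection lands on the suspect."""
        if self.mode == "paper":
            return round(1.0 / self.lineup_size, 5)
        return 1.0 / self.lineup_size


@dataclass(frozen=True)
class Equal:
    """Equate one parameter across a group of conditions (one free value)."""

    param: str
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        _check_param(self.param)
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if len(self.conditions) < 2:
            raise ValueError("Equal needs at least two conditions")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("Equal conditions must be distinct")

    def describe(self) -> str:
        return f"equal: {self.param} across [{', '.join(self.conditions)}]"


@dataclass(frozen=True)
class Fix:
    """Pin one parameter in one condition to a constant in [0, 1]."""

    param: str
    condition: str
    value: float

    def __post_init__(self) -> None:
        _check_param(self.param)
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"fixed value must be in [0, 1], got {self.value}")

    def describe(self) -> str:
        return f"fix: {self.param}@{self.condition} = {self.value:g}"


def _check_param(name: str) -> None:
    if name not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {name!r}; expected one of {PARAM_NAMES}")


@dataclass(frozen=True)
class RestrictionMap:
    """A set of equality / fixed-value constraints on condition parameters.

    Each parameter instance (parameter, condition) may appear in at most one
    constraint.  The map determines how the per-condition parameter matrix is
    packed into (and expanded from) the free-parameter vector.
    """

    constraints: tuple[Equal | Fix, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "constraints", tuple(self.constraints))
        seen: set[tuple[str, str]] = set()
        for con in self.constraints:
            if isinstance(con, Equal):
                instances = [(con.param, c) for c in con.conditions]
            elif isinstance(con, Fix):
                instances = [(con.param, con.condition)]
            else:  # pragma: no cover - defensive
                raise TypeError(f"unsupported constraint {con!r}")
            for inst in instances:
                if inst in seen:
                    raise ValueError(
                        f"parameter instance {inst[0]}@{inst[1]} appears in more than one constraint"
                    )
                seen.add(inst)

    def describe(self) -> list[str]:
        return [con.describe() for con in self.constraints]


@dataclass(frozen=True)
class ModelSpec:
    """The 2-HT model for a set of conditions plus its restrictions.

    The free-parameter vector is ordered by parameter blocks ``dP, g, b, dA``
    and, within a block, by condition order; an equality group occupies one
    slot at the position of its first condition, and fixed parameters occupy
    no slot.  This ordering is part of the serialization contract.
    """

    design: LineupDesign
    condition_names: tuple[str, ...]
    restrictions: RestrictionMap = field(default_factory=RestrictionMap)

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition_names", tuple(self.condition_names))
        if not self.condition_names:
            raise ValueError("at least one condition is required")
        if len(set(self.condition_names)) != len(self.condition_names):
            raise ValueError("condition names must be unique")
        if any(not c for c in self.condition_names):
            raise ValueError("condition names must be non-empty")
        for con in self.restrictions.constraints:
            conds = con.conditions if isinstance(con, Equal) else (con.condition,)
            for c in conds:
                if c not in self.condition_names:
                    raise ValueError(f"constraint references unknown condition {c!r}")
        if self.df < 0:
            raise ValueError(
                f"model not identifiable from the data: df = {self.df} < 0"
            )

    # -- free-vector bookkeeping ------------------------------------------

    def _slots(self) -> tuple[list[tuple[str, tuple[str, ...]]], dict[tuple[str, str], object]]:
        """Free slots in canonical order plus the (param, cond) -> slot/Fix map."""
        assignment: dict[tuple[str, str], object] = {}
        for con in self.restrictions.constraints:
            if isinstance(con, Fix):
                assignment[(con.param, con.condition)] = con
            else:
                for c in con.conditions:
                    assignment[(con.param, c)] = con
        slots: list[tuple[str, tuple[str, ...]]] = []
        placed: set[int] = set()
        for param in PARAM_NAMES:
            for cond in self.condition_names:
                con = assignment.get((param, cond))
                if con is None:
                    slots.append((param, (cond,)))
                elif isinstance(con, Fix):
                    continue
                elif id(con) not in placed:
                    placed.add(id(con))
                    slots.append((param, tuple(con.conditions)))
        return slots, assignment

    @property
    def free_parameter_names(self) -> tuple[str, ...]:
        """Labels of the free vector, e.g. ``dP[FYC]`` or ``b[FYC,noFYC]``."""
        slots, _ = self._slots()
        return tuple(f"{p}[{','.join(conds)}]" for p, conds in slots)

    @property
    def n_free(self) -> int:
        return len(self._slots()[0])

    @property
    def n_conditions(self) -> int:
        return len(self.condition_names)

    @property
    def df(self) -> int:
        """Goodness-of-fit degrees of freedom.

        Each condition contributes two multinomial trees with three categories
        each, i.e. ``2 * (3 - 1)`` independent proportions.
        """
        return 4 * self.n_conditions - self.n_free

    # -- expand / pack -----------------------------------------------------

    def expand(self, free_vector: Sequence[float]) -> np.ndarray:
        """Expand the free vector to the full (n_conditions, 4) parameter matrix.

        Columns follow :data:`PARAM_NAMES`.  Equality-constrained parameters
        are replicated across their group; fixed parameters take their pinned
        value regardless of the free vector.
        """
        free = np.asarray(free_vector, dtype=float)
        slots, assignment = self._slots()
        if free.shape != (len(slots),):
            raise ValueError(
                f"free vector has length {free.size}, expected {len(slots)}"
            )
        theta = np.empty((self.n_conditions, len(PARAM_NAMES)), dtype=float)
        cond_idx = {c: i for i, c in enumerate(self.condition_names)}
        for value, (param, conds) in zip(free, slots):
            j = PARAM_NAMES.index(param)
            for c in conds:
                theta[cond_idx[c], j] = value
        for (param, cond), con in assignment.items():
            if isinstance(con, Fix):
                theta[cond_idx[cond], PARAM_NAMES.index(param)] = con.value
        return theta

    def pack(self, theta: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`expand` (reads the first member of each group)."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_conditions, len(PARAM_NAMES)):
            raise ValueError(
                f"parameter matrix has shape {theta.shape}, expected "
                f"{(self.n_conditions, len(PARAM_NAMES))}"
            )
        slots, _ = self._slots()
        cond_idx = {c: i for i, c in enumerate(self.condition_names)}
        return np.array(
            [theta[cond_idx[conds[0]], PARAM_NAMES.index(p)] for p, conds in slots]
        )

    def parameter_table(self, free_vector: Sequence[float]) -> dict[str, dict[str, float]]:
        """Expanded parameters as ``{condition: {param: value}}``."""
        theta = self.expand(free_vector)
        return {
            cond: {p: float(theta[i, j]) for j, p in enumerate(PARAM_NAMES)}
            for i, cond in enumerate(self.condition_names)
        }

    def with_restrictions(self, extra: Iterable[Equal | Fix]) -> "ModelSpec":
        """A new spec with additional constraints appended."""
        return ModelSpec(
            design=self.design,
            condition_names=self.condition_names,
            restrictions=RestrictionMap(self.restrictions.constraints + tuple(extra)),
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "lineup_size": self.design.lineup_size,
            "mode": self.design.mode,
            "conditions": list(self.condition_names),
            "restrictions": self.restrictions.describe(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        design = LineupDesign(
            lineup_size=int(d.get("lineup_size", 6)), mode=d.get("mode", "paper")
        )
        constraints = [parse_restriction(s) for s in d.get("restrictions", [])]
        return cls(
            design=design,
            condition_names=tuple(d["conditions"]),
            restrictions=RestrictionMap(tuple(constraints)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "ModelSpec":
        """Load a spec from a YAML or JSON config file."""
        text = open(path).read()
        d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(d)


_EQUAL_RE = re.compile(r"^\s*equal:\s*(\w+)\s+across\s*\[([^\]]+)\]\s*$")
_FIX_RE = re.compile(r"^\s*fix:\s*(\w+)\s*@\s*([^=\s]+)\s*=\s*([0-9.eE+-]+)\s*$")


def parse_restriction(text: str) -> Equal | Fix:
    """Parse ``"equal: b across [FYC, noFYC]"`` or ``"fix: b@FYC = 0"``."""
    m = _EQUAL_RE.match(text)
    if m:
        conds = tuple(c.strip() for c in m.group(2).split(","))
        return Equal(m.group(1), conds)
    m = _FIX_RE.match(text)
    if m:
        return Fix(m.group(1), m.group(2), float(m.group(3)))
    raise ValueError(f"cannot parse restriction {text!r}")


def category_probabilities(
    params: Sequence[float] | Mapping[str, float] | np.ndarray,
    design: LineupDesign | float = LineupDesign(),
) -> np.ndarray:
    """Outcome-category probabilities of the 2-HT trees.

    Parameters
    ----------
    params
    Either a mapping with keys ``dP, g, b, dA``, or an array whose last
        axis holds ``(dP, g, b, dA)`` in that order; leading axes (e.g.
        conditions) are broadcast.
    design
        A :class:`LineupDesign`, or the suspect constant ``c`` directly.

    Returns
    -------
    numpy.ndarray
        Probabilities in the order of :data:`CATEGORY_LABELS` — three
        culprit-present categories then three culprit-absent categories —
        appended as the last axis.  Each tree's three probabilities sum to 1.
    """
    c = design.suspect_constant if isinstance(design, LineupDesign) else float(design)
    if not 0.0 < c < 1.0:
        raise ValueError(f"suspect constant must be in (0, 1), got {c}")
    if isinstance(params, Mapping):
        arr = np.array([params[p] for p in PARAM_NAMES], dtype=float)
    else:
        arr = np.asarray(params, dtype=float)
    if arr.shape[-1] != 4:
        raise ValueError("params must supply (dP, g, b, dA) on the last axis")
    for j, name in enumerate(PARAM_NAMES):
        block = arr[..., j]
        if np.any((block < 0.0) | (block > 1.0)):
            raise ValueError(f"parameter {name} outside [0, 1]")
    dP, g, b, dA = (arr[..., j] for j in range(4))
    pick_suspect = b + (1.0 - b) * g * c          # suspect chosen without detection
    pick_filler = (1.0 - b) * g * (1.0 - c)
    no_pick = (1.0 - b) * (1.0 - g)
    out = np.empty(arr.shape[:-1] + (6,), dtype=float)
    out[..., 0] = dP + (1.0 - dP) * pick_suspect
    out[..., 1] = (1.0 - dP) * pick_filler
    out[..., 2] = (1.0 - dP) * no_pick
    out[..., 3] = (1.0 - dA) * pick_suspect
    out[..., 4] = (1.0 - dA) * pick_filler
    out[..., 5] = dA + (1.0 - dA) * no_pick
    return out


def base_model_spec(
    condition_names: Sequence[str] = ("FYC", "noFYC"),
    lineup_size: int = 6,
    mode: str = "paper",
) -> ModelSpec:
    """The base model: ``b`` and ``dA`` each equated across all conditions.

    With two conditions this leaves six free parameters (``dP`` and ``g`` per
    condition plus shared ``b`` and ``dA``) and a goodness-of-fit test with
    two degrees of freedom.
    """
    conds = tuple(condition_names)
    restrictions: tuple[Equal | Fix, ...] = ()
    if len(conds) > 1:
        restrictions = (Equal("b", conds), Equal("dA", conds))
    return ModelSpec(
        design=LineupDesign(lineup_size=lineup_size, mode=mode),
        condition_names=conds,
        restrictions=RestrictionMap(restrictions),
    )
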
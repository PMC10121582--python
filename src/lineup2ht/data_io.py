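"""Reading, writing and describing lineup response-frequency tables.

The on-disk CSV dialect has columns ``condition, lineup_type, outcome, count``
with ``lineup_type`` in ``{culprit_present, culprit_absent}`` and ``outcome``
in ``{suspect, filler, rejection}``; lines starting with ``#`` are comments.
A JSON mirror nests the same cells as
``{"conditions": {name: {lineup_type: {outcome: count}}}}``.

Two fixture tables ship with the package: the reanalysed sequential-lineup
frequencies of Horry et al. (``horry_reanalysis``) and the conceptual
replication (``replication``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LINEUP_TYPES",
    "OUTCOMES",
    "ResponseTable",
    "load_response_table",
    "save_response_table",
    "descriptive_rates",
    "load_fixture",
    "fixture_path",
]

LINEUP_TYPES: tuple[str, ...] = ("culprit_present", "culprit_absent")
OUTCOMES: tuple[str, ...] = ("suspect", "filler", "rejection")


@dataclass(frozen=True)
class ResponseTable:
    """Observed identification decisions for one experiment.

    ``counts`` has shape ``(n_conditions, 2, 3)``: axis 1 is lineup type
    (culprit-present, culprit-absent) and axis 2 is outcome (suspect ID,
    filler ID, rejection).
    """

    condition_names: tuple[str, ...]
    counts: np.ndarray
    label: str = ""
    lineup_size: int = 6

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition_names", tuple(self.condition_names))
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.condition_names), 2, 3):
            raise ValueError(
                f"counts must have shape (n_conditions, 2, 3), got {counts.shape}"
            )
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be non-negative integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(counts.sum(axis=2) == 0):
            raise ValueError("each condition needs at least one decision per lineup type")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        self.counts.setflags(write=False)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_names)

    @property
    def flat_counts(self) -> np.ndarray:
        """Counts as ``(n_conditions, 6)`` in :data:`CATEGORY_LABELS` order."""
        return self.counts.reshape(self.n_conditions, 6)

    @property
    def tree_totals(self) -> np.ndarray:
        """Decisions per condition and lineup type, shape ``(n_conditions, 2)``."""
        return self.counts.sum(axis=2)

    @property
    def n_total(self) -> int:
        """Total number of identification decisions."""
        return int(self.counts.sum())

    def reordered(self, condition_names) -> "ResponseTable":
        """The same table with conditions in the given order."""
        idx = [self.condition_names.index(c) for c in condition_names]
        return ResponseTable(
            tuple(condition_names), self.counts[idx], self.label, self.lineup_size
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (cond, lt, oc, int(self.counts[i, j, k]))
            for i, cond in enumerate(self.condition_names)
            for j, lt in enumerate(LINEUP_TYPES)
            for k, oc in enumerate(OUTCOMES)
        ]
        return pd.DataFrame(rows, columns=["condition", "lineup_type", "outcome", "count"])

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "lineup_size": self.lineup_size,
            "conditions": {
                cond: {
                    lt: {oc: int(self.counts[i, j, k]) for k, oc in enumerate(OUTCOMES)}
                    for j, lt in enumerate(LINEUP_TYPES)
                }
                for i, cond in enumerate(self.condition_names)
            },
        }


def _table_from_frame(df: pd.DataFrame, label: str, lineup_size: int) -> ResponseTable:
    required = {"condition", "lineup_type", "outcome", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    conditions: list[str] = []
    for cond in df["condition"].astype(str):
        if cond not in conditions:
            conditions.append(cond)
    counts = np.full((len(conditions), 2, 3), -1, dtype=np.int64)
    cells = zip(
        df.index, df["condition"].astype(str), df["lineup_type"], df["outcome"], df["count"]
    )
    for idx, cond, lineup_type, outcome, n in cells:
        if lineup_type not in LINEUP_TYPES:
            raise ValueError(f"row {idx}: unknown lineup_type {lineup_type!r}")
        if outcome not in OUTCOMES:
            raise ValueError(f"row {idx}: unknown outcome {outcome!r}")
        if float(n) != int(n) or int(n) < 0:
            raise ValueError(f"row {idx}: count must be a non-negative integer, got {n!r}")
        i = conditions.index(cond)
        j = LINEUP_TYPES.index(lineup_type)
        k = OUTCOMES.index(outcome)
        if counts[i, j, k] != -1:
            raise ValueError(f"row {idx}: duplicate cell {cond}/{lineup_type}/{outcome}")
        counts[i, j, k] = int(n)
    if np.any(counts < 0):
        i, j, k = np.argwhere(counts < 0)[0]
        raise ValueError(
            f"missing cell {conditions[i]}/{LINEUP_TYPES[j]}/{OUTCOMES[k]}"
        )
    return ResponseTable(tuple(conditions), counts, label=label, lineup_size=lineup_size)


def load_response_table(
    path, format: str | None = None, label: str | None = None, lineup_size: int = 6
) -> ResponseTable:
    """Load a :class:`ResponseTable` from a CSV or JSON file.

    ``format`` defaults to the file extension.  Malformed files (unknown
    labels, negative, fractional or duplicated counts, missing cells) raise
    ``ValueError`` naming the offending row or cell.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if label is None:
        label = path.stem
    if fmt == "csv":
        try:
            df = pd.read_csv(path, comment="#")
        except pd.errors.EmptyDataError as exc:
            raise ValueError(f"{path}: no data rows") from exc
        return _table_from_frame(df, label, lineup_size)
    if fmt == "json":
        d = json.loads(path.read_text())
        conds = list(d["conditions"])
        counts = np.array(
            [
                [[d["conditions"][c][lt][oc] for oc in OUTCOMES] for lt in LINEUP_TYPES]
                for c in conds
            ]
        )
        return ResponseTable(
            tuple(conds),
            counts,
            label=d.get("label", label),
            lineup_size=int(d.get("lineup_size", lineup_size)),
        )
    raise ValueError(f"unknown format {fmt!r}")


def save_response_table(table: ResponseTable, path, format: str | None = None) -> None:
    """Write a table in the CSV dialect or the JSON mirror."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        table.to_frame().to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(table.to_dict(), indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def descriptive_rates(table: ResponseTable) -> pd.DataFrame:
    """Model-free response rates per condition.

    Returns one row per condition with the culprit-present suspect-ID rate,
    the culprit-absent (innocent-suspect) ID rate, filler-ID rates per lineup
    type, and the lineup rejection rate pooled over both lineup types —
    the two-component summary (suspect IDs down, rejections up) that a
    stricter response criterion produces.
    """
    totals = table.tree_totals
    if np.any(totals == 0):
        raise ValueError("descriptive rates undefined for a lineup type with zero decisions")
    c = table.counts.astype(float)
    rows = {
        "suspect_id_rate_cp": c[:, 0, 0] / totals[:, 0],
        "suspect_id_rate_ca": c[:, 1, 0] / totals[:, 1],
        "filler_id_rate_cp": c[:, 0, 1] / totals[:, 0],
        "filler_id_rate_ca": c[:, 1, 1] / totals[:, 1],
        "rejection_rate_pooled": (c[:, 0, 2] + c[:, 1, 2]) / totals.sum(axis=1),
        "n_decisions": totals.sum(axis=1).astype(int),
    }
    return pd.DataFrame(rows, index=pd.Index(table.condition_names, name="condition"))


_FIXTURES = {
    "horry_reanalysis": "horry_reanalysis.csv",
    "replication": "replication.csv",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture (``horry_reanalysis`` or ``replication``)."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    return Path(str(resources.files("lineup2ht.data") / _FIXTURES[name]))


def load_fixture(name: str) -> ResponseTable:
    """Load one of the packaged response-frequency tables."""
    return load_response_table(fixture_path(name), label=name)
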
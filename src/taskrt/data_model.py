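"""Domain types, validation and file I/O for task datasets.

A *task dataset* bundles the observables of one administration of a
simulation-based assessment task: a person-by-item matrix of dichotomous
item scores, a person-by-item matrix of item response times (RTs, in
seconds), per-item metadata (item type, response format, chance-level
proportion correct under uniform random guessing), and an optional table
of person covariates.  All analysis stages consume a validated
:class:`TaskDataset`.

Conventions
-----------
* Matrices are addressed positionally (0-based) in code; item and person
  identifiers are preserved as labels and all reports are 1-based.
* Wide CSV layout: one row per person, a ``person_id`` column, and
  ``item_1 .. item_I`` columns for responses and RTs.
* Quantiles everywhere use linear interpolation between order statistics
  (the "type 7" convention).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "DimensionError",
    "ItemMeta",
    "TaskDataset",
    "TaskSummary",
    "load_dataset",
    "save_dataset",
    "summarize",
    "save_results",
    "load_results",
]


class ValidationError(ValueError):
    """A cell or field violates a dataset invariant."""


class DimensionError(ValueError):
    """Input tables disagree in shape or keying."""


MC = "MC"
CR = "CR"
RESPONSE_FORMATS = (
    "single-selection",
    "multiple-selection",
    "order",
    "simulation",
    "explanation",
)


@dataclass(frozen=True)
class ItemMeta:
    """Metadata for one item.

    Parameters
    ----------
    item_id
        1-based item index.
    item_type
        ``"MC"`` (selected response) or ``"CR"`` (constructed response).
    response_format
        One of ``single-selection``, ``multiple-selection``, ``order``,
        ``simulation``, ``explanation``.
    chance_pc
        Chance-level proportion correct: the probability of a correct
        response under uniform random guessing.  ``0`` for CR items; an
        ordering item over ``k`` options has ``1/k!``.
    """

    item_id: int
    item_type: str
    response_format: str
    chance_pc: float

    def __post_init__(self) -> None:
        if self.item_id < 1:
            raise ValidationError(f"item_id must be 1-based, got {self.item_id}")
        if self.item_type not in (MC, CR):
            raise ValidationError(
                f"item {self.item_id}: item_type must be 'MC' or 'CR', got {self.item_type!r}"
            )
        if self.response_format not in RESPONSE_FORMATS:
            raise ValidationError(
                f"item {self.item_id}: unknown response_format {self.response_format!r}"
            )
        if not 0.0 <= self.chance_pc <= 1.0:
            raise ValidationError(
                f"item {self.item_id}: chance_pc must lie in [0, 1], got {self.chance_pc}"
            )
        if self.item_type == CR and self.chance_pc != 0.0:
            raise ValidationError(
                f"item {self.item_id}: CR items have chance_pc = 0, got {self.chance_pc}"
            )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ItemMeta":
        return cls(
            item_id=int(d["item_id"]),
            item_type=str(d["item_type"]),
            response_format=str(d["response_format"]),
            chance_pc=float(d["chance_pc"]),
        )


@dataclass
class TaskDataset:
    """Validated observables for one task administration.

    Attributes
    ----------
    Y
        ``(J, I)`` integer matrix of item scores, each 0 or 1.
    T
        ``(J, I)`` float matrix of item RTs in seconds, all strictly
        positive.  The task has no missing cells (no time limit, forced
        item order), so NaNs are rejected.
    items
        ``I`` :class:`ItemMeta` records.
    covariates
        Optional person table indexed like the rows of ``Y``; nominal
        columns are pandas ``Categorical``, the rest numeric.
    person_ids
        Person labels, preserved from input files.
    """

    Y: np.ndarray
    T: np.ndarray
    items: list[ItemMeta]
    covariates: pd.DataFrame | None = None
    person_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        self.T = np.asarray(self.T, dtype=float)
        if self.Y.ndim != 2 or self.T.ndim != 2:
            raise DimensionError("Y and T must be 2-D person-by-item matrices")
        if self.Y.shape != self.T.shape:
            raise DimensionError(
                f"response matrix is {self.Y.shape} but RT matrix is {self.T.shape}"
            )
        if len(self.items) != self.Y.shape[1]:
            raise DimensionError(
                f"{len(self.items)} item records for {self.Y.shape[1]} item columns"
            )
        bad = np.argwhere(~np.isin(self.Y, (0, 1)))
        if bad.size:
            j, i = bad[0]
            raise ValidationError(
                f"non-binary response {self.Y[j, i]!r} at person row {j}, item {i + 1}"
            )
        self.Y = self.Y.astype(np.int8)
        bad = np.argwhere(~(self.T > 0) | ~np.isfinite(self.T))
        if bad.size:
            j, i = bad[0]
            raise ValidationError(
                f"non-positive RT {self.T[j, i]!r} at person row {j}, item {i + 1}"
            )
        if not self.person_ids:
            self.person_ids = [str(j + 1) for j in range(self.Y.shape[0])]
        if len(self.person_ids) != self.Y.shape[0]:
            raise DimensionError(
                f"{len(self.person_ids)} person ids for {self.Y.shape[0]} rows"
            )
        if self.covariates is not None:
            if len(self.covariates) != self.Y.shape[0]:
                raise DimensionError(
                    f"covariate table has {len(self.covariates)} rows, "
                    f"responses have {self.Y.shape[0]}"
                )
            self.covariates = self.covariates.reset_index(drop=True)

    @property
    def J(self) -> int:
        return self.Y.shape[0]

    @property
    def I(self) -> int:
        return self.Y.shape[1]

    @property
    def task_time(self) -> np.ndarray:
        """Per-person task time: row sum of the item RTs (seconds)."""
        return self.T.sum(axis=1)

    @property
    def task_score(self) -> np.ndarray:
        """Per-person task score: row sum of the item scores."""
        return self.Y.sum(axis=1).astype(int)

    @property
    def chance_pc(self) -> np.ndarray:
        return np.array([m.chance_pc for m in self.items])


FIVE_NUM_LABELS = ("min", "q1", "median", "q3", "max")


def five_number(x: np.ndarray) -> dict[str, float]:
    """Min, quartiles (type-7 linear interpolation) and max of a vector."""
    x = np.asarray(x, dtype=float)
    qs = np.quantile(x, [0.0, 0.25, 0.5, 0.75, 1.0])
    return dict(zip(FIVE_NUM_LABELS, map(float, qs)))


@dataclass
class TaskSummary:
    """Descriptive summary of a task dataset.

    ``task_time``/``task_score`` are per-person sums; ``item_rt`` holds a
    five-number RT summary per item; ``item_prop_correct`` is the column
    mean of the score matrix.
    """

    task_time: np.ndarray
    task_score: np.ndarray
    task_time_fivenum: dict[str, float]
    task_score_fivenum: dict[str, float]
    item_rt: pd.DataFrame
    item_prop_correct: np.ndarray

    def to_dict(self) -> dict[str, Any]:
        return {
            "task_time": self.task_time.tolist(),
            "task_score": self.task_score.tolist(),
            "task_time_fivenum": self.task_time_fivenum,
            "task_score_fivenum": self.task_score_fivenum,
            "item_rt": self.item_rt.to_dict(orient="list"),
            "item_prop_correct": self.item_prop_correct.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TaskSummary":
        return cls(
            task_time=np.asarray(d["task_time"], dtype=float),
            task_score=np.asarray(d["task_score"], dtype=int),
            task_time_fivenum=dict(d["task_time_fivenum"]),
            task_score_fivenum=dict(d["task_score_fivenum"]),
            item_rt=pd.DataFrame(d["item_rt"])[["item", *FIVE_NUM_LABELS]],
            item_prop_correct=np.asarray(d["item_prop_correct"], dtype=float),
        )


def summarize(dataset: TaskDataset) -> TaskSummary:
    """Per-person task time/score and per-item timing/accuracy summaries."""
    rows = []
    for i in range(dataset.I):
        rows.append({"item": i + 1, **five_number(dataset.T[:, i])})
    return TaskSummary(
        task_time=dataset.task_time,
        task_score=dataset.task_score,
        task_time_fivenum=five_number(dataset.task_time),
        task_score_fivenum=five_number(dataset.task_score.astype(float)),
        item_rt=pd.DataFrame(rows),
        item_prop_correct=dataset.Y.mean(axis=0),
    )


# ---------------------------------------------------------------------------
# CSV I/O


def _item_columns(df: pd.DataFrame, path: str | Path) -> list[str]:
    cols = [c for c in df.columns if c.startswith("item_")]
    if not cols:
        raise DimensionError(f"{path}: no 'item_*' columns found")
    try:
        cols.sort(key=lambda c: int(c.split("_", 1)[1]))
    except ValueError as exc:
        raise DimensionError(f"{path}: malformed item column name: {exc}") from exc
    return cols


def _read_wide(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    if "person_id" not in df.columns:
        raise DimensionError(f"{path}: missing 'person_id' column")
    cols = _item_columns(df, path)
    return df["person_id"].astype(str).tolist(), df[cols].to_numpy()


def load_items(path: str | Path) -> list[ItemMeta]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"item_id", "item_type", "response_format", "chance_pc"}
    missing = required - set(df.columns)
    if missing:
        raise DimensionError(f"{path}: missing item-metadata columns {sorted(missing)}")
    items = []
    for _, row in df.iterrows():
        fmt = row["response_format"]
        items.append(
            ItemMeta(
                item_id=int(row["item_id"]),
                item_type=str(row["item_type"]),
                response_format="" if pd.isna(fmt) else str(fmt),
                chance_pc=float(row["chance_pc"]),
            )
        )
    return items


def apply_covariate_schema(
    df: pd.DataFrame, schema: dict[str, Any] | None
) -> pd.DataFrame:
    """Type covariate columns per a declared schema.

    ``schema`` maps column name to either ``"numeric"`` or a list of
    category labels (nominal, reference level first).  Categories are
    closed: an observed value outside the declared list is an error, not
    a new level.  Without a schema, object columns become nominal with
    observed categories in sorted order.
    """
    out = df.copy()
    if schema is None:
        for col in out.columns:
            if out[col].dtype == object:
                out[col] = pd.Categorical(
                    out[col], categories=sorted(out[col].dropna().unique())
                )
        return out
    for col, kind in schema.items():
        if col not in out.columns:
            raise DimensionError(f"covariate schema names missing column {col!r}")
        if kind == "numeric":
            out[col] = pd.to_numeric(out[col])
        else:
            cats = list(kind)
            values = out[col].astype(str)
            unknown = set(values.unique()) - set(cats)
            if unknown:
                raise ValidationError(
                    f"covariate {col!r}: unknown categories {sorted(unknown)}"
                )
            out[col] = pd.Categorical(values, categories=cats)
    return out


def load_dataset(
    responses_path: str | Path,
    rts_path: str | Path,
    items_path: str | Path,
    covariates_path: str | Path | None = None,
    covariate_schema: dict[str, Any] | None = None,
) -> TaskDataset:
    """Read and validate a task dataset from wide CSV files.

    All person-level files must agree on the ``person_id`` column; the
    response and RT files must have identical item columns.
    """
    ids_y, Y = _read_wide(responses_path)
    ids_t, T = _read_wide(rts_path)
    if len(ids_y) != len(ids_t):
        raise DimensionError(
            f"{responses_path} has {len(ids_y)} persons but {rts_path} has {len(ids_t)}"
        )
    if ids_y != ids_t:
        raise DimensionError(f"person ids differ between {responses_path} and {rts_path}")
    items = load_items(items_path)
    covariates = None
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path)
        if "person_id" not in cov.columns:
            raise DimensionError(f"{covariates_path}: missing 'person_id' column")
        if cov["person_id"].astype(str).tolist() != ids_y:
            raise DimensionError(
                f"person ids in {covariates_path} do not match {responses_path}"
            )
        covariates = apply_covariate_schema(
            cov.drop(columns=["person_id"]), covariate_schema
        )
    return TaskDataset(Y=Y, T=T, items=items, covariates=covariates, person_ids=ids_y)


def save_dataset(dataset: TaskDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset back to the wide-CSV layout ``load_dataset`` reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = [f"item_{i + 1}" for i in range(dataset.I)]
    paths = {}
    for name, M in (("responses", dataset.Y), ("rts", dataset.T)):
        df = pd.DataFrame(M, columns=cols)
        df.insert(0, "person_id", dataset.person_ids)
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    items_df = pd.DataFrame([m.to_dict() for m in dataset.items])
    p = out / "items.csv"
    items_df.to_csv(p, index=False)
    paths["items"] = p
    if dataset.covariates is not None:
        cov = dataset.covariates.copy()
        cov.insert(0, "person_id", dataset.person_ids)
        p = out / "covariates.csv"
        cov.to_csv(p, index=False)
        paths["covariates"] = p
    return paths


# ---------------------------------------------------------------------------
# Result artifact serialization
#
# Every stage result is a dataclass with to_dict/from_dict; save_results
# wraps the payload with the class name plus the configuration/seed the
# caller passes, so artifacts are self-describing and round-trippable.

_RESULT_REGISTRY: dict[str, type] = {}


def register_result(cls: type) -> type:
    """Class decorator: make a result type round-trippable via JSON."""
    _RESULT_REGISTRY[cls.__name__] = cls
    return cls


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_results(
    result: Any,
    path: str | Path,
    config: dict[str, Any] | None = None,
    seed: int | None = None,
) -> Path:
    """Serialize a stage result to JSON, stamped with config and seed."""
    path = Path(path)
    if hasattr(result, "to_dict"):
        payload = result.to_dict()
        kind = type(result).__name__
    elif dataclasses.is_dataclass(result):
        payload = dataclasses.asdict(result)
        kind = type(result).__name__
    else:
        payload = result
        kind = type(result).__name__
    doc = {
        "kind": kind,
        "config": _jsonable(config) if config else None,
        "seed": seed,
        "payload": _jsonable(payload),
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return path


def load_results(path: str | Path) -> Any:
    """Reload a result saved by :func:`save_results`.

    Returns the original dataclass when its type is registered, else the
    raw payload dict.
    """
    doc = json.loads(Path(path).read_text())
    cls = _RESULT_REGISTRY.get(doc["kind"])
    if cls is not None and hasattr(cls, "from_dict"):
        return cls.from_dict(doc["payload"])
    return doc["payload"]


register_result(TaskSummary)
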
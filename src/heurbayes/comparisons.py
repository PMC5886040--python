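"""Data model for binary-comparison decision tasks.

Objects (rows of a table with a numeric criterion and a set of cues) are
turned into paired comparisons: for each pair of objects, each cue is coded
+1 if it favors the first ("left") object, -1 if it favors the second, and
0 if the two objects are equal on that cue; the outcome y is +1 if the left
object has the larger criterion value and -1 otherwise.  All models in this
package operate on these signed comparison matrices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "FormatError",
    "InputError",
    "ObjectTable",
    "PairedComparisons",
    "ValidationReport",
    "make_pairs",
    "read_objects",
    "read_pairs",
    "validate_pairs",
    "write_objects",
    "write_pairs",
]


class ConfigError(ValueError):
    """A configuration value (column name, spec field, ...) is invalid."""


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class InputError(ValueError):
    """Input data violate a precondition of an operation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ObjectTable:
    """A table of objects with one numeric criterion and m cue columns.

    ``true_weights`` and ``directions`` are filled in by the synthetic
    environment generator (the realized generating weights and their signs);
    they are ``None`` for tables read from files.
    """

    object_ids: list[str]
    criterion: np.ndarray          # shape (n_objects,)
    cues: np.ndarray               # shape (n_objects, m)
    cue_names: list[str]
    true_weights: np.ndarray | None = None
    directions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.criterion = np.asarray(self.criterion, dtype=float)
        self.cues = np.atleast_2d(np.asarray(self.cues, dtype=float))
        if len(self.object_ids) < 2:
            raise InputError("need at least 2 objects")
        if self.cues.shape[1] < 1:
            raise InputError("need at least 1 cue")
        if self.cues.shape[0] != len(self.object_ids):
            raise InputError("cue matrix rows must match number of objects")
        if self.criterion.shape != (len(self.object_ids),):
            raise InputError("criterion must be one numeric value per object")
        if not np.all(np.isfinite(self.criterion)):
            raise InputError("criterion contains non-finite values")
        if not np.all(np.isfinite(self.cues)):
            raise InputError("cue matrix contains non-finite values")

    @property
    def n_objects(self) -> int:
        return len(self.object_ids)

    @property
    def m(self) -> int:
        return self.cues.shape[1]


@dataclass
class PairedComparisons:
    """n binary comparisons on m cues: X in {-1,0,+1}^(n x m), y in {-1,+1}^n."""

    X: np.ndarray
    y: np.ndarray
    cue_names: list[str]
    directions: np.ndarray | None = None   # known a-priori cue signs, if any
    pair_ids: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=int))
        self.y = np.asarray(self.y, dtype=int)
        if self.directions is not None:
            self.directions = np.asarray(self.directions, dtype=int)
        if not self.pair_ids:
            self.pair_ids = [(f"L{i}", f"R{i}") for i in range(len(self.y))]
        rep = validate_pairs(self, strict=False)
        if not rep.ok:
            raise InputError("; ".join(rep.problems))

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "PairedComparisons":
        """Row subset (used by the cross-validation harness)."""
        idx = np.asarray(idx)
        return PairedComparisons(
            X=self.X[idx],
            y=self.y[idx],
            cue_names=list(self.cue_names),
            directions=None if self.directions is None else self.directions.copy(),
            pair_ids=[self.pair_ids[i] for i in idx],
        )


@dataclass
class ValidationReport:
    ok: bool
    n: int
    m: int
    discrimination_counts: np.ndarray
    problems: list[str]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _median_split(cues: np.ndarray) -> np.ndarray:
    """Dichotomize each continuous cue at its median; {0,1} cues pass through.

    Already-binary columns are left untouched so the operation is idempotent.
    """
    out = cues.astype(float).copy()
    for j in range(cues.shape[1]):
        col = cues[:, j]
        if np.isin(col, (0.0, 1.0)).all():
            continue
        out[:, j] = (col > np.median(col)).astype(float)
    return out


def make_pairs(objects: ObjectTable, dichotomize: bool = False) -> PairedComparisons:
    """Build all pairwise comparisons from an object table.

    For each unordered pair (A, B) taken in table order, cue j is coded
    sign(cue_j(A) - cue_j(B)) and the outcome sign(criterion(A) - criterion(B)).
    Pairs whose criterion values tie are dropped: the outcome space {-1,+1}
    has no code for "equally good".
    """
    cues = _median_split(objects.cues) if dichotomize else objects.cues
    rows, ys, ids = [], [], []
    for a, b in itertools.combinations(range(objects.n_objects), 2):
        dy = objects.criterion[a] - objects.criterion[b]
        if dy == 0:
            continue
        rows.append(np.sign(cues[a] - cues[b]).astype(int))
        ys.append(1 if dy > 0 else -1)
        ids.append((objects.object_ids[a], objects.object_ids[b]))
    if not rows:
        X = np.zeros((0, objects.m), dtype=int)
        y = np.zeros(0, dtype=int)
    else:
        X = np.array(rows, dtype=int)
        y = np.array(ys, dtype=int)
    return PairedComparisons(
        X=X,
        y=y,
        cue_names=list(objects.cue_names),
        directions=None if objects.directions is None else objects.directions.copy(),
        pair_ids=ids,
    )


def read_objects(path, criterion_column: str, id_column: str = "id") -> ObjectTable:
    """Read an object table from a delimited text file (CSV/TSV, header row).

    The named criterion column is the outcome; an ``id`` column, if present,
    labels the objects; every remaining column must be numeric and becomes
    a cue.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # noqa: BLE001 - surface as a format problem
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if criterion_column not in df.columns:
        raise ConfigError(
            f"criterion column {criterion_column!r} not in file "
            f"(columns: {list(df.columns)})"
        )
    if id_column in df.columns:
        ids = df[id_column].astype(str).tolist()
        df = df.drop(columns=[id_column])
    else:
        ids = [str(i) for i in range(len(df))]
    cue_cols = [c for c in df.columns if c != criterion_column]
    if not cue_cols:
        raise FormatError("file has no cue columns")
    for col in [criterion_column, *cue_cols]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad) > 0:
            row = int(bad[0])
            kind = "criterion" if col == criterion_column else "cue"
            msg = (
                f"non-numeric or missing {kind} value in column {col!r}, "
                f"row {row} (value {df[col].iloc[row]!r})"
            )
            if col == criterion_column:
                raise FormatError(msg)
            raise InputError(msg)
        df[col] = vals
    return ObjectTable(
        object_ids=ids,
        criterion=df[criterion_column].to_numpy(float),
        cues=df[cue_cols].to_numpy(float),
        cue_names=cue_cols,
    )


def write_objects(objects: ObjectTable, path) -> None:
    df = pd.DataFrame(objects.cues, columns=objects.cue_names)
    df.insert(0, "criterion", objects.criterion)
    df.insert(0, "id", objects.object_ids)
    df.to_csv(path, index=False)


def write_pairs(pc: PairedComparisons, path) -> None:
    """Export comparisons as CSV with columns x_1..x_m and y."""
    df = pd.DataFrame(pc.X, columns=[f"x_{j + 1}" for j in range(pc.m)])
    df["y"] = pc.y
    df.to_csv(path, index=False)


def read_pairs(path) -> PairedComparisons:
    df = pd.read_csv(path)
    if "y" not in df.columns:
        raise FormatError("pairs file must have a 'y' column")
    xcols = [c for c in df.columns if c != "y"]
    return PairedComparisons(
        X=df[xcols].to_numpy(int), y=df["y"].to_numpy(int), cue_names=xcols
    )


def validate_pairs(pc, strict: bool = False) -> ValidationReport:
    """Check the {-1,0,+1}/{-1,+1} encoding and count discriminations per cue.

    ``pc`` is a :class:`PairedComparisons` or an ``(X, y)`` pair of raw
    arrays.  With ``strict=True`` an encoding violation raises; otherwise it
    is reported in the returned report.
    """
    problems: list[str] = []
    if isinstance(pc, PairedComparisons):
        X, y, directions = pc.X, pc.y, pc.directions
    else:
        X, y = pc
        X = np.atleast_2d(np.asarray(X, dtype=int))
        y = np.asarray(y, dtype=int)
        directions = None
    bad_x = np.argwhere(~np.isin(X, (-1, 0, 1)))
    for i, j in bad_x[:10]:
        problems.append(f"X[{i},{j}]={X[i, j]} not in {{-1,0,1}}")
    bad_y = np.flatnonzero(~np.isin(y, (-1, 1)))
    for i in bad_y[:10]:
        problems.append(f"y[{i}]={y[i]} not in {{-1,1}}")
    if X.shape[0] != y.shape[0]:
        problems.append(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    if directions is not None and not np.isin(directions, (-1, 1)).all():
        problems.append("directions must be in {-1,+1}")
    report = ValidationReport(
        ok=not problems,
        n=X.shape[0],
        m=X.shape[1],
        discrimination_counts=np.count_nonzero(X, axis=0),
        problems=problems,
    )
    if strict and not report.ok:
        raise InputError("; ".join(problems))
    return report
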
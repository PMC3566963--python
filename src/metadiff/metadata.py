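"""Sample metadata: reading, automatic variable typing, selection, grouping.

Variables are typed automatically: a column is *numerical* iff every
non-missing value parses as a finite real under strict full-string parsing
("1e3" is numeric, "3+" is not); otherwise it is *categorical*. Missing
markers are the empty cell, "NA" and "NaN" (case-insensitive). Samples with
a missing value in a predicate's variable never satisfy that predicate —
cohort filters silently exclude incomplete records rather than erroring.

Two disjoint groups defined by metadata predicates (e.g. lean ``BMI<25``
versus obese ``BMI>30``) are the unit of comparison for the two-group
statistics in :mod:`metadiff.group_stats`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, UnknownIdError, UsageError
import warnings

__all__ = [
    "SampleMetadata",
    "SampleGroups",
    "read_metadata",
    "parse_predicate",
    "select_samples",
    "define_groups",
]

MISSING_MARKERS = frozenset({"", "na", "nan"})

_NUM_OPS = ("<", "<=", ">", ">=", "==", "!=")
_CAT_OPS = ("==", "!=", "in")


def _parse_number(text: str) -> float | None:
    """Strict full-string parse to a finite float, else None."""
    try:
        value = float(text)
    except ValueError:
        return None
    return value if math.isfinite(value) else None


@dataclass(frozen=True)
class SampleGroups:
    """Two labelled, disjoint, non-empty sample sets."""

    label_a: str
    samples_a: tuple[str, ...]
    label_b: str
    samples_b: tuple[str, ...]

    def __post_init__(self):
        if not self.samples_a:
            raise UsageError(f"group {self.label_a!r} is empty")
        if not self.samples_b:
            raise UsageError(f"group {self.label_b!r} is empty")
        shared = sorted(set(self.samples_a) & set(self.samples_b))
        if shared:
            raise UsageError(
                f"groups {self.label_a!r} and {self.label_b!r} share samples: {shared}"
            )


class SampleMetadata:
    """Per-sample variables, each typed numerical or categorical."""

    def __init__(self, df: pd.DataFrame, types: dict[str, str]) -> None:
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        self.df = df
        self.types = dict(types)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def variables(self) -> list[str]:
        return list(self.df.columns)

    def type_of(self, variable: str) -> str:
        if variable not in self.types:
            raise UnknownIdError(
                f"unknown metadata variable {variable!r}; available: {self.variables}"
            )
        return self.types[variable]

    def numeric_values(self, variable: str) -> pd.Series:
        if self.type_of(variable) != "numerical":
            raise UsageError(f"variable {variable!r} is categorical, not numerical")
        return self.df[variable].astype(float)


def read_metadata(source) -> SampleMetadata:
    """Read a tab-separated metadata file (first column sample id)."""
    try:
        raw = pd.read_csv(
            source, sep="\t", comment="#", index_col=0, dtype=str, keep_default_na=False
        )
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse metadata file: {exc}") from None
    raw.index = raw.index.astype(str).str.strip()
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"duplicate sample id {dup!r} in metadata")
    types: dict[str, str] = {}
    cols: dict[str, pd.Series] = {}
    for var in raw.columns:
        values = raw[var].astype(str).str.strip()
        missing = values.str.lower().isin(MISSING_MARKERS)
        present = values[~missing]
        if present.empty:
            warnings.warn(f"metadata variable {var!r} has no values; kept as categorical",
                          stacklevel=2)
            types[var] = "categorical"
            cols[var] = values.where(~missing, np.nan)
            continue
        parsed = present.map(_parse_number)
        if parsed.notna().all():
            types[var] = "numerical"
            col = pd.Series(np.nan, index=values.index, dtype=float)
            col[~missing] = parsed.astype(float)
            cols[var] = col
        else:
            types[var] = "categorical"
            cols[var] = values.where(~missing, np.nan)
    df = pd.DataFrame(cols, index=raw.index)
    df.index.name = "sample_id"
    return SampleMetadata(df, types)


# ---------------------------------------------------------------------------
# selection

_PRED_RE = re.compile(r"^\s*([^<>=!\s]+)\s*(<=|>=|==|!=|<|>| in )\s*(.+?)\s*$")


def parse_predicate(text: str) -> tuple[str, str, str]:
    """Parse a predicate string like ``"BMI<25"`` or ``"disease==CD"``.

    The ``in`` operator takes a comma-separated value list:
    ``"nationality in Spanish,Danish"``.
    """
    m = _PRED_RE.match(text)
    if not m:
        raise UsageError(
            f"cannot parse predicate {text!r}; expected VAR<OP>VALUE with OP in "
            f"{sorted(set(_NUM_OPS) | set(_CAT_OPS))}"
        )
    var, op, value = m.groups()
    return var, op.strip(), value


def _predicate_mask(md: SampleMetadata, variable: str, op: str, value) -> pd.Series:
    vtype = md.type_of(variable)
    col = md.df[variable]
    present = col.notna()
    if vtype == "numerical":
        if op not in _NUM_OPS:
            raise UsageError(
                f"operator {op!r} not valid for numerical variable {variable!r}; "
                f"use one of {_NUM_OPS}"
            )
        threshold = _parse_number(str(value))
        if threshold is None:
            raise UsageError(
                f"value {value!r} is not numeric (variable {variable!r} is numerical)"
            )
        vals = col.astype(float)
        ops = {
            "<": vals < threshold, "<=": vals <= threshold,
            ">": vals > threshold, ">=": vals >= threshold,
            "==": vals == threshold, "!=": vals != threshold,
        }
        mask = ops[op]
    else:
        if op not in _CAT_OPS:
            raise UsageError(
                f"operator {op!r} not valid for categorical variable {variable!r}; "
                f"use one of {_CAT_OPS}"
            )
        if op == "in":
            allowed = [v.strip() for v in str(value).split(",")]
            mask = col.isin(allowed)
        elif op == "==":
            mask = col == str(value)
        else:
            mask = (col != str(value)) & present
    return mask & present  # missing values never satisfy a predicate


def select_samples(md: SampleMetadata, predicates) -> list[str]:
    """Samples satisfying the conjunction of predicates, in metadata order.

    Each predicate is a ``(variable, operator, value)`` triple or a string
    accepted by :func:`parse_predicate`. An empty list selects all samples.
    """
    mask = pd.Series(True, index=md.df.index)
    for pred in predicates:
        if isinstance(pred, str):
            pred = parse_predicate(pred)
        variable, op, value = pred
        mask &= _predicate_mask(md, variable, op, value)
    return list(md.df.index[mask])


def define_groups(
    md: SampleMetadata,
    predicates_a,
    predicates_b,
    label_a: str = "A",
    label_b: str = "B",
) -> SampleGroups:
    """Build two disjoint comparison groups from metadata predicates."""
    samples_a = select_samples(md, predicates_a)
    samples_b = select_samples(md, predicates_b)
    if not samples_a:
        raise UsageError(f"group {label_a!r} selected no samples")
    if not samples_b:
        raise UsageError(f"group {label_b!r} selected no samples")
    return SampleGroups(label_a, tuple(samples_a), label_b, tuple(samples_b))
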
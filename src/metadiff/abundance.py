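"""Abundance matrices and hierarchy-aware aggregation.

An :class:`AbundanceTable` holds a features x samples matrix of non-negative
values — raw annotation counts or per-sample relative abundances — tagged
with the hierarchy level its features live at. The central operation is
:func:`aggregate_to_level`: abundance is propagated up the hierarchy one
level at a time, each node's mass divided equally among its parents (a node
with k parents sends value/k to each). On strict trees this reduces to plain
group-by-ancestor summation; on DAGs with shared children it is the unique
local rule that conserves per-sample totals at every intermediate level.

Features absent from the database go to a synthetic ``Unmapped`` bucket by
default, so the per-sample column sums are conserved exactly and the
unannotated fraction stays visible; a ``drop`` policy removes them instead.

Aggregation is linear, so counts and relative tables aggregate identically
and ``normalize -> aggregate`` equals ``aggregate -> normalize`` under the
bucket policy.
"""

from __future__ import annotations

import io
import warnings

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError, ValidationError
from .hierarchy import HierarchyDB

__all__ = [
    "AbundanceTable",
    "UNMAPPED_ID",
    "read_abundance",
    "write_abundance",
    "normalize_relative",
    "aggregate_to_level",
    "mean_relative_abundance",
]

#: synthetic node collecting features that are absent from the hierarchy
UNMAPPED_ID = "Unmapped"

_REL_TOL = 1e-9


class AbundanceTable:
    """Features x samples matrix of non-negative abundances.

    Parameters
    ----------
    data:
        DataFrame with feature ids as index and sample ids as columns.
    mode:
        ``"counts"`` (raw, any non-negative scale) or ``"relative"``
        (each sample column sums to 1; all-zero columns excepted).
    level:
        Hierarchy level index of the features (0 = leaf features).
    level_name:
        Display label for the level, used in output headers and results.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        mode: str = "counts",
        level: int = 0,
        level_name: str = "",
        _strict: bool = True,
    ) -> None:
        if mode not in ("counts", "relative"):
            raise UsageError(f"mode must be 'counts' or 'relative', got {mode!r}")
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        values = data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at feature {data.index[r]!r}, sample {data.columns[c]!r}"
            )
        if values.size and (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value {values[r, c]} at feature {data.index[r]!r}, "
                f"sample {data.columns[c]!r}"
            )
        if mode == "relative" and _strict and values.size:
            sums = values.sum(axis=0)
            bad = np.where((sums > 0) & (np.abs(sums - 1.0) > _REL_TOL * np.maximum(sums, 1)))[0]
            if bad.size:
                raise ValidationError(
                    f"relative table column {data.columns[bad[0]]!r} sums to {sums[bad[0]]!r}, not 1"
                )
        self.data = data.astype(float)
        self.mode = mode
        self.level = int(level)
        self.level_name = level_name or f"level{level}"

    # convenience views -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def column_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise UsageError(f"samples not in abundance table: {missing}")
        return AbundanceTable(
            self.data[list(sample_ids)], self.mode, self.level, self.level_name, _strict=False
        )

    def __repr__(self) -> str:
        nf, ns = self.shape
        return (
            f"AbundanceTable({nf} features x {ns} samples, mode={self.mode!r}, "
            f"level={self.level_name!r})"
        )


# ---------------------------------------------------------------------------
# IO


def read_abundance(source) -> AbundanceTable:
    """Read a tab-separated abundance file (features x samples, counts).

    First column holds feature ids, the header row sample ids; ``#`` comment
    lines are ignored. Duplicate feature rows are summed with a warning;
    duplicate sample ids, non-numeric cells and negative values are errors.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    header_line = next(
        (ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")), ""
    )
    sample_ids = header_line.split("\t")[1:]
    if len(set(sample_ids)) != len(sample_ids):  # pandas would mangle duplicates
        dup = next(s for i, s in enumerate(sample_ids) if s in sample_ids[:i])
        raise FormatError(f"duplicate sample id {dup!r} in abundance header")
    try:
        raw = pd.read_csv(
            io.StringIO(text), sep="\t", comment="#", index_col=0, dtype=str,
            keep_default_na=False,
        )
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse abundance file: {exc}") from None
    if raw.shape[1] == 0:
        raise FormatError("abundance file has no sample columns")
    numeric = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col].str.strip(), errors="coerce")
        bad = converted.isna()
        if bad.any():
            feat = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"non-numeric cell at feature {feat!r}, sample {col!r}: "
                f"{raw.loc[feat, col]!r}"
            )
        numeric[col] = converted
    if numeric.index.has_duplicates:
        dups = sorted(set(numeric.index[numeric.index.duplicated()]))
        warnings.warn(f"summed duplicate feature rows: {dups}", stacklevel=2)
        numeric = numeric.groupby(level=0, sort=False).sum()
    numeric.index = numeric.index.astype(str).str.strip()
    numeric.index.name = "feature_id"
    return AbundanceTable(numeric, mode="counts", level=0)


def write_abundance(table: AbundanceTable, path_or_buf) -> None:
    """Write a table in the tab-separated input format, level recorded in a comment."""
    header = f"# level: {table.level_name}\n# mode: {table.mode}\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(header)
        table.data.to_csv(path_or_buf, sep="\t", index_label="feature_id")
    else:
        with open(path_or_buf, "w", encoding="utf-8") as fh:
            fh.write(header)
            table.data.to_csv(fh, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# transforms


def normalize_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample column by its total; all-zero columns stay zero."""
    if table.mode == "relative":
        warnings.warn("table is already relative; returning it unchanged", stacklevel=2)
        return table
    sums = table.data.sum(axis=0)
    zero_cols = list(sums.index[sums == 0])
    if zero_cols:
        warnings.warn(f"all-zero sample columns left as zero: {zero_cols}", stacklevel=2)
    safe = sums.replace(0, 1.0)
    out = AbundanceTable(
        table.data.div(safe, axis=1), mode="relative", level=table.level,
        level_name=table.level_name,
    )
    out.data.attrs["zero_columns"] = zero_cols
    return out


def aggregate_to_level(
    table: AbundanceTable,
    db: HierarchyDB,
    target_level: int | str,
    unmapped_policy: str = "bucket",
) -> AbundanceTable:
    """Propagate abundance up the hierarchy to ``target_level``.

    One level at a time, each node's abundance is divided equally among its
    k parents; a parent's abundance is the sum of the shares it receives.
    Features absent from the database (or stranded without parents below the
    target) go to the ``Unmapped`` bucket (``unmapped_policy="bucket"``,
    conserving per-sample totals exactly) or are removed and reported
    (``"drop"``; dropped ids in ``result.data.attrs["dropped_features"]``).
    """
    if unmapped_policy not in ("bucket", "drop"):
        raise UsageError(f"unmapped_policy must be 'bucket' or 'drop', got {unmapped_policy!r}")
    target = db.level_index(target_level)
    if not 0 <= target < db.n_levels:
        raise UsageError(
            f"target level {target} out of range; database has levels 0..{db.n_levels - 1}"
        )
    if target <= table.level:
        raise UsageError(
            f"target level {target} must be above the table's level {table.level}"
        )

    n_samples = len(table.sample_ids)
    dropped: list[str] = []
    current: dict[str, np.ndarray] = {}
    n_mapped = 0
    for fid, row in zip(table.feature_ids, table.values):
        if fid in db and db.node(fid).level == table.level:
            current[fid] = current.get(fid, np.zeros(n_samples)) + row
            n_mapped += 1
        elif unmapped_policy == "bucket":
            current[UNMAPPED_ID] = current.get(UNMAPPED_ID, np.zeros(n_samples)) + row
        else:
            dropped.append(fid)
    if n_mapped == 0:
        raise ValidationError(
            "no feature ids match database nodes at the table's level; "
            "check that the right database and level were selected"
        )

    for level in range(table.level, target):
        nxt: dict[str, np.ndarray] = {}

        def _add(nid: str, vec: np.ndarray) -> None:
            if nid in nxt:
                nxt[nid] = nxt[nid] + vec
            else:
                nxt[nid] = vec.copy()

        for nid, vec in current.items():
            parents = sorted(db.parents_of(nid)) if nid != UNMAPPED_ID and nid in db else []
            if nid == UNMAPPED_ID or not parents:
                # unmapped mass, or a node stranded without parents below target
                if nid != UNMAPPED_ID and unmapped_policy == "drop":
                    dropped.append(nid)
                elif unmapped_policy == "bucket":
                    _add(UNMAPPED_ID, vec)
                continue
            share = vec / len(parents)
            for parent in parents:
                _add(parent, share)
        current = nxt

    order = sorted(nid for nid in current if nid != UNMAPPED_ID)
    if UNMAPPED_ID in current:
        order.append(UNMAPPED_ID)
    data = pd.DataFrame(
        np.array([current[nid] for nid in order]) if order else np.empty((0, n_samples)),
        index=pd.Index(order, name="feature_id"),
        columns=table.sample_ids,
    )
    out = AbundanceTable(
        data,
        mode=table.mode,
        level=target,
        level_name=db.level_names[target],
        _strict=False,  # drop policy may remove relative mass
    )
    out.data.attrs["dropped_features"] = dropped
    return out


def mean_relative_abundance(table: AbundanceTable, sample_subset=None) -> pd.Series:
    """Per-feature arithmetic mean relative abundance over a sample subset."""
    if table.mode != "relative":
        raise UsageError("mean relative abundance requires a relative table; normalize first")
    subset = list(sample_subset) if sample_subset is not None else table.sample_ids
    if not subset:
        raise UsageError("sample subset is empty")
    return table.subset_samples(subset).data.mean(axis=1)
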
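"""Leveled hierarchical databases (taxonomies, KEGG Orthology, COG, PFAM ...).

A hierarchy is a directed acyclic graph of nodes arranged in ordered levels,
leaf-first: level 0 holds the features that appear in abundance files
(species, KO/COG/PFAM accessions, genes), higher levels hold progressively
coarser groupings (genus, pathway, functional category). Every edge connects
a child to a parent exactly one level up, and a child may have several
parents — a KEGG ortholog that belongs to two pathways, for instance. That
multi-parent case is what distinguishes these databases from plain trees and
drives the equal-split aggregation rule in :mod:`metadiff.abundance`.

The canonical on-disk form is a *lineage table*: one tab-separated row per
root-to-leaf path, header row naming the levels. This is how NCBI taxonomy
dumps and KEGG BRITE exports are commonly flattened. An edge-list dialect
(``child<TAB>parent<TAB>child_level_index``) is accepted as an alternative.

Unranked gaps — blank or ``NA`` cells inside a lineage row — are bridged by
placeholder nodes named ``"<child name> (unranked)"`` so that every edge
still spans exactly one level; the gaps are surfaced by :func:`validate`.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

from .errors import AmbiguityError, FormatError, UnknownIdError, UsageError

__all__ = [
    "HierarchyNode",
    "HierarchyDB",
    "ValidationReport",
    "parse_hierarchy",
    "validate",
]

#: cell values treated as "this level is absent in this lineage row"
MISSING_CELLS = frozenset({"", "na", "nan"})

_UNRANKED_SUFFIX = " (unranked)"


@dataclass(frozen=True)
class HierarchyNode:
    """One entry at one level of a hierarchy.

    ``node_id`` is unique within a database. Identity of a node is the pair
    (name, level): the same display string at two different levels denotes
    two distinct nodes (taxonomy names can repeat across ranks), in which
    case the non-leaf occurrences get level-qualified ids.
    """

    node_id: str
    name: str
    level: int
    placeholder: bool = False  # synthesized to bridge an unranked gap


@dataclass
class ValidationReport:
    """Outcome of :func:`validate` — advisory, never raises."""

    level_counts: dict[str, int]
    orphans: list[str] = field(default_factory=list)
    level_violations: list[str] = field(default_factory=list)
    gap_nodes: list[str] = field(default_factory=list)
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


class HierarchyDB:
    """In-memory leveled DAG with leaf-first level ordering."""

    def __init__(
        self,
        level_names: list[str],
        nodes: list[HierarchyNode],
        edges: set[tuple[str, str]],
    ) -> None:
        if not level_names:
            raise FormatError("hierarchy has no levels")
        self.level_names = list(level_names)
        self._nodes: dict[str, HierarchyNode] = {}
        for node in nodes:
            if node.node_id in self._nodes:
                raise AmbiguityError(f"duplicate node id {node.node_id!r}")
            if not 0 <= node.level < len(level_names):
                raise FormatError(
                    f"node {node.node_id!r} has level {node.level}, "
                    f"outside 0..{len(level_names) - 1}"
                )
            self._nodes[node.node_id] = node
        self._parents: dict[str, set[str]] = {nid: set() for nid in self._nodes}
        self._children: dict[str, set[str]] = {nid: set() for nid in self._nodes}
        for child, parent in edges:
            if child not in self._nodes or parent not in self._nodes:
                raise FormatError(f"edge ({child!r}, {parent!r}) references unknown node")
            if self._nodes[parent].level != self._nodes[child].level + 1:
                raise FormatError(
                    f"edge ({child!r}, {parent!r}) does not span exactly one level"
                )
            self._parents[child].add(parent)
            self._children[parent].add(child)
        self.edges = frozenset(edges)

    # -- queries ---------------------------------------------------------

    @property
    def n_levels(self) -> int:
        return len(self.level_names)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, node_id: str) -> HierarchyNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise UnknownIdError(f"unknown node id {node_id!r}") from None

    def nodes(self) -> list[HierarchyNode]:
        return sorted(self._nodes.values(), key=lambda n: (n.level, n.node_id))

    def nodes_at_level(self, level: int) -> list[HierarchyNode]:
        return [n for n in self.nodes() if n.level == level]

    def leaves(self) -> list[HierarchyNode]:
        return self.nodes_at_level(0)

    def parents_of(self, node_id: str) -> frozenset[str]:
        self.node(node_id)
        return frozenset(self._parents[node_id])

    def children_of(self, node_id: str) -> frozenset[str]:
        self.node(node_id)
        return frozenset(self._children[node_id])

    def level_index(self, level: int | str) -> int:
        """Resolve a level given either its index or its name."""
        if isinstance(level, str):
            try:
                return self.level_names.index(level)
            except ValueError:
                raise UnknownIdError(
                    f"unknown level {level!r}; levels are {self.level_names}"
                ) from None
        return int(level)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HierarchyDB):
            return NotImplemented
        return (
            self.level_names == other.level_names
            and set(self._nodes.values()) == set(other._nodes.values())
            and self.edges == other.edges
        )

    # -- serialization ---------------------------------------------------

    def lineage_rows(self) -> list[list[str]]:
        """Root-to-leaf paths as lineage rows (root-first column order).

        Placeholder (unranked) nodes are written as blank cells so that a
        write/parse round trip reproduces the database exactly.
        """
        rows: set[tuple[str, ...]] = set()
        for leaf in self.leaves():
            for path in self._paths_up(leaf.node_id):
                cells = [
                    "" if self._nodes[nid].placeholder else self._nodes[nid].name
                    for nid in path
                ]
                cells += [""] * (self.n_levels - len(cells))  # parentless below root
                rows.add(tuple(reversed(cells)))  # leaf-first -> root-first
        return [list(r) for r in sorted(rows)]

    def _paths_up(self, node_id: str) -> list[list[str]]:
        parents = sorted(self._parents[node_id])
        if not parents:
            return [[node_id]]
        out = []
        for parent in parents:
            for tail in self._paths_up(parent):
                out.append([node_id] + tail)
        return out

    def write_lineage(self, path_or_buf, orientation: str = "root_first") -> None:
        """Write the canonical tab-separated lineage table."""
        header = list(reversed(self.level_names))  # root-first
        rows = self.lineage_rows()
        if orientation == "leaf_first":
            header = header[::-1]
            rows = [r[::-1] for r in rows]
        elif orientation != "root_first":
            raise _bad_orientation(orientation)
        text = "\n".join("\t".join(r) for r in [header] + rows) + "\n"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w", encoding="utf-8") as fh:
                fh.write(text)


def _bad_orientation(orientation) -> UsageError:
    return UsageError(f"orientation must be 'root_first' or 'leaf_first', got {orientation!r}")


# ---------------------------------------------------------------------------
# parsing


def _read_rows(source) -> list[list[str]]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        if not os.path.exists(source):
            raise FormatError(f"hierarchy file not found: {source}")
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append(line.rstrip("\n").split("\t"))
    return rows


def parse_hierarchy(
    source,
    orientation: str = "root_first",
    dialect: str = "lineage",
    level_names: list[str] | None = None,
) -> HierarchyDB:
    """Parse a hierarchy file into a :class:`HierarchyDB`.

    Parameters
    ----------
    source:
        Path or text file object. Tab-separated, ``#`` comments allowed.
    orientation:
        Column order of the lineage dialect: ``root_first`` (NCBI/KEGG style,
        superkingdom ... species) or ``leaf_first``.
    dialect:
        ``lineage`` (one row per root-to-leaf path, header = level names) or
        ``edges`` (child, parent, child_level_index).
    level_names:
        Required for the edge-list dialect; overrides the header otherwise.
    """
    rows = _read_rows(source)
    if not rows:
        raise FormatError("empty hierarchy file")
    if dialect == "edges":
        return _parse_edge_list(rows, level_names)
    if dialect != "lineage":
        raise FormatError(f"unknown hierarchy dialect {dialect!r}")

    header, data = rows[0], rows[1:]
    if orientation == "leaf_first":
        header = header[::-1]
        data = [r[::-1] for r in data]
    elif orientation != "root_first":
        raise _bad_orientation(orientation)
    n_levels = len(header)
    # internal convention: leaf-first level names
    names = list(level_names) if level_names is not None else list(reversed(header))
    if len(names) != n_levels:
        raise FormatError(
            f"level_names has {len(names)} entries but the file has {n_levels} columns"
        )
    if not data:
        raise FormatError("hierarchy file has a header but no lineage rows")

    # first pass: resolve each row to a full leaf-first chain of (name, level)
    chains: list[list[tuple[str, int]]] = []
    for rowno, row in enumerate(data, start=2):
        if len(row) != n_levels:
            raise FormatError(
                f"lineage row {rowno} has {len(row)} columns, expected {n_levels}"
            )
        cells = list(reversed([c.strip() for c in row]))  # leaf-first
        if cells[0].lower() in MISSING_CELLS:
            raise FormatError(f"lineage row {rowno} has a blank leaf cell")
        chain: list[tuple[str, int]] = [(cells[0], 0)]
        for level in range(1, n_levels):
            cell = cells[level]
            if cell.lower() in MISSING_CELLS:
                cell = chain[-1][0] + _UNRANKED_SUFFIX
            chain.append((cell, level))
        chains.append(chain)

    placeholder_keys = {
        (name, lvl)
        for chain in chains
        for name, lvl in chain
        if name.endswith(_UNRANKED_SUFFIX)
    }
    levels_by_name: dict[str, set[int]] = {}
    for chain in chains:
        for name, lvl in chain:
            levels_by_name.setdefault(name, set()).add(lvl)

    def node_id(name: str, lvl: int) -> str:
        # same string at two levels -> two distinct nodes; leaf keeps the raw
        # name (it must match abundance feature ids), others get qualified
        if len(levels_by_name[name]) == 1 or lvl == 0:
            return name
        return f"{name}|{names[lvl]}"

    nodes: dict[str, HierarchyNode] = {}
    edges: set[tuple[str, str]] = set()
    for chain in chains:
        ids = [node_id(name, lvl) for name, lvl in chain]
        for (name, lvl), nid in zip(chain, ids):
            nodes.setdefault(
                nid,
                HierarchyNode(nid, name, lvl, placeholder=(name, lvl) in placeholder_keys),
            )
        for child, parent in zip(ids, ids[1:]):
            edges.add((child, parent))
    return HierarchyDB(names, list(nodes.values()), edges)


def _parse_edge_list(rows: list[list[str]], level_names: list[str] | None) -> HierarchyDB:
    header, data = rows[0], rows[1:]
    if len(header) != 3:
        raise FormatError("edge-list dialect requires 3 columns: child, parent, child_level_index")
    if not data:
        raise FormatError("edge-list file has a header but no edges")
    level_of: dict[str, int] = {}
    edges: set[tuple[str, str]] = set()
    max_level = 0
    for rowno, row in enumerate(data, start=2):
        if len(row) != 3:
            raise FormatError(f"edge row {rowno} has {len(row)} columns, expected 3")
        child, parent, lvl_s = (c.strip() for c in row)
        try:
            lvl = int(lvl_s)
        except ValueError:
            raise FormatError(f"edge row {rowno}: child level {lvl_s!r} is not an integer") from None
        for nid, nlvl in ((child, lvl), (parent, lvl + 1)):
            if nid in level_of and level_of[nid] != nlvl:
                raise AmbiguityError(
                    f"node {nid!r} declared at levels {level_of[nid]} and {nlvl}"
                )
            level_of[nid] = nlvl
        edges.add((child, parent))
        max_level = max(max_level, lvl + 1)
    names = list(level_names) if level_names else [f"level{i}" for i in range(max_level + 1)]
    if len(names) <= max_level:
        raise FormatError(
            f"edge list uses {max_level + 1} levels but only {len(names)} level names given"
        )
    nodes = [HierarchyNode(nid, nid, lvl) for nid, lvl in level_of.items()]
    return HierarchyDB(names, nodes, edges)


# ---------------------------------------------------------------------------
# validation


def validate(db: HierarchyDB) -> ValidationReport:
    """Report structural issues without raising.

    Flags non-leaf nodes unreachable from any leaf (orphans), edges that do
    not span exactly one level (impossible by construction, checked anyway),
    unranked-gap placeholder nodes, and an empty leaf level.
    """
    counts = {name: 0 for name in db.level_names}
    orphans: list[str] = []
    gaps: list[str] = []
    for node in db.nodes():
        counts[db.level_names[node.level]] += 1
        if node.level > 0 and not db.children_of(node.node_id):
            orphans.append(node.node_id)
        if node.placeholder:
            gaps.append(node.node_id)
    violations = [
        f"edge ({c}, {p}) spans {db.node(p).level - db.node(c).level} levels"
        for c, p in sorted(db.edges)
        if db.node(p).level != db.node(c).level + 1
    ]
    issues = []
    if counts[db.level_names[0]] == 0:
        issues.append("hierarchy has zero leaf nodes")
    issues += [f"orphan node {nid!r} (no children, unreachable from leaves)" for nid in orphans]
    issues += violations
    return ValidationReport(
        level_counts=counts,
        orphans=orphans,
        level_violations=violations,
        gap_nodes=gaps,
        issues=issues,
    )
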
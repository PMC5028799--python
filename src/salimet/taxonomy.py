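"""NCBI-style taxonomy: dump parsing, lineages, LCA, descendants, name resolution.

The tree is loaded from ``nodes.dmp``/``names.dmp``/``merged.dmp`` dialect
files (fields separated by ``\\t|\\t``, records terminated by ``\\t|``).
Lineages are reported over *all* nodes on the root path, including
``no rank``/``clade`` nodes; nothing is collapsed onto canonical ranks, so the
lowest common ancestor of a taxon set may legitimately carry any rank label.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping

from .errors import (
    NameResolutionError,
    TaxonomyStructureError,
    UnknownTaxonError,
)

#: ranks at or below the species level; used when deciding whether an LCA is
#: "species-mapped" and when promoting sub-species LCAs for database reduction
SPECIES_OR_BELOW = frozenset(
    {"species", "subspecies", "strain", "varietas", "forma", "forma specialis", "isolate"}
)


@dataclass(frozen=True)
class Lineage:
    """Root-to-taxon path as an ordered list of ``(taxid, rank)`` pairs."""

    steps: tuple[tuple[int, str], ...]

    def taxids(self) -> tuple[int, ...]:
        return tuple(t for t, _ in self.steps)

    def __contains__(self, taxid: int) -> bool:
        return any(t == taxid for t, _ in self.steps)

    def __iter__(self):
        return iter(self.steps)

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class TaxonomyTree:
    """Rank-annotated rooted tree over integer taxon ids.

    ``nodes`` maps taxid -> (parent taxid, rank label); the root is its own
    parent in the dump and is stored in ``root``.  ``merged`` maps retired ids
    to their current replacement and is resolved transitively on lookup.
    """

    nodes: dict[int, tuple[int, str]]
    names: dict[int, str]
    merged: dict[int, int] = field(default_factory=dict)
    root: int = 1

    # -- id handling -------------------------------------------------------

    def resolve_id(self, taxid: int) -> int:
        """Map a possibly-merged taxid to its current id; raise if unknown."""
        seen = set()
        while taxid not in self.nodes:
            if taxid in seen or taxid not in self.merged:
                raise UnknownTaxonError(taxid)
            seen.add(taxid)
            taxid = self.merged[taxid]
        return taxid

    def rank(self, taxid: int) -> str:
        return self.nodes[self.resolve_id(taxid)][1]

    def name(self, taxid: int) -> str:
        tid = self.resolve_id(taxid)
        return self.names.get(tid, str(tid))

    def find_by_name(self, name: str) -> int | None:
        """Reverse name lookup (exact scientific name); None if absent."""
        return self._name_index.get(name)

    @functools.cached_property
    def _name_index(self) -> dict[str, int]:
        return {v: k for k, v in self.names.items()}

    # -- queries -----------------------------------------------------------

    def lineage(self, taxid: int) -> Lineage:
        """Root-to-taxon path.  ``lineage(root)`` is the single-element path."""
        tid = self.resolve_id(taxid)
        steps: list[tuple[int, str]] = []
        while True:
            parent, rank = self.nodes[tid]
            steps.append((tid, rank))
            if tid == self.root:
                break
            tid = parent
        steps.reverse()
        return Lineage(tuple(steps))

    def lca(self, taxa: Iterable[int]) -> tuple[int, str]:
        """Deepest node present in every member's lineage.

        Accepts any non-empty iterable; duplicates and ordering are
        irrelevant.  Returns ``(taxid, rank)``.
        """
        ids = {self.resolve_id(t) for t in taxa}
        if not ids:
            raise ValueError("lca of an empty taxon set is undefined")
        first = ids.pop()
        path = self.lineage(first)
        common = None
        others = [set(self.lineage(t).taxids()) for t in ids]
        for tid, rank in reversed(path.steps):
            if all(tid in o for o in others):
                common = (tid, rank)
                break
        assert common is not None  # root is shared by construction
        return common

    def descendants(self, taxid: int) -> set[int]:
        """The subtree rooted at ``taxid``, including ``taxid`` itself."""
        tid = self.resolve_id(taxid)
        out = {tid}
        stack = [tid]
        children = self._children
        while stack:
            for c in children.get(stack.pop(), ()):
                out.add(c)
                stack.append(c)
        return out

    @functools.cached_property
    def _children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {}
        for tid, (parent, _) in self.nodes.items():
            if tid != self.root:
                ch.setdefault(parent, []).append(tid)
        return ch

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """The unique ancestor (or self) carrying ``rank``, else None."""
        for tid, r in self.lineage(taxid):
            if r == rank:
                return tid
        return None

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        for tid, (parent, _) in self.nodes.items():
            if parent not in self.nodes:
                raise TaxonomyStructureError(
                    f"node {tid} has orphan parent id {parent}"
                )
        # cycle check: walk every node to root with memoisation
        ok: set[int] = {self.root}
        for tid in self.nodes:
            path = []
            cur = tid
            while cur not in ok:
                if cur in path:
                    raise TaxonomyStructureError(f"cycle detected at node {cur}")
                path.append(cur)
                parent = self.nodes[cur][0]
                if parent == cur and cur != self.root:
                    raise TaxonomyStructureError(
                        f"node {cur} is its own parent but is not the root"
                    )
                cur = parent
            ok.update(path)


# -- dump parsing ----------------------------------------------------------


def _iter_dmp(path: str | PathLike) -> Iterable[list[str]]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            if line.endswith("\t|"):
                line = line[: -len("\t|")]
            yield line.split("\t|\t")


def load_taxonomy(
    nodes_source: str | PathLike,
    names_source: str | PathLike,
    merged_source: str | PathLike | None = None,
) -> TaxonomyTree:
    """Parse taxonomy dump files and return a validated :class:`TaxonomyTree`."""
    nodes: dict[int, tuple[int, str]] = {}
    root = None
    for fields in _iter_dmp(nodes_source):
        tid, parent, rank = int(fields[0]), int(fields[1]), fields[2].strip()
        nodes[tid] = (parent, rank)
        if tid == parent:
            root = tid
    if root is None:
        raise TaxonomyStructureError("no root node (a node that is its own parent)")

    names: dict[int, str] = {}
    for fields in _iter_dmp(names_source):
        tid, name = int(fields[0]), fields[1].strip()
        name_class = fields[3].strip() if len(fields) > 3 else "scientific name"
        if name_class == "scientific name":
            names[tid] = name

    merged: dict[int, int] = {}
    if merged_source is not None:
        for fields in _iter_dmp(merged_source):
            merged[int(fields[0])] = int(fields[1])

    tree = TaxonomyTree(nodes=nodes, names=names, merged=merged, root=root)
    tree.validate()
    # merged targets must themselves resolve
    for old in merged:
        tree.resolve_id(old)
    return tree


# -- name resolution -------------------------------------------------------


def load_name_map(path: str | PathLike) -> dict[str, int]:
    """Two-column TSV (name, taxid) with one header line."""
    out: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        next(fh)  # header
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            name, taxid = line.split("\t")[:2]
            out[name] = int(taxid)
    return out


def resolve_name(
    tree: TaxonomyTree, species_name: str, name_map: Mapping[str, int]
) -> int:
    """Resolve a species name to its taxid: exact match, then case-insensitive.

    Unresolvable names (absent, or pointing at an id unknown to the tree ---
    e.g. a deleted taxid) raise :class:`NameResolutionError`; nothing is
    silently dropped.
    """
    taxid = name_map.get(species_name)
    if taxid is None:
        folded = species_name.casefold()
        for k, v in name_map.items():
            if k.casefold() == folded:
                taxid = v
                break
    if taxid is None:
        raise NameResolutionError(species_name)
    try:
        return tree.resolve_id(taxid)
    except UnknownTaxonError:
        raise NameResolutionError(species_name) from None


# functional aliases matching the operation-style surface used elsewhere
def lineage_of(tree: TaxonomyTree, taxid: int) -> Lineage:
    return tree.lineage(taxid)


def lca_of(tree: TaxonomyTree, taxa: Iterable[int]) -> tuple[int, str]:
    return tree.lca(taxa)


def descendants_of(tree: TaxonomyTree, taxid: int) -> set[int]:
    return tree.descendants(taxid)
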
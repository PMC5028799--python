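"""Taxonomic assignment of protein groups and search-space reduction.

Each protein group is assigned the lowest common ancestor (LCA) of the taxa
its accessions map to.  In the first pass only the accessions carrying the
most peptide associations ("majority" accessions) vote; in the second pass,
run against the reduced database, every accession votes.  Groups whose LCA is
primate-ambiguous (the parvorder Catarrhini, which contains humans) are
re-labelled human: curated protein databases mix primate orthologs, so such
groups are in practice human proteins.  LCAs at genus or species rank, plus
all of their taxonomic descendants, define the reduced database for the
second identification pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from os import PathLike
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import FormatError
from .proteingroups import ProteinGroup
from .taxonomy import SPECIES_OR_BELOW, TaxonomyTree

log = logging.getLogger(__name__)

HUMAN_TAXID = 9606
CATARRHINI_NAME = "Catarrhini"

KINGDOM_HUMAN = "human"
KINGDOM_BACTERIA = "bacteria"
KINGDOM_OTHER = "other"


@dataclass(frozen=True)
class LCAAssignment:
    group_id: int
    lca_taxid: int | None
    lca_rank: str | None
    kingdom: str
    human_override_applied: bool = False
    unresolved_accessions: tuple[str, ...] = ()


def load_accession_taxmap(path: str | PathLike) -> dict[str, int]:
    """Sidecar two-column TSV (accession, taxid), one header line."""
    out: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            acc, taxid = line.split("\t")[:2]
            out[acc] = int(taxid)
    return out


def majority_accessions(group: ProteinGroup) -> set[str]:
    """All accessions tied at the maximum peptide-association count.

    Keeping every tied accession (rather than an arbitrary one) makes the
    first-pass LCA independent of input order.
    """
    if not group.peptide_counts:
        raise ValueError(f"group {group.group_id} has no peptide counts")
    top = max(group.peptide_counts.values())
    return {a for a, c in group.peptide_counts.items() if c == top}


def _kingdom_of(tree: TaxonomyTree, taxid: int, bacteria_taxid: int | None) -> str:
    if tree.resolve_id(taxid) == HUMAN_TAXID:
        return KINGDOM_HUMAN
    if bacteria_taxid is not None and bacteria_taxid in tree.lineage(taxid):
        return KINGDOM_BACTERIA
    return KINGDOM_OTHER


def assign_lca(
    group: ProteinGroup,
    taxmap: Mapping[str, int],
    tree: TaxonomyTree,
    mode: str = "first_iteration",
) -> LCAAssignment:
    """LCA over the group's accession taxa.

    ``mode='first_iteration'`` votes with the majority accessions only;
    ``'second_iteration'`` votes with all accessions.  Accessions absent from
    the accession->taxon map are recorded on the assignment; a group with no
    resolvable accession at all is assigned kingdom ``other`` with a null
    taxid (and a warning is logged).
    """
    if mode == "first_iteration":
        accs: Iterable[str] = sorted(majority_accessions(group))
    elif mode == "second_iteration":
        accs = group.majority_accessions
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    taxa = []
    unresolved = []
    for a in accs:
        t = taxmap.get(a)
        if t is None:
            unresolved.append(a)
        else:
            taxa.append(t)
    if not taxa:
        log.warning("group %s: no resolvable accession; kingdom=other", group.group_id)
        return LCAAssignment(
            group.group_id, None, None, KINGDOM_OTHER, False, tuple(unresolved)
        )
    lca_taxid, lca_rank = tree.lca(taxa)
    bacteria = tree.find_by_name("Bacteria")
    kingdom = _kingdom_of(tree, lca_taxid, bacteria)
    return LCAAssignment(
        group.group_id, lca_taxid, lca_rank, kingdom, False, tuple(unresolved)
    )


def apply_human_override(
    assignment: LCAAssignment, tree: TaxonomyTree, mode: str = "ancestor"
) -> LCAAssignment:
    """Re-label primate-ambiguous LCAs as human.

    ``mode='exact'`` fires only when the LCA *is* Catarrhini; the default
    ``'ancestor'`` additionally fires for any above-species LCA inside the
    Catarrhini clade (e.g. the genus Homo, or the family Hominidae), since
    such assignments are primate-ambiguous in the same way.  A clean
    species-level assignment to a non-human primate is left untouched.
    Idempotent: a human assignment is returned unchanged.
    """
    if assignment.lca_taxid is None:
        return assignment
    cat = tree.find_by_name(CATARRHINI_NAME)
    if cat is None:
        return assignment
    tid = tree.resolve_id(assignment.lca_taxid)
    if tid == HUMAN_TAXID:
        return assignment
    fire = tid == cat
    if not fire and mode == "ancestor":
        fire = cat in tree.lineage(tid) and assignment.lca_rank not in SPECIES_OR_BELOW
    if not fire:
        return assignment
    return replace(
        assignment,
        lca_taxid=HUMAN_TAXID,
        lca_rank="species",
        kingdom=KINGDOM_HUMAN,
        human_override_applied=True,
    )


def assign_all(
    groups: list[ProteinGroup],
    taxmap: Mapping[str, int],
    tree: TaxonomyTree,
    mode: str = "first_iteration",
    override_mode: str = "ancestor",
) -> list[LCAAssignment]:
    """Assign and human-override every group."""
    return [
        apply_human_override(assign_lca(g, taxmap, tree, mode), tree, override_mode)
        for g in groups
    ]


# -- search-space reduction ------------------------------------------------


def _record_taxid(record, sidecar: Mapping[str, int] | None) -> int:
    if sidecar is not None and record.id in sidecar:
        return sidecar[record.id]
    for token in record.description.split():
        if token.startswith("OX="):
            return int(token[3:])
    raise FormatError(f"FASTA record {record.id!r} carries no taxon annotation")


def build_reduced_database(
    assignments: Iterable[LCAAssignment],
    tree: TaxonomyTree,
    db: str | PathLike,
    out: str | PathLike,
    taxmap: Mapping[str, int] | None = None,
) -> int:
    """Write the reduced FASTA for the second identification pass.

    Keeps every record whose taxon falls under a genus- or species-rank LCA
    (including all descendants of those taxa); sub-species LCAs are promoted
    to their species before expansion.  When any assignment is human, all
    human records are kept as well.  Record order is preserved.  Taxon
    annotation comes from a sidecar accession->taxid map or an ``OX=`` header
    token, the sidecar taking precedence.  Returns the number of records
    written.
    """
    allowed: set[int] = set()
    any_human = False
    for a in assignments:
        if a.kingdom == KINGDOM_HUMAN:
            any_human = True
        if a.lca_taxid is None:
            continue
        tid = tree.resolve_id(a.lca_taxid)
        rank = tree.rank(tid)
        if rank in SPECIES_OR_BELOW and rank != "species":
            promoted = tree.ancestor_at_rank(tid, "species")
            if promoted is not None:
                log.info("promoted sub-species LCA %d to species %d", tid, promoted)
                tid, rank = promoted, "species"
        if rank in ("genus", "species"):
            allowed |= tree.descendants(tid)
    if any_human:
        allowed |= tree.descendants(HUMAN_TAXID)

    n = 0
    with open(out, "w", encoding="utf-8") as fh:
        for record in SeqIO.parse(str(db), "fasta"):
            tid = _record_taxid(record, taxmap)
            if tree.resolve_id(tid) in allowed:
                SeqIO.write(record, fh, "fasta-2line")
                n += 1
    return n


def write_assignments(
    assignments: Iterable[LCAAssignment], tree: TaxonomyTree, path: str | PathLike
) -> None:
    """TSV: group-id, lca_taxid, lca_name, lca_rank, kingdom, override-flag."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group_id\tlca_taxid\tlca_name\tlca_rank\tkingdom\thuman_override\n")
        for a in assignments:
            tid = "" if a.lca_taxid is None else str(a.lca_taxid)
            name = "" if a.lca_taxid is None else tree.name(a.lca_taxid)
            rank = a.lca_rank or ""
            fh.write(
                f"{a.group_id}\t{tid}\t{name}\t{rank}\t{a.kingdom}\t"
                f"{int(a.human_override_applied)}\n"
            )
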
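import pytest
from Bio import SeqIO

from salimet.errors import FormatError
from salimet.lca import (
    KINGDOM_BACTERIA,
    KINGDOM_HUMAN,
    KINGDOM_OTHER,
    apply_human_override,
    assign_lca,
    build_reduced_database,
    majority_accessions,
)

from conftest import make_group

TAXMAP = {
    "HUM": 9606,
    "MAC": 9544,
    "SAL1": 1304,   # S. salivarius
    "SAL2": 1304,
    "MIT": 28037,   # S. mitis (same genus)
    "LAC": 1358,    # L. lactis (same family, other genus)
    "BOS": 9913,
}


class TestMajority:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"A": 5, "B": 5, "C": 2}, {"A", "B"}),
            ({"A": 3}, {"A"}),
            ({"A": 1, "B": 1, "C": 1}, {"A", "B", "C"}),
        ],
    )
    def test_all_tied_top_accessions_kept(self, counts, expected):
        g = make_group(accs=tuple(counts), counts=tuple(counts.values()))
        assert majority_accessions(g) == expected


class TestAssign:
    def test_within_species_group_is_that_species(self, tree):
        g = make_group(accs=("SAL1", "SAL2"), counts=(3, 3))
        a = assign_lca(g, TAXMAP, tree)
        assert (a.lca_taxid, a.lca_rank, a.kingdom) == (1304, "species", KINGDOM_BACTERIA)

    def test_primate_ambiguous_group_becomes_human(self, tree):
        g = make_group(accs=("HUM", "MAC"), counts=(4, 4))
        a = assign_lca(g, TAXMAP, tree)
        assert (a.lca_taxid, a.lca_rank) == (9526, "parvorder")
        a = apply_human_override(a, tree)
        assert (a.lca_taxid, a.kingdom, a.human_override_applied) == (
            9606, KINGDOM_HUMAN, True,
        )

    def test_mode_changes_voting_set(self, tree):
        # majority accession is one species; the minority one is another
        # genus of the same family, so the all-accession LCA climbs to family
        g = make_group(accs=("SAL1", "LAC"), counts=(4, 1))
        first = assign_lca(g, TAXMAP, tree, "first_iteration")
        second = assign_lca(g, TAXMAP, tree, "second_iteration")
        assert (first.lca_taxid, first.lca_rank) == (1304, "species")
        assert (second.lca_taxid, second.lca_rank) == (1300, "family")

    def test_unresolvable_accessions_recorded(self, tree):
        g = make_group(accs=("NOPE",), counts=(2,))
        a = assign_lca(g, TAXMAP, tree)
        assert a.kingdom == KINGDOM_OTHER
        assert a.lca_taxid is None
        assert a.unresolved_accessions == ("NOPE",)

    def test_food_protein_is_other(self, tree):
        a = assign_lca(make_group(accs=("BOS",), counts=(2,)), TAXMAP, tree)
        assert a.kingdom == KINGDOM_OTHER

    def test_second_iteration_never_deeper_than_first(self, tree, cohort):
        for g in cohort.groups[::17]:
            first = assign_lca(g, cohort.taxmap, tree, "first_iteration")
            second = assign_lca(g, cohort.taxmap, tree, "second_iteration")
            # the all-accession LCA must be an ancestor-or-equal of the
            # majority-accession LCA
            assert second.lca_taxid in tree.lineage(first.lca_taxid)


class TestOverride:
    def test_bacterial_genus_unchanged(self, tree):
        a = assign_lca(make_group(accs=("SAL1", "MIT"), counts=(2, 2)), TAXMAP, tree)
        assert apply_human_override(a, tree) == a

    def test_human_species_unchanged_flag_unset(self, tree):
        a = assign_lca(make_group(accs=("HUM",), counts=(2,)), TAXMAP, tree)
        out = apply_human_override(a, tree)
        assert out == a and not out.human_override_applied

    def test_idempotent(self, tree):
        a = assign_lca(make_group(accs=("HUM", "MAC"), counts=(2, 2)), TAXMAP, tree)
        once = apply_human_override(a, tree)
        assert apply_human_override(once, tree) == once

    def test_ancestor_mode_catches_internal_primate_nodes(self, tree):
        # LCA at genus Homo (internal, above species, inside Catarrhini)
        taxmap = {"H1": 9606, "H2": 9605}
        a = assign_lca(make_group(accs=("H1", "H2"), counts=(2, 2)), taxmap, tree)
        assert a.lca_taxid == 9605
        assert apply_human_override(a, tree, "ancestor").kingdom == KINGDOM_HUMAN
        assert apply_human_override(a, tree, "exact") == a

    def test_clean_macaque_species_not_overridden(self, tree):
        a = assign_lca(make_group(accs=("MAC",), counts=(2,)), {"MAC": 9544}, tree)
        assert apply_human_override(a, tree) == a


@pytest.fixture()
def fasta(tmp_path):
    records = [
        ("SAL1", 1304), ("MIT", 28037), ("ORA", 1303), ("PARA", 1318),
        ("MITB6", 365659), ("LAC", 1358), ("HUM", 9606), ("PREV", 28132),
    ]
    p = tmp_path / "db.fasta"
    with open(p, "w") as fh:
        for acc, ox in records:
            fh.write(f">{acc} OX={ox}\nMSEQ\n")
    return p


def _ids(path):
    return [r.id for r in SeqIO.parse(str(path), "fasta")]


class TestReducedDatabase:
    def test_genus_assignment_pulls_all_genus_records(self, tree, fasta, tmp_path):
        g = make_group(accs=("SAL1", "MIT"), counts=(2, 2))
        a = assign_lca(g, TAXMAP, tree)
        assert a.lca_rank == "genus"
        out = tmp_path / "red.fasta"
        build_reduced_database([a], tree, fasta, out)
        # every Streptococcus record, incl. the strain, in original order
        assert _ids(out) == ["SAL1", "MIT", "ORA", "PARA", "MITB6"]

    def test_species_assignment_includes_strain_descendants(self, tree, fasta, tmp_path):
        a = assign_lca(make_group(accs=("MIT",), counts=(2,)), TAXMAP, tree)
        out = tmp_path / "red.fasta"
        build_reduced_database([a], tree, fasta, out)
        assert _ids(out) == ["MIT", "MITB6"]

    def test_subspecies_lca_promoted_to_species(self, tree, fasta, tmp_path):
        a = assign_lca(make_group(accs=("MB6",), counts=(2,)), {"MB6": 365659}, tree)
        assert a.lca_rank == "strain"
        out = tmp_path / "red.fasta"
        build_reduced_database([a], tree, fasta, out)
        assert _ids(out) == ["MIT", "MITB6"]

    def test_no_eligible_assignment_gives_empty_output(self, tree, fasta, tmp_path):
        a = assign_lca(make_group(accs=("SAL1", "LAC"), counts=(2, 2)), TAXMAP, tree)
        assert a.lca_rank == "family"
        out = tmp_path / "red.fasta"
        assert build_reduced_database([a], tree, fasta, out) == 0

    def test_human_assignment_brings_human_records(self, tree, fasta, tmp_path):
        a = assign_lca(make_group(accs=("HUM",), counts=(2,)), TAXMAP, tree)
        out = tmp_path / "red.fasta"
        build_reduced_database([a], tree, fasta, out)
        assert _ids(out) == ["HUM"]

    def test_monotone_in_assignments(self, tree, fasta, tmp_path):
        a1 = assign_lca(make_group(accs=("MIT",), counts=(2,)), TAXMAP, tree)
        a2 = assign_lca(make_group(accs=("PREV",), counts=(2,)), {"PREV": 28132}, tree)
        small, big = tmp_path / "a.fasta", tmp_path / "b.fasta"
        build_reduced_database([a1], tree, fasta, small)
        build_reduced_database([a1, a2], tree, fasta, big)
        assert set(_ids(small)) <= set(_ids(big))

    def test_unannotated_record_is_format_error(self, tree, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">X no taxon here\nMSEQ\n")
        a = assign_lca(make_group(accs=("MIT",), counts=(2,)), TAXMAP, tree)
        with pytest.raises(FormatError, match="X"):
            build_reduced_database([a], tree, p, tmp_path / "out.fasta")

    def test_sidecar_wins_over_header_token(self, tree, tmp_path):
        p = tmp_path / "db.fasta"
        p.write_text(">X OX=9606\nMSEQ\n")
        a = assign_lca(make_group(accs=("MIT",), counts=(2,)), TAXMAP, tree)
        out = tmp_path / "out.fasta"
        # sidecar re-annotates X as S. mitis -> kept despite the human header
        build_reduced_database([a], tree, p, out, taxmap={"X": 28037})
        assert _ids(out) == ["X"]
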
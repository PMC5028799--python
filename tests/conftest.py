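import numpy as np
import pytest

from salimet.proteingroups import ProteinGroup, SampleDesign
from salimet.simulate import CohortSpec, fixture_tree, simulate_cohort
from salimet.taxonomy import TaxonomyTree


@pytest.fixture(scope="session")
def tree() -> TaxonomyTree:
    return fixture_tree()


@pytest.fixture(scope="session")
def cohort():
    """One default cohort shared across tests (seed fixed)."""
    return simulate_cohort(CohortSpec(seed=11))


@pytest.fixture()
def toy_tree() -> TaxonomyTree:
    """Hand-written 8-node tree: one genus with 3 species, one with 2 strains.

        root(1) -- Bacteria(2, superkingdom) -- GenusG(10, genus)
            species 11, 12, 13; 11 has strains 111, 112
    """
    nodes = {
        1: (1, "no rank"),
        2: (1, "superkingdom"),
        10: (2, "genus"),
        11: (10, "species"),
        12: (10, "species"),
        13: (10, "species"),
        111: (11, "strain"),
        112: (11, "strain"),
    }
    names = {
        1: "root",
        2: "Bacteria",
        10: "Genus G",
        11: "Species A",
        12: "Species B",
        13: "Species C",
        111: "Species A str. 1",
        112: "Species A str. 2",
    }
    t = TaxonomyTree(nodes=nodes, names=names, merged={7: 12}, root=1)
    t.validate()
    return t


def make_group(gid=0, accs=("A",), counts=None, unique=2, razor=2, intensities=None):
    accs = list(accs)
    counts = dict(zip(accs, counts)) if counts else {a: 1 for a in accs}
    return ProteinGroup(
        group_id=gid,
        majority_accessions=accs,
        peptide_counts=counts,
        unique_peptide_count=unique,
        razor_unique_count=razor,
        intensities=intensities or {},
    )


@pytest.fixture()
def two_group_design() -> SampleDesign:
    samples = [f"c{i}" for i in range(10)] + [f"h{i}" for i in range(10)]
    labels = {s: ("caries" if s.startswith("c") else "healthy") for s in samples}
    return SampleDesign(samples, labels)


def random_tree(rng: np.random.Generator, n: int = 50) -> TaxonomyTree:
    """Random rooted tree over ids 1..n (node i's parent drawn among 1..i-1)."""
    nodes = {1: (1, "no rank")}
    for i in range(2, n + 1):
        nodes[i] = (int(rng.integers(1, i)), "no rank")
    return TaxonomyTree(nodes=nodes, names={i: f"n{i}" for i in nodes}, root=1)


def brute_force_lca(tree: TaxonomyTree, taxa) -> int:
    """Oracle: intersect full lineage lists, return the deepest shared node."""
    lineages = [tree.lineage(t).taxids() for t in taxa]
    shared = set(lineages[0])
    for lin in lineages[1:]:
        shared &= set(lin)
    # deepest = the shared node with the longest root path
    return max(shared, key=lambda t: len(tree.lineage(t)))
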
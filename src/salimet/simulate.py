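"""Seedable synthetic cohorts with planted ground truth.

Emulates the study design end to end: a 3-group x 10-sample saliva cohort of
~4,000 protein groups of mixed human / bacterial / food origin, with

* a fixture taxonomy (NCBI-dump dialect) holding both superkingdoms, a
  primate clade with the parvorder Catarrhini (human + macaque), ten oral
  bacterial genera with 22 species and a few strains, and food taxa;
* log-normal intensities whose kingdom means are scaled to the 95/3/2
  human/bacteria/other biomass split;
* a genus abundance profile whose top five genera carry ~70% of the
  bacterial mass, with planted disease effects (Veillonella up in caries,
  Fusobacterium up in periodontitis, Haemophilus down in both);
* planted differentially abundant human proteins in three response patterns
  (up in both diseases / caries-specific / periodontitis-specific);
* intensity-dependent missingness, accession sets engineered to land LCAs at
  strain/species/genus/family level, primate-ambiguous (Catarrhini) groups,
  and HMM hit tables plus NOG->term maps for the annotation stage.

Every file the generator writes parses through the corresponding reader, and
identical seeds give byte-identical output (intensities are serialised at
fixed precision).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from os import PathLike
from pathlib import Path

import numpy as np

from .lca import KINGDOM_BACTERIA, KINGDOM_HUMAN, KINGDOM_OTHER
from .proteingroups import ProteinGroup, SampleDesign, write_protein_groups
from .taxonomy import TaxonomyTree, load_taxonomy

# ---------------------------------------------------------------------------
# fixture taxonomy: (taxid, parent, rank, scientific name)

_TAXA: list[tuple[int, int, str, str]] = [
    (1, 1, "no rank", "root"),
    # eukaryotes: primates, food animals, food plants
    (2759, 1, "superkingdom", "Eukaryota"),
    (33208, 2759, "kingdom", "Metazoa"),
    (7711, 33208, "phylum", "Chordata"),
    (40674, 7711, "class", "Mammalia"),
    (9443, 40674, "order", "Primates"),
    (9526, 9443, "parvorder", "Catarrhini"),
    (9604, 9526, "family", "Hominidae"),
    (9605, 9604, "genus", "Homo"),
    (9606, 9605, "species", "Homo sapiens"),
    (9527, 9526, "family", "Cercopithecidae"),
    (9539, 9527, "genus", "Macaca"),
    (9544, 9539, "species", "Macaca mulatta"),
    (9895, 40674, "family", "Bovidae"),
    (9903, 9895, "genus", "Bos"),
    (9913, 9903, "species", "Bos taurus"),
    (33090, 2759, "kingdom", "Viridiplantae"),
    (35493, 33090, "phylum", "Streptophyta"),
    (4479, 35493, "family", "Poaceae"),
    (4564, 4479, "genus", "Triticum"),
    (4565, 4564, "species", "Triticum aestivum"),
    (3803, 35493, "family", "Fabaceae"),
    (3846, 3803, "genus", "Glycine"),
    (3847, 3846, "species", "Glycine max"),
    # bacteria: five phyla, eight oral families, ten genera
    (2, 1, "superkingdom", "Bacteria"),
    (1239, 2, "phylum", "Firmicutes"),
    (1300, 1239, "family", "Streptococcaceae"),
    (1301, 1300, "genus", "Streptococcus"),
    (1304, 1301, "species", "Streptococcus salivarius"),
    (28037, 1301, "species", "Streptococcus mitis"),
    (1303, 1301, "species", "Streptococcus oralis"),
    (1318, 1301, "species", "Streptococcus parasanguinis"),
    (365659, 28037, "strain", "Streptococcus mitis B6"),
    (1357, 1300, "genus", "Lactococcus"),
    (1358, 1357, "species", "Lactococcus lactis"),
    (31977, 1239, "family", "Veillonellaceae"),
    (29465, 31977, "genus", "Veillonella"),
    (39777, 29465, "species", "Veillonella atypica"),
    (29466, 29465, "species", "Veillonella parvula"),
    (39778, 29465, "species", "Veillonella dispar"),
    (479436, 29466, "strain", "Veillonella parvula DSM 2008"),
    (970, 31977, "genus", "Selenomonas"),
    (69823, 970, "species", "Selenomonas sputigena"),
    (976, 2, "phylum", "Bacteroidetes"),
    (171552, 976, "family", "Prevotellaceae"),
    (838, 171552, "genus", "Prevotella"),
    (28132, 838, "species", "Prevotella melaninogenica"),
    (470565, 838, "species", "Prevotella histicola"),
    (255745, 838, "species", "Prevotella salivae"),
    (201174, 2, "phylum", "Actinobacteria"),
    (1268, 201174, "family", "Micrococcaceae"),
    (32207, 1268, "genus", "Rothia"),
    (43675, 32207, "species", "Rothia mucilaginosa"),
    (2047, 32207, "species", "Rothia dentocariosa"),
    (1224, 2, "phylum", "Proteobacteria"),
    (481, 1224, "family", "Neisseriaceae"),
    (482, 481, "genus", "Neisseria"),
    (484, 482, "species", "Neisseria flavescens"),
    (28449, 482, "species", "Neisseria subflava"),
    (712, 1224, "family", "Pasteurellaceae"),
    (724, 712, "genus", "Haemophilus"),
    (729, 724, "species", "Haemophilus parainfluenzae"),
    (727, 724, "species", "Haemophilus influenzae"),
    (32066, 2, "phylum", "Fusobacteria"),
    (203492, 32066, "family", "Fusobacteriaceae"),
    (848, 203492, "genus", "Fusobacterium"),
    (851, 848, "species", "Fusobacterium nucleatum"),
    (860, 848, "species", "Fusobacterium periodonticum"),
    (190304, 851, "strain", "Fusobacterium nucleatum ATCC 25586"),
    (1129771, 32066, "family", "Leptotrichiaceae"),
    (32067, 1129771, "genus", "Leptotrichia"),
    (40542, 32067, "species", "Leptotrichia buccalis"),
    (157687, 32067, "species", "Leptotrichia wadei"),
]

#: retired ids kept in merged.dmp so alias resolution is exercised
_MERGED: list[tuple[int, int]] = [(999001, 1304), (999002, 9606)]

#: species pool per genus for the abundance-profiled genera
_GENUS_SPECIES: dict[str, list[int]] = {
    "Streptococcus": [1304, 28037, 1303, 1318],
    "Prevotella": [28132, 470565, 255745],
    "Veillonella": [39777, 29466, 39778],
    "Rothia": [43675, 2047],
    "Neisseria": [484, 28449],
    "Haemophilus": [729, 727],
    "Fusobacterium": [851, 860],
    "Leptotrichia": [40542, 157687],
}

#: species with strain children (for strain-level LCAs)
_SPECIES_STRAINS: dict[int, list[int]] = {28037: [365659], 29466: [479436], 851: [190304]}

#: cross-genus pairs sharing a family (for family-level LCAs)
_FAMILY_PAIRS: list[tuple[int, int]] = [(1304, 1358), (39777, 69823)]

FOOD_SPECIES = [9913, 4565, 3847]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

KEGG_UNIVERSE = [f"ko{n:05d}" for n in (
    10, 20, 30, 40, 51, 190, 230, 240, 250, 260, 270, 280, 290, 300, 330,
    400, 500, 520, 550, 561, 620, 630, 640, 650, 660, 670, 680, 710, 720, 910,
)]
GO_UNIVERSE = [f"GO:{n:07d}" for n in range(6950, 6950 + 40)]


@dataclass
class CohortSpec:
    """Study conditions for the synthetic cohort.

    Defaults mirror the study design: three groups of ten samples; ~4,000
    protein groups split 2,000 human / 1,900 bacterial / 100 food-or-other;
    95/3/2 biomass; an oral genus profile whose top five genera carry ~70%
    of bacterial mass; 60 differential human proteins at a 2-log2-unit
    (4-fold) shift, the size typical of salivary inflammation markers; and
    LCA-level fractions chosen so ~92% of bacterial groups map to genus
    level and ~34% to species level or below.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"periodontitis": 10, "caries": 10, "healthy": 10}
    )
    n_human: int = 2000
    n_bacterial: int = 1900
    n_other: int = 100
    biomass: dict[str, float] = field(
        default_factory=lambda: {"human": 0.95, "bacteria": 0.03, "other": 0.02}
    )
    #: baseline relative bacterial mass per genus; the five most predominant
    #: (Streptococcus, Prevotella, Veillonella, Rothia, Neisseria) carry 70%
    genus_profile: dict[str, float] = field(
        default_factory=lambda: {
            "Streptococcus": 0.22,
            "Prevotella": 0.14,
            "Veillonella": 0.12,
            "Rothia": 0.11,
            "Neisseria": 0.11,
            "Haemophilus": 0.10,
            "Fusobacterium": 0.10,
            "Leptotrichia": 0.10,
        }
    )
    #: (genus, sample-group) -> intensity fold change relative to healthy
    genus_effects: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("Veillonella", "caries"): 3.0,
            ("Fusobacterium", "periodontitis"): 3.0,
            ("Haemophilus", "caries"): 1 / 3,
            ("Haemophilus", "periodontitis"): 1 / 3,
        }
    )
    n_diff_human: int = 60
    diff_effect: float = 2.0  # log2 units
    #: per-sample inflammation severity spread; planted human proteins are
    #: co-regulated through one severity score per sample (disease samples
    #: centred at 1, healthy baseline inflammation centred at 0)
    severity_sd: float = 0.3
    healthy_severity_sd: float = 0.15
    #: spread of per-protein inflammation responsiveness across the whole
    #: human proteome (oral inflammation shifts saliva composition broadly,
    #: e.g. through serum leakage, not only through the headline markers)
    inflammation_loading_sd: float = 0.3
    between_sd: float = 1.5  # protein baseline spread, log2 units
    within_sd: float = 0.8  # per-sample noise, log2 units
    genus_sample_sd: float = 0.3  # per-(sample, genus) biological wobble
    missing_rate: float = 0.10
    mu_bacteria: float = 22.0  # log2 baseline for bacterial proteins
    #: bacterial LCA-level mix: strain + species ~= species-mapped share,
    #: + genus ~= genus-mapped share; remainder lands at family
    frac_strain: float = 0.02
    frac_species: float = 0.32
    frac_genus: float = 0.58
    #: share of human groups made primate-ambiguous (Catarrhini LCA)
    frac_catarrhini: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs >= 2 samples")
        if abs(sum(self.biomass.values()) - 1.0) > 1e-9:
            raise ValueError("biomass targets must sum to 1")
        if not all(0 < f < 1 for f in self.biomass.values()):
            raise ValueError("biomass fractions must lie in (0, 1)")
        if self.n_diff_human > self.n_human:
            raise ValueError("more planted differential proteins than human proteins")
        if self.frac_strain + self.frac_species + self.frac_genus > 1.0 + 1e-9:
            raise ValueError("LCA level fractions exceed 1")


@dataclass
class GroundTruth:
    """Bookkeeping consistent with the emitted files."""

    kingdom: dict[int, str]  # group id -> kingdom
    lca: dict[int, int]  # group id -> true all-accession LCA taxid
    lca_level: dict[int, str]  # strain | species | genus | family | catarrhini | human | other
    diff_human: dict[int, str]  # group id -> planted response pattern
    genus_of_group: dict[int, str]  # bacterial group id -> source genus
    genus_abundance: dict[str, dict[str, float]]  # sample group -> genus -> expected share


@dataclass
class Cohort:
    spec: CohortSpec
    design: SampleDesign
    groups: list[ProteinGroup]
    taxmap: dict[str, int]  # accession -> taxid
    sequences: dict[str, str]  # accession -> amino-acid sequence
    hmm_hits: dict[str, list[tuple[str, float, int, int]]]  # acc -> (nog, E, start, end)
    nog_terms: dict[str, tuple[list[str], list[str]]]  # nog -> (GO list, KEGG list)
    truth: GroundTruth


# -- taxonomy emission -----------------------------------------------------


def write_taxonomy_dumps(outdir: str | PathLike) -> dict[str, Path]:
    """Write nodes/names/merged dumps plus name-map TSVs; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "nodes": outdir / "nodes.dmp",
        "names": outdir / "names.dmp",
        "merged": outdir / "merged.dmp",
        "name_map": outdir / "name_map.tsv",
    }
    with open(paths["nodes"], "w", encoding="utf-8") as fh:
        for tid, parent, rank, _ in _TAXA:
            fh.write(f"{tid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(paths["names"], "w", encoding="utf-8") as fh:
        for tid, _, _, name in _TAXA:
            fh.write(f"{tid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")
    with open(paths["merged"], "w", encoding="utf-8") as fh:
        for old, new in _MERGED:
            fh.write(f"{old}\t|\t{new}\t|\n")
    with open(paths["name_map"], "w", encoding="utf-8") as fh:
        fh.write("name\ttaxid\n")
        for tid, _, rank, name in _TAXA:
            if rank in ("species", "strain"):
                fh.write(f"{name}\t{tid}\n")
    return paths


def simulate_taxonomy(outdir: str | PathLike) -> TaxonomyTree:
    """Emit the fixture taxonomy dumps and load them back (round-trip)."""
    paths = write_taxonomy_dumps(outdir)
    return load_taxonomy(paths["nodes"], paths["names"], paths["merged"])


def fixture_tree() -> TaxonomyTree:
    """The fixture taxonomy as an in-memory tree (no files touched)."""
    nodes = {tid: (parent, rank) for tid, parent, rank, _ in _TAXA}
    names = {tid: name for tid, _, _, name in _TAXA}
    tree = TaxonomyTree(nodes=nodes, names=names, merged=dict(_MERGED), root=1)
    tree.validate()
    return tree


# -- cohort simulation -----------------------------------------------------


def _design(spec: CohortSpec) -> SampleDesign:
    prefix = {"periodontitis": "P", "caries": "C", "healthy": "H"}
    samples, labels = [], {}
    for g, n in spec.group_sizes.items():
        p = prefix.get(g, g[:1].upper())
        for i in range(1, n + 1):
            s = f"{p}{i:02d}"
            samples.append(s)
            labels[s] = g
    return SampleDesign(samples, labels)


def _kingdom_means(spec: CohortSpec) -> dict[str, float]:
    """log2 means per kingdom scaled so expected summed intensity hits the
    biomass targets (log-normal mean factor cancels: equal sigma)."""
    b = spec.biomass
    mu_b = spec.mu_bacteria
    n_b = max(spec.n_bacterial, 1)
    mu_h = mu_b + np.log2((b["human"] / b["bacteria"]) * (n_b / max(spec.n_human, 1)))
    mu_o = mu_b + np.log2((b["other"] / b["bacteria"]) * (n_b / max(spec.n_other, 1)))
    return {KINGDOM_HUMAN: mu_h, KINGDOM_BACTERIA: mu_b, KINGDOM_OTHER: mu_o}


def simulate_cohort(spec: CohortSpec, rng: np.random.Generator | None = None) -> Cohort:
    """Draw a complete cohort with planted ground truth (in memory)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    design = _design(spec)
    samples = design.samples
    ns = len(samples)
    mu = _kingdom_means(spec)
    genera = list(spec.genus_profile)
    profile = np.array([spec.genus_profile[g] for g in genera])
    profile = profile / profile.sum()

    groups: list[ProteinGroup] = []
    taxmap: dict[str, int] = {}
    truth = GroundTruth({}, {}, {}, {}, {}, {})

    # expected genus shares per sample group (planted effects applied, renormalised)
    for sg in design.groups:
        w = {
            g: spec.genus_profile[g] * spec.genus_effects.get((g, sg), 1.0)
            for g in genera
        }
        tot = sum(w.values())
        truth.genus_abundance[sg] = {g: w[g] / tot for g in genera}

    # per-(sample, genus) biological wobble, shared across that genus' proteins
    genus_wobble = {
        g: rng.normal(0.0, spec.genus_sample_sd, size=ns) for g in genera
    }

    gid = 0

    def _emit(accs, baseline, offsets, kingdom, lca, level):
        nonlocal gid
        x = baseline + offsets + rng.normal(0.0, spec.within_sd, size=ns)
        # intensity-dependent missingness: low-abundance values vanish more
        centre = baseline - spec.within_sd
        p_miss = 2 * spec.missing_rate / (1.0 + np.exp((x - centre)))
        missing = rng.random(ns) < p_miss
        inten = np.where(missing, 0.0, np.exp2(x))
        # peptide counts scale with log-intensity; min 1
        lam = max(baseline / 3.0, 1.0)
        pep = {}
        if level == "catarrhini":
            shared = int(max(1, rng.poisson(lam)))
            pep = {a: shared for a in accs}  # tie -> both accessions majority
        else:
            for a in accs:
                pep[a] = int(max(1, rng.poisson(lam)))
        maxpep = max(pep.values())
        unique = int(rng.binomial(maxpep, 0.75))
        razor = unique + int(rng.poisson(1.2))
        groups.append(
            ProteinGroup(
                group_id=gid,
                majority_accessions=list(accs),
                peptide_counts=pep,
                unique_peptide_count=unique,
                razor_unique_count=razor,
                intensities=dict(zip(samples, inten.tolist())),
            )
        )
        truth.kingdom[gid] = kingdom
        truth.lca[gid] = lca
        truth.lca_level[gid] = level
        gid += 1

    # ---- human proteins ---------------------------------------------------
    diff_ids = rng.choice(spec.n_human, size=spec.n_diff_human, replace=False)
    patterns = ["both", "caries", "periodontitis"]
    pattern_of = {int(i): patterns[k % 3] for k, i in enumerate(np.sort(diff_ids))}
    n_cat = int(round(spec.frac_catarrhini * spec.n_human))
    group_of_sample = np.array([design.group(s) for s in samples])
    # shared per-sample inflammation severity: planted proteins co-vary with
    # it when the sample's group belongs to the protein's response pattern,
    # and with a baseline-inflammation score otherwise
    is_healthy = group_of_sample == "healthy"
    baseline_inflammation = rng.normal(0.0, spec.healthy_severity_sd, size=ns)
    severity = np.where(
        is_healthy,
        baseline_inflammation,
        rng.normal(1.0, spec.severity_sd, size=ns),
    )
    for i in range(spec.n_human):
        acc = f"HUP{i:05d}"
        taxmap[acc] = 9606
        baseline = rng.normal(mu[KINGDOM_HUMAN], spec.between_sd)
        loading = rng.normal(0.0, spec.inflammation_loading_sd)
        offsets = loading * severity
        pat = pattern_of.get(i)
        if pat is not None:
            up_in = ("caries", "periodontitis") if pat == "both" else (pat,)
            expressing = np.isin(group_of_sample, up_in)
            offsets = offsets + spec.diff_effect * np.where(
                expressing, severity, baseline_inflammation
            )
        if i < n_cat:
            macc = f"MAC{i:05d}"
            taxmap[macc] = 9544
            _emit([acc, macc], baseline, offsets, KINGDOM_HUMAN, 9526, "catarrhini")
        else:
            _emit([acc], baseline, offsets, KINGDOM_HUMAN, 9606, "human")
        if pat is not None:
            truth.diff_human[gid - 1] = pat

    # ---- food / other proteins -------------------------------------------
    for i in range(spec.n_other):
        acc = f"FOO{i:04d}"
        sp = FOOD_SPECIES[i % len(FOOD_SPECIES)]
        taxmap[acc] = sp
        baseline = rng.normal(mu[KINGDOM_OTHER], spec.between_sd)
        _emit([acc], baseline, np.zeros(ns), KINGDOM_OTHER, sp, "other")

    # ---- bacterial protein groups ----------------------------------------
    level_p = np.array(
        [spec.frac_strain, spec.frac_species, spec.frac_genus]
    )
    level_p = np.append(level_p, max(0.0, 1.0 - level_p.sum()))
    levels = np.array(["strain", "species", "genus", "family"])
    fam_tree = fixture_tree()
    genus_idx = rng.choice(len(genera), size=spec.n_bacterial, p=profile)
    level_choice = rng.choice(4, size=spec.n_bacterial, p=level_p)
    for i in range(spec.n_bacterial):
        genus = genera[genus_idx[i]]
        level = levels[level_choice[i]]
        species_pool = _GENUS_SPECIES[genus]
        if level == "strain":
            with_strains = [s for s in species_pool if s in _SPECIES_STRAINS]
            if not with_strains:
                level = "species"
        if level == "family":
            s1, s2 = _FAMILY_PAIRS[int(rng.integers(len(_FAMILY_PAIRS)))]
            taxa = [s1, s2]
        elif level == "genus":
            if len(species_pool) >= 2:
                pick = rng.choice(len(species_pool), size=2, replace=False)
                taxa = [species_pool[pick[0]], species_pool[pick[1]]]
            else:
                taxa, level = [species_pool[0]], "species"
        elif level == "strain":
            sp = with_strains[int(rng.integers(len(with_strains)))]
            taxa = [_SPECIES_STRAINS[sp][0]]
        else:
            sp = species_pool[int(rng.integers(len(species_pool)))]
            taxa = [sp] * int(rng.integers(1, 3))
        accs = []
        for k, t in enumerate(taxa):
            acc = f"BAC{i:05d}_{k}"
            taxmap[acc] = t
            accs.append(acc)
        # intensity offsets: planted disease effect + per-sample genus wobble
        eff = np.array(
            [
                np.log2(spec.genus_effects.get((genus, design.group(s)), 1.0))
                for s in samples
            ]
        )
        offsets = eff + genus_wobble[genus]
        baseline = rng.normal(mu[KINGDOM_BACTERIA], spec.between_sd)
        if level == "family":
            lca = fam_tree.lca(taxa)[0]
        elif level == "genus":
            lca = {g: t for g, t in zip(genera, [1301, 838, 29465, 32207, 482, 724, 848, 32067])}[genus]
        else:
            lca = taxa[0]
        _emit(accs, baseline, offsets, KINGDOM_BACTERIA, int(lca), str(level))
        truth.genus_of_group[gid - 1] = genus

    # ---- sequences, HMM hits, NOG terms -----------------------------------
    sequences = {
        acc: "".join(rng.choice(AMINO_ACIDS, size=int(rng.integers(120, 320))))
        for acc in taxmap
    }
    nog_terms = {}
    for k in range(120):
        nog = f"NOG{k:04d}"
        kegg = list(rng.choice(KEGG_UNIVERSE, size=int(rng.integers(1, 3)), replace=False))
        go = list(rng.choice(GO_UNIVERSE, size=int(rng.integers(1, 4)), replace=False))
        nog_terms[nog] = (sorted(go), sorted(kegg))
    nogs = sorted(nog_terms)
    hmm_hits: dict[str, list[tuple[str, float, int, int]]] = {}
    for acc, tid in taxmap.items():
        if not acc.startswith("BAC"):
            continue
        length = len(sequences[acc])
        n_hits = int(rng.integers(1, 5))
        hits = []
        for _ in range(n_hits):
            nog = nogs[int(rng.integers(len(nogs)))]
            ev = float(10.0 ** rng.uniform(-12, -1))
            start = int(rng.integers(1, max(2, length - 60)))
            end = min(length, start + int(rng.integers(40, 90)))
            hits.append((nog, ev, start, end))
        hmm_hits[acc] = hits

    return Cohort(
        spec=spec,
        design=design,
        groups=groups,
        taxmap=taxmap,
        sequences=sequences,
        hmm_hits=hmm_hits,
        nog_terms=nog_terms,
        truth=truth,
    )


# -- file emission ---------------------------------------------------------


def write_cohort(cohort: Cohort, outdir: str | PathLike) -> dict[str, Path]:
    """Write every input file the pipeline consumes; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = write_taxonomy_dumps(outdir)
    paths["protein_groups"] = outdir / "proteinGroups.txt"
    paths["design"] = outdir / "design.tsv"
    paths["fasta"] = outdir / "database.fasta"
    paths["taxa_sidecar"] = outdir / "database.taxa.tsv"
    paths["hmm_hits"] = outdir / "hmm_hits.tsv"
    paths["nog_terms"] = outdir / "nog_terms.tsv"
    paths["ground_truth"] = outdir / "ground_truth.json"
    paths["manifest"] = outdir / "manifest.json"

    write_protein_groups(cohort.groups, cohort.design, paths["protein_groups"])
    with open(paths["design"], "w", encoding="utf-8") as fh:
        fh.write("sample\tgroup\n")
        for s in cohort.design.samples:
            fh.write(f"{s}\t{cohort.design.group(s)}\n")
    with open(paths["fasta"], "w", encoding="utf-8") as fh:
        for acc in sorted(cohort.sequences):
            fh.write(f">{acc} OX={cohort.taxmap[acc]}\n{cohort.sequences[acc]}\n")
    with open(paths["taxa_sidecar"], "w", encoding="utf-8") as fh:
        fh.write("accession\ttaxid\n")
        for acc in sorted(cohort.taxmap):
            fh.write(f"{acc}\t{cohort.taxmap[acc]}\n")
    with open(paths["hmm_hits"], "w", encoding="utf-8") as fh:
        fh.write("# target\tmodel\tevalue\tenv_start\tenv_end\n")
        for acc in sorted(cohort.hmm_hits):
            for nog, ev, start, end in cohort.hmm_hits[acc]:
                fh.write(f"{acc}\t{nog}\t{ev:.6e}\t{start}\t{end}\n")
    with open(paths["nog_terms"], "w", encoding="utf-8") as fh:
        fh.write("nog\tgo_terms\tkegg_pathways\n")
        for nog in sorted(cohort.nog_terms):
            go, kegg = cohort.nog_terms[nog]
            fh.write(f"{nog}\t{','.join(go)}\t{','.join(kegg)}\n")
    truth = cohort.truth
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "kingdom": truth.kingdom,
                "lca": truth.lca,
                "lca_level": truth.lca_level,
                "diff_human": truth.diff_human,
                "genus_of_group": truth.genus_of_group,
                "genus_abundance": truth.genus_abundance,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    manifest = {k: str(v) for k, v in paths.items() if k != "manifest"}
    manifest["seed"] = cohort.spec.seed
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return paths


def restrict_to_accessions(
    groups: list[ProteinGroup], accessions: set[str]
) -> list[ProteinGroup]:
    """Re-emit protein groups restricted to a reduced database.

    Stands in for the second identification pass: accessions absent from the
    reduced search space are dropped from each group, and groups left with no
    accession disappear.
    """
    out = []
    for g in groups:
        kept = [a for a in g.majority_accessions if a in accessions]
        if not kept:
            continue
        out.append(
            replace(
                g,
                majority_accessions=kept,
                peptide_counts={a: g.peptide_counts[a] for a in kept},
            )
        )
    return out
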
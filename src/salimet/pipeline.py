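"""Two-pass workflow orchestration, configuration and run reports.

The first pass reads the protein-group table from the broad search (full
curated database + oral microbiome database), applies the identification
filters, assigns majority-accession LCAs with the primate override, and
writes the reduced FASTA search space.  The second pass consumes the
protein-group table produced against that reduced space, assigns
all-accession LCAs, and runs the quantitative (biomass, abundance profiles,
between-group statistics, PCA, clustering) and functional (hit selection,
term mapping, KEGG enrichment, pathway characterisation) stages.  Reports
carry per-stage record counts in the style of an identification-overview
table: totals per kingdom, genus- and species-mapped counts and percentages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annot, lca, proteingroups as pg, quant
from .errors import SalimetError
from .taxonomy import TaxonomyTree, load_taxonomy

log = logging.getLogger(__name__)

ENRICH_COMPARISONS = (
    ("caries", "healthy"),
    ("periodontitis", "healthy"),
    ("periodontitis", "caries"),
)


@dataclass
class PipelineConfig:
    """All thresholds with their study defaults, plus file paths."""

    # paths
    protein_groups: str = ""
    nodes: str = ""
    names: str = ""
    merged: str = ""
    fasta: str = ""
    taxa_sidecar: str = ""
    design: str = ""
    hmm_hits: str = ""
    nog_terms: str = ""
    outdir: str = "run"
    # identification filter
    min_unique: int = 2
    min_samples: int = 5
    # quantification filter
    min_razor_unique: int = 2
    quant_min_samples: int = 5
    # statistics
    impute_constant: float = 19.0
    alpha: float = 0.05
    # functional annotation
    hmm_max_evalue: float = 1e-4
    hmm_max_overlap: int = 8
    enrich_fdr: float = 0.01
    fc_low: float = 0.5
    fc_high: float = 2.0
    coverage: float = 0.90
    # behaviour
    override_mode: str = "ancestor"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.enrich_fdr < 1 and 0 < self.coverage <= 1):
            raise ValueError("alpha, enrich_fdr and coverage must lie in (0, 1]")
        if self.fc_low >= self.fc_high:
            raise ValueError("fc_low must be below fc_high")
        if min(self.min_unique, self.min_samples, self.hmm_max_overlap) < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def pct(count: int, total: int) -> float:
    """Percentage to one decimal, the precision used in the overview table."""
    if total == 0:
        return 0.0
    return round(100.0 * count / total, 1)


def summarize_assignments(
    assignments: list[lca.LCAAssignment], tree: TaxonomyTree
) -> dict:
    """Identification-overview bookkeeping for a set of assignments.

    "Mapped to genus level" counts bacterial groups whose LCA rank is genus
    or any rank below it; species-level likewise (the nesting makes the
    genus count a superset of the species count).
    """
    kingdoms = {"human": 0, "bacteria": 0, "other": 0}
    genus_mapped = species_mapped = 0
    for a in assignments:
        kingdoms[a.kingdom] += 1
        if a.kingdom == lca.KINGDOM_BACTERIA and a.lca_taxid is not None:
            lin = tree.lineage(a.lca_taxid)
            ranks = {r for _, r in lin}
            if "genus" in ranks:
                genus_mapped += 1
            if "species" in ranks:
                species_mapped += 1
    total = len(assignments)
    nb = kingdoms["bacteria"]
    return {
        "total": total,
        "human": kingdoms["human"],
        "bacteria": nb,
        "other": kingdoms["other"],
        "kingdom_assigned_pct": pct(kingdoms["human"] + nb, total),
        "genus_mapped": genus_mapped,
        "genus_mapped_pct": pct(genus_mapped, nb),
        "species_mapped": species_mapped,
        "species_mapped_pct": pct(species_mapped, nb),
    }


@dataclass
class RunReport:
    stage: str
    counts: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _load_common(cfg: PipelineConfig):
    tree = load_taxonomy(cfg.nodes, cfg.names, cfg.merged or None)
    design = pg.load_design(cfg.design)
    taxmap = lca.load_accession_taxmap(cfg.taxa_sidecar)
    return tree, design, taxmap


def run_iteration1(cfg: PipelineConfig):
    """First pass: filter, majority-accession LCA, reduced search space."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        tree, design, taxmap = _load_common(cfg)
        groups = pg.read_protein_groups(cfg.protein_groups, design)
        kept = pg.filter_groups(groups, cfg.min_unique, cfg.min_samples)
        assignments = lca.assign_all(
            kept, taxmap, tree, "first_iteration", cfg.override_mode
        )
        lca.write_assignments(assignments, tree, out / "assignments_iter1.tsv")
        n_records = lca.build_reduced_database(
            assignments, tree, cfg.fasta, out / "reduced.fasta", taxmap
        )
    except SalimetError as e:
        raise SalimetError(f"iteration 1 failed: {e}") from e
    report = RunReport(
        stage="iteration1",
        counts={
            "input_groups": len(groups),
            "after_filters": len(kept),
            "reduced_fasta_records": n_records,
        },
        summary=summarize_assignments(assignments, tree),
        config=dataclasses.asdict(cfg),
    )
    report.write(out / "report_iter1.json")
    return assignments, report


def run_iteration2(cfg: PipelineConfig, second_table):
    """Second pass: all-accession LCA, quantitative and functional stages."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        tree, design, taxmap = _load_common(cfg)
        groups = pg.read_protein_groups(second_table, design)
        assignments = lca.assign_all(
            groups, taxmap, tree, "second_iteration", cfg.override_mode
        )
        lca.write_assignments(assignments, tree, out / "assignments_iter2.tsv")
        kingdom = {a.group_id: a.kingdom for a in assignments}

        # quantification path
        quant_groups = pg.filter_quant(
            groups, cfg.min_razor_unique, cfg.quant_min_samples
        )
        raw = pg.intensity_matrix(quant_groups, design)
        norm = quant.quantile_normalize(raw)
        quant_assign = [a for a in assignments if a.group_id in set(raw.index)]
        biomass = quant.biomass_partition(raw, quant_assign)

        abundances = {}
        taxa_tests = []
        for rank in ("genus", "species"):
            ab = quant.taxon_abundance(raw, quant_assign, tree, rank)
            abundances[rank] = ab
            ab.rename(index=lambda t: tree.name(t)).to_csv(
                out / f"abundance_{rank}.tsv", sep="\t"
            )
            if not ab.empty:
                res = quant.compare_taxa(ab, design)
                taxa_tests.extend(
                    quant.TestResult(
                        tree.name(r.feature), r.statistic, r.p, r.q, f"{rank}:{r.comparison}"
                    )
                    for r in res
                )
        quant.results_frame(taxa_tests).to_csv(
            out / "taxon_tests.tsv", sep="\t", index=False
        )

        # human-protein path
        human_ids = [
            gid for gid in norm.index if kingdom.get(gid) == lca.KINGDOM_HUMAN
        ]
        human = quant.log2_and_impute(norm.loc[human_ids], impute=False)
        anova = quant.anova_screen(human, design, cfg.alpha)
        quant.results_frame(anova).to_csv(out / "anova.tsv", sep="\t", index=False)
        sig = [r.feature for r in anova if r.q < cfg.alpha]
        imputed = quant.log2_and_impute(
            norm.loc[human_ids], cfg.impute_constant, impute=True
        )
        pca = quant.pca_scores(imputed)
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        clustering = None
        if len(sig) >= 2:
            clustering = quant.cluster_rows(quant.impute_row_mean(human.loc[sig]))

        # functional path: bacterial groups with LCA at genus rank or below
        hits = annot.read_hmm_hits(cfg.hmm_hits) if cfg.hmm_hits else {}
        nog_terms = annot.load_nog_terms(cfg.nog_terms) if cfg.nog_terms else {}
        accepted = {
            acc: annot.select_hits(h, cfg.hmm_max_evalue, cfg.hmm_max_overlap)
            for acc, h in hits.items()
        }
        terms = annot.map_terms(accepted, nog_terms)
        eligible = {
            a.group_id
            for a in assignments
            if a.kingdom == lca.KINGDOM_BACTERIA
            and a.lca_taxid is not None
            and tree.ancestor_at_rank(a.lca_taxid, "genus") is not None
        }
        detected = {
            sg: {
                g.group_id
                for g in groups
                if g.group_id in eligible
                and any(g.intensities.get(s, 0) > 0 for s in design.members(sg))
            }
            for sg in design.groups
        }
        group_terms = {
            g.group_id: frozenset().union(
                *(terms.get(a, annot.Terms(frozenset(), frozenset())).kegg
                  for a in g.majority_accessions)
            )
            for g in groups
            if g.group_id in eligible
        }
        assoc = {
            sg: _association_counts(detected[sg], group_terms)
            for sg in design.groups
        }
        enrichment = {}
        for ga, gb in ENRICH_COMPARISONS:
            if ga in assoc and gb in assoc and assoc[ga] and assoc[gb]:
                res = annot.enrich_kegg(
                    assoc[ga], assoc[gb], cfg.enrich_fdr, cfg.fc_low, cfg.fc_high
                )
                enrichment[f"{ga}_vs_{gb}"] = res
                _write_enrichment(res, out / f"enrichment_{ga}_vs_{gb}.tsv")
        characterization = {
            sg: annot.characterize_pathways(assoc[sg], cfg.coverage)
            for sg in design.groups
            if assoc.get(sg)
        }
    except SalimetError as e:
        raise SalimetError(f"iteration 2 failed: {e}") from e

    report = RunReport(
        stage="iteration2",
        counts={
            "input_groups": len(groups),
            "quantified_groups": len(quant_groups),
            "human_tested": len(anova),
            "human_significant": len(sig),
            "enrichment_terms": {k: len(v) for k, v in enrichment.items()},
        },
        summary=summarize_assignments(assignments, tree),
        config=dataclasses.asdict(cfg),
    )
    report.summary["biomass"] = {k: round(v, 4) for k, v in biomass.items()}
    report.write(out / "report_iter2.json")
    return {
        "assignments": assignments,
        "biomass": biomass,
        "abundances": abundances,
        "taxon_tests": taxa_tests,
        "anova": anova,
        "significant": sig,
        "pca": pca,
        "clustering": clustering,
        "enrichment": enrichment,
        "characterization": characterization,
        "report": report,
    }


def _association_counts(group_ids, group_terms) -> dict[str, int]:
    """Protein-group-term association counts for one sample category."""
    counts: dict[str, int] = {}
    for gid in group_ids:
        for term in group_terms.get(gid, ()):
            counts[term] = counts.get(term, 0) + 1
    return counts


def _write_enrichment(results, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tcount_a\tcount_b\tfold_change\tp\tq\tpasses_fc\tpasses_fdr\n")
        for r in results:
            fh.write(
                f"{r.term}\t{r.count_a}\t{r.count_b}\t{r.fold_change:.4f}\t"
                f"{r.p:.6g}\t{r.q:.6g}\t{int(r.passes_fc)}\t{int(r.passes_fdr)}\n"
            )
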
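"""Functional annotation of bacterial proteins and KEGG pathway enrichment.

Proteins are annotated by HMM hits against bacterial orthologous-group (NOG)
models; hits are kept when their E-value is at most 1e-4 and accepted
greedily in ascending E-value order, rejecting any hit whose envelope
overlaps an already-accepted hit by more than eight amino acids.  Accepted
NOGs are mapped to GO terms and KEGG pathways.  Pairwise group enrichment
uses Fisher's exact test on the 2x2 association table, Benjamini-Hochberg
FDR at 1%, and a fold-change gate (>= 2 or <= 0.5).  The functional overview
keeps the most-associated pathways until 90% cumulative coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Mapping, NamedTuple

from scipy import stats

from .errors import DegenerateInputError, RecordError
from .quant import bh_adjust

log = logging.getLogger(__name__)

MAX_EVALUE = 1e-4
MAX_OVERLAP = 8
ENRICH_FDR = 0.01
FC_LOW = 0.5
FC_HIGH = 2.0
COVERAGE = 0.90


@dataclass(frozen=True)
class HmmHit:
    accession: str
    model: str
    evalue: float
    start: int  # envelope start, 1-based inclusive
    end: int    # envelope end, 1-based inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise RecordError(
                f"hit {self.accession}/{self.model}: start {self.start} > end {self.end}"
            )
        if not self.evalue > 0:
            raise RecordError(
                f"hit {self.accession}/{self.model}: non-positive E-value {self.evalue}"
            )


def overlap(a: HmmHit, b: HmmHit) -> int:
    """Inclusive envelope overlap in residues; 0 when disjoint."""
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def read_hmm_hits(path: str | PathLike) -> dict[str, list[HmmHit]]:
    """Domain-table-style TSV/whitespace file, ``#`` lines ignored.

    Columns: target accession, model id, E-value, env-start, env-end.
    """
    hits: dict[str, list[HmmHit]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            acc, model, ev, start, end = line.split()[:5]
            hits.setdefault(acc, []).append(
                HmmHit(acc, model, float(ev), int(start), int(end))
            )
    return hits


def select_hits(
    hits: Iterable[HmmHit],
    max_evalue: float = MAX_EVALUE,
    max_overlap: int = MAX_OVERLAP,
) -> list[HmmHit]:
    """Greedy best-E-value hit selection for one protein.

    Hits above ``max_evalue`` are discarded; the rest are visited in
    ascending E-value order (ties broken by coordinates then model id, so the
    result is deterministic) and accepted unless they overlap an accepted hit
    by more than ``max_overlap`` residues.
    """
    pool = sorted(
        (h for h in hits if h.evalue <= max_evalue),
        key=lambda h: (h.evalue, h.start, h.end, h.model),
    )
    accepted: list[HmmHit] = []
    for h in pool:
        if all(overlap(h, a) <= max_overlap for a in accepted):
            accepted.append(h)
    return accepted


class Terms(NamedTuple):
    go: frozenset[str]
    kegg: frozenset[str]


def load_nog_terms(path: str | PathLike) -> dict[str, Terms]:
    """TSV (NOG id, comma-separated GO ids, comma-separated KEGG ids), one header."""
    out: dict[str, Terms] = {}
    with open(path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            nog = parts[0]
            go = frozenset(t for t in parts[1].split(",") if t) if len(parts) > 1 else frozenset()
            kegg = frozenset(t for t in parts[2].split(",") if t) if len(parts) > 2 else frozenset()
            out[nog] = Terms(go, kegg)
    return out


def map_terms(
    accepted: Mapping[str, list[HmmHit]], nog_terms: Mapping[str, Terms]
) -> dict[str, Terms]:
    """Union of term sets over each protein's accepted NOGs.

    Proteins with no accepted hit (or only unknown NOGs, which are logged)
    map to empty term sets and are retained.
    """
    out: dict[str, Terms] = {}
    for acc, hits in accepted.items():
        go: set[str] = set()
        kegg: set[str] = set()
        for h in hits:
            t = nog_terms.get(h.model)
            if t is None:
                log.info("NOG %s absent from term table; contributes no terms", h.model)
                continue
            go |= t.go
            kegg |= t.kegg
        out[acc] = Terms(frozenset(go), frozenset(kegg))
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    count_a: int
    count_b: int
    fold_change: float
    p: float
    q: float
    passes_fc: bool
    passes_fdr: bool

    @property
    def significant(self) -> bool:
        return self.passes_fc and self.passes_fdr


def enrich_kegg(
    group_a: Mapping[str, int],
    group_b: Mapping[str, int],
    fdr: float = ENRICH_FDR,
    fc_low: float = FC_LOW,
    fc_high: float = FC_HIGH,
) -> list[EnrichmentResult]:
    """Pairwise KEGG-term enrichment between two sample categories.

    Inputs are per-term protein-group association counts.  Each term is
    tested with Fisher's exact test on the 2x2 table (term vs not-term,
    A vs B); the fold change is the ratio of term shares, with a +0.5
    continuity correction applied to both counts whenever either is zero.
    BH correction runs across terms; a term is significant when q <= ``fdr``
    AND fc >= ``fc_high`` or <= ``fc_low``.
    """
    tot_a = sum(group_a.values())
    tot_b = sum(group_b.values())
    if tot_a == 0 or tot_b == 0:
        raise DegenerateInputError("a group has zero term associations")
    terms = sorted(set(group_a) | set(group_b))
    ps, fcs, counts = [], [], []
    for t in terms:
        a = group_a.get(t, 0)
        b = group_b.get(t, 0)
        _, p = stats.fisher_exact([[a, tot_a - a], [b, tot_b - b]])
        if a == 0 or b == 0:
            fc = ((a + 0.5) / tot_a) / ((b + 0.5) / tot_b)
        else:
            fc = (a / tot_a) / (b / tot_b)
        ps.append(float(p))
        fcs.append(fc)
        counts.append((a, b))
    qs = bh_adjust(ps)
    out = []
    for t, (a, b), fc, p, q in zip(terms, counts, fcs, ps, qs):
        out.append(
            EnrichmentResult(
                term=t,
                count_a=a,
                count_b=b,
                fold_change=fc,
                p=p,
                q=float(q),
                passes_fc=fc >= fc_high or fc <= fc_low,
                passes_fdr=q <= fdr,
            )
        )
    return out


def characterize_pathways(
    group_counts: Mapping[str, int], coverage: float = COVERAGE
) -> list[tuple[str, float, float]]:
    """Most-associated pathways up to cumulative ``coverage``.

    Counts are converted to percentages, sorted descending (ties broken by
    term id), and the minimal prefix whose cumulative percentage reaches
    ``coverage * 100`` is retained.  Returns (term, percent, cumulative
    percent) tuples; all-zero counts give an empty result with a warning.
    """
    total = sum(group_counts.values())
    if total == 0:
        log.warning("all-zero pathway counts; nothing to characterise")
        return []
    ranked = sorted(group_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    out = []
    cum = 0.0
    target = coverage * 100.0 - 1e-9
    for term, c in ranked:
        pct = 100.0 * c / total
        cum += pct
        out.append((term, pct, cum))
        if cum >= target:
            break
    return out
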
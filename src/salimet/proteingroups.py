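"""Protein-group table IO and quality filters.

Consumes the MaxQuant ``proteinGroups.txt`` dialect: tab-separated, one header
line, accession lists ``;``-separated within a cell, per-sample summed
intensities in ``Intensity <sample>`` columns, and 0 meaning "not detected".
Two distinct filters are exposed because the study states them differently:
an identification filter (>=2 unique peptides, detected in >=5 samples) used
before taxonomic assignment, and a stricter quantification filter
(razor+unique > 1, detected in > 5 samples) used before normalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike

import pandas as pd

from .errors import FormatError

log = logging.getLogger(__name__)

COL_MAJORITY = "Majority protein IDs"
COL_PEPTIDE_COUNTS = "Peptide counts (all)"
COL_UNIQUE = "Unique peptides"
COL_RAZOR_UNIQUE = "Razor + unique peptides"
COL_REVERSE = "Reverse"
COL_CONTAMINANT = "Potential contaminant"
INTENSITY_PREFIX = "Intensity "


@dataclass
class SampleDesign:
    """Sample ids and their group labels (one label per sample)."""

    samples: list[str]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.samples if s not in self.labels]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    def group(self, sample: str) -> str:
        return self.labels[sample]

    def members(self, group: str) -> list[str]:
        return [s for s in self.samples if self.labels[s] == group]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if self.labels[s] not in seen:
                seen.append(self.labels[s])
        return seen


def load_design(path: str | PathLike) -> SampleDesign:
    """Sidecar design TSV: columns (sample-id, group), one header line."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("design file needs two columns: sample-id, group")
    samples = df.iloc[:, 0].tolist()
    return SampleDesign(samples, dict(zip(samples, df.iloc[:, 1])))


@dataclass
class ProteinGroup:
    """One identified protein group.

    ``peptide_counts`` holds the per-accession peptide-association counts for
    the majority accessions (aligned with ``majority_accessions``);
    ``intensities`` maps sample id to summed MS intensity, 0 = not detected.
    """

    group_id: int
    majority_accessions: list[str]
    peptide_counts: dict[str, int]
    unique_peptide_count: int
    razor_unique_count: int
    intensities: dict[str, float] = field(default_factory=dict)

    def detected_in(self) -> int:
        return sum(1 for v in self.intensities.values() if v > 0)


def read_protein_groups(
    table: str | PathLike, design: SampleDesign
) -> list[ProteinGroup]:
    """Read a protein-group TSV; drop reverse/contaminant-flagged rows.

    Raises :class:`FormatError` naming the first missing mandatory column, or
    the offending line for a non-numeric intensity.  Absent intensity values
    are read as 0 (not detected).
    """
    df = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    for col in (COL_MAJORITY, COL_PEPTIDE_COUNTS, COL_UNIQUE, COL_RAZOR_UNIQUE):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col!r}")
    for s in design.samples:
        if INTENSITY_PREFIX + s not in df.columns:
            raise FormatError(f"missing intensity column for sample {s!r}")

    groups: list[ProteinGroup] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        if rec.get(COL_REVERSE, "").strip() or rec.get(COL_CONTAMINANT, "").strip():
            log.debug("dropped row %d reason=reverse_or_contaminant", i)
            continue
        accs = [a for a in rec[COL_MAJORITY].split(";") if a]
        if not accs:
            raise FormatError(f"line {i + 2}: empty accession list")
        counts_raw = [c for c in rec[COL_PEPTIDE_COUNTS].split(";") if c != ""]
        if len(counts_raw) < len(accs):  # pad defensively; uniform fallback
            counts_raw += ["1"] * (len(accs) - len(counts_raw))
            log.warning("line %d: fewer peptide counts than accessions; padded", i + 2)
        counts = {a: int(c) for a, c in zip(accs, counts_raw)}
        intens: dict[str, float] = {}
        for s in design.samples:
            raw = rec[INTENSITY_PREFIX + s].strip()
            if raw == "":
                intens[s] = 0.0
                continue
            try:
                intens[s] = float(raw)
            except ValueError:
                raise FormatError(
                    f"line {i + 2}: non-numeric intensity {raw!r} for sample {s!r}"
                ) from None
        gid = int(rec["id"]) if "id" in rec and rec["id"] != "" else i
        groups.append(
            ProteinGroup(
                group_id=gid,
                majority_accessions=accs,
                peptide_counts=counts,
                unique_peptide_count=int(rec[COL_UNIQUE]),
                razor_unique_count=int(rec[COL_RAZOR_UNIQUE]),
                intensities=intens,
            )
        )
    return groups


def write_protein_groups(
    groups: list[ProteinGroup], design: SampleDesign, path: str | PathLike
) -> None:
    """Emit the same dialect :func:`read_protein_groups` consumes."""
    cols = ["id", COL_MAJORITY, COL_PEPTIDE_COUNTS, COL_UNIQUE, COL_RAZOR_UNIQUE]
    cols += [INTENSITY_PREFIX + s for s in design.samples]
    rows = []
    for g in groups:
        row = {
            "id": g.group_id,
            COL_MAJORITY: ";".join(g.majority_accessions),
            COL_PEPTIDE_COUNTS: ";".join(
                str(g.peptide_counts[a]) for a in g.majority_accessions
            ),
            COL_UNIQUE: g.unique_peptide_count,
            COL_RAZOR_UNIQUE: g.razor_unique_count,
        }
        for s in design.samples:
            v = g.intensities.get(s, 0.0)
            row[INTENSITY_PREFIX + s] = "0" if v == 0 else f"{v:.4f}"
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def filter_groups(
    groups: list[ProteinGroup], min_unique: int = 2, min_samples: int = 5
) -> list[ProteinGroup]:
    """Identification-quality filter: >= ``min_unique`` unique peptides and
    detected (intensity > 0) in >= ``min_samples`` samples.  Order preserved."""
    out = []
    for g in groups:
        if g.unique_peptide_count < min_unique:
            log.debug("dropped group %s reason=unique_peptides", g.group_id)
        elif g.detected_in() < min_samples:
            log.debug("dropped group %s reason=min_samples", g.group_id)
        else:
            out.append(g)
    return out


def filter_quant(
    groups: list[ProteinGroup], min_razor_unique: int = 2, min_samples: int = 5
) -> list[ProteinGroup]:
    """Quantification filter: razor+unique peptides >= ``min_razor_unique``
    (i.e. more than one at the default) and detected in strictly more than
    ``min_samples`` samples."""
    out = []
    for g in groups:
        if g.razor_unique_count < min_razor_unique:
            log.debug("dropped group %s reason=razor_unique", g.group_id)
        elif g.detected_in() <= min_samples:
            log.debug("dropped group %s reason=quant_min_samples", g.group_id)
        else:
            out.append(g)
    return out


def intensity_matrix(groups: list[ProteinGroup], design: SampleDesign) -> pd.DataFrame:
    """Groups x samples intensity matrix; 0 (not detected) becomes NaN."""
    df = pd.DataFrame(
        {s: [g.intensities.get(s, 0.0) for g in groups] for s in design.samples},
        index=[g.group_id for g in groups],
        dtype=float,
    )
    return df.mask(df <= 0)
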
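"""Exception hierarchy shared across the pipeline stages."""


class SalimetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SalimetError):
    """A file does not conform to its expected dialect (missing column, bad row)."""


class TaxonomyStructureError(SalimetError):
    """Taxonomy dump violates structural invariants (cycle, orphan parent)."""


class UnknownTaxonError(SalimetError, KeyError):
    """A taxon id is absent from the tree (including merged ids)."""


class NameResolutionError(SalimetError, KeyError):
    """A species name could not be mapped to a taxon id."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"cannot resolve species name: {self.name!r}"


class DegenerateInputError(SalimetError):
    """Input is structurally valid but statistically degenerate (constant matrix, zero total)."""


class RecordError(SalimetError):
    """A single record is malformed (bad coordinates, non-positive E-value)."""
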
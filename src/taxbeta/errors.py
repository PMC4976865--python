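"""Exception hierarchy and warning categories used across the pipeline."""


class TaxbetaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TaxbetaError):
    """Input table is missing required columns or has an unusable layout."""


class ValidationError(TaxbetaError):
    """Input values violate an invariant (e.g. negative record counts)."""


class DuplicateRecordError(ValidationError):
    """The same (group, species, site) triple appears more than once."""

    def __init__(self, triples):
        self.triples = list(triples)
        shown = ", ".join(repr(t) for t in self.triples[:5])
        more = "" if len(self.triples) <= 5 else f" (+{len(self.triples) - 5} more)"
        super().__init__(f"duplicate (group, species, site) triples: {shown}{more}")


class UnknownGroupError(TaxbetaError, KeyError):
    """A requested faunal group is absent from the occurrence table."""


class UnknownSiteError(TaxbetaError, KeyError):
    """A requested site label is absent from the occurrence table."""


class UnassignedSpeciesError(TaxbetaError):
    """Species present in the occurrences lack a taxonomy assignment row."""

    def __init__(self, species, group=None):
        self.species = sorted(species)
        where = f" for group {group!r}" if group else ""
        super().__init__(
            f"species without taxonomy assignment{where}: {', '.join(self.species)}"
        )


class DesignError(TaxbetaError):
    """A synthetic community design is infeasible or self-contradictory."""


class PipelineError(TaxbetaError):
    """A pipeline stage failed; message is tagged with the stage name."""

    def __init__(self, stage, message):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class UndefinedValueWarning(UserWarning):
    """A dissimilarity, coverage or contribution value is undefined and
    propagated as missing (NaN), never silently as zero."""


class EmptySiteWarning(UserWarning):
    """A site has no presences for the group under analysis."""


class SmallSampleWarning(UserWarning):
    """Coverage estimated from a sample too small to be reliable."""
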
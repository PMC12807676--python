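"""Exception hierarchy for the gene-building pipeline.

Every error the pipeline raises deliberately derives from :class:`NcgeneError`
so callers (and the CLI exit-code mapping) can distinguish expected failure
modes from genuine bugs.
"""


class NcgeneError(Exception):
    """Base class for all pipeline errors."""


class GFFParseError(NcgeneError):
    """A GFF3 line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class LinkageError(NcgeneError):
    """An exon references a Parent transcript that does not exist."""


class ValidationError(NcgeneError):
    """A record violates a structural invariant (e.g. multi-chromosome transcript)."""


class OntologyError(NcgeneError):
    """The ontology input is unusable (cycle, empty term set, ...)."""


class TermLookupError(NcgeneError, KeyError):
    """A term has no embedding vector."""


class ConfigError(NcgeneError):
    """A configuration value is outside its documented range."""


class InputError(NcgeneError):
    """Inputs are structurally valid but unusable for the requested operation."""


class DegenerateTrainingError(InputError):
    """The labeled pair table contains a single class; a two-class model cannot fit."""


class ContractError(NcgeneError):
    """A cross-component contract is violated (feature order, fingerprints, NaN input)."""
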
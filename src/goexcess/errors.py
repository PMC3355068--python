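"""Exception hierarchy shared across the pipeline."""


class GoexcessError(Exception):
    """Base class for all package errors."""


class OboParseError(GoexcessError):
    """Raised for malformed OBO input; message names the offending line."""


class GafParseError(GoexcessError):
    """Raised for malformed GAF input; message names the offending line."""


class OntologyValidationError(GoexcessError):
    """Raised when a parsed ontology violates a structural invariant."""


class UnknownTermError(KeyError, GoexcessError):
    """Raised when a term identifier is not in the ontology."""


class UndefinedICError(GoexcessError):
    """Raised when a term's information content cannot be computed
    because the term is absent from both genomes' frequency tables."""


class PairValidationError(GoexcessError):
    """Raised when a homolog pair violates its invariants."""


class GenerationError(GoexcessError):
    """Raised on inconsistent synthetic-data generator configuration."""


class PipelineError(GoexcessError):
    """Raised when a pipeline stage aborts; message names the stage."""
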
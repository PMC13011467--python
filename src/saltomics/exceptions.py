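"""Exception hierarchy shared by all pipeline stages."""


class SaltOmicsError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(SaltOmicsError):
    """A simulation or pipeline configuration is internally inconsistent."""


class InvalidInputError(SaltOmicsError):
    """An input table violates its schema or value constraints."""


class InvalidDesignError(SaltOmicsError):
    """The sample design is not the complete balanced factorial the
    statistics require (e.g. a missing replicate cell)."""


class InvalidRecordError(SaltOmicsError):
    """A fragment/interval record is malformed (bad strand, start >= end)."""


class InvalidAnnotationError(SaltOmicsError):
    """A gene model is malformed (end < start, unknown strand)."""


class PipelineStateError(SaltOmicsError):
    """An operation was applied in the wrong order (e.g. pseudocount twice)."""
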
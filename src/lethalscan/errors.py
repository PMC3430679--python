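"""Exception types shared across the pipeline."""


class LethalscanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LethalscanError, ValueError):
    """A simulation or run configuration violates its invariants."""


class DataError(LethalscanError, ValueError):
    """Input data violate a precondition (missing samples, unphased controls, ...)."""


class UnsupportedDeletionError(LethalscanError, ValueError):
    """A deletion splits an exon; only whole-exon deletions are modelled."""


class AmbiguousPrimerError(LethalscanError, ValueError):
    """A primer matches a template more than once on a strand."""


class ModelError(LethalscanError, ValueError):
    """A gene model is internally inconsistent (no ATG, internal stop, ...)."""
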
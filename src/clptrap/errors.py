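"""Typed exceptions raised by the pipeline.

Validation is total: malformed input always raises one of these, never a
silent drop.
"""


class ClptrapError(Exception):
    """Base class for all package errors."""


class DesignError(ClptrapError):
    """Invalid study design (missing/duplicate role, bad replicate count)."""


class EvidenceError(ClptrapError):
    """Invalid evidence record or table (invariant violation, bad key)."""


class MzTabError(ClptrapError):
    """Malformed or incomplete mzTab input."""


class AnnotationError(ClptrapError):
    """Invalid annotation table (e.g. duplicate protein accession)."""


class EvaluationError(ClptrapError):
    """Truth table and classification results cannot be reconciled."""


class ParamError(ClptrapError):
    """Filter or simulation parameters violate their invariants."""


class ConfigError(ClptrapError):
    """Invalid run configuration (no input source, unknown keys...)."""
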
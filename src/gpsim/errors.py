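"""Exception hierarchy for gpsim.

All package-specific failures derive from :class:`GPSimError` so callers can
catch one base class at pipeline boundaries (e.g. the CLI).
"""


class GPSimError(Exception):
    """Base class for all gpsim errors."""


class OboParseError(GPSimError):
    """An OBO file could not be parsed; the message names the offending stanza."""


class OntologyStructureError(GPSimError):
    """Structural violation: cyclic is-a edges, no root, or disconnected terms."""


class TermNotFoundError(GPSimError, KeyError):
    """A term id is unknown or obsolete in the queried ontology."""


class AnnotationError(GPSimError):
    """Annotation counts cannot support information-content computation."""


class UndefinedSimilarityError(GPSimError):
    """A set similarity is undefined (an operand set is empty).

    Deliberately a signal rather than a value: the combination layer decides
    the fallback policy, component measures never invent a score.
    """


class NoDataError(GPSimError):
    """A disease carries neither gene nor phenotype associations."""


class BenchmarkError(GPSimError, ValueError):
    """Invalid benchmark construction (too few pairs, single-class input)."""
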
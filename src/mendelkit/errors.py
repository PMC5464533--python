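"""Exception hierarchy.

Everything raised on bad data or bad configuration derives from
:class:`MendelkitError` so the CLI can map it to a single exit code.
"""


class MendelkitError(Exception):
    """Base class for all data/format/configuration errors."""


class VcfFormatError(MendelkitError):
    """Malformed VCF content (bad header, garbled line, unknown compression)."""


class PanelError(MendelkitError):
    """Reference panel cannot be indexed or queried (e.g. unsorted rows)."""


class AnnotationError(MendelkitError):
    """Annotation failure: INFO prefix collision, bad panel value, panel abort."""


class CatalogError(MendelkitError):
    """Gene/disease catalog violates its contract (duplicate symbol, bad column)."""


class FilterConfigError(MendelkitError):
    """A FilterSpec references an annotation field absent from every record."""


class PedigreeError(MendelkitError):
    """Pedigree does not supply what an inheritance model requires."""


class ComparisonError(MendelkitError):
    """VCF comparison misconfiguration (unknown sample name, no genotypes)."""


class SynthConfigError(MendelkitError):
    """Invalid synthetic-data configuration."""
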
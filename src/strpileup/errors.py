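"""Exception hierarchy.

Every error a caller might want to catch selectively derives from
:class:`StrPileupError`; the CLI maps these onto distinct exit codes.
"""


class StrPileupError(Exception):
    """Base class for all package errors."""


class CatalogError(StrPileupError):
    """Malformed or inconsistent locus catalog / configuration."""


class FormatError(StrPileupError):
    """Malformed input record (VCF, TSV, tag payload...)."""


class GenotypeError(StrPileupError):
    """Missing or unusable repeat genotype."""


class AlignmentError(StrPileupError):
    """Invalid alignment request (empty read, unknown segment...)."""


class SimulationError(StrPileupError):
    """Simulator configuration cannot be realized."""
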
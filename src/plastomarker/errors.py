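"""Exception hierarchy shared across the pipeline."""


class PlastomarkerError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PlastomarkerError):
    """Malformed input file (GenBank, FASTA, annotation table, formula)."""


class CoordinateError(PlastomarkerError):
    """A feature or variant coordinate falls outside the sequence."""


class StructureNotFound(PlastomarkerError):
    """No inverted repeat of the required length: input is not quadripartite."""


class CollinearityError(PlastomarkerError):
    """Two genomes could not be anchored collinearly (likely rearranged)."""


class DesignFailure(PlastomarkerError):
    """No primer pair satisfying the design constraints exists at a locus."""
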
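"""Exception hierarchy; the CLI maps these onto exit code 1."""


class RnaDcaError(Exception):
    """Base class for all package errors."""


class AlignmentFormatError(RnaDcaError):
    """Malformed alignment file (ragged rows, empty file, unknown format)."""


class StructureFormatError(RnaDcaError):
    """Malformed secondary-structure annotation or file."""


class ParameterError(RnaDcaError):
    """Out-of-range user parameter."""


class NumericalError(RnaDcaError):
    """Numerical failure, e.g. a singular correlation matrix."""


class MappingError(RnaDcaError):
    """Failure to reconcile two coordinate systems (chain vs. target)."""
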
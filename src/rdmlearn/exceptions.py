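"""Exception hierarchy."""


class RdmlearnError(Exception):
    """Base class for all package errors."""


class RepresentationError(RdmlearnError):
    """Malformed matrix/vector shapes or packing violations."""


class AlignmentError(RdmlearnError):
    """Geometries cannot be superimposed (atom count/element mismatch)."""


class ConfigurationError(RdmlearnError):
    """Unresolvable method, basis, or workflow configuration."""


class ConvergenceError(RdmlearnError):
    """An iterative procedure failed to converge."""


class InputError(RdmlearnError):
    """Physically inconsistent input (trace violation, frame mismatch, ...)."""
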
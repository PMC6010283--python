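"""Exception hierarchy shared across the package.

``InputError`` marks problems with user-supplied files or arguments and maps
to CLI exit status 2; ``NumericalError`` marks failures of the numerical
procedure itself (e.g. a disconnected contact graph) and maps to exit
status 3.
"""


class DynCommError(Exception):
    """Base class for all package errors."""


class InputError(DynCommError, ValueError):
    """Invalid input file, selection or argument."""


class NumericalError(DynCommError, RuntimeError):
    """Numerical procedure cannot proceed (singularity, disconnection...)."""
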
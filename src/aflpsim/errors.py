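"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`InputError` -> 2,
:class:`InfeasibleConfigError` -> 3.
"""


class AflpsimError(Exception):
    """Base class for all package errors."""


class InputError(AflpsimError):
    """Malformed or inconsistent user input (files, coordinates, formats)."""


class InfeasibleConfigError(AflpsimError):
    """A synthetic-genome configuration that cannot be realised."""
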
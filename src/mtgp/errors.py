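"""Exception hierarchy shared across the package.

Data problems (bad files, inconsistent identifiers, invalid settings) raise
:class:`DataValidationError`; numerical failures inside the samplers raise
:class:`NumericalError`.  The CLI maps these onto exit codes 2 and 3.
"""


class DataValidationError(ValueError):
    """Invalid input data or run configuration."""


class NumericalError(RuntimeError):
    """A numerical operation failed (non-PSD matrix, singular solve, ...)."""
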
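"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`DataError` -> 2,
:class:`StatPreconditionError` -> 3.
"""


class GillsymError(Exception):
    """Base class for all package-specific errors."""


class DataError(GillsymError, ValueError):
    """Malformed, inconsistent, or out-of-contract input data."""


class StatPreconditionError(GillsymError, RuntimeError):
    """A statistical procedure was invoked outside its preconditions.

    Example: requesting Dunn's post hoc comparisons when the omnibus
    Kruskal-Wallis test was not significant and ``force`` was not set.
    """
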
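"""Exception hierarchy.

Validation problems (bad input data, malformed CSV, impossible requests)
map to CLI exit code 2; fitting problems map to exit code 3.
"""


class TreefxError(Exception):
    """Base class for package errors."""


class ValidationError(TreefxError):
    """Input data or configuration violates a precondition."""


class FitError(TreefxError):
    """The tree-fitting procedure cannot proceed."""
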
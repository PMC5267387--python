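"""Error types shared across the package.

``DomainError`` signals an argument outside the mathematical domain of an
operation (e.g. a rank-sum difference beyond the support of the null
distribution).  ``ValidationError`` signals malformed user input such as a
ragged or non-numeric data table.  The command-line interface maps them to
distinct exit codes.
"""


class DomainError(ValueError):
    """A parameter violates a mathematical precondition."""


class ValidationError(ValueError):
    """An input table or option set is malformed."""
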
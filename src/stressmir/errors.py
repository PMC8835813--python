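"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation problems (bad parameters,
malformed inputs) exit 2, data problems (empty datasets, label conflicts)
exit 3, anything else exits 4.
"""


class StressmirError(Exception):
    """Base class for all package errors."""

    exit_code = 4


class ValidationError(StressmirError):
    """Invalid parameter value or malformed input file."""

    exit_code = 2


class DataError(StressmirError):
    """Input data that cannot be processed (empty set, label conflict...)."""

    exit_code = 3
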
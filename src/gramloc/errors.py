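"""Exception hierarchy shared across the package.

``InputError`` covers malformed user inputs (FASTA, evidence tables,
dialect files, catalogs); ``ConfigError`` covers bad run configuration.
The CLI maps them to distinct exit codes (3 and 4 respectively).
"""


class GramlocError(Exception):
    """Base class for all package errors."""


class InputError(GramlocError):
    """Malformed or inconsistent input data."""


class ConfigError(GramlocError):
    """Invalid run configuration (unknown keys, bad values)."""
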
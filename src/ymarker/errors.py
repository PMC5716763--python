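"""Exception hierarchy shared by the library and the CLI.

CLI exit codes: ConfigError -> 2, DataError -> 3 (click maps these in cli.py).
"""


class YmarkerError(Exception):
    """Base class for all package errors."""


class ConfigError(YmarkerError):
    """Invalid configuration or incompatible parameters (exit code 2)."""


class DataError(YmarkerError):
    """Malformed or inconsistent input data (exit code 3)."""


class FastqParseError(DataError):
    """A FASTQ/FASTA record could not be parsed.

    ``line`` is the 1-based line number at which the offending record starts
    (approximate for gzip streams).
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (at line {line})"
        super().__init__(message)


class PairingError(DataError):
    """Mate files disagree (count mismatch or non-matching read ids)."""


class ContractError(YmarkerError):
    """A documented precondition was violated by the caller."""
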
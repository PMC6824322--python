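"""Exception types shared across the package."""


class PopgwasError(Exception):
    """Base class for user-facing errors (CLI exit code 1)."""


class EmptyResultError(PopgwasError):
    """An operation removed every record (e.g. QC left no SNPs)."""


class PlantingError(PopgwasError):
    """A causal-haplotype carrier frequency target could not be realized."""


class BedParseError(PopgwasError):
    """A BED line could not be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")
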
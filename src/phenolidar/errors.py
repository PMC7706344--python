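"""Exception hierarchy.

Validation failures (bad arguments, malformed inputs) are kept distinct from
data-driven signals (empty plots, missing phenology) so callers and the CLI
can map them to different exit codes.
"""


class PhenolidarError(Exception):
    """Base class for all package errors."""


class ValidationError(PhenolidarError, ValueError):
    """Invalid argument or inconsistent input."""


class CloudFormatError(ValidationError):
    """Unknown or unsupported point-cloud file format."""


class CloudParseError(ValidationError):
    """Malformed point-cloud file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class EmptyPlotError(PhenolidarError):
    """A plot rectangle contains no points (distinct from parse errors)."""


class DateRangeError(ValidationError):
    """Target date outside the interpolation window; no extrapolation."""


class PhenologyError(PhenolidarError, KeyError):
    """Phenology missing for one or more genotypes."""

    def __init__(self, genotypes):
        self.genotypes = tuple(sorted(genotypes))
        super().__init__(
            "phenology missing for genotype(s): " + ", ".join(self.genotypes)
        )
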
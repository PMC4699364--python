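"""Exception types shared across the pipeline."""


class MeqtlseqError(Exception):
    """Base class for all package errors."""


class ConfigError(MeqtlseqError, ValueError):
    """Invalid configuration value (negative length, empty MAF range, ...)."""


class ShortfallError(MeqtlseqError, ValueError):
    """Not enough eligible loci/regions to satisfy a planting request."""


class EstimationError(MeqtlseqError, RuntimeError):
    """A data-driven estimate (fragment-size survival, background threshold)
    could not be formed from the provided reads."""


class DegenerateSiteError(MeqtlseqError, ValueError):
    """A methylation site has zero variance across subjects and cannot be
    rank-transformed."""


class DegenerateTestError(MeqtlseqError, ValueError):
    """A permutation test with zero-variance null distribution (e.g. constant
    annotation flag)."""


class CollinearityError(MeqtlseqError, ValueError):
    """Covariate design matrix is rank deficient; names the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear covariate columns: {self.columns}")


class FormatError(MeqtlseqError, ValueError):
    """Malformed input file; carries the 1-based line number when known."""

    def __init__(self, message, line=None, path=None):
        self.line = line
        self.path = path
        loc = "" if line is None else f" (line {line})"
        src = "" if path is None else f" in {path}"
        super().__init__(f"{message}{loc}{src}")
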
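"""Exception and warning types shared across the package."""


class HlapopError(Exception):
    """Base class for all package errors."""


class AlleleParseError(HlapopError, ValueError):
    """Malformed HLA allele name; carries the offending token and position."""

    def __init__(self, text: str, position: int, message: str):
        self.text = text
        self.position = position
        super().__init__(f"cannot parse allele name {text!r}: {message} (at position {position})")


class GenotypeParseError(HlapopError, ValueError):
    """Malformed genotype-list string."""


class MappingError(HlapopError, ValueError):
    """Allele mapping is not total on the data it is applied to."""

    def __init__(self, unmapped):
        self.unmapped = sorted(unmapped)
        super().__init__("no mapping entry for allele(s): " + ", ".join(self.unmapped))


class UnknownCodeError(HlapopError, KeyError):
    """Abbreviation (NMDP-style) code absent from the code table."""

    def __init__(self, code):
        self.code = code
        super().__init__(f"unknown abbreviation code {code!r}")


class KitError(HlapopError, ValueError):
    """Allele outside the kit universe or malformed kit description."""


class UninterpretablePatternError(HlapopError, ValueError):
    """Reactivity pattern explained by no allele pair in the kit universe."""

    def __init__(self, pattern, nearest):
        self.pattern = pattern
        #: list of (hamming_distance, pattern) diagnostics, closest first
        self.nearest = nearest
        super().__init__(
            "uninterpretable reactivity pattern; nearest interpretable "
            f"pattern(s) at Hamming distance {nearest[0][0] if nearest else '?'}"
        )


class ConvergenceError(HlapopError, RuntimeError):
    """EM failed to converge; carries the log-likelihood trajectory."""

    def __init__(self, message, trajectory=None):
        self.trajectory = trajectory
        super().__init__(message)


class NullAlleleMergeWarning(UserWarning):
    """A null-expression (N) allele was merged into an expressed allele group."""


class SuffixLossWarning(UserWarning):
    """An expression suffix was dropped when truncating an allele name."""


class SampleSizeWarning(UserWarning):
    """Sample smaller than the recommended minimum of 100 individuals."""
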
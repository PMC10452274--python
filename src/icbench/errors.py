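"""Exception hierarchy shared across the package."""


class IcbenchError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IcbenchError):
    """A file could not be parsed into the expected tabular/GMT structure."""


class MissingGeneError(IcbenchError):
    """A required gene (or too many signature genes) is absent from the matrix."""


class DegenerateDataError(IcbenchError):
    """The input is structurally valid but statistically degenerate
    (constant scores, empty group, no events, ...)."""


class RegistryError(IcbenchError):
    """Invalid signature specification or registry operation."""


class CoverageWarning(UserWarning):
    """Some signature genes are missing from the transcriptome."""


class DegenerateWarning(UserWarning):
    """A computation hit a degenerate case handled by a documented convention."""
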
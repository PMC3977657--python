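"""Exception hierarchy.

Every error the library raises derives from :class:`CDQCError`, so callers
(and the test runner, which maps :class:`DataUnavailableError` onto the
"data unavailable" status) can catch one base class.
"""


class CDQCError(Exception):
    """Base class for all cdqc errors."""


class MalformedSpectrumError(CDQCError):
    """A spectrum violates its structural invariants (ordering, duplicates, length)."""


class IncompatibleSpectraError(CDQCError):
    """Two spectra cannot be combined (mismatched grids, units or disjoint ranges)."""


class InvalidParameterError(CDQCError):
    """An operation parameter is out of its legal domain (e.g. even smoothing window)."""


class InvalidSequenceError(CDQCError):
    """An amino-acid sequence contains illegal characters or is empty."""


class InvalidMetadataError(CDQCError):
    """A metadata value is present but unusable (non-numeric, non-positive, ...)."""


class DataUnavailableError(CDQCError):
    """A required input is absent; validation tests report this as 'unavailable'."""


class ParseError(CDQCError):
    """A spectral or metadata file could not be parsed."""


class InvalidReferenceError(CDQCError):
    """A reference artefact (basis, envelope, ...) cannot be built as requested."""


class UndefinedResidualError(CDQCError):
    """Projection residual is undefined (zero spectrum)."""
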
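"""Exception hierarchy for the mwfp pipeline.

All errors derive from :class:`MWFPError` so callers can catch pipeline
failures with a single except clause while tests can assert on the
specific failure mode.
"""


class MWFPError(Exception):
    """Base class for all mwfp errors."""


class ChromatogramStructureError(MWFPError, ValueError):
    """The time grid is non-monotonic, non-uniform, or otherwise invalid."""


class ChromatogramParseError(MWFPError, ValueError):
    """A chromatogram file contains a non-numeric or malformed row."""


class StudyError(MWFPError, ValueError):
    """A study manifest is incomplete, inconsistent, or ambiguous."""


class GridMismatchError(MWFPError, ValueError):
    """Channels to be fused do not share a common time grid."""


class EmptyMatrixError(MWFPError, ValueError):
    """Peak matching produced no peak group satisfying the presence rule."""
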
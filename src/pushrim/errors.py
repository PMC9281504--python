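"""Exception hierarchy for the pushrim pipeline.

Every anticipated failure mode has its own class so callers (and the CLI)
can distinguish malformed files from degenerate signals from bad study
designs without string-matching messages.
"""


class PushrimError(Exception):
    """Base class for all pushrim-specific errors."""


class FormatError(PushrimError):
    """A trial file does not have the expected columns/layout."""


class SamplingError(PushrimError):
    """The time channel is inconsistent with the declared sampling rate."""


class IntegrityError(PushrimError):
    """A channel contains NaN or otherwise corrupt samples."""


class CoverageError(PushrimError):
    """Offset estimation mask is too small or spans less than one revolution."""


class InsufficientPushesError(PushrimError):
    """Too few pushes remain for analysis after transitional exclusion."""


class OverlapError(PushrimError):
    """A segmentation edit produced overlapping or misordered pushes."""


class ShortPushError(PushrimError):
    """A push is too short for the requested derivative-based metric."""


class DegeneratePushError(PushrimError):
    """A push contains samples where a metric's denominator vanishes."""


class DegenerateDataError(PushrimError):
    """A statistical input has no variance or is otherwise degenerate."""


class CompletenessError(PushrimError):
    """A study manifest is missing cells of the 2x2 within-subject design."""
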
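"""Exception hierarchy.

All user-facing failures derive from :class:`BlindcutError` so the CLI can
map them to exit code 1 (user error) while anything else is an internal
error (exit code 2).
"""


class BlindcutError(Exception):
    """Base class for all errors raised by blindcut."""


class FormatError(BlindcutError):
    """Unsupported media file extension."""


class DecodeError(BlindcutError):
    """A media file exists but cannot be decoded."""


class BoundsError(BlindcutError):
    """Frame index outside the valid range."""


class GeometryError(BlindcutError):
    """Rectangle violates its invariants against the source dimensions."""


class LabelError(BlindcutError):
    """Segment label violates the label grammar."""


class DuplicateLabelError(LabelError):
    """Segment label already used elsewhere in the analysis."""


class SequencingError(BlindcutError):
    """Score submitted for a segment that is not the current one."""


class SessionLoadError(BlindcutError):
    """Session state file is absent, corrupt, or violates its invariants."""


class IncompleteSessionError(BlindcutError):
    """Export requested before every segment was scored."""


class BlindingError(BlindcutError):
    """A blinded artifact would leak a label or source filename."""


class PlateSpecError(BlindcutError):
    """Synthetic plate specification is inconsistent."""


class ConfigError(BlindcutError):
    """Analysis configuration is invalid (mixed media types, bad paths...)."""
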
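"""Exception hierarchy.

``InputError`` covers anything wrong with user-supplied files or
parameters (exit code 2 in the CLI); everything else that is raised on
purpose derives from :class:`MsipeaksError` (exit code 1).
"""


class MsipeaksError(Exception):
    """Base class for all errors raised deliberately by msipeaks."""


class InputError(MsipeaksError):
    """A user-supplied file, region or parameter is unusable."""


class SiteParseError(InputError):
    """A sites/baseline/labels TSV row could not be parsed."""

    def __init__(self, path, line_number, message):
        self.path = path
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


class ConfigError(InputError):
    """A simulation or pipeline configuration is internally inconsistent."""


class NoMarkersError(MsipeaksError):
    """Marker selection retained zero sites; a classifier cannot be trained."""


class MarkerTestError(MsipeaksError):
    """A per-site statistical test could not be carried out."""


class ModelFormatError(MsipeaksError):
    """A model bundle file is unreadable or from an incompatible version."""
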
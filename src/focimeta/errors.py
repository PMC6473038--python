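"""Exception taxonomy shared across the package.

Everything derives from :class:`ValueError` so callers that do not care
about the fine distinctions can catch a single type.
"""


class FociMetaError(ValueError):
    """Base class for all focimeta errors."""


class FormatError(FociMetaError):
    """A table or file does not conform to the declared dialect."""


class DatasetError(FociMetaError):
    """A dataset-level precondition is violated (empty input, length mismatch...)."""


class GridMismatchError(FociMetaError):
    """Two volumes that must share a grid do not."""


class ROIError(FociMetaError):
    """A seed region is empty or falls outside the mask."""
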
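"""Exception hierarchy for the delineation pipeline.

Every error carries enough context to be rendered as a machine-readable
CLI exit; the ``exit_code`` class attribute is what the command-line
front end reports.
"""


class SadtError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(SadtError):
    """Malformed input file (wrong dimensionality, count mismatch...)."""

    exit_code = 2


class GridError(SadtError):
    """Inputs do not share a voxel grid (shape/spacing/orientation)."""

    exit_code = 3


class DegenerateHistogramError(SadtError):
    """All values identical: no Otsu separation exists."""

    exit_code = 4


class EmptyDelineationError(SadtError):
    """The raw VTV came out empty; thresholds attached for diagnostics."""

    exit_code = 5

    def __init__(self, message, dwi_threshold=None, adc_threshold=None):
        super().__init__(message)
        self.dwi_threshold = dwi_threshold
        self.adc_threshold = adc_threshold
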
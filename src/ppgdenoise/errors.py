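"""Exception hierarchy.

Recoverable conditions (period not found, a pole in the beta formula,
a degenerate artifact-free frame) get their own classes so the pipeline
can apply the documented fallbacks; everything else is a hard error.
"""


class PPGDenoiseError(Exception):
    """Base class for all package errors."""


class EmptyInputError(PPGDenoiseError, ValueError):
    """An operation received an empty sequence where samples are required."""


class DomainError(PPGDenoiseError, ValueError):
    """A parameter is outside its admissible domain (band, bpm, rate...)."""


class ShapeError(PPGDenoiseError, ValueError):
    """Sequence lengths are inconsistent."""


class DegenerateSignalError(PPGDenoiseError, ValueError):
    """The input carries no information for the requested estimate
    (constant signal, zero-variance residual, all-zero frame)."""


class ZeroPowerError(DegenerateSignalError):
    """A spectral quantity was requested on a zero-power frame."""


class PeriodNotFoundError(PPGDenoiseError):
    """No admissible autocorrelation peak in the physiologic lag range.

    Recoverable: the pipeline falls back to the previous frame's period.
    """


class PoleError(PPGDenoiseError):
    """beta = alpha*c/(alpha-1) evaluated too close to the alpha=1 pole.

    Recoverable: the pipeline carries the previous frame's beta.
    """


class FormatError(PPGDenoiseError, ValueError):
    """A file does not match the documented on-disk format."""


class SamplingError(PPGDenoiseError, ValueError):
    """The time column of a recording is not uniformly sampled."""
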
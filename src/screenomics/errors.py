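"""Exception hierarchy shared across the toolkit."""


class ScreenomicsError(Exception):
    """Base class for all toolkit errors."""


class FormatError(ScreenomicsError):
    """A file violates the documented table or KGML dialect."""


class DegenerateNullError(ScreenomicsError):
    """Null-model fit impossible (e.g. all gene scores identical)."""


class NonSigmoidError(ScreenomicsError):
    """Dose-response data cannot support a four-parameter logistic fit."""


class NoCrossingError(ScreenomicsError):
    """A fitted response curve never crosses the half-maximal level."""


class AbsentLayerError(ScreenomicsError):
    """A query touched an omics layer that was not loaded."""


class NotFoundError(ScreenomicsError):
    """Gene or protein unknown to every loaded layer."""


class ConfigurationError(ScreenomicsError):
    """A required layer or mapping is missing for the requested analysis."""
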
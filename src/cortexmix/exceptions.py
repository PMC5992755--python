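"""Exception hierarchy shared across the package."""


class CortexMixError(Exception):
    """Base class for all cortexmix errors."""


class ConfigurationError(CortexMixError, ValueError):
    """An invalid parameter or configuration value; names the violated constraint."""


class DataError(CortexMixError, ValueError):
    """Invalid input data: negative expression, missing markers, shape mismatches."""


class CurationError(CortexMixError, RuntimeError):
    """Reference-panel curation could not finish.

    Carries the partial :class:`~cortexmix.panel.CurationReport` produced up to
    the failing round in :attr:`report`.
    """

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report
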
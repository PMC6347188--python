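"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`GutDockError`, so callers can catch one type at a pipeline boundary.
"""


class GutDockError(Exception):
    """Base class for all gutdock errors."""


class InputError(GutDockError):
    """Invalid or empty input data (empty structure, empty ensemble, ...)."""


class ParseError(GutDockError):
    """A file or text block could not be parsed in the expected dialect."""


class ConfigError(GutDockError):
    """Invalid configuration (duplicate generic labels, bad box, ...)."""


class CorrespondenceError(GutDockError):
    """Two poses cannot be put in atom-by-atom correspondence."""


class MetricUndefinedError(GutDockError):
    """An enrichment metric is undefined (no actives, or no decoys)."""


class InsufficientDataError(GutDockError):
    """Too few shared observations to compute a statistic."""


class EngineError(GutDockError):
    """The external docking engine failed or is missing; carries its log."""

    def __init__(self, message: str, log: str = ""):
        super().__init__(message)
        self.log = log
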
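"""Exception hierarchy for plsde."""


class PlsdeError(Exception):
    """Base class for all plsde errors."""


class InvalidParameterError(PlsdeError, ValueError):
    """A parameter violates its documented domain."""


class FormatError(PlsdeError, ValueError):
    """An input file is malformed; the message locates the offence."""


class ConvergenceError(PlsdeError, RuntimeError):
    """NIPALS failed to converge within ``max_iter`` for some component."""


class RankDeficiencyError(PlsdeError, RuntimeError):
    """The working matrix ran out of rank before the requested number of
    components; ``n_components_available`` reports how many were extracted."""

    def __init__(self, message: str, n_components_available: int | None = None):
        super().__init__(message)
        self.n_components_available = n_components_available


class ConfigError(PlsdeError, ValueError):
    """A pipeline configuration is invalid (detected before any computation)."""
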
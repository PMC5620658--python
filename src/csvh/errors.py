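"""Exception hierarchy for the csvh package."""


class CSVHError(Exception):
    """Base class for csvh errors."""


class ConfigError(CSVHError, ValueError):
    """Invalid configuration value (kernel width, neighborhood size, ...)."""


class InputError(CSVHError, ValueError):
    """Invalid user-supplied data (dimension mismatch, empty input, ...)."""


class DegenerateModelError(CSVHError, RuntimeError):
    """The fitted geometry collapsed (no support vectors, zero radius, ...)."""


class SolverError(CSVHError, RuntimeError):
    """The QP solver failed to reach the requested KKT tolerance."""


class ModelIOError(CSVHError, ValueError):
    """Model file cannot be parsed or has an incompatible schema."""
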
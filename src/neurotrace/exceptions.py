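"""Exception hierarchy shared across the package."""


class NeurotraceError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NeurotraceError, ValueError):
    """A numeric or structural parameter is outside its admissible range."""


class ConfigurationError(NeurotraceError, ValueError):
    """A configuration object is internally inconsistent or incomplete."""


class DegenerateInputError(NeurotraceError, ValueError):
    """Input data cannot support the requested estimate (e.g. one class only)."""


class ModelMismatchError(NeurotraceError, ValueError):
    """Data dimensionality does not match the fitted model."""


class EmptySessionError(NeurotraceError, ValueError):
    """A session or scenario contains no events to process."""
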
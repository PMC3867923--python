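"""Exception hierarchy shared across the package."""


class LesionMILError(Exception):
    """Base class for package-specific failures."""


class ParameterError(LesionMILError, ValueError):
    """A configuration field or argument is outside its valid range."""


class StateError(LesionMILError, RuntimeError):
    """An operation was invoked before its inputs were prepared."""


class ConfigurationError(LesionMILError, ValueError):
    """A dataset/configuration combination cannot be processed (e.g. degenerate folds)."""


class SelectionError(LesionMILError, RuntimeError):
    """Instance selection produced an empty result."""


class PredictionError(LesionMILError, RuntimeError):
    """A bag cannot be predicted (e.g. every instance was removed as background)."""
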
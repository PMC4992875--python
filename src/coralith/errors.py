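"""Exception hierarchy shared across the pipeline stages."""


class CoralithError(Exception):
    """Base class for all package errors."""


class ParameterError(CoralithError, ValueError):
    """A numeric or structural parameter is outside its documented range."""


class InputError(CoralithError, ValueError):
    """Malformed or inconsistent input data (reads, tables, labels)."""


class ConfigError(CoralithError, ValueError):
    """Invalid pipeline configuration (missing files, indistinguishable primers...)."""


class StateError(CoralithError, RuntimeError):
    """Operation called on an object in the wrong state (e.g. untrained classifier)."""
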
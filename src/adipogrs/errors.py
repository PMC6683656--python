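"""Package exception types."""


class ConfigurationError(ValueError):
    """A simulation or run configuration is internally inconsistent."""


class DataError(ValueError):
    """Input data violate a documented contract (types, ranges, columns)."""


class DegenerateInputError(DataError):
    """A statistical routine received input it cannot operate on
    (e.g. a constant vector passed to a normality test)."""
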
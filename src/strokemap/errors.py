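"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input data violates a documented contract (bad scores, grids, labels...)."""


class ConfigError(ValueError):
    """A configuration object is internally inconsistent or infeasible."""
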
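"""Exception hierarchy shared across the pipeline."""


class PsnetError(Exception):
    """Base class for all errors raised by psnet."""


class ConfigError(PsnetError):
    """Invalid configuration, parameter or input schema (exit code 1 in the CLI)."""


class SchemaError(ConfigError):
    """An input file does not carry the columns the pipeline requires."""


class UndefinedMetricError(PsnetError):
    """A network metric is undefined on this graph (too few nodes / pairs / triples)."""


class EstimationError(PsnetError):
    """The ERGM fit cannot be computed (degenerate or rank-deficient design)."""


class SeparationWarning(UserWarning):
    """A covariate pattern perfectly predicts ties; a coefficient diverges."""
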
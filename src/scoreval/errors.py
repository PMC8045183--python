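"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes (config 2, data 3, computation 4).
"""


class ScorevalError(Exception):
    """Base class for all package errors."""


class ConfigError(ScorevalError):
    """Invalid or inconsistent configuration (thresholds, designs, study specs)."""


class DataError(ScorevalError):
    """Malformed or invariant-violating input data (tables, scores, designs)."""


class ComputationError(ScorevalError):
    """A computation could not be carried out (e.g. bootstrap estimator failures)."""
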
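"""Exception hierarchy used across the pipeline.

Every error a stage can raise derives from :class:`DietselError`, so the
orchestrator can distinguish pipeline failures from programming errors.
"""


class DietselError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(DietselError, ValueError):
    """A config field is missing, out of range, or inconsistent."""


class DataError(DietselError, ValueError):
    """An input table violates a data contract (missing sample, bad group...)."""


class DegenerateSampleError(DataError):
    """A sample vector is constant or too short for the requested statistic."""


class DegenerateVariableError(DataError):
    """A variable has zero variance (cannot be scaled or correlated)."""


class AlignmentError(DataError):
    """Two objects that must share a variable universe do not."""


class PreconditionError(DietselError, ValueError):
    """An operation's structural precondition is violated (e.g. curve not sorted)."""
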
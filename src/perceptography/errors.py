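"""Exception hierarchy for the perceptography pipeline."""


class PerceptographyError(Exception):
    """Base class for all package errors."""


class ParameterError(PerceptographyError):
    """An argument or latent-parameter invariant was violated.

    The message names the offending field.
    """


class SchedulingError(PerceptographyError):
    """A session schedule cannot satisfy its presentation constraints."""


class DataError(PerceptographyError):
    """An artifact (image id, trial log, checkpoint) is missing or inconsistent."""


class ValidationError(PerceptographyError):
    """A campaign configuration violates one or more documented invariants."""
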
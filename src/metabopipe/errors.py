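"""Exception hierarchy shared across the package."""


class MetaboPipeError(Exception):
    """Base class for all package errors."""


class ValidationError(MetaboPipeError):
    """A data-model invariant was violated.

    ``violations`` carries one human-readable record per broken rule.
    """

    def __init__(self, message, violations=None):
        self.violations = list(violations) if violations else [message]
        if violations:
            message = f"{message}: " + "; ".join(self.violations)
        super().__init__(message)


class FormatError(MetaboPipeError):
    """A file could not be parsed as the expected external format."""


class PipelineError(MetaboPipeError):
    """A pipeline step was invoked with missing or inconsistent inputs."""
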
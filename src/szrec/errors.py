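"""Exception types shared across the pipeline stages."""


class ConfigurationError(ValueError):
    """A configuration value is invalid; the message names the offending field."""


class ContractError(RuntimeError):
    """A documented precondition or postcondition was violated by a caller or plugin."""


class DatasetFormatError(ValueError):
    """A serialized dataset file failed schema validation.

    Carries the file, line number and field that failed so broken exports can
    be located without a debugger.
    """

    def __init__(self, file: str, line: int, field: str, message: str):
        self.file = file
        self.line = line
        self.field = field
        super().__init__(f"{file}:{line}: field '{field}': {message}")


class DependencyError(RuntimeError):
    """An upstream stage artifact is missing; the message names the stage."""


class SingleClassError(ValueError):
    """An operation needing both classes received labels of a single class."""
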
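"""Exception hierarchy shared across the package."""


class CotargetError(Exception):
    """Base class for all package errors."""


class ParseError(CotargetError):
    """A file could not be parsed under the named dialect.

    Carries the offending line number where available.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)


class ValidationError(CotargetError):
    """Input values violate a documented invariant."""


class UsageError(CotargetError):
    """A parameter is outside its documented domain."""
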
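"""Shared exception types."""


class CnaphaseError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(CnaphaseError, ValueError):
    """A configuration value violates its documented invariant."""


class DegenerateProfileError(CnaphaseError, ValueError):
    """A per-cell profile cannot be processed (e.g. all-zero counts)."""


class FormatError(CnaphaseError, ValueError):
    """A file does not conform to its declared format.

    Carries the offending path and, where known, the 1-based line number.
    """

    def __init__(self, message: str, path=None, line=None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
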
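"""Exception hierarchy.

Every error carries a stable ``code`` string so CLI and log output can be
matched programmatically; messages are for humans.
"""

from __future__ import annotations


class DynacheckError(Exception):
    """Base class for all package errors."""

    code = "ERROR"

    def __init__(self, message: str, **info):
        super().__init__(message)
        self.info = info

    def __str__(self) -> str:  # pragma: no cover - trivial
        base = super().__str__()
        return f"[{self.code}] {base}"


class ParseError(DynacheckError):
    """Raised by the rule-DSL / expression parsers; carries line and column."""

    code = "PARSE_ERROR"

    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


class DuplicateRuleIdError(DynacheckError):
    code = "DUPLICATE_RULE_ID"


class TypeMismatchError(DynacheckError):
    code = "TYPE_MISMATCH"


class RuleCycleError(DynacheckError):
    code = "RULE_CYCLE"


class DanglingRefError(DynacheckError):
    code = "DANGLING_REF"


class InvalidModelError(DynacheckError):
    code = "INVALID_MODEL"


class NotEnabledError(DynacheckError):
    code = "NOT_ENABLED"


class RoleMismatchError(DynacheckError):
    code = "ROLE_MISMATCH"


class TooLargeError(DynacheckError):
    code = "TOO_LARGE"


class DanglingItemRefError(DynacheckError):
    code = "DANGLING_ITEM_REF"


class UnknownFormatError(DynacheckError):
    code = "UNKNOWN_FORMAT"


class NoOptionsError(DynacheckError):
    code = "NO_OPTIONS"


class BadOptionError(DynacheckError):
    code = "BAD_OPTION"


class UnsupportedElementError(DynacheckError):
    code = "UNSUPPORTED_ELEMENT"


class SchemaViolationError(DynacheckError):
    code = "SCHEMA_VIOLATION"

    def __init__(self, message: str, pointer: str):
        super().__init__(f"{message} (at {pointer})")
        self.pointer = pointer
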
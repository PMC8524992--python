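"""Exception hierarchy shared across the package."""

from __future__ import annotations


class CandexError(Exception):
    """Base class for all package errors."""


class ConfigError(CandexError):
    """Config file missing, unreadable, or malformed."""


class ValidationError(CandexError):
    """A value failed validation; message names the offending key."""


class SchemaError(CandexError):
    """An input table lacks a required column or has the wrong shape."""


class ParseError(CandexError):
    """A cell could not be parsed; message carries row/column coordinates."""


class DuplicateIDError(CandexError):
    """An identifier that must be unique appears more than once."""


class NotFoundError(CandexError, KeyError):
    """Lookup of an identifier failed.

    Carries ``suggestions``: exact-prefix matches from the index that may be
    what the caller meant.
    """

    def __init__(self, query: str, suggestions: list[str] | None = None):
        self.query = query
        self.suggestions = list(suggestions or [])
        msg = f"identifier not found: {query!r}"
        if self.suggestions:
            msg += f" (nearest prefix matches: {', '.join(self.suggestions[:5])})"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError would repr() the args tuple
        return self.args[0]


class MergeError(CandexError):
    """Dataset merge produced an empty or unusable result."""


class CapabilityMissingError(CandexError):
    """An accessor needs a dataset that is not loaded in this store."""
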
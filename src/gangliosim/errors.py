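"""Exception hierarchy for gangliosim."""

from __future__ import annotations


class GangliosimError(ValueError):
    """Base class for all errors raised by this package."""


class GlycanParseError(GangliosimError):
    """A structure identifier (or external notation) could not be parsed.

    Carries the offending text and, where known, the 0-based character
    position at which parsing failed.
    """

    def __init__(self, message: str, text: str | None = None, position: int | None = None):
        self.text = text
        self.position = position
        if text is not None and position is not None:
            message = f"{message} (in {text!r} at position {position})"
        elif text is not None:
            message = f"{message} (in {text!r})"
        super().__init__(message)


class UnclassifiableStructureError(GangliosimError):
    """The structure is not generated by the ganglioside grammar.

    Raised instead of silently mis-assigning core positions; the message
    names the offending feature.
    """


class PatternError(GangliosimError):
    """An acceptor pattern is malformed (unbalanced brackets, misplaced wildcard)."""


class InvalidKnockoutError(GangliosimError):
    """A knockout refers to an enzyme number absent from the rule set."""


class NoNameError(GangliosimError):
    """No systematic Svennerholm name is defined for this structure.

    Applies to bare ceramide and to glucosylceramide, which precede the
    naming system's cores.
    """


class NameParseError(GangliosimError):
    """A Svennerholm name is malformed or internally inconsistent."""


class UnreachableTargetError(GangliosimError):
    """The target glycan cannot be derived under the given enzyme rule set.

    ``blocked`` holds the canonical identifier of the first intermediate
    found to have no admissible precursor.
    """

    def __init__(self, message: str, blocked: str):
        self.blocked = blocked
        super().__init__(message)
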
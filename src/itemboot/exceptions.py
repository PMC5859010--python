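"""Typed errors raised by itemboot.

All inherit from :class:`ItembootError` so callers can catch the package's
failures with a single except clause; each also subclasses ``ValueError``
because every one of them signals invalid input rather than internal state.
"""


class ItembootError(ValueError):
    """Base class for all itemboot errors."""


class BoundsError(ItembootError):
    """A response value lies outside the declared scale bounds."""

    def __init__(self, message: str, respondent_id=None, item=None):
        super().__init__(message)
        self.respondent_id = respondent_id
        self.item = item  # 1-based item label/position where known


class UndefinedAlphaError(ItembootError):
    """Cronbach's alpha is undefined (zero total-score variance)."""


class DegenerateResponseError(ItembootError):
    """All item responses identical: the bootstrap score distribution is a
    constant and no confidence interval exists."""

    def __init__(self, respondent_id=None, occasion=None):
        self.respondent_id = respondent_id
        self.occasion = occasion
        where = f" (respondent {respondent_id!r}" if respondent_id is not None else ""
        if where and occasion is not None:
            where += f", occasion {occasion!r}"
        if where:
            where += ")"
        super().__init__(
            "constant response vector: bootstrap distribution is degenerate"
            + where
        )


class InputFormatError(ItembootError):
    """A response file violates the expected layout (missing cells,
    non-integer values, duplicated ids, wrong column count)."""
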
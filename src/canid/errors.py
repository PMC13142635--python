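"""Exception hierarchy shared across the package.

Validation errors always identify the offending session (and trial, where
applicable) so that problems in hand-entered data sheets can be located.
"""

from __future__ import annotations


class CanidError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CanidError):
    """A file does not match the expected CSV dialect (e.g. missing column)."""


class ValidationError(CanidError):
    """Data violates a protocol invariant.

    Parameters
    ----------
    message : str
        Human-readable description of the violation.
    dog_id, timepoint, index : optional
        Location of the violation, included in the message when given.
    """

    def __init__(self, message, dog_id=None, timepoint=None, index=None):
        loc = []
        if dog_id is not None:
            loc.append(f"dog_id={dog_id}")
        if timepoint is not None:
            loc.append(f"timepoint={timepoint}")
        if index is not None:
            loc.append(f"trial index={index}")
        if loc:
            message = f"{message} [{', '.join(loc)}]"
        super().__init__(message)
        self.dog_id = dog_id
        self.timepoint = timepoint
        self.index = index


class FittingError(CanidError):
    """A model could not be fitted (e.g. too few complete cases)."""


class InsufficientDataError(FittingError):
    """Not enough observations for the requested estimate."""


class NotFittedError(CanidError):
    """A frozen scoring model was used before being fitted."""
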
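"""Exception types shared across the landscape machinery."""

from __future__ import annotations


class KTNError(Exception):
    """Base class for package errors."""


class NonConvergenceError(KTNError):
    """An iterative search hit its iteration cap; carries the best point."""

    def __init__(self, message, coords=None, energy=None, rms=None):
        super().__init__(message)
        self.coords = coords
        self.energy = energy
        self.rms = rms


class PathologyError(KTNError):
    """A descent diverged (energy below floor or coordinates unbounded)."""


class SaddleIndexError(KTNError):
    """A saddle search converged to a point that is not index-1."""

    def __init__(self, message, n_negative=None, coords=None):
        super().__init__(message)
        self.n_negative = n_negative
        self.coords = coords


class NotConnectedError(KTNError):
    """No path exists between the requested endpoints."""


class ReferentialIntegrityError(KTNError):
    """A transition state references a minimum id absent from the network."""


class KTNParseError(KTNError):
    """Malformed network file; carries the offending line number."""

    def __init__(self, message, line_number=None):
        super().__init__(message)
        self.line_number = line_number
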
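"""Exception hierarchy shared across the toolkit.

Exit-code mapping used by the CLI: :class:`InputError` -> 2,
:class:`ConvergenceError` / :class:`AmbiguityError` -> 3.
"""


class UvkitError(Exception):
    """Base class for all toolkit errors."""


class InputError(UvkitError):
    """Malformed or inconsistent user input (bad file, bad grid, bad config)."""


class GridMismatchError(InputError):
    """Binary spectrum operation on differing wavelength grids.

    Spectra must be brought onto a common grid explicitly (``resample``)
    before subtraction or comparison; no silent interpolation is performed.
    """


class DomainError(InputError):
    """Parameter outside the physically meaningful domain."""


class SaturationError(UvkitError):
    """Observed proportion of differing sites p >= 1: the Poisson
    correction -ln(1-p) diverges and the distance is undefined."""


class ConvergenceError(UvkitError):
    """A nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_params=None, residual=None):
        super().__init__(message)
        self.last_params = last_params
        self.residual = residual


class AmbiguityError(UvkitError):
    """A genomic query resolved to several equally good candidates."""

    def __init__(self, message, candidates=()):
        super().__init__(message)
        self.candidates = list(candidates)
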
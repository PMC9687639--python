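"""Typed exceptions shared across the package."""


class SacIsolateError(Exception):
    """Base class for all package errors."""


class MeshIOError(SacIsolateError):
    """A mesh or field file could not be read or written."""


class MeshValidationError(SacIsolateError):
    """Input data violates a structural invariant (names the invariant)."""


class FitError(SacIsolateError):
    """Fourier-series fit failed to converge within the restart budget.

    Carries the best RMSE (mm) reached so callers can report diagnostics.
    """

    def __init__(self, message: str, best_rmse: float = float("nan")):
        super().__init__(message)
        self.best_rmse = best_rmse


class NoSacDetectedError(SacIsolateError):
    """The silhouette has no curvature change to delimit (e.g. a straight tube)."""


class SacIsolationError(SacIsolateError):
    """Whole-surface sac isolation failed; carries per-projection diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class MaterialRangeError(SacIsolateError):
    """A strain-energy exponential overflowed; names the offending term."""
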
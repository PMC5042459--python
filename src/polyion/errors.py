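"""Exception hierarchy for polyion analyses."""


class PolyionError(Exception):
    """Base class for all polyion errors."""


class InvalidGeometryError(PolyionError, ValueError):
    """Scattering geometry outside its physical domain."""


class InvalidModelError(PolyionError, ValueError):
    """A relaxation-mode model that cannot be evaluated."""


class DegenerateInputError(PolyionError, ValueError):
    """Input data carry no usable signal (e.g. constant correlation trace)."""


class FitFailureError(PolyionError, RuntimeError):
    """Optimization failed to converge; carries the best candidate found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class DegenerateFitError(PolyionError, ValueError):
    """A fit whose parameters admit no further interpretation (all-zero amplitudes)."""


class InsufficientDataError(PolyionError, ValueError):
    """Fewer observations than the analysis requires."""


class AssociationDominatedError(PolyionError, ValueError):
    """Dilute-solution virial form does not hold over the requested fit range."""


class UnsolvableDesignError(PolyionError, ValueError):
    """Forward titration design admits no electroneutral pH in the bracket."""


class SchemaError(PolyionError, ValueError):
    """Tabular input does not match the expected column schema."""
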
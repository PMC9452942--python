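"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A configuration or call parameter is outside its valid domain."""


class DegenerateStainError(ValueError):
    """A stain absorbance row is zero and cannot be normalized."""


class SingularStainMatrixError(ValueError):
    """Stain rows are linearly dependent; deconvolution is undefined."""


class InvalidAnnotationError(ValueError):
    """A nucleus annotation falls outside the image or map bounds."""


class SpecViolationError(ValueError):
    """Layer shapes in a network specification do not chain consistently."""


class LayoutBudgetError(RuntimeError):
    """Rejection sampling could not place the requested nuclei."""
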
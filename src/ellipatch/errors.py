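"""Exception types shared across the package."""


class SpecError(ValueError):
    """An ellipsoid patch specification violates an invariant."""


class DomainError(ValueError):
    """A point lies outside the domain of the requested operation."""


class ShapeBranchError(ValueError):
    """The requested sampler/formula branch does not match the patch shape."""


class QuadratureError(RuntimeError):
    """Numerical quadrature failed to reach the requested accuracy."""
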
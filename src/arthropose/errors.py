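"""Exception hierarchy for the arthropose toolbox."""


class ArthroposeError(Exception):
    """Base class for all toolbox errors."""


class ValidationError(ArthroposeError):
    """A model, mesh, or parameter set violates its invariants."""


class ParseError(ArthroposeError):
    """A keyword or mesh file could not be parsed."""

    def __init__(self, message, path=None, line=None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += str(path)
        if line is not None:
            prefix += f":{line}"
        if prefix:
            message = f"{prefix}: {message}"
        super().__init__(message)


class DegenerateGeometryError(ArthroposeError):
    """Input geometry is degenerate for the requested fit or solve."""


class NonConvergenceError(ArthroposeError):
    """An iterative solve exhausted its iteration budget."""

    def __init__(self, message, residual=None):
        self.residual = residual
        if residual is not None:
            message = f"{message} (last residual: {residual:.3e})"
        super().__init__(message)


class NonPositiveCurvatureError(ArthroposeError):
    """Condyle surface is locally flat or concave at a contact point."""

    def __init__(self, compartment, kappa):
        self.compartment = compartment
        self.kappa = kappa
        super().__init__(
            f"non-positive normal curvature ({kappa:.3e} 1/mm) at the "
            f"{compartment} contact point"
        )


class DegenerateAxisError(ArthroposeError):
    """The two helical-axis intersection points coincide."""


class PenetrationError(ArthroposeError):
    """Penetration resolution failed; carries the residual report."""

    def __init__(self, message, report=None):
        self.report = report
        super().__init__(message)
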
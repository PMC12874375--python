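"""Exception hierarchy shared across the package."""


class QpelError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(QpelError, ValueError):
    """An input parameter is outside its valid domain."""


class SingularGeometryError(QpelError):
    """Two interaction sites (nearly) coincide; the potential is singular."""


class StructureError(QpelError):
    """Inconsistent structural data (bead counts, site counts, shapes)."""


class SelectionError(QpelError, KeyError):
    """An atom/species selection matched nothing."""


class IntegrationFailureError(QpelError):
    """The integrator produced non-finite or exploding energies."""

    def __init__(self, step: int, message: str = ""):
        self.step = step
        super().__init__(f"integration failed at step {step}: {message}")


class ConvergenceError(QpelError):
    """A minimization hit its iteration cap; carries the best state found."""

    def __init__(self, message: str, best=None):
        self.best = best
        super().__init__(message)


class NotAMinimumError(QpelError):
    """A Hessian has more negative directions than the 3 allowed zero modes."""


class SamplingError(QpelError):
    """A trajectory is too short/degenerate for the requested sampling."""


class RankError(QpelError):
    """A regression design matrix is (numerically) rank deficient."""


class NoRootError(QpelError):
    """A bracketing root search found no sign change in the window."""

    def __init__(self, lo, hi, f_lo, f_hi):
        self.bounds = (lo, hi)
        self.values = (f_lo, f_hi)
        super().__init__(
            f"no sign change in [{lo}, {hi}]: f(lo)={f_lo:.6g}, f(hi)={f_hi:.6g}"
        )


class AssemblyError(QpelError):
    """A thermodynamic assembly is missing a fitted component."""


class ParseError(QpelError):
    """Malformed table or structure file; carries the offending record."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        loc = f" (line {line})" if line is not None else ""
        super().__init__(message + loc)
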